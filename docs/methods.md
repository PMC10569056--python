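# Methods

## Unit system and constants

All internal quantities use eV (energy), Å (length), amu (mass), fs
(time) and K (temperature); β = 1/(k_B T) is in eV⁻¹. Mass-weighted
coordinates x√m carry Å·√amu. The only nontrivial conversion is between
eV and the mechanical energy unit amu·Å²/fs² (1 eV ≈ 9.6485×10⁻³
amu·Å²/fs²); it enters when Hessian eigenvalues (eV Å⁻² amu⁻¹) are
turned into frequencies in fs⁻¹ and when thermal widths are expressed in
Å·√amu. `transtube --version` prints the constants table; conversions
round-trip to 1e-12.

## Harmonic thermal sampling

Normal-mode analysis diagonalizes M^(−1/2) H M^(−1/2). Eigenvalues λ_i
map to signed frequencies ω_i = sign(λ_i)·√|λ_i| — an imaginary mode is
stored as a negative ω of the same magnitude, keeping all types real.
Modes with |ω| below `zero_mode_threshold` (default 1e-4 fs⁻¹ ≈ 0.5
cm⁻¹) are flagged flat and excluded from the internal set. An optional
`n_zero_expected` check (6 for nonlinear molecules, 5 for linear ones)
turns a silent miscount — which would corrupt every thermal width — into
an error. Note that for confined model systems the count differs from
the molecular 6/5: the shipped 2D double-well potential is not
translation-invariant, so a particle on it has exactly one flat
direction (z) at the minima and two at the degenerate barrier top.

Thermal widths per mode: classical σ² = 1/(βω²); quantum
σ² = (ħ/2ω)·coth(βħω/2) = 1/(β\*ω²) with
β\* = (2/ħω)·tanh(βħω/2). The quantum width is implemented through the
same Gaussian sampler with the mode-dependent effective temperature, so
quantum candidate generation costs the same as classical. At T = 0 the
classical width vanishes and the quantum one becomes the zero-point
width √(ħ/2ω). Assumption inherited from the harmonic picture: the
auxiliary ensemble is only a *coverage device* for candidate generation,
never used for expectation values, so anharmonicity of the real surface
matters only insofar as coverage degrades.

Sampling draws one seeded `numpy` Generator stream per candidate set;
candidate sets are bitwise reproducible from (inputs, seed).

## Minimum-energy paths

CI-NEB uses the energy-weighted upwind tangent, a constant spring
(default 4.86 eV/Å²), 15 images with linearly interpolated
initialization, and a force criterion of 0.007 eV/Å by default —
standard values for molecular work. Two deliberate numerical choices:

- **Symmetry-breaking bump.** A linear interpolation that lies exactly
  on a symmetry ridge of the surface is a (unstable) fixed point of the
  NEB dynamics and would converge onto a maximum instead of falling
  into the reaction channel. The initial band therefore receives a tiny
  deterministic transverse half-sine bump (default 1e-3 Å) along a
  fixed pseudo-random direction orthogonal to the band; on surfaces
  where the straight line already is the MEP the bump simply relaxes
  away.
- **Conditional climbing.** The climbing image is activated only while
  the global band maximum is an interior image; on a barrier-less
  profile a climbing image would be driven uphill without bound.
- The FIRE-style optimizer caps dt at 0.15 fs-equivalent so the
  integrator is stable for curvatures up to ~100 eV/Å² per unit mass,
  and caps per-image moves at 0.1 Å.

The discrete band becomes a continuous path by componentwise natural
cubic splines over the chordal parameter, reparametrized to normalized
Cartesian arc length on a dense grid (the knots are included in the
grid, so input frames are reproduced exactly). ‖dR/dξ‖ deviates from L
by <1e-3 relative. ξ and the linear sampling density (Å⁻¹) are defined
in the plain Cartesian configuration-space metric — the only reading
under which a density per Å is well defined. Tangents and the
perpendicular projector Q = 1 − ττᵀ, however, act in *mass-weighted*
coordinates, consistent with the normal-mode inner product used for the
distortions (for unit masses the metrics coincide). Multi-atom paths
are stored after sequential mass-weighted Kabsch alignment to the first
frame so rigid-body motion cannot masquerade as internal displacement;
single-particle model systems are left untouched (their potentials are
not translation-invariant).

## Transition tube construction

Control-point placement is user-supplied, typically {0, ξ_TS, 1}; the
code never auto-places. Parent weights are cos²/sin² ramps between
neighboring control points — the simplest complementary pair summing to
unity exactly (any such pair would do); the first/last control point
keeps weight 1 on overhangs. The number of on-path references is
round(ρ·L). Each reference is distorted with its parent's *real*
internal modes only (zero and imaginary modes omitted), projected with
Q(ξ): local harmonic expansions carried away from their origin are
corrected by enforcing exact perpendicularity, while the decaying
p_c(ξ) keeps modes near their origin. No Hessian interpolation between
control points is attempted. Gaussians are untruncated by default (a
configurable n-σ clip exists for high-temperature use).

**Endpoint caps.** The open tube ends are sealed with plain NMS samples
at the endpoint minima, keeping only displacements whose mass-weighted
projection on the outward tangent is ≥ 0. The retained count per
endpoint is N_cap = ρ_mw·√(π/2)·σ_τ, which equates the half-Gaussian's
peak linear density along the tangent, N_cap·√(2/π)/σ_τ, to the on-path
density ρ_mw (the Cartesian density ρ converted to the mass-weighted
metric at the endpoint). σ_τ is the exact width of the NMS displacement
projected on the tangent, σ_τ² = Σ_i σ_i²⟨τ, Ω_i⟩² — exact for the
Gaussian ensemble, and equal to the single-mode width whenever the
tangent is an eigenmode. (A nearest-mode proxy was considered and
rejected: it breaks the density-continuity contract whenever the
tangent mixes modes.) At classical T = 0 the caps are empty.

With a single control point (zero path length) the tube sampler reduces
*bitwise* to plain NMS with the same seed; the degenerate branch
requires an explicit sample count since no length×density arithmetic
exists there.

## The 2D model potential

V(x,y) = (1/6)·{4(1−x²−y²)² + 2(x²−2)² + [(x+y)²−1]² + [(x−y)²−1]² − 2},
treated as a single unit-mass particle in the xy-plane so the entire
pipeline runs on it unchanged. Exact stationary points: minima at
(±√5/2, 0) with V = −1/12, a maximum at (0,0) with V = 2, and two
symmetry-related barrier tops at (0, ±1) with V = 1 whose Hessian
eigenvalues are exactly {0, 8}: along the relaxed path
V ≈ 1 − (13/9)x⁴, a *degenerate* (quartic) saddle. Consequences used
throughout the tests:

- exactly at the barrier top there is no negative Hessian eigenvalue;
  the converged climbing image sits a numerically small distance off
  the top, where the relaxed curvature is resolvably negative — so a
  converged CI-NEB still reports an index-1 point;
- the soft direction at the ξ = 0.5 control point must be flagged flat
  (zero-mode threshold 1e-3 fs⁻¹ for this system), not sampled
  thermally.

## Committee models and active learning

The QbC loop is model-agnostic: members implement `fit(labeled)` /
`predict(geometry) → (E, F)`. The per-structure score is the mean over
(masked) atoms of the Euclidean norm of the componentwise population
standard deviation of member forces; the mask default is all atoms, and
selection uses forces only. Ties break toward the lower candidate
index. Retraining is from scratch each iteration; selected candidates
leave the pool, so nothing is labeled twice and the fixed schedules
have exact arithmetic (e.g. 20 + 40×10 = 420). The optional stopping
rule halts when mean(selected)/mean(remaining) ≤ 1.5 (boundary
inclusive, checked before labeling); the threshold is configurable
because "similar" has no canonical value, and the default errs toward a
few extra iterations.

The shipped reference model is RBF kernel ridge on flattened Cartesians
(or interatomic distances, rotation-invariant, with analytic feature
Jacobians), energies fit and forces obtained as the analytic negative
gradient of the surrogate. It exists so the loop is testable end to
end; it is *not* a neural-network potential. For the toy-scale
QbC-vs-random study the committee uses eight full-data members
diversified by ±30% kernel-width jitter around γ = 10 Å⁻²
(lengthscale ≈ 0.22 Å, matched to the 300 K tube: width ~0.05 Å, path
3.2 Å) with ridge 1e-6: at a few dozen training points, subset
resampling mostly injects noise, whereas lengthscale sensitivity makes
the committee disagreement a clean indicator of data sparsity, which is
the signal the selection rule needs. The production default remains
90% subsets per member, the standard protocol at realistic training-set
sizes. One structure is labeled per iteration in the study (a
compromise between the greedy optimum and iteration count; production
schedules use 10–15).

Guaranteed property, tested every run: the committee-mean energy RMSE
on any held-out set never exceeds the worst member's (Jensen).

## What the generators emulate — and what they do not

The analytic calculators (2D double-well, N-D harmonic) stand in for
the ab initio engines that label structures in production. They
exercise every numerical pathway — Hessians, NEB, thermal widths,
projections, labeling — with exact oracles, so passing tests establish
the *sampling constructions and the loop logic*, not chemical accuracy:
no electronic-structure effects, no anharmonic coupling between modes,
no rotational/conformational congestion, and system sizes of 1–2
particles. The harmonic straight-tube fixture has, by construction, a
constant Hessian, so harmonic-limit tests verify exact Gaussian moment
identities rather than robustness to curvature variation along real
paths. The replay calculator bridges to reality by serving
pre-computed labels from file without live coupling.

## Default study sizes

Statistical contracts use n = 1e5 draws for width calibration (2%
tolerance ≈ 4–5 sampling σ), n = 1e4 for tube-moment and histogram
checks (5–10% tolerances), and 20 seeded repeats for the QbC-vs-random
comparison; the full acceptance script runs in about a minute on one
CPU. These sizes were chosen so that the stated tolerances sit several
sampling standard deviations away from the expected fluctuation scale.

## Known limitations

- No periodic systems, no PDB/CIF, no trajectory formats beyond
  multi-frame (ext)XYZ; Hessians as plain text only.
- Local harmonic expansions are used exactly as computed at their
  control point (no interpolation along ξ); very sparse control points
  on strongly curved paths degrade the tube's thermal fidelity.
- The half-Gaussian cap construction presumes the endpoints are true
  minima; shared-endpoint (cyclic) paths are unsupported.
- The quantum widths are the harmonic closed form; no path-integral
  sampling and no anharmonic corrections.
- NEB offers a single spring constant and no variable-spring/free-end
  variants; the string method is out of scope.
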