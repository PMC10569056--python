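# transtube

Training-set generation for machine-learning potentials (MLPs) of
**reactive molecules**: thermal normal-mode sampling (NMS), transition
tube sampling (TTS) along minimum-energy paths, and query-by-committee
(QbC) active learning — all exercisable end to end on analytic
potentials, with a pluggable calculator contract for real electronic-
structure labels.

## The problem

An MLP is only as good as its training set. For a molecule with a single
minimum, thermally distributed training geometries can be drawn at
negligible cost from the harmonic ensemble: diagonalizing the
mass-weighted Hessian gives frequencies ω_i and normal modes **Ω**_i,
and each normal coordinate Ω_i is an independent Gaussian with

- classical width σ_i² = 1/(β ω_i²), β = 1/k_BT,
- quantum width σ_i² = (ħ/2ω_i)·coth(βħω_i/2) ≡ 1/(β*_i ω_i²),

where β*_i = (2/ħω_i)·tanh(βħω_i/2) is the mode's *quantum effective
inverse temperature* — the classical temperature at which a classical
oscillator matches the quantum thermal width. Sampling Ω_i and
back-transforming, **R** = **R**₀ + M^(−1/2) Σ_i Ω_i **Ω**_i, yields
fully decorrelated thermal geometries.

Reactive systems break this picture: multiple minima joined by
minimum-energy paths (MEPs), with transition regions that a thermal
ensemble (and hence any training set drawn from it) grossly
under-represents. **Transition tube sampling** fixes this by sampling
*uniformly along* the MEP and *thermally perpendicular* to it:

1. converge a climbing-image NEB band between the reactant and product
   minima and fit a continuous, arc-length-parametrized spline
   **R**(ξ), ξ ∈ [0, 1];
2. compute Hessians at a sparse set of user-chosen control points ξ_c
   (typically the two minima and the transition state) to get local
   modes Ω_{c,i};
3. draw reference points uniformly in ξ and assign each a parent
   control point through cos²/sin² weights p_c(ξ) that form a partition
   of unity (Σ_c p_c ≡ 1);
4. distort each reference with thermally drawn local normal-mode
   amplitudes, projected strictly perpendicular to the path,
   **R** = **R**₀(ξ) + M^(−1/2) Q(ξ) Σ′_i Ω_{c,i} **Ω**_{c,i},
   Q = 1 − ττᵀ (imaginary modes omitted);
5. seal the open tube ends with half-Gaussian NMS caps whose peak
   density matches the on-path density.

The resulting candidate pool is screened by **query by committee**: a
committee of surrogate models is retrained each iteration, every
remaining candidate is scored by the standard deviation of the members'
force predictions, and the most-disputed structures are labeled with the
reference calculator and added to the training set. The loop
concentrates expensive labeling on exactly the configurations the
current model understands least.

## Worked example

```python
import transtube as tt
from transtube.mep import fit_mep_spline
from transtube.tts import build_control_points, tts_generate
from transtube.qbc import CommitteeSpec, KernelRidgeModel, qbc_run

calc = tt.Toy2D()                       # analytic 2D double-well
a = tt.relax(calc, tt.Geometry(["X"], [[-1.1, 0.05, 0]]), f_tol=1e-9)
b = tt.relax(calc, tt.Geometry(["X"], [[ 1.1, 0.05, 0]]), f_tol=1e-9)
band = tt.neb_optimize(calc, a, b, f_tol=1e-4)        # CI-NEB, 15 images
mep  = fit_mep_spline(band)
cps  = build_control_points(mep, [0, 0.5, 1], calc, zero_mode_threshold=1e-3)
cands = tts_generate(mep, [0, 0.5, 1], calc, tt.ThermalSpec(300.0),
                     linear_density=300.0, seed=7, control_points=cps)
print(len(cands))
```

Running `python examples/04_transition_tube_sampling.py` prints

```
path length L = 3.179 Å, density 300 /Å
1010 candidates: 954 on-path, 56 caps
perpendicular tube width (rms): 0.0521 Å·√amu
```

i.e. round(300 × 3.179) = 954 uniformly placed on-path geometries plus
56 half-Gaussian cap samples whose count matches the on-path linear
density, with a 300 K thermal tube width of ≈0.05 Å. The climbing image
of the band sits at (0, −1.000) with barrier 1.083 above the minima
(`examples/02_cineb_saddle_search.py`), and the QbC loop in
`examples/05_qbc_active_learning.py` shows the selected force
disagreement decaying toward the pool mean as the committee's weak
regions are filled.

The same stages are available as a CLI for file-based workflows:
`transtube minimize | neb | modes | nms | tts | qbc | pipeline`
(see `transtube --version` for the internal unit system: eV, Å, amu,
fs, K).

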