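"""Transition tube sampling: thermally distorted candidates along an MEP.

The sampler draws reference geometries uniformly along the continuous
path R(ξ), assigns each to a parent control point through the
partition-of-unity weights p_c(ξ), displaces it with thermal normal-mode
amplitudes drawn from the parent's local harmonic expansion, projects the
displacement strictly perpendicular to the path, and finally closes the
open tube ends with half-Gaussian normal-mode caps at the endpoint minima
whose peak linear density matches the on-path density.

In the zero-path-length limit (a single control point) the procedure
degenerates exactly to plain thermal normal-mode sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calculators import Calculator, numerical_hessian
from .geometry import CandidateSet, Geometry, Provenance
from .harmonic import (
    NormalModeSet,
    ThermalSpec,
    mode_sigma,
    normal_mode_analysis,
    nms_sample,
)
from .mep import ContinuousMEP, tangent


@dataclass
class ControlPoint:
    """A point on the MEP carrying a local harmonic expansion.

    ``index`` is the 0-based position in the (strictly ξ-increasing)
    control-point list; ``modes`` holds the local normal-mode set at
    R(ξ_c).  Endpoint control points must be true minima (no imaginary
    internal modes); interior ones may sit at transition states.
    """

    index: int
    xi: float
    geometry: Geometry
    modes: NormalModeSet

    @property
    def n_imaginary(self) -> int:
        return self.modes.n_imaginary


def build_control_points(
    mep: ContinuousMEP,
    xi_list,
    calc: Calculator,
    displacement: float = 0.0005,
    zero_mode_threshold: float = 1e-4,
    n_zero_expected: int | None = None,
) -> list[ControlPoint]:
    """Compute Hessians and local modes at user-chosen positions ξ_c.

    ``xi_list`` must be strictly increasing, span [0, 1] (include both
    endpoints) — control-point placement is deliberately user-supplied,
    never silently automatic.  Raises if an endpoint carries imaginary
    internal modes: the tube ends must be minima for the caps to make
    sense.
    """
    xi_arr = np.asarray(list(xi_list), dtype=float)
    if xi_arr.size < 1:
        raise ValueError("need at least one control point")
    if np.any(np.diff(xi_arr) <= 0):
        raise ValueError("xi_list must be strictly increasing")
    if np.any((xi_arr < 0) | (xi_arr > 1)):
        raise ValueError("control points must lie within [0, 1]")
    if xi_arr.size >= 2 and (xi_arr[0] != 0.0 or xi_arr[-1] != 1.0):
        raise ValueError("xi_list must include the endpoints 0 and 1")
    points: list[ControlPoint] = []
    for c, xi in enumerate(xi_arr):
        g = mep.geometry(float(xi))
        h = numerical_hessian(calc, g, displacement=displacement)
        modes = normal_mode_analysis(
            h,
            g.masses,
            g,
            zero_mode_threshold=zero_mode_threshold,
            n_zero_expected=n_zero_expected,
        )
        if c in (0, xi_arr.size - 1) and modes.n_imaginary:
            raise ValueError(
                f"endpoint control point at xi={xi} has "
                f"{modes.n_imaginary} imaginary mode(s); endpoints must be minima"
            )
        points.append(ControlPoint(index=c, xi=float(xi), geometry=g, modes=modes))
    return points


def control_point_weights(xi, xi_centers) -> np.ndarray:
    """Partition-of-unity weights p_c(ξ) of each control point at ξ.

    Squares of harmonic functions on the intervals between neighboring
    control points: on [ξ_c, ξ_{c+1}], p_c = cos²(u·π/2) and
    p_{c+1} = sin²(u·π/2) with u the fractional position, so the weights
    sum to one identically; p_c peaks at 1 at its own ξ_c and vanishes
    outside [ξ_{c−1}, ξ_{c+1}].  The first/last control point carries
    weight 1 on any overhang toward ξ = 0 / ξ = 1.

    ``xi`` may be a scalar or an array; returns shape ``(..., N_p)``.
    """
    centers = np.asarray(list(xi_centers), dtype=float)
    if centers.size == 0:
        raise ValueError("need at least one control point")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("control point positions must be strictly increasing")
    xi_in = np.asarray(xi, dtype=float)
    scalar = xi_in.ndim == 0
    xi_flat = np.atleast_1d(xi_in).ravel()
    if np.any((xi_flat < 0) | (xi_flat > 1)):
        raise ValueError("xi must lie in [0, 1]")
    n_p = centers.size
    w = np.zeros((xi_flat.size, n_p))
    if n_p == 1:
        w[:, 0] = 1.0
    else:
        seg = np.clip(np.searchsorted(centers, xi_flat, side="right") - 1, -1, n_p - 1)
        for k in range(xi_flat.size):
            s = seg[k]
            if s < 0:  # overhang before the first control point
                w[k, 0] = 1.0
            elif s == n_p - 1:  # at or past the last control point
                w[k, n_p - 1] = 1.0
            else:
                u = (xi_flat[k] - centers[s]) / (centers[s + 1] - centers[s])
                w[k, s] = math.cos(0.5 * math.pi * u) ** 2
                w[k, s + 1] = math.sin(0.5 * math.pi * u) ** 2
    out_shape = (np.atleast_1d(xi_in)).shape + (n_p,)
    return w[0] if scalar else w.reshape(out_shape)


def sample_reference_points(
    mep: ContinuousMEP,
    control_points: list[ControlPoint],
    linear_density: float,
    seed=None,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, int]]:
    """Uniform on-path reference positions with parent assignments.

    Draws ``n = round(linear_density · L)`` values of ξ uniformly on
    [0, 1] (L is the Cartesian arc length, so ``linear_density`` is in
    Å⁻¹) and assigns each a parent control point with probability
    p_c(ξ).  Returns a list of ``(ξ, parent_index)`` pairs.
    """
    if linear_density <= 0:
        raise ValueError("linear_density must be positive")
    n = int(round(linear_density * mep.arc_length))
    if n < 1:
        raise ValueError(
            f"density {linear_density}/Å on a {mep.arc_length:.3g} Å path "
            "yields no samples"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    xis = rng.uniform(0.0, 1.0, size=n)
    centers = [cp.xi for cp in control_points]
    weights = control_point_weights(xis, centers)
    u = rng.uniform(size=n)
    cum = np.cumsum(weights, axis=1)
    parents = (u[:, None] < cum).argmax(axis=1)
    return [(float(x), int(p)) for x, p in zip(xis, parents)]


def distort_reference(
    mep: ContinuousMEP,
    xi: float,
    parent: ControlPoint,
    thermal: ThermalSpec,
    rng: np.random.Generator | None = None,
    seed=None,
) -> Geometry:
    """Thermally distort R(ξ) perpendicular to the path.

    Normal-coordinate amplitudes are drawn for the parent control point's
    real internal modes (imaginary and zero modes are omitted from the
    sum), the mass-weighted displacement is projected with Q(ξ) = 1 − ττᵀ
    so it is strictly perpendicular to the MEP, and transformed back to
    Cartesians.  Provenance (ξ, parent) is recorded in the metadata.
    """
    freqs, vecs = parent.modes.real_modes()
    if freqs.size == 0:
        raise ValueError("parent control point has no real internal modes")
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = np.atleast_1d(mode_sigma(freqs, thermal))
    q = rng.standard_normal(freqs.size) * sigma
    delta_mw = vecs.T @ q
    tau = tangent(mep, xi)
    delta_mw = delta_mw - tau * float(tau @ delta_mw)
    ref = mep.geometry(xi)
    delta = delta_mw / np.sqrt(np.repeat(ref.masses, 3))
    out = ref.with_coords(ref.flat() + delta)
    out.metadata.update(xi=float(xi), parent=parent.index, source="tts-path")
    return out


def _tangent_sigma(
    cp: ControlPoint, tau_out: np.ndarray, thermal: ThermalSpec
) -> float:
    """Width of the NMS displacement projected on the outward tangent.

    The NMS displacement Σ_i Ω_i Ω⃗_i projected on a unit vector τ is
    Gaussian with variance Σ_i σ_i² ⟨τ, Ω⃗_i⟩², which is the width the
    density-continuity match at the tube ends needs.
    """
    freqs, vecs = cp.modes.real_modes()
    sigma = np.atleast_1d(mode_sigma(freqs, thermal))
    overlaps = vecs @ tau_out
    return float(np.sqrt(np.sum((sigma * overlaps) ** 2)))


def endpoint_caps(
    mep: ContinuousMEP,
    end_control_points: tuple[ControlPoint, ControlPoint],
    thermal: ThermalSpec,
    linear_density: float,
    seed=None,
    rng: np.random.Generator | None = None,
) -> CandidateSet:
    """Half-Gaussian normal-mode caps sealing the open tube ends.

    At each endpoint minimum, ordinary thermal NMS samples are drawn and
    only those whose mass-weighted displacement has a non-negative
    projection on the *outward* tangent are kept, i.e. the half of the
    Gaussian that does not overlap the tube.  The number of retained
    samples per endpoint, N_cap = ρ_mw·√(π/2)·σ_τ, matches the peak of
    the half-Gaussian's linear density along the tangent to the uniform
    on-path density (ρ_mw is the on-path density per unit mass-weighted
    arc length at the endpoint and σ_τ the thermal width of the
    displacement projected on the tangent).
    """
    if linear_density <= 0:
        raise ValueError("linear_density must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = CandidateSet()
    for cp, xi_end, sign in (
        (end_control_points[0], 0.0, -1.0),
        (end_control_points[1], 1.0, +1.0),
    ):
        if cp.n_imaginary:
            raise ValueError("cap endpoints must be minima (imaginary modes found)")
        tau_out = sign * tangent(mep, xi_end)
        sigma_tau = _tangent_sigma(cp, tau_out, thermal)
        if sigma_tau == 0.0:
            continue  # zero-temperature classical limit: no cap
        # on-path density per unit mass-weighted arc length at this end
        d_cart = mep.derivative(xi_end)
        gamma = np.linalg.norm(
            d_cart * np.sqrt(np.repeat(mep.masses, 3))
        ) / np.linalg.norm(d_cart)
        n_cap = int(round(linear_density / gamma * math.sqrt(math.pi / 2.0) * sigma_tau))
        freqs, vecs = cp.modes.real_modes()
        sigma = np.atleast_1d(mode_sigma(freqs, thermal))
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(cp.geometry.masses, 3))
        kept = 0
        while kept < n_cap:
            batch = max(2 * (n_cap - kept), 16)
            q = rng.standard_normal((batch, freqs.size)) * sigma[None, :]
            delta_mw = q @ vecs
            proj = delta_mw @ tau_out
            for row in np.flatnonzero(proj >= 0.0):
                if kept >= n_cap:
                    break
                g = cp.geometry.with_coords(
                    cp.geometry.flat() + delta_mw[row] * inv_sqrt_m
                )
                g.metadata.update(xi=xi_end, parent=cp.index, source="tts-cap")
                out.append(g, Provenance(source="tts-cap", xi=xi_end, parent=cp.index))
                kept += 1
    return out


def tts_generate(
    mep: ContinuousMEP | Geometry,
    xi_control,
    calc: Calculator,
    thermal: ThermalSpec,
    linear_density: float,
    seed=None,
    n_single: int | None = None,
    displacement: float = 0.0005,
    zero_mode_threshold: float = 1e-4,
    n_zero_expected: int | None = None,
    control_points: list[ControlPoint] | None = None,
) -> CandidateSet:
    """Full transition-tube candidate generation.

    Concatenates the on-path perpendicular distortions with the endpoint
    caps; everything carries provenance (source, ξ, parent control point)
    and the whole set is deterministic under a fixed ``seed``.

    Passing a bare :class:`Geometry` (or a single control point) selects
    the zero-path-length degenerate limit, which is *exactly* plain
    thermal NMS: ``n_single`` samples are drawn with the same seed
    semantics as :func:`transtube.harmonic.nms_sample`.
    """
    single = isinstance(mep, Geometry) or (
        control_points is None and len(list(xi_control)) == 1
    ) or (control_points is not None and len(control_points) == 1)
    if single:
        if n_single is None:
            raise ValueError(
                "the single-control-point (zero-length path) limit needs "
                "an explicit sample count n_single"
            )
        minimum = mep if isinstance(mep, Geometry) else mep.geometry(
            float(np.atleast_1d(list(xi_control))[0])
        )
        return nms_sample(
            minimum,
            calc,
            thermal,
            n_single,
            seed=seed,
            zero_mode_threshold=zero_mode_threshold,
            n_zero_expected=n_zero_expected,
            hessian_displacement=displacement,
        )

    if control_points is None:
        control_points = build_control_points(
            mep,
            xi_control,
            calc,
            displacement=displacement,
            zero_mode_threshold=zero_mode_threshold,
            n_zero_expected=n_zero_expected,
        )
    rng = np.random.default_rng(seed)
    refs = sample_reference_points(mep, control_points, linear_density, rng=rng)
    out = CandidateSet()
    for xi, parent_idx in refs:
        g = distort_reference(mep, xi, control_points[parent_idx], thermal, rng=rng)
        out.append(g, Provenance(source="tts-path", xi=xi, parent=parent_idx))
    caps = endpoint_caps(
        mep,
        (control_points[0], control_points[-1]),
        thermal,
        linear_density,
        rng=rng,
    )
    out.extend(caps)
    return out
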