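"""Normal-mode analysis and classical/quantum thermal sampling.

The harmonic picture underlying everything here: diagonalizing the
mass-weighted Hessian M^{-1/2} H M^{-1/2} yields frequencies ω_i and
orthonormal mode vectors Ω⃗_i in mass-weighted coordinates.  At inverse
temperature β each mode's normal coordinate Ω_i is an independent
zero-mean Gaussian with

    classical:  σ_i² = 1 / (β ω_i²)
    quantum:    σ_i² = (ħ / 2ω_i) coth(β ħ ω_i / 2) = 1 / (β*_i ω_i²)

where β*_i = (2/ħω_i) tanh(βħω_i/2) is the mode-dependent quantum
effective inverse temperature: the classical β at which a classical
oscillator has the same thermal width as the quantum one at β.  Since
coth x ≥ 1/x, the quantum width is never below the classical one, and
β* → β as ω → 0 (classical limit) while β* → 2/(ħω) as β → ∞
(zero-point motion).

Imaginary frequencies (negative Hessian eigenvalues) are encoded as
negative ω of the same magnitude.  They are never thermally sampled —
they are omitted from every sum, as are the rigid-body zero modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import EV_TO_AMU_A2_FS2, HBAR, beta_from_temperature
from .calculators import Calculator, numerical_hessian
from .geometry import CandidateSet, Geometry, Provenance


@dataclass
class NormalModeSet:
    """Frequencies and mass-weighted normal modes at a reference geometry.

    ``frequencies`` (fs⁻¹) and ``modes`` (rows, shape ``(n_internal, 3N)``,
    orthonormal in mass-weighted coordinates) hold the internal modes only;
    the near-zero translational/rotational (or genuinely flat) modes are
    recorded by ``zero_mode_indices`` into the original eigenvalue
    ordering.  A negative frequency encodes an imaginary mode of magnitude
    |ω| (unstable curvature); such modes are retained but flagged.
    """

    reference: Geometry
    frequencies: np.ndarray
    modes: np.ndarray
    zero_mode_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        n3 = 3 * self.reference.n_atoms
        if self.modes.shape != (self.frequencies.size, n3):
            raise ValueError("modes must have shape (n_internal, 3N)")
        if self.frequencies.size + len(self.zero_mode_indices) != n3:
            raise ValueError("mode count plus zero modes must equal 3N")
        gram = self.modes @ self.modes.T
        if self.frequencies.size and np.max(
            np.abs(gram - np.eye(self.frequencies.size))
        ) > 1e-8:
            raise ValueError("mode vectors are not orthonormal")

    @property
    def n_internal(self) -> int:
        return int(self.frequencies.size)

    @property
    def imaginary_indices(self) -> np.ndarray:
        """Indices (into the internal modes) of imaginary frequencies."""
        return np.flatnonzero(self.frequencies < 0)

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.frequencies < 0))

    def real_modes(self) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies, mode vectors) of the real internal modes only."""
        keep = self.frequencies > 0
        return self.frequencies[keep], self.modes[keep]


def normal_mode_analysis(
    hessian: np.ndarray,
    masses: np.ndarray,
    reference: Geometry,
    zero_mode_threshold: float = 1e-4,
    n_zero_expected: int | None = None,
) -> NormalModeSet:
    """Diagonalize the mass-weighted Hessian into a :class:`NormalModeSet`.

    Parameters
    ----------
    hessian:
        Symmetric ``(3N, 3N)`` matrix in eV/Å².
    masses:
        Per-atom masses in amu.
    reference:
        Geometry at which the Hessian was evaluated.
    zero_mode_threshold:
        Modes with |ω| below this (fs⁻¹) are flagged as zero modes
        (translations/rotations or genuinely flat directions) and excluded
        from the internal set.
    n_zero_expected:
        When given, the number of detected zero modes must match exactly
        (6 for a nonlinear gas-phase molecule, 5 for a linear one) —
        a silent mode miscount would corrupt every thermal width.
    """
    hessian = np.asarray(hessian, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n3 = 3 * reference.n_atoms
    if hessian.shape != (n3, n3):
        raise ValueError(f"hessian must have shape {(n3, n3)}")
    scale = max(float(np.max(np.abs(hessian))), 1e-300)
    if np.max(np.abs(hessian - hessian.T)) > 1e-8 * scale:
        raise ValueError("hessian must be symmetric")
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    mw = hessian * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    mw = 0.5 * (mw + mw.T)
    evals, evecs = np.linalg.eigh(mw)  # ascending; eigenvalues in eV/(Å² amu)
    omega = np.sign(evals) * np.sqrt(np.abs(evals) * EV_TO_AMU_A2_FS2)
    zero = np.abs(omega) < zero_mode_threshold
    if np.all(zero):
        raise ValueError("all modes fall below the zero-mode threshold")
    if n_zero_expected is not None and int(np.sum(zero)) != n_zero_expected:
        raise ValueError(
            f"expected {n_zero_expected} zero modes, found {int(np.sum(zero))} "
            f"(threshold {zero_mode_threshold} fs⁻¹)"
        )
    keep = ~zero
    return NormalModeSet(
        reference=reference.copy(),
        frequencies=omega[keep],
        modes=evecs.T[keep],
        zero_mode_indices=np.flatnonzero(zero),
    )


@dataclass
class ThermalSpec:
    """Target temperature and statistics (classical or quantum widths)."""

    temperature: float
    statistics: str = "classical"

    def __post_init__(self) -> None:
        if self.statistics not in ("classical", "quantum"):
            raise ValueError("statistics must be 'classical' or 'quantum'")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def beta(self) -> float:
        """Inverse temperature in eV⁻¹ (``inf`` at 0 K)."""
        return beta_from_temperature(self.temperature)

    def beta_star(self, omega) -> np.ndarray:
        """Per-mode quantum effective inverse temperature (eV⁻¹)."""
        return effective_inverse_temperature(omega, self.beta)

    def sigma(self, omega) -> np.ndarray:
        """Thermal width of the mass-weighted normal coordinate (Å·√amu)."""
        return mode_sigma(omega, self)


def effective_inverse_temperature(omega, beta: float, hbar: float = HBAR):
    """Quantum effective inverse temperature β* = (2/ħω)·tanh(βħω/2).

    ``omega`` in fs⁻¹ (strictly positive — imaginary and zero modes are
    never thermally sampled), ``beta`` in eV⁻¹; returns eV⁻¹.  β* ≤ β
    always, with equality only in the ω → 0 limit; β* → 2/(ħω) as
    β → ∞.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    if beta <= 0:
        raise ValueError("beta must be strictly positive")
    if math.isinf(beta):
        result = 2.0 / (hbar * omega)
    else:
        result = 2.0 / (hbar * omega) * np.tanh(beta * hbar * omega / 2.0)
    return result if result.shape else float(result)


def thermal_variance(omega, beta: float, statistics: str, hbar: float = HBAR):
    """Thermal variance of a harmonic normal coordinate, natural units.

    Classical: 1/(βω²).  Quantum: (ħ/2ω)·coth(βħω/2), equivalently
    1/(β*ω²).  The result carries units of energy·time² in whatever
    consistent unit system (ħ, β, ω) are expressed in; multiply by the
    energy conversion factor to obtain mass·length² units.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("imaginary or zero modes have no thermal width")
    if statistics == "classical":
        if math.isinf(beta):
            var = np.zeros_like(omega)
        else:
            var = 1.0 / (beta * omega**2)
    elif statistics == "quantum":
        if math.isinf(beta):
            var = hbar / (2.0 * omega)  # zero-point width, coth → 1
        else:
            var = hbar / (2.0 * omega) / np.tanh(beta * hbar * omega / 2.0)
    else:
        raise ValueError("statistics must be 'classical' or 'quantum'")
    return var if var.shape else float(var)


def mode_sigma(omega, thermal: ThermalSpec):
    """Standard deviation of the mass-weighted normal coordinate (Å·√amu)."""
    var = thermal_variance(omega, thermal.beta, thermal.statistics)
    return np.sqrt(np.asarray(var) * EV_TO_AMU_A2_FS2) if np.ndim(var) else float(
        np.sqrt(var * EV_TO_AMU_A2_FS2)
    )


def sample_normal_coordinates(
    modes: NormalModeSet,
    thermal: ThermalSpec,
    n: int,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` independent thermal normal-coordinate vectors.

    Returns shape ``(n, n_internal)``; column ``i`` is a zero-mean
    Gaussian with the classical or quantum width of mode ``i``.  All
    internal modes must be real: attempting to thermally sample an
    imaginary mode is an error, not a warning.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if modes.n_imaginary:
        raise ValueError(
            "cannot thermally sample imaginary modes; they must be excluded"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = np.atleast_1d(mode_sigma(modes.frequencies, thermal))
    return rng.standard_normal((n, modes.n_internal)) * sigma[None, :]


def displace(
    reference: Geometry, modes: NormalModeSet, normal_coords
) -> Geometry:
    """Back-transform normal coordinates to a Cartesian geometry.

    R = R₀ + M^{-1/2} Σ_i Ω_i Ω⃗_i : each supplied normal-coordinate value
    Ω_i displaces along its mass-weighted mode vector and the sum is
    un-mass-weighted back to Cartesians.
    """
    q = np.asarray(normal_coords, dtype=float)
    if q.shape != (modes.n_internal,):
        raise ValueError(
            f"normal_coords length {q.shape} does not match "
            f"{modes.n_internal} modes"
        )
    delta_mw = modes.modes.T @ q
    delta = delta_mw / np.sqrt(np.repeat(reference.masses, 3))
    return reference.with_coords(reference.flat() + delta)


def _displace_batch(
    reference: Geometry, mode_vectors: np.ndarray, q: np.ndarray
) -> np.ndarray:
    """Vectorized back-transform: (n, n_modes) → Cartesian flat (n, 3N)."""
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(reference.masses, 3))
    return reference.flat()[None, :] + (q @ mode_vectors) * inv_sqrt_m[None, :]


def nms_sample(
    minimum: Geometry,
    calc_or_hessian,
    thermal: ThermalSpec,
    n: int,
    seed=None,
    rng: np.random.Generator | None = None,
    zero_mode_threshold: float = 1e-4,
    n_zero_expected: int | None = None,
    hessian_displacement: float = 0.0005,
) -> CandidateSet:
    """Thermal normal-mode sampling around a single minimum.

    Draws ``n`` completely uncorrelated thermal geometries from the
    auxiliary harmonic ensemble at ``minimum``.  The reference must be a
    true minimum: any imaginary internal mode is an error (use the
    transition-tube sampler for reactive landscapes).  Zero modes are
    never displaced.
    """
    modes = _resolve_modes(
        minimum, calc_or_hessian, zero_mode_threshold, n_zero_expected,
        hessian_displacement,
    )
    if modes.n_imaginary:
        raise ValueError(
            f"{modes.n_imaginary} imaginary internal mode(s) at the reference: "
            "not a minimum — use transition tube sampling (tts) instead"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    q = sample_normal_coordinates(modes, thermal, n, rng=rng)
    flats = _displace_batch(minimum, modes.modes, q)
    out = CandidateSet()
    for k in range(n):
        out.append(
            minimum.with_coords(flats[k]),
            Provenance(source="nms"),
        )
    return out


def _resolve_modes(
    reference: Geometry,
    calc_or_hessian,
    zero_mode_threshold: float,
    n_zero_expected: int | None,
    hessian_displacement: float,
) -> NormalModeSet:
    if isinstance(calc_or_hessian, NormalModeSet):
        return calc_or_hessian
    if isinstance(calc_or_hessian, Calculator):
        h = numerical_hessian(
            calc_or_hessian, reference, displacement=hessian_displacement
        )
    else:
        h = np.asarray(calc_or_hessian, dtype=float)
    return normal_mode_analysis(
        h,
        reference.masses,
        reference,
        zero_mode_threshold=zero_mode_threshold,
        n_zero_expected=n_zero_expected,
    )
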