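"""Minimum-energy-path machinery: climbing-image NEB, arc-length splines,
tangents and perpendicular projectors.

The discrete band produced by NEB is turned into a continuous path
R(ξ), ξ ∈ [0, 1], by componentwise cubic splines reparametrized to
normalized Cartesian arc length, so that ‖dR/dξ‖ is constant and equal
to the total arc length L.  Tangents and the perpendicular projector
Q = 1 − τ τᵀ are evaluated in *mass-weighted* coordinates, consistent
with the normal-mode inner product used for thermal distortions (for
unit masses the two metrics coincide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .align import align_path, rmsd
from .calculators import Calculator
from .geometry import Geometry


class NEBConvergenceError(RuntimeError):
    """NEB ran out of steps; carries the last band and residual force."""

    def __init__(self, message: str, band: "DiscretePath", residual: float):
        super().__init__(message)
        self.band = band
        self.residual = residual


@dataclass
class DiscretePath:
    """An ordered, aligned chain of geometries along a reaction path."""

    frames: list[Geometry]
    endpoints_fixed: bool = True
    align: bool = True

    def __post_init__(self) -> None:
        if len(self.frames) < 3:
            raise ValueError("a discrete path needs at least 3 frames")
        if self.align:
            self.frames = align_path(self.frames)
        for a, b in zip(self.frames, self.frames[1:]):
            if rmsd(a, b) <= 0.0:
                raise ValueError("consecutive frames must differ")

    @property
    def energies(self) -> np.ndarray:
        return np.array(
            [np.nan if f.energy is None else f.energy for f in self.frames]
        )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def highest_image(self) -> int:
        """Index of the highest-energy frame (the climbing image)."""
        return int(np.nanargmax(self.energies))


def linear_interpolation(
    start: Geometry, end: Geometry, n_images: int
) -> np.ndarray:
    """Linearly interpolated band coordinates, shape ``(n_images, 3N)``."""
    a, b = start.flat(), end.flat()
    t = np.linspace(0.0, 1.0, n_images)
    return a[None, :] + t[:, None] * (b - a)[None, :]


def _improved_tangents(x: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Energy-weighted upwind tangent estimate at the interior images."""
    n = x.shape[0]
    taus = np.zeros((n - 2, x.shape[1]))
    for i in range(1, n - 1):
        dplus = x[i + 1] - x[i]
        dminus = x[i] - x[i - 1]
        if e[i + 1] > e[i] > e[i - 1]:
            tau = dplus
        elif e[i + 1] < e[i] < e[i - 1]:
            tau = dminus
        else:
            demax = max(abs(e[i + 1] - e[i]), abs(e[i - 1] - e[i]))
            demin = min(abs(e[i + 1] - e[i]), abs(e[i - 1] - e[i]))
            if e[i + 1] > e[i - 1]:
                tau = dplus * demax + dminus * demin
            else:
                tau = dplus * demin + dminus * demax
        norm = np.linalg.norm(tau)
        taus[i - 1] = tau / norm if norm > 0 else tau
    return taus


def neb_optimize(
    calc: Calculator,
    start: Geometry,
    end: Geometry,
    n_images: int = 15,
    spring_k: float = 4.86,
    climbing: bool = True,
    f_tol: float = 0.007,
    max_steps: int = 20000,
    max_move: float = 0.1,
    perturbation: float = 1e-3,
) -> DiscretePath:
    """Climbing-image NEB between two relaxed minima.

    The band starts from ``n_images`` linearly interpolated replicas
    including the two fixed endpoints, plus a tiny deterministic
    transverse bump (amplitude ``perturbation`` Å, half-sine along the
    band) that breaks the symmetry of ridge-shaped initial paths — a
    straight interpolation lying exactly on a symmetry ridge would
    otherwise never fall into the true reaction channel.  On surfaces
    where the straight line already is the MEP the bump simply relaxes
    away.  Interior images feel the true
    force perpendicular to the (energy-weighted upwind) tangent plus a
    spring force of constant ``spring_k`` (eV/Å²) along it; when
    ``climbing`` the highest-energy interior image instead feels the true
    force with its tangential component inverted and no spring, so it
    converges to the barrier top.  Optimization is FIRE-style damped
    dynamics; convergence requires every NEB force component ≤ ``f_tol``
    (eV/Å).

    Raises :class:`NEBConvergenceError` (carrying the last band and the
    residual force) if ``max_steps`` is exhausted.
    """
    if start.n_atoms != end.n_atoms:
        raise ValueError("start and end must have the same atom count")
    if rmsd(start, end) < 1e-8:
        raise ValueError("start and end coincide: degenerate band")
    if n_images < 3:
        raise ValueError("need at least 3 images")

    x = linear_interpolation(start, end, n_images)
    if perturbation > 0:
        d = end.flat() - start.flat()
        d_hat = d / np.linalg.norm(d)
        # fixed pseudo-random transverse direction: generic overlap with
        # any unstable perpendicular mode, bitwise deterministic
        u = np.random.default_rng(0).standard_normal(d.size)
        u -= d_hat * float(d_hat @ u)
        u /= np.linalg.norm(u)
        bump = np.sin(np.pi * np.linspace(0.0, 1.0, n_images))
        x[1:-1] += perturbation * bump[1:-1, None] * u[None, :]
    e_start, _ = calc.evaluate(start.coords)
    e_end, _ = calc.evaluate(end.coords)

    # FIRE parameters; dt_max is kept conservative so the integrator stays
    # stable (dt < 2/√k) up to curvatures of ~100 eV/Å² per unit mass
    dt, dt_max = 0.02, 0.15
    alpha, alpha0 = 0.1, 0.1
    f_inc, f_dec, f_alpha, n_min = 1.1, 0.5, 0.99, 5
    v = np.zeros((n_images - 2, x.shape[1]))
    steps_since_neg = 0

    def band_forces(x):
        energies = np.empty(n_images)
        forces = np.empty((n_images, x.shape[1]))
        energies[0], energies[-1] = e_start, e_end
        forces[0] = forces[-1] = 0.0
        for i in range(1, n_images - 1):
            e, f = calc.evaluate(x[i].reshape(-1, 3))
            energies[i] = e
            forces[i] = f.reshape(-1)
        taus = _improved_tangents(x, energies)
        # climb only when a genuine interior barrier exists: on a
        # barrier-less profile (maximum at an endpoint) a climbing image
        # would be driven uphill without bound
        climb = -1
        if climbing and 0 < int(np.argmax(energies)) < n_images - 1:
            climb = int(np.argmax(energies))
        neb_f = np.empty((n_images - 2, x.shape[1]))
        for i in range(1, n_images - 1):
            tau = taus[i - 1]
            f_true = forces[i]
            f_par = float(f_true @ tau)
            if i == climb:
                neb_f[i - 1] = f_true - 2.0 * f_par * tau
            else:
                d_plus = np.linalg.norm(x[i + 1] - x[i])
                d_minus = np.linalg.norm(x[i] - x[i - 1])
                f_spring = spring_k * (d_plus - d_minus)
                neb_f[i - 1] = (f_true - f_par * tau) + f_spring * tau
        return energies, neb_f

    energies, f = band_forces(x)
    for _ in range(max_steps):
        fmax = float(np.max(np.abs(f)))
        if fmax <= f_tol:
            break
        # FIRE velocity update
        power = float(np.sum(f * v))
        if power > 0:
            fn = np.linalg.norm(f)
            vn = np.linalg.norm(v)
            if fn > 0:
                v = (1 - alpha) * v + alpha * vn * f / fn
            steps_since_neg += 1
            if steps_since_neg > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            v[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            steps_since_neg = 0
        v = v + dt * f
        dx = dt * v
        # cap the per-image displacement for stability
        norms = np.linalg.norm(dx.reshape(n_images - 2, -1, 3), axis=2)
        biggest = float(np.max(norms)) if norms.size else 0.0
        if biggest > max_move:
            dx *= max_move / biggest
        x[1:-1] += dx
        energies, f = band_forces(x)
    else:
        band = _band_to_path(start, x, energies)
        raise NEBConvergenceError(
            f"NEB did not converge in {max_steps} steps "
            f"(residual {np.max(np.abs(f)):.3e} eV/Å)",
            band,
            float(np.max(np.abs(f))),
        )
    return _band_to_path(start, x, energies)


def _band_to_path(
    template: Geometry, x: np.ndarray, energies: np.ndarray
) -> DiscretePath:
    frames = []
    for i in range(x.shape[0]):
        g = template.with_coords(x[i])
        g.energy = float(energies[i])
        frames.append(g)
    return DiscretePath(frames=frames)


@dataclass
class ContinuousMEP:
    """Smooth arc-length-parametrized path R(ξ), ξ ∈ [0, 1].

    Built by :func:`fit_mep_spline`.  ``arc_length`` is the total path
    length in the plain Cartesian configuration-space metric (Å); the
    parametrization is normalized arc length, so ‖dR/dξ‖ ≈ L everywhere.
    """

    template: Geometry
    _spline: CubicSpline = field(repr=False)
    _t_of_xi: PchipInterpolator = field(repr=False)
    arc_length: float = 0.0
    knot_xi: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def masses(self) -> np.ndarray:
        return self.template.masses

    def _check_xi(self, xi: float) -> float:
        xi = float(xi)
        if not (0.0 <= xi <= 1.0):
            raise ValueError(f"xi must lie in [0, 1], got {xi}")
        return xi

    def coords(self, xi: float) -> np.ndarray:
        """Cartesian coordinates at ξ, shape ``(N, 3)``."""
        xi = self._check_xi(xi)
        t = float(self._t_of_xi(xi))
        return np.asarray(self._spline(t)).reshape(-1, 3)

    def geometry(self, xi: float) -> Geometry:
        g = self.template.with_coords(self.coords(xi))
        g.metadata["xi"] = float(xi)
        return g

    def derivative(self, xi: float) -> np.ndarray:
        """dR/dξ, flat shape ``(3N,)`` (‖·‖ ≈ arc_length)."""
        xi = self._check_xi(xi)
        t = float(self._t_of_xi(xi))
        dt_dxi = float(self._t_of_xi.derivative()(xi))
        return np.asarray(self._spline(t, 1)).reshape(-1) * dt_dxi


def fit_mep_spline(path: DiscretePath, grid: int = 4001) -> ContinuousMEP:
    """Fit a continuous arc-length-parametrized spline through a band.

    Componentwise natural cubic splines over the chordal parameter,
    reparametrized to normalized Cartesian arc length on a dense grid.
    The curve passes through every input frame.
    """
    x = np.array([f.flat() for f in path.frames])
    chord = np.linalg.norm(np.diff(x, axis=0), axis=1)
    if np.any(chord <= 0):
        raise ValueError("duplicate consecutive frames")
    t_knots = np.concatenate([[0.0], np.cumsum(chord)])
    t_knots /= t_knots[-1]
    spline = CubicSpline(t_knots, x, axis=0, bc_type="natural")

    t_dense = np.union1d(np.linspace(0.0, 1.0, grid), t_knots)
    speed = np.linalg.norm(spline(t_dense, 1), axis=1)
    # cumulative arc length by trapezoid on the dense grid
    seg = 0.5 * (speed[1:] + speed[:-1]) * np.diff(t_dense)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(s[-1])
    xi_dense = s / length
    t_of_xi = PchipInterpolator(xi_dense, t_dense)

    knot_pos = np.searchsorted(t_dense, t_knots)
    return ContinuousMEP(
        template=path.frames[0].copy(),
        _spline=spline,
        _t_of_xi=t_of_xi,
        arc_length=length,
        knot_xi=xi_dense[knot_pos],
    )


def tangent(mep: ContinuousMEP, xi: float) -> np.ndarray:
    """Unit tangent τ(ξ) in mass-weighted coordinates, shape ``(3N,)``."""
    d = mep.derivative(xi)
    v = d * np.sqrt(np.repeat(mep.masses, 3))
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"vanishing tangent at xi={xi}")
    return v / n


def perpendicular_projector(mep: ContinuousMEP, xi: float) -> np.ndarray:
    """Projector Q = 1 − τ τᵀ onto the subspace perpendicular to the path.

    Acts on mass-weighted displacement vectors; symmetric, idempotent,
    annihilates the tangent, trace 3N − 1.
    """
    tau = tangent(mep, xi)
    return np.eye(tau.size) - np.outer(tau, tau)
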