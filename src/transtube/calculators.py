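"""Potential-energy calculators: the pluggable contract, analytic reference
potentials, a replay calculator for externally labeled data, and numerical
Hessians.

Every downstream stage (normal-mode analysis, NEB, tube sampling, active
learning) talks to a :class:`Calculator` and nothing else, so the whole
pipeline is exercisable on analytic potentials without any electronic-
structure software.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .geometry import Geometry


class Calculator(ABC):
    """Contract: ``evaluate(coords) -> (energy [eV], forces [eV/Å])``.

    ``coords`` has shape ``(N, 3)``; forces are the negative gradient of
    the energy (verified for shipped calculators by the finite-difference
    gradient test, :func:`check_forces`).
    """

    #: number of atoms the calculator expects, or None if it adapts
    n_atoms: int | None = None

    @abstractmethod
    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        ...

    def label(self, geometry: Geometry) -> Geometry:
        """Copy of ``geometry`` with energy and forces filled in."""
        e, f = self.evaluate(geometry.coords)
        g = geometry.copy()
        g.energy = float(e)
        g.forces = f
        return g


class Toy2D(Calculator):
    """The two-dimensional double-minimum model potential.

    V(x, y) = (1/6)·{4(1 − x² − y²)² + 2(x² − 2)² + [(x + y)² − 1]²
              + [(x − y)² − 1]² − 2}

    A single unit-mass particle moving in the xy-plane (the z coordinate
    is ignored and feels no force), so the full reaction-path pipeline —
    normal modes, NEB, tube sampling — runs on it unchanged.  The exact
    stationary points are two minima at (±√5/2, 0) with V = −1/12, a
    maximum at (0, 0) with V = 2, and two symmetry-related degenerate
    barrier tops at (0, ±1) with V = 1 whose Hessian eigenvalues are
    exactly {0, 8}: the barrier is quartic along the path.
    """

    n_atoms = 1

    #: exact minima, handy as starting guesses
    MINIMA = ((-(5.0**0.5) / 2.0, 0.0), ((5.0**0.5) / 2.0, 0.0))
    #: exact (degenerate) transition states
    SADDLES = ((0.0, 1.0), (0.0, -1.0))

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if coords.shape[0] != 1:
            raise ValueError("Toy2D describes a single particle")
        x, y = coords[0, 0], coords[0, 1]
        e, (fx, fy) = toy2d_evaluate((x, y))
        return e, np.array([[fx, fy, 0.0]])


def toy2d_evaluate(point: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Energy and forces of the 2D model potential at ``(x, y)``.

    Returns ``(V, (fx, fy))`` with forces the negative analytic gradient.
    Defined everywhere; natural units.
    """
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("point must be finite")
    a = 1.0 - x * x - y * y
    b = x * x - 2.0
    p = (x + y) ** 2 - 1.0
    m = (x - y) ** 2 - 1.0
    v = (4.0 * a * a + 2.0 * b * b + p * p + m * m - 2.0) / 6.0
    dvdx = (-16.0 * x * a + 8.0 * x * b + 4.0 * (x + y) * p + 4.0 * (x - y) * m) / 6.0
    dvdy = (-16.0 * y * a + 4.0 * (x + y) * p - 4.0 * (x - y) * m) / 6.0
    return v, (-dvdx, -dvdy)


class HarmonicND(Calculator):
    """Exact quadratic PES: E = ½ Δᵀ H Δ, forces = −H Δ.

    Serves as the closed-form oracle for every thermal-width and
    tube-moment contract: on this surface the harmonic approximation is
    exact, so sampled moments must match the analytic ones.
    """

    def __init__(self, minimum: Geometry, hessian: np.ndarray) -> None:
        hessian = np.asarray(hessian, dtype=float)
        n3 = 3 * minimum.n_atoms
        if hessian.shape != (n3, n3):
            raise ValueError(f"hessian must have shape {(n3, n3)}")
        if not np.allclose(hessian, hessian.T, atol=1e-10):
            raise ValueError("hessian must be symmetric")
        self.minimum = minimum.copy()
        self.hessian = hessian
        self.n_atoms = minimum.n_atoms

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        delta = (coords - self.minimum.coords).reshape(-1)
        hd = self.hessian @ delta
        energy = 0.5 * float(delta @ hd)
        return energy, -hd.reshape(self.n_atoms, 3)


class ReplayCalculator(Calculator):
    """Serve stored energies/forces for previously labeled geometries.

    Lets externally computed (e.g. ab initio) labels drive the
    active-learning loop without live coupling: geometries are matched
    against the stored pool by maximum absolute coordinate difference.
    """

    def __init__(self, labeled: Sequence[Geometry], tol: float = 1e-8) -> None:
        self.pool = [g for g in labeled]
        for g in self.pool:
            if g.energy is None or g.forces is None:
                raise ValueError("replay pool entries must carry energy and forces")
        self.tol = float(tol)
        self._flat = np.array([g.flat() for g in self.pool])

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        flat = np.asarray(coords, dtype=float).reshape(-1)
        diffs = np.max(np.abs(self._flat - flat), axis=1)
        i = int(np.argmin(diffs))
        if diffs[i] > self.tol:
            raise KeyError(
                f"no stored geometry within {self.tol} Å (closest: {diffs[i]:.3e})"
            )
        g = self.pool[i]
        return float(g.energy), g.forces.copy()


def numerical_hessian(
    calc: Calculator,
    geometry: Geometry,
    displacement: float = 0.0005,
    return_defect: bool = False,
):
    """Central-difference Hessian (eV/Å²) of ``calc`` at ``geometry``.

    Each Cartesian coordinate is displaced by ±``displacement`` (default
    0.0005 Å) and the Hessian column taken as the negative force
    difference quotient.  The result is symmetrized as (H + Hᵀ)/2; with
    ``return_defect=True`` the maximum absolute asymmetry before
    symmetrization is also returned.
    """
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    n3 = 3 * geometry.n_atoms
    flat = geometry.flat()
    h = np.empty((n3, n3))
    for k in range(n3):
        plus = flat.copy()
        plus[k] += displacement
        minus = flat.copy()
        minus[k] -= displacement
        _, fp = calc.evaluate(plus.reshape(-1, 3))
        _, fm = calc.evaluate(minus.reshape(-1, 3))
        h[:, k] = -(fp.reshape(-1) - fm.reshape(-1)) / (2.0 * displacement)
    defect = float(np.max(np.abs(h - h.T)))
    h_sym = 0.5 * (h + h.T)
    if return_defect:
        return h_sym, defect
    return h_sym


def check_forces(
    calc: Calculator,
    coords: np.ndarray,
    step: float = 1e-5,
) -> float:
    """Maximum relative mismatch between forces and −∇E by central differences."""
    coords = np.asarray(coords, dtype=float)
    flat = coords.reshape(-1)
    _, forces = calc.evaluate(coords)
    forces = forces.reshape(-1)
    num = np.empty_like(flat)
    for k in range(flat.size):
        p = flat.copy()
        p[k] += step
        m = flat.copy()
        m[k] -= step
        ep, _ = calc.evaluate(p.reshape(-1, 3))
        em, _ = calc.evaluate(m.reshape(-1, 3))
        num[k] = -(ep - em) / (2.0 * step)
    scale = max(float(np.max(np.abs(forces))), 1e-10)
    return float(np.max(np.abs(num - forces)) / scale)


def relax(
    calc: Calculator,
    geometry: Geometry,
    f_tol: float = 1e-5,
    max_steps: int = 5000,
) -> Geometry:
    """Local geometry optimization to max |force component| ≤ ``f_tol``.

    L-BFGS-B on the potential energy with analytic forces.  Returns the
    relaxed geometry with its energy and forces attached.
    """
    n = geometry.n_atoms

    def fun(x):
        e, f = calc.evaluate(x.reshape(n, 3))
        return e, -f.reshape(-1)

    res = _scipy_minimize(
        fun,
        geometry.flat(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": 0.1 * f_tol, "ftol": 0.0},
    )
    out = geometry.with_coords(res.x)
    e, f = calc.evaluate(out.coords)
    if np.max(np.abs(f)) > f_tol:
        raise RuntimeError(
            f"relaxation did not reach f_tol={f_tol} "
            f"(residual {np.max(np.abs(f)):.3e} eV/Å)"
        )
    out.energy = float(e)
    out.forces = f
    return out
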