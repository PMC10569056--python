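"""Shared fixtures: the model potential, converged bands, harmonic systems.

Oracles used by the tests are kept independent of the package: the 2D
model potential is re-implemented here symbolically from its closed form
and stationary points are refined by Newton iteration on that independent
implementation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import root

import transtube as tt
from transtube.mep import DiscretePath, fit_mep_spline
from transtube.tts import build_control_points


# --- independent closed-form oracle for the 2D model potential ------------

def oracle_v(x: float, y: float) -> float:
    """Independent evaluation of the printed closed form."""
    return (
        4.0 * (1.0 - x**2 - y**2) ** 2
        + 2.0 * (x**2 - 2.0) ** 2
        + ((x + y) ** 2 - 1.0) ** 2
        + ((x - y) ** 2 - 1.0) ** 2
        - 2.0
    ) / 6.0


def oracle_grad(p) -> np.ndarray:
    """Gradient of the oracle by high-order central differences."""
    h = 1e-6
    out = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h
        f1 = oracle_v(*(p + e))
        f_1 = oracle_v(*(p - e))
        f2 = oracle_v(*(p + 2 * e))
        f_2 = oracle_v(*(p - 2 * e))
        out[i] = (8 * (f1 - f_1) - (f2 - f_2)) / (12 * h)
    return out


def newton_stationary(guess) -> np.ndarray:
    """Newton-refine a stationary point of the oracle potential."""
    sol = root(oracle_grad, np.asarray(guess, dtype=float), tol=1e-12)
    # hybr's success flag is unreliable at the finite-difference noise
    # floor; the converged gradient norm is the real criterion
    assert np.linalg.norm(oracle_grad(sol.x)) < 1e-6
    return sol.x


@pytest.fixture(scope="session")
def oracle_minima():
    return newton_stationary([-1.1, 0.0]), newton_stationary([1.1, 0.0])


@pytest.fixture(scope="session")
def oracle_saddles():
    return newton_stationary([0.05, 0.95]), newton_stationary([0.05, -0.95])


# --- package-side toy-potential objects ------------------------------------

@pytest.fixture(scope="session")
def toy_calc():
    return tt.Toy2D()


@pytest.fixture(scope="session")
def toy_minima(toy_calc):
    a = tt.relax(toy_calc, tt.Geometry(["X"], [[-1.1, 0.05, 0.0]]), f_tol=1e-9)
    b = tt.relax(toy_calc, tt.Geometry(["X"], [[1.1, 0.05, 0.0]]), f_tol=1e-9)
    return a, b


@pytest.fixture(scope="session")
def toy_band(toy_calc, toy_minima):
    a, b = toy_minima
    return tt.neb_optimize(
        toy_calc, a, b, n_images=15, f_tol=1e-4, max_steps=100000
    )


@pytest.fixture(scope="session")
def toy_mep(toy_band):
    return fit_mep_spline(toy_band)


@pytest.fixture(scope="session")
def toy_control_points(toy_mep, toy_calc):
    # threshold 1e-3 fs⁻¹: the barrier top of this surface is quartic along
    # the path, so its soft direction must be flagged flat, not thermal
    return build_control_points(
        toy_mep, [0.0, 0.5, 1.0], toy_calc, zero_mode_threshold=1e-3
    )


# --- harmonic (exact-oracle) systems ---------------------------------------

@pytest.fixture(scope="session")
def harmonic_system():
    """Two atoms with unequal masses on a random stiff quadratic PES."""
    rng = np.random.default_rng(42)
    masses = np.array([1.0, 12.0])
    n3 = 6
    amat = rng.standard_normal((n3, n3))
    hessian = amat @ amat.T + n3 * np.eye(n3)
    minimum = tt.Geometry(
        ["X", "X"], rng.standard_normal((2, 3)), masses=masses
    )
    calc = tt.HarmonicND(minimum, hessian)
    return minimum, hessian, calc


@pytest.fixture(scope="session")
def straight_tube_system():
    """Harmonic PES whose MEP is a straight 2 Å segment.

    The Hessian has the path direction as an exact soft eigenvector
    (curvature 0.5 eV/Å²), so the straight line through the center is the
    minimum-energy path and every perpendicular thermal moment has a
    closed form.
    """
    rng = np.random.default_rng(7)
    masses = np.array([1.0, 12.0])
    n3 = 6
    amat = rng.standard_normal((n3, n3))
    h0 = amat @ amat.T + n3 * np.eye(n3)
    u = rng.standard_normal(n3)
    u /= np.linalg.norm(u)
    proj = np.eye(n3) - np.outer(u, u)
    hessian = proj @ h0 @ proj + 0.5 * np.outer(u, u)
    hessian = 0.5 * (hessian + hessian.T)
    center = rng.standard_normal((2, 3))
    minimum = tt.Geometry(["X", "X"], center, masses=masses)
    calc = tt.HarmonicND(minimum, hessian)
    length = 2.0
    start = center.reshape(-1) - 0.5 * length * u
    frames = [
        tt.Geometry(
            ["X", "X"], (start + t * length * u).reshape(2, 3), masses=masses
        )
        for t in np.linspace(0.0, 1.0, 9)
    ]
    path = DiscretePath(frames, align=False)
    mep = fit_mep_spline(path)
    return {
        "minimum": minimum,
        "hessian": hessian,
        "calc": calc,
        "mep": mep,
        "direction": u,
        "length": length,
    }
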