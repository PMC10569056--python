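"""Desk-scale reproducibility studies on the analytic model potentials.

Each function runs one self-contained numerical experiment — the QbC
schedule arithmetic, the partition-of-unity defect, thermal-width
calibration, tube perpendicularity, the CI-NEB saddle search on the 2D
model potential, the harmonic-limit tube moments, endpoint-cap density
continuity, and the QbC-vs-random comparison — and returns the measured
quantities.  They are what `scripts/acceptance.py` and the acceptance
test suite execute.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root
from scipy.stats import kstest

from .calculators import Toy2D, numerical_hessian, relax
from .constants import HBAR
from .geometry import CandidateSet, Geometry, Provenance, TrainingSet
from .harmonic import (
    ThermalSpec,
    effective_inverse_temperature,
    mode_sigma,
    nms_sample,
    normal_mode_analysis,
    sample_normal_coordinates,
)
from .mep import DiscretePath, fit_mep_spline, neb_optimize, tangent
from .qbc import CommitteeSpec, KernelRidgeModel, MockModel, qbc_run, train_committee
from .tts import build_control_points, control_point_weights, sample_reference_points, tts_generate


class ToyWorkflow:
    """The standard 2D-model-potential workflow, computed once and shared.

    Relaxes the two minima, converges a climbing-image NEB band, fits the
    continuous path and builds the three control points (two minima plus
    the barrier top).  ``f_tol`` is kept tight so the climbing image
    refines the degenerate barrier top to saddle-search quality.
    """

    def __init__(self, f_tol: float = 1e-4):
        self.calc = Toy2D()
        self.min_a = relax(
            self.calc, Geometry(["X"], [[-1.1, 0.05, 0.0]]), f_tol=1e-9
        )
        self.min_b = relax(
            self.calc, Geometry(["X"], [[1.1, 0.05, 0.0]]), f_tol=1e-9
        )
        self.band = neb_optimize(
            self.calc, self.min_a, self.min_b,
            n_images=15, f_tol=f_tol, max_steps=100000,
        )
        self.mep = fit_mep_spline(self.band)
        # zero-mode threshold 1e-3 fs⁻¹: the quartic barrier top's soft
        # path direction must be flagged flat rather than thermally wide
        self.control_points = build_control_points(
            self.mep, [0.0, 0.5, 1.0], self.calc, zero_mode_threshold=1e-3
        )

    def reference_committee_spec(self, seed: int) -> CommitteeSpec:
        """Reference committee for toy-scale studies: full-data members
        diversified by kernel-width jitter (lengthscale ≈ 0.2 Å)."""
        return CommitteeSpec(
            model_factory=lambda s: KernelRidgeModel(
                seed=s, gamma=10.0, alpha=1e-6, gamma_jitter=0.3
            ),
            n_members=8,
            training_fraction=1.0,
            seed=seed,
        )


def random_pool(n: int, seed: int) -> CandidateSet:
    """Cheap pool of single-particle geometries for protocol arithmetic."""
    rng = np.random.default_rng(seed)
    out = CandidateSet()
    for _ in range(n):
        coords = np.concatenate([rng.uniform(-1.5, 1.5, 2), [0.0]])
        out.append(Geometry(["X"], coords.reshape(1, 3)), Provenance("nms"))
    return out


def study_qbc_schedule(seed: int, n_init: int, n_iter: int, k_per_iter: int) -> int:
    """Run a full QbC schedule with a mock committee; return the final size."""
    pool = random_pool(n_init + n_iter * k_per_iter + 80, seed)
    spec = CommitteeSpec(
        model_factory=lambda s: MockModel(seed=s), n_members=8, seed=seed
    )
    training = qbc_run(
        pool, Toy2D(), spec,
        n_init=n_init, n_iter=n_iter, k_per_iter=k_per_iter, seed=seed,
    )
    return len(training)


def study_partition_unity(seed: int, n_layouts: int = 50, n_xi: int = 10_000) -> float:
    """Max |Σ_c p_c(ξ) − 1| over random control-point layouts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_layouts):
        n_p = int(rng.integers(2, 9))
        centers = np.sort(rng.uniform(0.0, 1.0, n_p))
        if np.any(np.diff(centers) <= 1e-9):
            continue
        xi = rng.uniform(0.0, 1.0, n_xi)
        w = control_point_weights(xi, centers)
        worst = max(worst, float(np.max(np.abs(w.sum(axis=1) - 1.0))))
    return worst


def study_thermal_widths(seed: int, n: int = 100_000) -> dict:
    """Sampled vs analytic thermal widths across three decades of ω."""
    omegas = np.array([0.003, 0.03, 0.3, 3.0])  # fs⁻¹
    from .constants import EV_TO_AMU_A2_FS2

    k = omegas**2 / EV_TO_AMU_A2_FS2
    ref = Geometry(["X", "X"], np.zeros((2, 3)), masses=[1.0, 1.0])
    modes = normal_mode_analysis(
        np.diag(np.concatenate([k, [0.0, 0.0]])),
        ref.masses, ref, zero_mode_threshold=1e-5,
    )
    out = {}
    for offset, stats in enumerate(("classical", "quantum")):
        thermal = ThermalSpec(300.0, stats)
        q = sample_normal_coordinates(modes, thermal, n, seed=seed + offset)
        sigma = mode_sigma(modes.frequencies, thermal)
        out[f"{stats}_max_rel_err"] = float(
            np.max(np.abs(q.var(axis=0) / sigma**2 - 1.0))
        )
    beta = ThermalSpec(300.0).beta
    omega_tiny = 1e-6 / (beta * HBAR)
    out["beta_star_classical_limit_rel_err"] = float(
        abs(effective_inverse_temperature(omega_tiny, beta) / beta - 1.0)
    )
    return out


def study_perpendicularity(workflow: ToyWorkflow, seed: int, n: int = 2000) -> float:
    """Worst relative tangent projection of on-path tube displacements."""
    thermal = ThermalSpec(300.0, "classical")
    cands = tts_generate(
        workflow.mep, [0.0, 0.5, 1.0], workflow.calc, thermal,
        n / workflow.mep.arc_length, seed=seed,
        control_points=workflow.control_points,
    )
    worst = 0.0
    for g, prov in zip(cands.items, cands.provenance):
        if prov.source != "tts-path":
            continue
        delta = g.mass_weighted() - workflow.mep.geometry(prov.xi).mass_weighted()
        norm = np.linalg.norm(delta)
        if norm == 0:
            continue
        tau = tangent(workflow.mep, prov.xi)
        worst = max(worst, abs(float(tau @ delta)) / norm)
    return worst


def study_xi_uniformity(workflow: ToyWorkflow, seed: int, n: int = 10_000) -> float:
    """KS p-value of the on-path ξ marginal against the uniform law."""
    refs = sample_reference_points(
        workflow.mep, workflow.control_points,
        n / workflow.mep.arc_length, seed=seed,
    )
    xis = np.array([x for x, _ in refs])
    return float(kstest(xis, "uniform").pvalue)


def study_neb_saddle(workflow: ToyWorkflow) -> dict:
    """Climbing image vs the Newton-refined transition point."""
    calc = workflow.calc

    def grad(p):
        _, f = calc.evaluate(np.array([[p[0], p[1], 0.0]]))
        return -f[0, :2]

    refined = min(
        (root(grad, np.array(g0), tol=1e-12).x for g0 in [(0.1, 0.9), (0.1, -0.9)]),
        key=lambda p: np.linalg.norm(
            p - workflow.band.frames[workflow.band.highest_image()].coords[0, :2]
        ),
    )
    hi = workflow.band.highest_image()
    ci = workflow.band.frames[hi].coords[0, :2]
    evals = np.linalg.eigvalsh(
        numerical_hessian(calc, workflow.band.frames[hi])
    )
    return {
        "saddle_distance": float(np.linalg.norm(ci - refined)),
        "n_negative_eigenvalues": int(np.sum(evals < 0)),
    }


def _straight_harmonic_system(seed: int = 7):
    from .calculators import HarmonicND

    rng = np.random.default_rng(seed)
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
    minimum = Geometry(["X", "X"], center, masses=masses)
    calc = HarmonicND(minimum, hessian)
    start = center.reshape(-1) - u
    frames = [
        Geometry(["X", "X"], (start + t * 2.0 * u).reshape(2, 3), masses=masses)
        for t in np.linspace(0.0, 1.0, 9)
    ]
    mep = fit_mep_spline(DiscretePath(frames, align=False))
    return minimum, calc, mep


def study_harmonic_limit(seed: int, n: int = 10_000) -> dict:
    """Tube moments on a quadratic PES with a straight MEP.

    The perpendicular candidate distribution must reproduce the analytic
    per-mode Gaussian widths, and with a single control point the tube
    sampler must coincide bitwise with plain NMS.
    """
    minimum, calc, mep = _straight_harmonic_system()
    thermal = ThermalSpec(300.0, "classical")
    cps = build_control_points(mep, [0.0, 0.5, 1.0], calc)
    rho = n / mep.arc_length
    cands = tts_generate(
        mep, [0.0, 0.5, 1.0], calc, thermal, rho, seed=seed, control_points=cps,
    )
    sqrt_m = np.sqrt(np.repeat(mep.masses, 3))
    tau = tangent(mep, 0.5)
    # the Hessian is constant, so every control point carries the same
    # mode set and the on-path displacements can be pooled across parents
    deltas = []
    for g, prov in zip(cands.items, cands.provenance):
        if prov.source != "tts-path":
            continue
        deltas.append((g.flat() - mep.coords(prov.xi).reshape(-1)) * sqrt_m)
    deltas = np.array(deltas)
    freqs, vecs = cps[0].modes.real_modes()
    sigma = np.atleast_1d(mode_sigma(freqs, thermal))
    overlaps = vecs @ tau
    worst = 0.0
    for kmode in range(freqs.size):
        c_k = overlaps[kmode]
        expected = sigma[kmode] ** 2 * (1 - c_k**2) ** 2 + sum(
            sigma[j] ** 2 * overlaps[j] ** 2 * c_k**2
            for j in range(freqs.size) if j != kmode
        )
        if expected < 1e-12:
            continue
        got = float(np.var(deltas @ vecs[kmode]))
        worst = max(worst, abs(got / expected - 1.0))
    direct = nms_sample(minimum, calc, thermal, 64, seed=seed)
    via_tube = tts_generate(
        minimum, [0.0], calc, thermal, rho, seed=seed, n_single=64
    )
    bitwise = all(
        np.array_equal(a.coords, b.coords)
        for a, b in zip(direct.items, via_tube.items)
    )
    return {
        "perp_moment_max_rel_err": worst,
        "single_point_bitwise_equals_nms": bool(bitwise),
    }


def study_cap_continuity(seed: int, n: int = 12_000) -> float:
    """On/cap linear-density ratio across an endpoint of a straight tube."""
    _, calc, mep = _straight_harmonic_system()
    thermal = ThermalSpec(300.0, "classical")
    cps = build_control_points(mep, [0.0, 0.5, 1.0], calc)
    cands = tts_generate(
        mep, [0.0, 0.5, 1.0], calc, thermal, n / mep.arc_length,
        seed=seed, control_points=cps,
    )
    sqrt_m = np.sqrt(np.repeat(mep.masses, 3))
    tau = tangent(mep, 0.0)
    x0 = mep.coords(0.0).reshape(-1) * sqrt_m
    gamma = np.linalg.norm(mep.derivative(0.0) * sqrt_m) / np.linalg.norm(
        mep.derivative(0.0)
    )
    proj = np.array([(g.mass_weighted() - x0) @ tau for g in cands.items])
    h = 0.04 * mep.arc_length * gamma
    cap_bin = np.sum((proj >= -h) & (proj < 0.0))
    path_bin = np.sum((proj >= 0.0) & (proj < h))
    return float(cap_bin / path_bin)


def study_committee_vs_worst_member(workflow: ToyWorkflow, seed: int) -> float:
    """Held-out energy RMSE ratio: committee mean over worst member (≤ 1)."""
    thermal = ThermalSpec(300.0, "classical")
    cands = tts_generate(
        workflow.mep, [0.0, 0.5, 1.0], workflow.calc, thermal,
        400.0 / workflow.mep.arc_length, seed=seed,
        control_points=workflow.control_points,
    )
    training = TrainingSet()
    for g in cands.items[:200]:
        training.add(workflow.calc.label(g), iteration=0)
    held_out = [workflow.calc.label(g) for g in cands.items[250:350]]
    spec = workflow.reference_committee_spec(seed)
    spec.training_fraction = 0.9
    committee = train_committee(training, spec)

    def rmse(pred):
        return float(np.sqrt(np.mean(
            [(pred(g)[0] - g.energy) ** 2 for g in held_out]
        )))

    return rmse(committee.predict) / max(rmse(m.predict) for m in committee.members)


def study_qbc_vs_random(
    workflow: ToyWorkflow, seed: int, repeats: int = 20
) -> float:
    """Fraction of seeded repeats where QbC beats equal-budget random
    selection on the worst-case energy error over a uniform tube grid."""
    calc = workflow.calc
    mep = workflow.mep
    thermal = ThermalSpec(300.0, "classical")
    grid = []
    for xi in np.linspace(0.0, 1.0, 41):
        tau = tangent(mep, xi)
        perp = np.array([-tau[1], tau[0], 0.0])
        perp /= np.linalg.norm(perp)
        x0 = mep.coords(xi).reshape(-1)
        for alpha in np.linspace(-0.1, 0.1, 7):
            grid.append(x0 + alpha * perp)
    grid = np.array(grid)
    e_true = np.array([calc.evaluate(p.reshape(1, 3))[0] for p in grid])

    def worst_err(training, spec):
        committee = train_committee(training, spec)
        return max(
            abs(committee.predict(Geometry(["X"], p.reshape(1, 3)))[0] - et)
            for p, et in zip(grid, e_true)
        )

    wins = 0
    for rep in range(repeats):
        rep_seed = seed + rep
        cands = tts_generate(
            mep, [0.0, 0.5, 1.0], calc, thermal, 130.0, seed=rep_seed,
            control_points=workflow.control_points,
        )
        spec = workflow.reference_committee_spec(rep_seed)
        tr_qbc = qbc_run(
            cands, calc, spec, n_init=10, n_iter=30, k_per_iter=1,
            seed=rep_seed,
        )
        rng = np.random.default_rng(rep_seed + 9999)
        idx = rng.choice(len(cands), size=len(tr_qbc), replace=False)
        tr_rand = TrainingSet()
        for i in sorted(idx):
            tr_rand.add(calc.label(cands[i]), iteration=0)
        if worst_err(tr_qbc, spec) <= worst_err(tr_rand, spec):
            wins += 1
    return wins / repeats
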