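"""Query-by-committee active learning over candidate geometry pools.

A committee of independently trained surrogate models scores every
candidate by the spread of its force predictions; the candidates the
committee disagrees on most are labeled with the reference calculator
and added to the training set, and the committee is retrained from
scratch.  Iterating this concentrates labeling effort on the least
understood regions of configuration space and yields compact training
sets of near-uniform accuracy.

The committee-model contract is deliberately thin — ``fit`` on labeled
geometries, ``predict`` returning (energy, forces) — so any regressor
can stand in for the neural-network potentials used in production.  The
shipped :class:`KernelRidgeModel` (RBF kernel ridge with analytic force
gradients) exists to make the loop testable end to end on analytic
potentials; :class:`MockModel` provides prescribed, instant predictions
for arithmetic and protocol tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.kernel_ridge import KernelRidge

from .calculators import Calculator
from .geometry import CandidateSet, Geometry, TrainingSet


class CommitteeModel(Protocol):
    """Trainable regressor contract used by committee members."""

    def fit(self, labeled: Sequence[Geometry]) -> None: ...

    def predict(self, geometry: Geometry) -> tuple[float, np.ndarray]: ...


@dataclass
class CommitteeSpec:
    """How to build a committee: member count, subset fraction, factory.

    Each member is trained on its own random ``training_fraction`` subset
    (without replacement, default 90%) with its own seed, to keep the
    committee diverse.  ``model_factory(seed)`` must return a fresh model.
    """

    model_factory: Callable[[int], CommitteeModel]
    n_members: int = 8
    training_fraction: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("a committee needs at least 2 members")
        if not (0.0 < self.training_fraction <= 1.0):
            raise ValueError("training fraction must lie in (0, 1]")


@dataclass
class DisagreementRecord:
    """Per-structure committee force disagreement.

    ``per_atom`` holds, for every atom, the Euclidean norm of the
    componentwise standard deviation of the member force predictions;
    ``sigma_f`` is the mean over the masked atoms (eV/Å).
    """

    sigma_f: float
    per_atom: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma_f < 0:
            raise ValueError("disagreement cannot be negative")


class Committee:
    """Trained committee: mean predictions plus member-level access."""

    def __init__(self, members: list[CommitteeModel], spec: CommitteeSpec):
        self.members = members
        self.spec = spec

    def predict_members(self, geometry: Geometry) -> list[tuple[float, np.ndarray]]:
        return [m.predict(geometry) for m in self.members]

    def predict(self, geometry: Geometry) -> tuple[float, np.ndarray]:
        """Committee prediction: the average over members."""
        preds = self.predict_members(geometry)
        e = float(np.mean([p[0] for p in preds]))
        f = np.mean([p[1] for p in preds], axis=0)
        return e, f


def train_committee(training: TrainingSet, spec: CommitteeSpec) -> Committee:
    """Fit every member on its own random subset of the training set."""
    n = len(training)
    if n < spec.n_members:
        raise ValueError(
            f"training set of {n} too small for {spec.n_members} members"
        )
    for g in training:
        if g.energy is None or g.forces is None:
            raise ValueError("training entries must be fully labeled")
    seed_rng = np.random.default_rng(spec.seed)
    members: list[CommitteeModel] = []
    size = max(1, int(round(spec.training_fraction * n)))
    for _ in range(spec.n_members):
        member_seed = int(seed_rng.integers(2**31))
        subset_rng = np.random.default_rng(member_seed)
        idx = subset_rng.choice(n, size=size, replace=False)
        model = spec.model_factory(member_seed)
        model.fit([training[i] for i in idx])
        members.append(model)
    return Committee(members, spec)


def force_disagreement(
    committee: Committee, geometry: Geometry, atom_mask=None
) -> DisagreementRecord:
    """Committee force disagreement for one structure.

    For each atom the componentwise (population) standard deviation of
    the member force predictions is reduced to its Euclidean norm; the
    per-structure scalar is the mean of these norms over the masked atoms
    (default: all atoms; pass a boolean mask or index list to restrict,
    e.g., to the heavy atoms).
    """
    forces = np.array([f for _, f in committee.predict_members(geometry)])
    if atom_mask is None:
        mask = np.ones(geometry.n_atoms, dtype=bool)
    else:
        mask = np.zeros(geometry.n_atoms, dtype=bool)
        mask[np.asarray(atom_mask, dtype=int)] = True
    if not np.any(mask):
        raise ValueError("atom mask selects no atoms")
    std = np.std(forces, axis=0, ddof=0)  # (N, 3)
    per_atom = np.linalg.norm(std, axis=1)
    sigma_f = float(np.mean(per_atom[mask]))
    return DisagreementRecord(sigma_f=sigma_f, per_atom=per_atom, mask=mask)


def qbc_select(candidates: CandidateSet, committee: Committee, k: int, atom_mask=None):
    """Indices of the ``k`` candidates with the highest force disagreement.

    Ties are broken deterministically toward the lower candidate index.
    Also returns the full score vector.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(candidates):
        raise ValueError(f"cannot select {k} from {len(candidates)} candidates")
    scores = np.array(
        [force_disagreement(committee, g, atom_mask).sigma_f for g in candidates]
    )
    order = np.argsort(-scores, kind="stable")
    return order[:k].tolist(), scores


def stopping_check(
    selected_disagreements, remaining_disagreements, ratio_threshold: float = 1.5
) -> bool:
    """Stop when selected and remaining disagreements are similar.

    Returns True (stop) when mean(selected) / mean(remaining) ≤
    ``ratio_threshold`` (boundary inclusive).
    """
    sel = np.asarray(selected_disagreements, dtype=float)
    rem = np.asarray(remaining_disagreements, dtype=float)
    if sel.size == 0 or rem.size == 0:
        raise ValueError("both disagreement sets must be non-empty")
    mean_rem = float(np.mean(rem))
    if mean_rem == 0.0:
        return True
    return float(np.mean(sel)) / mean_rem <= ratio_threshold


def qbc_run(
    candidates: CandidateSet,
    labeler: Calculator,
    spec: CommitteeSpec,
    n_init: int = 20,
    n_iter: int = 40,
    k_per_iter: int = 10,
    seed: int = 0,
    stopping: float | None = None,
    atom_mask=None,
) -> TrainingSet:
    """The query-by-committee loop: candidate pool → training set.

    Iteration 0 labels ``n_init`` uniformly random candidates.  Each
    subsequent iteration trains a fresh committee on the current training
    set, scores every remaining candidate, and labels the ``k_per_iter``
    with the highest force disagreement; selected candidates leave the
    pool, so nothing is ever labeled twice.  Without a stopping rule the
    final size is exactly ``n_init + n_iter · k_per_iter``; with
    ``stopping`` set, the loop ends early once the selected and remaining
    disagreements become similar (ratio ≤ ``stopping``), checked before
    labeling.  A per-iteration disagreement log lands in ``result.log``.
    """
    pool = list(range(len(candidates)))
    if len(pool) < n_init + n_iter * k_per_iter:
        raise ValueError(
            f"pool of {len(pool)} cannot supply "
            f"{n_init} + {n_iter}×{k_per_iter} structures"
        )
    rng = np.random.default_rng(seed)
    training = TrainingSet()
    init_idx = rng.choice(len(pool), size=n_init, replace=False)
    for i in sorted(init_idx):
        training.add(_label(labeler, candidates[pool[i]]), iteration=0)
    for i in sorted(init_idx, reverse=True):
        del pool[i]
    training.log.append({"iteration": 0, "n_selected": n_init, "size": len(training)})

    for it in range(1, n_iter + 1):
        committee = train_committee(
            training, _respec(spec, seed_offset=it)
        )
        remaining = CandidateSet(
            [candidates[i] for i in pool],
            [candidates.provenance[i] for i in pool],
        )
        top, scores = qbc_select(remaining, committee, k_per_iter, atom_mask)
        sel_scores = scores[top]
        rest_scores = np.delete(scores, top)
        entry = {
            "iteration": it,
            "n_selected": k_per_iter,
            "mean_selected": float(np.mean(sel_scores)) if len(top) else 0.0,
            "max_selected": float(np.max(sel_scores)) if len(top) else 0.0,
            "mean_remaining": float(np.mean(rest_scores)) if rest_scores.size else 0.0,
        }
        if (
            stopping is not None
            and rest_scores.size
            and stopping_check(sel_scores, rest_scores, stopping)
        ):
            entry["stopped"] = True
            training.log.append(entry)
            break
        for j in top:
            training.add(_label(labeler, candidates[pool[j]]), iteration=it)
        for j in sorted(top, reverse=True):
            del pool[j]
        entry["size"] = len(training)
        training.log.append(entry)
    return training


def augment_pool(
    training: TrainingSet,
    new_candidates: CandidateSet,
    labeler: Calculator,
    spec: CommitteeSpec,
    k_per_iter: int = 15,
    stopping: float = 1.5,
    max_iter: int = 200,
    atom_mask=None,
) -> TrainingSet:
    """Continue QbC from an existing training set against a new pool.

    Supports iterative refinement across model generations: a pool
    produced by any means (file, MD trajectory, a new tube) is screened
    and ``k_per_iter`` structures are added per iteration until the
    selected and remaining force disagreements become similar or the pool
    runs out.  The incoming training set is not modified.
    """
    if len(new_candidates) == 0:
        raise ValueError("new candidate pool is empty")
    out = TrainingSet()
    for g, it in zip(training.entries, training.iterations):
        out.add(g, it)
    out.log = list(training.log)
    start_iter = (training.iterations[-1] if len(training) else 0) + 1
    pool = list(range(len(new_candidates)))
    for it in range(start_iter, start_iter + max_iter):
        if len(pool) < k_per_iter:
            break
        committee = train_committee(out, _respec(spec, seed_offset=it))
        remaining = CandidateSet(
            [new_candidates[i] for i in pool],
            [new_candidates.provenance[i] for i in pool],
        )
        top, scores = qbc_select(remaining, committee, k_per_iter, atom_mask)
        sel_scores = scores[top]
        rest_scores = np.delete(scores, top)
        entry = {
            "iteration": it,
            "mean_selected": float(np.mean(sel_scores)),
            "mean_remaining": float(np.mean(rest_scores)) if rest_scores.size else 0.0,
        }
        if rest_scores.size and stopping_check(sel_scores, rest_scores, stopping):
            entry["stopped"] = True
            out.log.append(entry)
            break
        for j in top:
            out.add(_label(labeler, new_candidates[pool[j]]), iteration=it)
        for j in sorted(top, reverse=True):
            del pool[j]
        entry["size"] = len(out)
        out.log.append(entry)
    return out


def _label(labeler: Calculator, geometry: Geometry) -> Geometry:
    try:
        return labeler.label(geometry)
    except Exception as exc:
        raise RuntimeError(
            f"labeling failed for structure {geometry.metadata or geometry.coords[0]}: {exc}"
        ) from exc


def _respec(spec: CommitteeSpec, seed_offset: int) -> CommitteeSpec:
    return CommitteeSpec(
        model_factory=spec.model_factory,
        n_members=spec.n_members,
        training_fraction=spec.training_fraction,
        seed=spec.seed + seed_offset,
    )


# ---------------------------------------------------------------------------
# reference and mock committee models


class KernelRidgeModel:
    """RBF kernel-ridge energy surrogate with analytic force gradients.

    Features are either raw flattened Cartesians (``features="cartesian"``,
    appropriate for model potentials without rigid-body invariance) or the
    condensed vector of interatomic distances (``features="distances"``,
    translation/rotation invariant).  The kernel width follows the median
    pairwise-distance heuristic, jittered per member seed so members stay
    distinguishable even on identical subsets.  Energies only are fit;
    forces come from the analytic gradient of the fitted surrogate.
    """

    def __init__(
        self,
        seed: int | None = None,
        features: str = "cartesian",
        alpha: float = 1e-10,
        gamma: float | None = None,
        gamma_jitter: float = 0.2,
    ) -> None:
        if features not in ("cartesian", "distances"):
            raise ValueError("features must be 'cartesian' or 'distances'")
        self.seed = seed
        self.features = features
        self.alpha = alpha
        self.gamma = gamma
        self.gamma_jitter = gamma_jitter
        self._kr: KernelRidge | None = None
        self._x_train: np.ndarray | None = None

    def _featurize(self, geometry: Geometry) -> np.ndarray:
        if self.features == "cartesian":
            return geometry.flat()
        return pdist(geometry.coords)

    def _feature_jacobian(self, geometry: Geometry) -> np.ndarray:
        """d(features)/d(flat coords), shape (n_features, 3N)."""
        n = geometry.n_atoms
        if self.features == "cartesian":
            return np.eye(3 * n)
        jac = np.zeros((n * (n - 1) // 2, 3 * n))
        k = 0
        for a in range(n):
            for b in range(a + 1, n):
                d = geometry.coords[a] - geometry.coords[b]
                r = np.linalg.norm(d)
                jac[k, 3 * a : 3 * a + 3] = d / r
                jac[k, 3 * b : 3 * b + 3] = -d / r
                k += 1
        return jac

    def fit(self, labeled: Sequence[Geometry]) -> None:
        x = np.array([self._featurize(g) for g in labeled])
        y = np.array([g.energy for g in labeled], dtype=float)
        if self.gamma is None:
            d = pdist(x)
            med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
            gamma = 1.0 / (2.0 * med**2)
        else:
            gamma = self.gamma
        if self.seed is not None and self.gamma_jitter > 0:
            jit = np.random.default_rng(self.seed).uniform(
                1.0 - self.gamma_jitter, 1.0 + self.gamma_jitter
            )
            gamma *= jit
        self._gamma = float(gamma)
        self._kr = KernelRidge(alpha=self.alpha, kernel="rbf", gamma=self._gamma)
        self._kr.fit(x, y)
        self._x_train = x

    def predict(self, geometry: Geometry) -> tuple[float, np.ndarray]:
        if self._kr is None:
            raise RuntimeError("model is not fitted")
        x = self._featurize(geometry)
        diff = x[None, :] - self._x_train
        k = np.exp(-self._gamma * np.sum(diff**2, axis=1))
        coef = np.asarray(self._kr.dual_coef_).reshape(-1)
        energy = float(coef @ k)
        de_df = -2.0 * self._gamma * (coef * k) @ diff  # dE/d(features)
        de_dx = self._feature_jacobian(geometry).T @ de_df
        return energy, -de_dx.reshape(geometry.n_atoms, 3)


class MockModel:
    """Instant pseudo-model with deterministic, structure-hashed output.

    ``fit`` is a no-op; ``predict`` derives energy and forces from a hash
    of the coordinates and the member seed, so committees of mock members
    produce reproducible, nonzero disagreements at zero cost.  Used for
    protocol and arithmetic tests of the active-learning loop.
    """

    def __init__(self, seed: int = 0, force_scale: float = 0.1) -> None:
        self.seed = int(seed)
        self.force_scale = float(force_scale)

    def fit(self, labeled: Sequence[Geometry]) -> None:
        pass

    def predict(self, geometry: Geometry) -> tuple[float, np.ndarray]:
        digest = hashlib.sha256(
            geometry.coords.tobytes() + self.seed.to_bytes(8, "little")
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        energy = float(rng.normal())
        forces = self.force_scale * rng.standard_normal((geometry.n_atoms, 3))
        return energy, forces


class PrescribedDisagreementCommittee(Committee):
    """Two-member committee realizing a prescribed per-structure σ_F.

    ``score_fn(geometry)`` gives the desired force-disagreement scalar;
    the two members' forces differ by 2·N·σ_F on the first atom only, so
    :func:`force_disagreement` recovers exactly the prescribed value.
    Useful for testing selection and stopping logic in isolation.
    """

    def __init__(self, score_fn: Callable[[Geometry], float]):
        self.score_fn = score_fn
        self.members = [self, self]  # placeholder; predict_members overridden
        self.spec = None

    def predict_members(self, geometry: Geometry):
        n = geometry.n_atoms
        target = float(self.score_fn(geometry))
        f1 = np.zeros((n, 3))
        f2 = np.zeros((n, 3))
        f2[0, 0] = 2.0 * n * target
        return [(0.0, f1), (0.0, f2)]
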