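"""Committee training, force disagreement, selection and the QbC loop."""

import numpy as np
import pytest

import transtube as tt
from transtube.geometry import CandidateSet, Provenance, TrainingSet
from transtube.harmonic import ThermalSpec
from transtube.qbc import (
    Committee,
    CommitteeSpec,
    KernelRidgeModel,
    MockModel,
    PrescribedDisagreementCommittee,
    augment_pool,
    force_disagreement,
    qbc_run,
    qbc_select,
    stopping_check,
    train_committee,
)


def mock_spec(n_members=8, fraction=0.9, seed=0):
    return CommitteeSpec(
        model_factory=lambda s: MockModel(seed=s),
        n_members=n_members,
        training_fraction=fraction,
        seed=seed,
    )


def krr_spec(seed=0, n_members=8, fraction=1.0):
    """Reference committee used in the toy-potential studies."""
    return CommitteeSpec(
        model_factory=lambda s: KernelRidgeModel(
            seed=s, gamma=10.0, alpha=1e-6, gamma_jitter=0.3
        ),
        n_members=n_members,
        training_fraction=fraction,
        seed=seed,
    )


def random_candidates(n, n_atoms=2, seed=0):
    rng = np.random.default_rng(seed)
    out = CandidateSet()
    for _ in range(n):
        out.append(
            tt.Geometry(["X"] * n_atoms, rng.standard_normal((n_atoms, 3))),
            Provenance("nms"),
        )
    return out


def labeled_training(n, n_atoms=2, seed=0):
    rng = np.random.default_rng(seed)
    ts = TrainingSet()
    for _ in range(n):
        ts.add(
            tt.Geometry(
                ["X"] * n_atoms,
                rng.standard_normal((n_atoms, 3)),
                energy=float(rng.standard_normal()),
                forces=rng.standard_normal((n_atoms, 3)),
            ),
            iteration=0,
        )
    return ts


@pytest.fixture(scope="module")
def toy_tube(toy_mep, toy_calc, toy_control_points):
    """A small candidate tube on the model potential."""
    return tt.tts_generate(
        toy_mep, [0, 0.5, 1], toy_calc, ThermalSpec(300.0, "classical"),
        130.0, seed=42, control_points=toy_control_points,
    )


class TestCommitteeSpec:
    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            CommitteeSpec(model_factory=lambda s: MockModel(s), n_members=1)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_bad_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            CommitteeSpec(
                model_factory=lambda s: MockModel(s),
                training_fraction=fraction,
            )


class TestTrainCommittee:
    def test_full_fraction_deterministic_models_agree_exactly(self):
        """fraction = 1 with seed-independent models: zero disagreement."""
        training = labeled_training(12)
        spec = CommitteeSpec(
            model_factory=lambda s: KernelRidgeModel(
                seed=None, gamma=1.0, gamma_jitter=0.0
            ),
            n_members=3,
            training_fraction=1.0,
        )
        committee = train_committee(training, spec)
        rec = force_disagreement(committee, training[0])
        assert rec.sigma_f == pytest.approx(0.0, abs=1e-12)

    def test_training_smaller_than_committee_rejected(self):
        with pytest.raises(ValueError):
            train_committee(labeled_training(3), mock_spec(n_members=8))

    def test_committee_mean_beats_worst_member_on_held_out(
        self, toy_tube, toy_calc
    ):
        """Convexity in action: the committee-average energy RMSE on a
        held-out set never exceeds that of the worst single member."""
        training = TrainingSet()
        for i in range(0, 200, 1):
            training.add(toy_calc.label(toy_tube[i]), iteration=0)
        held_out = [toy_calc.label(toy_tube[i]) for i in range(300, 400)]
        committee = train_committee(training, krr_spec(seed=1, fraction=0.9))

        def rmse(pred):
            return float(np.sqrt(np.mean(
                [(pred(g)[0] - g.energy) ** 2 for g in held_out]
            )))

        rmse_committee = rmse(committee.predict)
        rmse_members = [rmse(m.predict) for m in committee.members]
        assert rmse_committee <= max(rmse_members) + 1e-12


class TestForceDisagreement:
    def test_identical_members_zero(self):
        g = tt.Geometry(["X", "X"], np.zeros((2, 3)))
        m = MockModel(seed=7)
        committee = Committee([m, m], spec=None)
        assert force_disagreement(committee, g).sigma_f == 0.0

    def test_two_member_hand_value(self):
        """Members differing by Δ on one of N atoms: σ_F = ‖Δ‖/(2N)."""
        n = 4
        g = tt.Geometry(["X"] * n, np.zeros((n, 3)))
        delta = np.array([0.3, -0.4, 1.2])

        class A:
            def predict(self, geom):
                return 0.0, np.zeros((n, 3))

        class B:
            def predict(self, geom):
                f = np.zeros((n, 3))
                f[2] = delta
                return 0.0, f

        rec = force_disagreement(Committee([A(), B()], None), g)
        assert rec.sigma_f == pytest.approx(np.linalg.norm(delta) / (2 * n))

    def test_mask_restricts_to_selected_atoms(self):
        n = 4
        g = tt.Geometry(["X"] * n, np.zeros((n, 3)))

        class A:
            def predict(self, geom):
                return 0.0, np.zeros((n, 3))

        class B:
            def predict(self, geom):
                f = np.zeros((n, 3))
                f[2, 0] = 2.0
                return 0.0, f

        committee = Committee([A(), B()], None)
        assert force_disagreement(committee, g, atom_mask=[0, 1]).sigma_f == 0.0
        assert force_disagreement(committee, g, atom_mask=[2]).sigma_f == pytest.approx(1.0)
        with pytest.raises(ValueError):
            force_disagreement(committee, g, atom_mask=[])


class TestSelect:
    def test_ordering_with_ties_toward_lower_index(self):
        cands = random_candidates(3)
        scores = {0: 3.0, 1: 1.0, 2: 2.0}
        committee = PrescribedDisagreementCommittee(
            lambda g: scores[id_of(g, cands)]
        )
        top, _ = qbc_select(cands, committee, 2)
        assert top == [0, 2]

    @pytest.mark.parametrize("k,expected_len", [(0, 0), (3, 3)])
    def test_boundary_k(self, k, expected_len):
        cands = random_candidates(3)
        committee = PrescribedDisagreementCommittee(lambda g: 1.0)
        top, _ = qbc_select(cands, committee, k)
        assert len(top) == expected_len

    def test_k_too_large_rejected(self):
        cands = random_candidates(3)
        committee = PrescribedDisagreementCommittee(lambda g: 1.0)
        with pytest.raises(ValueError):
            qbc_select(cands, committee, 4)


def id_of(g, cands):
    for i, c in enumerate(cands.items):
        if np.array_equal(c.coords, g.coords):
            return i
    raise KeyError


class TestStopping:
    def test_similar_distributions_stop(self):
        assert stopping_check([1.0, 1.1], [1.0, 0.9]) is True

    def test_large_gap_continues(self):
        assert stopping_check([10.0], [1.0]) is False

    def test_boundary_inclusive(self):
        assert stopping_check([1.5], [1.0], ratio_threshold=1.5) is True

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            stopping_check([], [1.0])


class TestQbcRun:
    @pytest.mark.parametrize(
        "n_init,n_iter,k,total",
        [(20, 40, 10, 420), (20, 40, 15, 620), (20, 0, 10, 20)],
    )
    def test_training_set_arithmetic(self, toy_calc, n_init, n_iter, k, total):
        """The fixed schedules yield their exact final training-set sizes."""
        pool = 700
        cands = random_candidates(pool, n_atoms=1, seed=3)
        training = qbc_run(
            cands, toy_calc, mock_spec(), n_init=n_init, n_iter=n_iter,
            k_per_iter=k, seed=5,
        )
        assert len(training) == total
        assert training.iterations[0] == 0
        assert training.iterations[-1] == (n_iter if n_iter else 0)

    def test_no_candidate_labeled_twice(self, toy_calc):
        cands = random_candidates(80, n_atoms=1, seed=4)
        training = qbc_run(
            cands, toy_calc, mock_spec(), n_init=10, n_iter=5, k_per_iter=5,
            seed=6,
        )
        coords = [tuple(g.coords.reshape(-1)) for g in training]
        assert len(set(coords)) == len(coords) == 35

    def test_pool_too_small_rejected(self, toy_calc):
        with pytest.raises(ValueError):
            qbc_run(
                random_candidates(30, n_atoms=1), toy_calc, mock_spec(),
                n_init=20, n_iter=40, k_per_iter=10, seed=0,
            )

    def test_per_iteration_log_emitted(self, toy_calc):
        training = qbc_run(
            random_candidates(60, n_atoms=1, seed=8), toy_calc, mock_spec(),
            n_init=10, n_iter=4, k_per_iter=5, seed=0,
        )
        assert len(training.log) == 5  # init + 4 iterations
        assert all("mean_selected" in e for e in training.log[1:])

    def test_selected_disagreement_decays_on_the_tube(self, toy_tube, toy_calc):
        """Across ≥5-iteration windows the mean selected disagreement of the
        reference committee does not increase (it chases the largest
        remaining gaps, which shrink as they are filled)."""
        training = qbc_run(
            toy_tube, toy_calc, krr_spec(seed=2), n_init=10, n_iter=20,
            k_per_iter=2, seed=2,
        )
        sel = [e["mean_selected"] for e in training.log[1:]]
        first, last = np.mean(sel[:5]), np.mean(sel[-5:])
        assert last <= first

    def test_stopping_rule_halts_early(self, toy_calc):
        """A mock committee's disagreements are statistically identical
        across the pool, so the ratio test fires immediately."""
        training = qbc_run(
            random_candidates(200, n_atoms=1, seed=9), toy_calc, mock_spec(),
            n_init=20, n_iter=10, k_per_iter=10, seed=1, stopping=1.5,
        )
        assert len(training) == 20
        assert training.log[-1].get("stopped") is True


class TestAugmentPool:
    def test_statistically_identical_pool_stops_immediately(self, toy_calc):
        training = TrainingSet()
        for g in random_candidates(30, n_atoms=1, seed=10).items:
            training.add(toy_calc.label(g), iteration=0)
        pool = random_candidates(100, n_atoms=1, seed=11)
        out = augment_pool(
            training, pool, toy_calc, mock_spec(), k_per_iter=15, stopping=1.5
        )
        assert len(out) == len(training)
        assert out.log[-1].get("stopped") is True

    def test_unseen_basin_selected_first(self, toy_calc, toy_minima):
        """A pool region absent from the training support (the second basin
        of the double-well) carries the top committee disagreement."""
        a, b = toy_minima
        thermal = ThermalSpec(300.0, "classical")
        seen = tt.nms_sample(a, toy_calc, thermal, 60, seed=12)
        training = TrainingSet()
        for g in seen.items[:40]:
            training.add(toy_calc.label(g), iteration=0)
        pool = CandidateSet()
        for g, p in zip(seen.items[40:], seen.provenance[40:]):
            pool.append(g, p)
        unseen = tt.nms_sample(b, toy_calc, thermal, 20, seed=13)
        for g, p in zip(unseen.items, unseen.provenance):
            pool.append(g, p)
        # kernel width comparable to the inter-basin distance, so the
        # committee can "see" (and disagree about) the far basin at all
        spec = CommitteeSpec(
            model_factory=lambda s: KernelRidgeModel(
                seed=s, gamma=1.0, alpha=1e-6, gamma_jitter=0.3
            ),
            n_members=8, training_fraction=1.0, seed=3,
        )
        committee = train_committee(training, spec)
        top, _ = qbc_select(pool, committee, 10)
        frac_unseen = np.mean([i >= 20 for i in top])
        assert frac_unseen >= 0.8

    def test_empty_pool_rejected(self, toy_calc):
        training = labeled_training(10, n_atoms=1)
        with pytest.raises(ValueError):
            augment_pool(
                training, CandidateSet(), toy_calc, mock_spec(), k_per_iter=5
            )


class TestKernelRidgeModel:
    def test_forces_are_negative_gradient_of_prediction(self, toy_tube, toy_calc):
        training = [toy_calc.label(g) for g in toy_tube.items[:50]]
        model = KernelRidgeModel(seed=0, gamma=10.0)
        model.fit(training)
        g = toy_tube[60]
        _, forces = model.predict(g)
        h = 1e-5
        for k in range(3):
            plus = g.flat().copy()
            plus[k] += h
            minus = g.flat().copy()
            minus[k] -= h
            ep, _ = model.predict(g.with_coords(plus))
            em, _ = model.predict(g.with_coords(minus))
            assert forces.reshape(-1)[k] == pytest.approx(
                -(ep - em) / (2 * h), abs=1e-5
            )

    def test_distance_features_rotation_invariant(self):
        rng = np.random.default_rng(14)
        training = [
            tt.Geometry(
                ["X"] * 3,
                rng.standard_normal((3, 3)),
                energy=float(rng.standard_normal()),
                forces=np.zeros((3, 3)),
            )
            for _ in range(20)
        ]
        model = KernelRidgeModel(seed=0, features="distances")
        model.fit(training)
        g = training[0]
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=1).as_matrix()
        g_rot = g.with_coords(g.coords @ rot.T)
        assert model.predict(g)[0] == pytest.approx(
            model.predict(g_rot)[0], rel=1e-10
        )
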