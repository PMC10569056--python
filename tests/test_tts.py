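"""Control points, partition-of-unity weights, tube sampling, caps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

import transtube as tt
from transtube.constants import KB
from transtube.harmonic import ThermalSpec, mode_sigma, normal_mode_analysis
from transtube.mep import tangent
from transtube.tts import (
    build_control_points,
    control_point_weights,
    distort_reference,
    endpoint_caps,
    sample_reference_points,
    tts_generate,
)


class TestBuildControlPoints:
    def test_toy_landscape_mode_structure(self, toy_control_points):
        """Endpoints are minima (one flat z direction); the barrier-top
        control point additionally has the flat quartic path direction."""
        first, middle, last = toy_control_points
        for cp in (first, last):
            assert cp.n_imaginary == 0
            assert len(cp.modes.zero_mode_indices) == 1
            assert cp.modes.n_internal == 2
        assert middle.n_imaginary == 0
        assert len(middle.modes.zero_mode_indices) == 2
        assert middle.modes.n_internal == 1

    def test_harmonic_pes_frequencies_identical_everywhere(
        self, straight_tube_system
    ):
        cps = build_control_points(
            straight_tube_system["mep"],
            [0.0, 0.4, 1.0],
            straight_tube_system["calc"],
        )
        ref = cps[0].modes.frequencies
        for cp in cps[1:]:
            assert np.allclose(cp.modes.frequencies, ref, rtol=1e-5)

    def test_unsorted_xi_rejected(self, toy_mep, toy_calc):
        with pytest.raises(ValueError):
            build_control_points(toy_mep, [0.0, 0.7, 0.5, 1.0], toy_calc)

    def test_endpoints_required(self, toy_mep, toy_calc):
        with pytest.raises(ValueError):
            build_control_points(toy_mep, [0.1, 0.5, 1.0], toy_calc)


class TestControlPointWeights:
    def test_peak_at_own_center(self):
        centers = [0.0, 0.3, 1.0]
        w = control_point_weights(0.3, centers)
        assert np.allclose(w, [0.0, 1.0, 0.0], atol=1e-15)

    def test_midway_split_is_half_half(self):
        w = control_point_weights(0.65, [0.0, 0.3, 1.0])
        assert w[1] == pytest.approx(0.5)
        assert w[2] == pytest.approx(0.5)

    def test_vanishes_outside_support(self):
        centers = [0.0, 0.25, 0.5, 1.0]
        w = control_point_weights(0.8, centers)
        assert w[0] == 0.0 and w[1] == 0.0

    def test_overhang_carries_full_weight(self):
        centers = [0.2, 0.6]
        assert control_point_weights(0.05, centers)[0] == 1.0
        assert control_point_weights(0.95, centers)[1] == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n_p=st.integers(2, 8),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_partition_of_unity_any_layout(self, n_p, seed):
        """Σ_c p_c(ξ) = 1 identically for any strictly increasing layout."""
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.uniform(0.0, 1.0, n_p))
        centers += np.arange(n_p) * 1e-6  # enforce strict monotonicity
        centers = np.clip(centers, 0.0, 1.0)
        if np.any(np.diff(centers) <= 0):
            return
        xi = rng.uniform(0.0, 1.0, 500)
        w = control_point_weights(xi, centers)
        assert np.max(np.abs(w.sum(axis=1) - 1.0)) < 1e-12
        assert np.all(w >= 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            control_point_weights(1.2, [0.0, 1.0])


class TestSampleReferencePoints:
    def test_count_follows_density_times_length(self, straight_tube_system):
        """ρ = 10³ Å⁻¹ on a 2 Å path gives exactly 2000 reference points."""
        mep = straight_tube_system["mep"]
        cps = build_control_points(
            mep, [0.0, 0.5, 1.0], straight_tube_system["calc"]
        )
        refs = sample_reference_points(mep, cps, 1000.0, seed=0)
        assert len(refs) == round(1000.0 * mep.arc_length) == 2000

    def test_xi_marginal_uniform(self, straight_tube_system):
        mep = straight_tube_system["mep"]
        cps = build_control_points(
            mep, [0.0, 0.5, 1.0], straight_tube_system["calc"]
        )
        refs = sample_reference_points(mep, cps, 10_000.0 / mep.arc_length, seed=1)
        xis = np.array([x for x, _ in refs])
        assert kstest(xis, "uniform").pvalue > 0.01

    def test_parent_assignment_follows_weights(self, straight_tube_system):
        mep = straight_tube_system["mep"]
        cps = build_control_points(
            mep, [0.0, 0.5, 1.0], straight_tube_system["calc"]
        )
        refs = sample_reference_points(mep, cps, 20_000.0 / mep.arc_length, seed=2)
        lo, hi = 0.2, 0.24
        sel = [(x, p) for x, p in refs if lo <= x < hi]
        n = len(sel)
        k = sum(1 for _, p in sel if p == 0)
        p_expected = float(
            np.mean(control_point_weights(np.linspace(lo, hi, 50), [0, 0.5, 1])[:, 0])
        )
        sd = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(k / n - p_expected) < 3 * sd + 1e-9

    def test_too_low_density_rejected(self, straight_tube_system):
        mep = straight_tube_system["mep"]
        cps = build_control_points(
            mep, [0.0, 0.5, 1.0], straight_tube_system["calc"]
        )
        with pytest.raises(ValueError):
            sample_reference_points(mep, cps, 1e-6, seed=0)


class TestDistortReference:
    def test_displacement_strictly_perpendicular(self, toy_mep, toy_control_points):
        thermal = ThermalSpec(300.0, "classical")
        rng = np.random.default_rng(3)
        sqrt_m = np.sqrt(np.repeat(toy_mep.masses, 3))
        for xi in rng.uniform(0, 1, 50):
            parent = toy_control_points[int(np.argmin(
                [abs(cp.xi - xi) for cp in toy_control_points]
            ))]
            g = distort_reference(toy_mep, xi, parent, thermal, rng=rng)
            delta_mw = (g.flat() - toy_mep.coords(xi).reshape(-1)) * sqrt_m
            norm = np.linalg.norm(delta_mw)
            if norm == 0:
                continue
            tau = tangent(toy_mep, xi)
            assert abs(tau @ delta_mw) / norm < 1e-8

    def test_zero_temperature_classical_no_displacement(
        self, toy_mep, toy_control_points
    ):
        g = distort_reference(
            toy_mep, 0.3, toy_control_points[0], ThermalSpec(0.0), seed=0
        )
        assert np.max(np.abs(g.coords - toy_mep.coords(0.3))) == 0.0

    def test_perpendicular_variances_match_mode_widths(
        self, straight_tube_system
    ):
        """On a quadratic PES with a straight MEP the perpendicular moments
        are exactly the analytic per-mode thermal widths."""
        mep = straight_tube_system["mep"]
        cps = build_control_points(
            mep, [0.0, 0.5, 1.0], straight_tube_system["calc"]
        )
        thermal = ThermalSpec(300.0, "classical")
        rng = np.random.default_rng(4)
        parent = cps[1]
        sqrt_m = np.sqrt(np.repeat(mep.masses, 3))
        n = 10_000
        xi = 0.5
        deltas = np.empty((n, 6))
        for i in range(n):
            g = distort_reference(mep, xi, parent, thermal, rng=rng)
            deltas[i] = (g.flat() - mep.coords(xi).reshape(-1)) * sqrt_m
        freqs, vecs = parent.modes.real_modes()
        tau = tangent(mep, xi)
        sigma = mode_sigma(freqs, thermal)
        for k in range(freqs.size):
            overlap = float(vecs[k] @ tau)
            expected = sigma[k] ** 2 * (1 - overlap**2) ** 2 + sum(
                sigma[j] ** 2 * (vecs[j] @ tau) ** 2 * (vecs[k] @ tau) ** 2
                for j in range(freqs.size) if j != k
            )
            got = np.var(deltas @ vecs[k])
            assert got == pytest.approx(expected, rel=0.05)


@pytest.fixture(scope="module")
def cap_setup(straight_tube_system):
    mep = straight_tube_system["mep"]
    cps = build_control_points(
        mep, [0.0, 0.5, 1.0], straight_tube_system["calc"]
    )
    return straight_tube_system, cps


class TestEndpointCaps:

    def test_all_caps_point_outward(self, cap_setup):
        system, cps = cap_setup
        mep = system["mep"]
        thermal = ThermalSpec(300.0, "classical")
        caps = endpoint_caps(mep, (cps[0], cps[-1]), thermal, 2000.0, seed=5)
        assert len(caps) > 0
        sqrt_m = np.sqrt(np.repeat(mep.masses, 3))
        for g, prov in zip(caps.items, caps.provenance):
            assert prov.source == "tts-cap"
            sign = -1.0 if prov.xi == 0.0 else +1.0
            tau_out = sign * tangent(mep, prov.xi)
            ref = mep.coords(prov.xi).reshape(-1)
            proj = ((g.flat() - ref) * sqrt_m) @ tau_out
            assert proj >= 0.0

    def test_density_continuity_across_the_endpoint(self, cap_setup):
        """The half-Gaussian cap's peak linear density along the tangent
        matches the uniform on-path density within 10%."""
        system, cps = cap_setup
        mep = system["mep"]
        thermal = ThermalSpec(300.0, "classical")
        rho = 12_000.0 / mep.arc_length
        cands = tts_generate(
            mep, [0.0, 0.5, 1.0], system["calc"], thermal, rho,
            seed=6, control_points=cps,
        )
        sqrt_m = np.sqrt(np.repeat(mep.masses, 3))
        tau = tangent(mep, 0.0)
        x0 = mep.coords(0.0).reshape(-1) * sqrt_m
        gamma = np.linalg.norm(mep.derivative(0.0) * sqrt_m) / np.linalg.norm(
            mep.derivative(0.0)
        )
        proj = np.array(
            [(g.mass_weighted() - x0) @ tau for g in cands.items]
        )
        length_mw = mep.arc_length * gamma
        h = 0.04 * length_mw
        cap_bin = np.sum((proj >= -h) & (proj < 0.0)) / h
        path_bin = np.sum((proj >= 0.0) & (proj < h)) / h
        assert cap_bin / path_bin == pytest.approx(1.0, abs=0.10)

    def test_zero_temperature_caps_empty(self, cap_setup):
        system, cps = cap_setup
        caps = endpoint_caps(
            system["mep"], (cps[0], cps[-1]), ThermalSpec(0.0), 1000.0, seed=0
        )
        assert len(caps) == 0


class TestTTSGenerate:
    def test_candidates_confined_to_thermal_tube(
        self, toy_mep, toy_calc, toy_control_points
    ):
        """Perpendicular mass-weighted distance stays below 6 σ_max."""
        thermal = ThermalSpec(300.0, "classical")
        cands = tts_generate(
            toy_mep, [0.0, 0.5, 1.0], toy_calc, thermal,
            2000.0 / toy_mep.arc_length, seed=7,
            control_points=toy_control_points,
        )
        sigma_max = max(
            float(np.max(mode_sigma(cp.modes.real_modes()[0], thermal)))
            for cp in toy_control_points
        )
        for g, prov in zip(cands.items, cands.provenance):
            if prov.source != "tts-path":
                continue
            delta_mw = g.mass_weighted() - toy_mep.geometry(prov.xi).mass_weighted()
            assert np.linalg.norm(delta_mw) < 6.0 * sigma_max

    def test_candidate_count_arithmetic(self, straight_tube_system):
        system = straight_tube_system
        thermal = ThermalSpec(300.0, "classical")
        rho = 1500.0
        cands = tts_generate(
            system["mep"], [0.0, 0.5, 1.0], system["calc"], thermal, rho, seed=8
        )
        srcs = [p.source for p in cands.provenance]
        n_on = srcs.count("tts-path")
        assert n_on == round(rho * system["mep"].arc_length)
        assert len(cands) == n_on + srcs.count("tts-cap")

    def test_single_control_point_degenerates_to_nms(self, harmonic_system):
        """Zero-length path: the tube sampler IS plain thermal NMS, bitwise."""
        minimum, _, calc = harmonic_system
        thermal = ThermalSpec(300.0, "classical")
        via_tts = tts_generate(
            minimum, [0.0], calc, thermal, 100.0, seed=9, n_single=50
        )
        direct = tt.nms_sample(minimum, calc, thermal, 50, seed=9)
        assert len(via_tts) == len(direct) == 50
        for a, b in zip(via_tts.items, direct.items):
            assert np.array_equal(a.coords, b.coords)
        with pytest.raises(ValueError):
            tts_generate(minimum, [0.0], calc, thermal, 100.0, seed=9)

    def test_deterministic_under_seed(
        self, toy_mep, toy_calc, toy_control_points
    ):
        thermal = ThermalSpec(300.0, "quantum")
        kw = dict(
            thermal=thermal, linear_density=150.0, seed=11,
            control_points=toy_control_points,
        )
        a = tts_generate(toy_mep, [0, 0.5, 1], toy_calc, **kw)
        b = tts_generate(toy_mep, [0, 0.5, 1], toy_calc, **kw)
        assert len(a) == len(b)
        for ga, gb in zip(a.items, b.items):
            assert np.array_equal(ga.coords, gb.coords)

    def test_quantum_tube_broader_than_classical(
        self, toy_mep, toy_calc, toy_control_points
    ):
        kw = dict(linear_density=1500.0, seed=12, control_points=toy_control_points)
        cl = tts_generate(
            toy_mep, [0, 0.5, 1], toy_calc, ThermalSpec(300.0, "classical"), **kw
        )
        qm = tts_generate(
            toy_mep, [0, 0.5, 1], toy_calc, ThermalSpec(300.0, "quantum"), **kw
        )

        def perp_spread(cands):
            d = []
            for g, prov in zip(cands.items, cands.provenance):
                if prov.source == "tts-path":
                    d.append(np.linalg.norm(
                        g.mass_weighted()
                        - toy_mep.geometry(prov.xi).mass_weighted()
                    ))
            return np.sqrt(np.mean(np.array(d) ** 2))

        assert perp_spread(qm) > perp_spread(cl)
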