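"""Kymographs, elongation/on-rate, zippering, curvature, counting, branches."""

import numpy as np
import pytest
from scipy import stats

from polarimap import kinetics, synthetic


class TestUnitConversion:
    def test_printed_equivalence_38_um_min_is_230_subunits_s(self):
        # 229.47 exactly; 230 at the tens-digit precision of the reference
        v = kinetics.um_per_min_to_subunits_per_s(38.0)
        assert round(v, -1) == 230

    def test_closed_form_for_arbitrary_velocity(self, rng):
        for v in rng.uniform(1, 100, 10):
            assert kinetics.um_per_min_to_subunits_per_s(v) == pytest.approx(
                v * 1000 / 60 / 2.76)

    def test_unit_consistency_um_min_vs_nm_s(self):
        fit = kinetics.elongation_rate([0, 1, 2], [0, 27.6, 55.2])
        assert fit.rate_um_per_min * 1000 / 60 == pytest.approx(fit.rate_nm_per_s)
        assert fit.subunits_per_s == pytest.approx(10.0)


class TestElongationRate:
    def test_zero_slope(self):
        fit = kinetics.elongation_rate([0, 5, 10, 15], [3.0, 3.0, 3.0, 3.0])
        assert fit.rate_nm_per_s == 0.0

    def test_translation_and_time_origin_invariance(self, rng):
        t = np.arange(0, 100, 5.0)
        x = 27.6 * t + rng.normal(0, 10, t.size)
        f1 = kinetics.elongation_rate(t, x)
        f2 = kinetics.elongation_rate(t + 1000.0, x + 5e4)
        assert f2.rate_nm_per_s == pytest.approx(f1.rate_nm_per_s)

    def test_noisy_trace_within_2se_of_truth(self):
        spec = synthetic.GrowthSimSpec(k_on=10.0, actin_conc=1.0,
                                       localization_noise=20.0, seed=3)
        tr = synthetic.generate_growth_trace(spec)
        fit = kinetics.elongation_rate(tr.time_s, tr.tip_nm)
        assert abs(fit.rate_nm_per_s - 27.6) <= 2 * fit.stderr_nm_per_s


class TestOnRate:
    @pytest.mark.parametrize("subunits,conc,expected", [
        (10.0, 1.0, 10.0), (20.0, 2.0, 10.0)])
    def test_simple_ratio(self, subunits, conc, expected):
        assert kinetics.on_rate(subunits, conc) == expected

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            kinetics.on_rate(10.0, 0.0)

    def test_end_to_end_recovery_within_five_percent_over_50_seeds(self):
        # generator truth -> traces -> fitted rates -> mean k_on
        estimates = []
        for seed in range(50):
            spec = synthetic.GrowthSimSpec(k_on=10.0, actin_conc=1.0,
                                           localization_noise=20.0,
                                           duration=300.0, frame_interval=5.0,
                                           seed=seed)
            tr = synthetic.generate_growth_trace(spec)
            fit = kinetics.elongation_rate(tr.time_s, tr.tip_nm)
            estimates.append(kinetics.on_rate(fit.subunits_per_s, 1.0))
        assert np.mean(estimates) == pytest.approx(10.0, rel=0.05)


class TestZippering:
    def test_paper_scale_conversion(self):
        t = np.arange(0, 10, 0.5)
        z = (38.0 / 60.0) * t  # um, 38 um/min
        ev = kinetics.zippering_velocity(t, z)
        assert ev.velocity_um_per_min == pytest.approx(38.0)
        assert round(ev.velocity_subunits_per_s, -1) == 230

    def test_zero_velocity(self):
        ev = kinetics.zippering_velocity([0, 1, 2], [1.0, 1.0, 1.0])
        assert ev.velocity_um_per_min == 0.0


class TestKymograph:
    def test_static_line_gives_constant_columns(self):
        stack = np.zeros((6, 5, 30))
        stack[:, 2, :15] = 10.0
        kymo = kinetics.build_kymograph(stack, (2, 0), (2, 29))
        assert np.ptp(kymo, axis=0) == pytest.approx(0.0)

    def test_advancing_tip_one_pixel_per_frame(self):
        stack = np.zeros((20, 5, 40))
        for t in range(20):
            stack[t, 2, : 5 + t] = 100.0
        kymo = kinetics.build_kymograph(stack, (2, 0), (2, 39))
        tips = kinetics.kymograph_edge(kymo)
        slope = stats.linregress(np.arange(20), tips).slope
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_synthetic_movie_edge_matches_generator_rate(self):
        spec = synthetic.GrowthSimSpec(k_on=10.0, actin_conc=1.0,
                                       duration=200.0, frame_interval=5.0)
        pixel_nm = 100.0
        stack, tr = synthetic.generate_growth_movie(spec, pixel_size_nm=pixel_nm)
        h = stack.shape[1] // 2
        kymo = kinetics.build_kymograph(stack, (h, 0), (h, stack.shape[2] - 1))
        tips = kinetics.kymograph_edge(kymo)
        fit = kinetics.elongation_rate(tr.time_s, tips * pixel_nm)
        # quantization to whole pixels allows ~1 px/frame of slack
        assert abs(fit.rate_nm_per_s - tr.true_rate_nm_per_s) <= pixel_nm / 5.0


class TestCurvature:
    def test_straight_line_zero(self):
        pts = np.column_stack([np.linspace(0, 10, 30), np.zeros(30)])
        assert kinetics.bundle_curvature(pts)["max_curvature_per_um"] == pytest.approx(0.0, abs=1e-9)

    def test_circle_radius_five_gives_point_two(self):
        theta = np.linspace(0, np.pi, 200)
        pts = 5.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        res = kinetics.bundle_curvature(pts, smooth_window=1)
        assert res["max_curvature_per_um"] == pytest.approx(0.2, rel=1e-3)

    def test_noisy_circle_within_ten_percent(self, rng):
        theta = np.linspace(0, np.pi, 300)
        pts = 5.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        pts += rng.normal(0, 0.01, pts.shape)
        # window chosen to average ~20 samples (~0.3 um of arc) of 10 nm noise
        res = kinetics.bundle_curvature(pts, smooth_window=21)
        assert res["max_curvature_per_um"] == pytest.approx(0.2, rel=0.10)


class TestCountFilaments:
    @pytest.mark.parametrize("ratio,expected", [(3.1, 3), (0.9, 1), (6.6, 7)])
    def test_rounding(self, ratio, expected):
        single = np.ones(10)
        count, raw = kinetics.count_filaments(single * ratio, single)
        assert count == expected
        assert raw == pytest.approx(ratio)

    @pytest.mark.parametrize("k", range(1, 10))
    def test_overlapping_filaments_recovered_up_to_nine(self, k, rng):
        # bundle of k identical filaments plus mild noise on the profile
        single = np.exp(-0.5 * ((np.arange(31) - 15) / 3.0) ** 2) * 100.0
        bundle = k * single + rng.normal(0, 1.0, single.size)
        count, _ = kinetics.count_filaments(bundle, single)
        assert count == k


class TestBranchDensity:
    def test_one_junction_per_ten_um(self):
        import networkx as nx
        g = nx.Graph()
        g.add_edge(0, 1, length_um=4.0)
        g.add_edge(1, 2, length_um=4.0)
        g.add_edge(1, 3, length_um=2.0)  # node 1 is the junction
        assert kinetics.branch_density(g) == pytest.approx(0.1)

    def test_unbranched_zero(self):
        g = synthetic.generate_branched_network(0.0)
        assert kinetics.branch_density(g) == 0.0

    def test_poisson_generator_rate_recovered_in_aggregate(self):
        # junction count over many seeds ~ Poisson(r * L_mother)
        rate, length, total_j = 0.4, 10.0, 0
        n_seeds = 40
        for seed in range(n_seeds):
            g = synthetic.generate_branched_network(
                rate, mother_length_um=length, max_generations=1, seed=seed)
            total_j += sum(1 for n in g.nodes if g.degree(n) >= 3)
        mean = total_j / n_seeds
        se = np.sqrt(rate * length / n_seeds)
        assert abs(mean - rate * length) <= 3 * se
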