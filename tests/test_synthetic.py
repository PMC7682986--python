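"""Generators: ground-truth correctness, noise statistics, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polarimap import synthetic
from polarimap.angles import circular_distance, wrap_angle
from polarimap.errors import InvalidSpecError


class TestGenerateBundle:
    def test_zero_noise_uniform_psi_identical(self):
        spec = synthetic.BundleSpec(n_filaments=5, segments_per_filament=20,
                                    polarity_pattern="uniform", psi_noise_sigma=0.0)
        poses, truth = synthetic.generate_bundle(spec)
        assert len(poses) == 100
        assert poses["psi_deg"].nunique() == 1
        assert (truth["polarity"] == "+").all()

    def test_alternating_psi_forms_two_groups_half_turn_apart(self):
        spec = synthetic.BundleSpec(n_filaments=9, segments_per_filament=5,
                                    polarity_pattern="alternating")
        poses, truth = synthetic.generate_bundle(spec)
        groups = poses["psi_deg"].unique()
        assert len(groups) == 2
        assert circular_distance(groups[0], groups[1]) == pytest.approx(180.0)
        # adjacent lattice filaments have opposite polarity (checkerboard)
        pol = truth.set_index("filament_id")["polarity"]
        assert pol[0] != pol[1] and pol[0] != pol[3]  # 3x3 grid neighbors

    def test_random_polarity_fraction_within_binomial_band(self):
        # binomial oracle: 95% band for p=0.5, n=100 is 0.5 +/- 1.96*sqrt(.25/100)
        spec = synthetic.BundleSpec(n_filaments=100, segments_per_filament=2,
                                    polarity_pattern="random", p_plus=0.5, seed=42)
        _, truth = synthetic.generate_bundle(spec)
        frac = (truth["polarity"] == "+").mean()
        half_width = 1.96 * np.sqrt(0.25 / 100)
        assert abs(frac - 0.5) <= half_width

    def test_psi_wrapped_to_half_open_interval(self):
        spec = synthetic.BundleSpec(n_filaments=20, segments_per_filament=10,
                                    polarity_pattern="random", psi_noise_sigma=90.0,
                                    psi_plus=170.0, seed=1)
        poses, _ = synthetic.generate_bundle(spec)
        assert (poses["psi_deg"] >= -180.0).all()
        assert (poses["psi_deg"] < 180.0).all()

    def test_reproducible_under_seed(self):
        spec = synthetic.BundleSpec(n_filaments=10, segments_per_filament=10,
                                    polarity_pattern="random", psi_noise_sigma=10.0,
                                    position_jitter=2.0, seed=7)
        a = synthetic.generate_bundle(spec)
        b = synthetic.generate_bundle(spec)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    @pytest.mark.parametrize("kwargs", [
        {"n_filaments": 0, "segments_per_filament": 5},
        {"n_filaments": 5, "segments_per_filament": 5, "segment_spacing": -1.0},
        {"n_filaments": 5, "segments_per_filament": 5, "lattice_spacing": 0.0},
        {"n_filaments": 5, "segments_per_filament": 5, "p_plus": 1.5},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            synthetic.BundleSpec(**kwargs)


class TestSaturationDataset:
    def test_half_saturation_and_asymptote_noise_free(self):
        spec = synthetic.BindingSimSpec(true_kd=35.0, bmax=2.0,
                                        actin_range=(35.0, 3.5e6))
        df = synthetic.generate_saturation_dataset(spec)
        assert df["bound"].iloc[0] == pytest.approx(1.0)          # bmax/2 at A=KD
        assert df["bound"].iloc[1] == pytest.approx(2.0, rel=1e-4)  # -> bmax

    def test_reproducible_bit_exact(self):
        spec = synthetic.BindingSimSpec.log_spaced(0.2, 1.0, 25, noise_cv=0.05, seed=9)
        a = synthetic.generate_saturation_dataset(spec)
        b = synthetic.generate_saturation_dataset(spec)
        assert (a["bound"].to_numpy() == b["bound"].to_numpy()).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidSpecError):
            synthetic.BindingSimSpec(true_kd=1.0, bmax=1.0, actin_range=())


class TestGrowthTrace:
    def test_noise_free_slope_is_kon_conc_rise(self):
        spec = synthetic.GrowthSimSpec(k_on=10.0, actin_conc=1.0,
                                       rise_per_subunit=2.76, duration=100.0,
                                       frame_interval=5.0)
        tr = synthetic.generate_growth_trace(spec)
        slopes = np.diff(tr.tip_nm) / np.diff(tr.time_s)
        assert slopes == pytest.approx(27.6)

    def test_zero_on_rate_gives_flat_trace(self):
        spec = synthetic.GrowthSimSpec(k_on=0.0, actin_conc=1.0, duration=50.0,
                                       frame_interval=5.0)
        tr = synthetic.generate_growth_trace(spec)
        assert (tr.tip_nm == 0.0).all()

    def test_noisy_slope_recovers_truth_within_2se(self):
        # least-squares SE oracle computed from first principles
        spec = synthetic.GrowthSimSpec(k_on=10.0, actin_conc=1.0,
                                       localization_noise=20.0, duration=300.0,
                                       frame_interval=5.0, seed=11)
        tr = synthetic.generate_growth_trace(spec)
        t, x = tr.time_s, tr.tip_nm
        tc = t - t.mean()
        slope = float(np.sum(tc * x) / np.sum(tc**2))
        resid = x - x.mean() - slope * tc
        se = float(np.sqrt(np.sum(resid**2) / (t.size - 2) / np.sum(tc**2)))
        assert abs(slope - tr.true_rate_nm_per_s) <= 2 * se

    def test_frame_interval_must_be_below_duration(self):
        with pytest.raises(InvalidSpecError):
            synthetic.GrowthSimSpec(k_on=10.0, actin_conc=1.0,
                                    duration=5.0, frame_interval=5.0)


class TestTwoChannelImage:
    def test_uniform_disk_gives_constant_ratio(self):
        density = synthetic.disk_density_map((40, 40), (20, 20), 10, value=5.0)
        actin, vinc, truth = synthetic.generate_two_channel_image(
            density, kd=2.0, bmax=1.0)
        inside = density > 0
        ratio = vinc[inside] / actin[inside]
        assert np.allclose(ratio, ratio[0])

    def test_sparser_network_has_higher_occupancy_ratio(self):
        # mass-action: B/A = Bmax/(KD+A) decreases with actin density
        low = synthetic.disk_density_map((20, 20), (10, 10), 6, value=1.0)
        high = synthetic.disk_density_map((20, 20), (10, 10), 6, value=10.0)
        _, _, t_low = synthetic.generate_two_channel_image(low, kd=2.0, bmax=1.0)
        _, _, t_high = synthetic.generate_two_channel_image(high, kd=2.0, bmax=1.0)
        r_low = np.nanmean(t_low["ratio_true"])
        r_high = np.nanmean(t_high["ratio_true"])
        assert r_low > r_high

    def test_noisy_image_reproducible(self):
        density = synthetic.disk_density_map((30, 30), (15, 15), 8, value=3.0)
        a1, v1, _ = synthetic.generate_two_channel_image(
            density, kd=1.0, bmax=1.0, noise_sd=0.1, seed=4)
        a2, v2, _ = synthetic.generate_two_channel_image(
            density, kd=1.0, bmax=1.0, noise_sd=0.1, seed=4)
        assert (a1 == a2).all() and (v1 == v2).all()


class TestBranchedNetwork:
    def test_zero_rate_single_unbranched_filament(self):
        g = synthetic.generate_branched_network(0.0, seed=0)
        assert g.number_of_edges() == 1
        assert all(g.degree(n) <= 2 for n in g.nodes)

    def test_junction_count_within_poisson_band_of_rate_times_length(self):
        # Poisson-mean oracle: junctions on the mother ~ Poisson(r * L)
        rate, length = 0.8, 10.0
        g = synthetic.generate_branched_network(rate, mother_length_um=length,
                                                max_generations=1, seed=21)
        junctions = sum(1 for n in g.nodes if g.degree(n) >= 3)
        lo, hi = stats.poisson.ppf([0.005, 0.995], rate * length)
        assert lo <= junctions <= hi

    def test_reproducible_under_seed(self):
        g1 = synthetic.generate_branched_network(0.5, seed=3)
        g2 = synthetic.generate_branched_network(0.5, seed=3)
        assert sorted(g1.edges) == sorted(g2.edges)
        p1 = [g1.nodes[n]["pos"] for n in sorted(g1.nodes)]
        p2 = [g2.nodes[n]["pos"] for n in sorted(g2.nodes)]
        assert p1 == p2


def test_wrap_angle_interval_and_periodicity():
    vals = np.array([-540.0, -180.0, -1.0, 0.0, 179.9, 180.0, 360.0, 725.0])
    wrapped = wrap_angle(vals)
    assert (wrapped >= -180.0).all() and (wrapped < 180.0).all()
    assert np.allclose(np.cos(np.radians(wrapped)), np.cos(np.radians(vals)))
    assert np.allclose(np.sin(np.radians(wrapped)), np.sin(np.radians(vals)))
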