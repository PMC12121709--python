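"""Coarse-scale bias diagnostics: filters, splits, BOLD fits, accuracy bias."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import stereomotion as sm
from stereomotion import bias as bias_mod
from stereomotion import preprocess as pre
from stereomotion import synth

from conftest import make_session_matrix


def toy_population(rows):
    """VertexPopulation from hand-written (ecc, polar, ve) triples."""
    table = pd.DataFrame(rows, columns=["ecc", "polar", "ve"])
    for col, val in (("roi", "MT"), ("tuning", "retinal_2d"), ("s_v", 0.0),
                     ("g_ecc", 0.0), ("g_rad", 0.0), ("g_int", 0.0), ("beta0", 0.0)):
        table[col] = val
    return synth.VertexPopulation(table, ecc_ref=float(table["ecc"].mean()))


class TestFilterVertices:
    def test_hand_written_survivor_set(self):
        pop = toy_population([
            (5.0, 0.0, 0.10),    # kept
            (9.0, 0.0, 0.50),    # ecc too large
            (0.1, 0.0, 0.30),    # ecc too small
            (3.0, 0.0, 0.05),    # VE at threshold -> dropped (strict >)
            (0.2, 0.0, 0.051),   # kept (boundary ecc included)
            (8.0, 0.0, 1.00),    # kept
        ])
        assert bias_mod.filter_vertices(pop).tolist() == [0, 4, 5]

    def test_empty_result_allowed(self, caplog):
        pop = toy_population([(9.0, 0.0, 0.5)])
        with caplog.at_level("WARNING"):
            ids = bias_mod.filter_vertices(pop)
        assert ids.size == 0


class TestSplits:
    def test_eccentricity_boundary_goes_to_edge(self):
        pop = toy_population([(3.9, 0, 0.5), (4.1, 0, 0.5), (4.0, 0, 0.5),
                              (2.0, 0, 0.5), (7.0, 0, 0.5)])
        split = bias_mod.split_eccentricity(np.arange(5), pop)
        assert sorted(split.group_a) == [0, 3]          # central
        assert sorted(split.group_b) == [1, 2, 4]       # edge incl. exactly 4 deg

    def test_polar_wedge_examples(self):
        pop = toy_population([(3, 10.0, 0.5), (3, 45.0, 0.5), (3, 170.0, 0.5),
                              (3, -150.5, 0.5), (3, 90.0, 0.5)])
        split = bias_mod.split_polar(np.arange(5), pop)
        assert sorted(split.group_a) == [0, 2, 3]       # HM incl. left meridian
        assert sorted(split.group_b) == [1, 4]

    def test_uniform_polar_population_hm_fraction_one_third(self):
        spec = sm.RoiSpec("MT", ecc_dist="uniform", ecc_params=(0.5, 7.5))
        pop = sm.sample_vertices(spec, 30000, seed=0)
        split = bias_mod.split_polar(np.arange(pop.n_vertices), pop)
        frac = split.group_a.size / pop.n_vertices
        assert frac == pytest.approx(1.0 / 3.0, abs=3 * np.sqrt(2 / 9 / 30000) + 0.005)

    def test_uniform_ecc_group_counts_match_area_oracle(self):
        """Uniform-over-area eccentricities: counts follow annulus areas."""
        spec = sm.RoiSpec("V1", ecc_dist="areal", ecc_params=(0.2, 8.0))
        pop = sm.sample_vertices(spec, 20000, seed=1)
        ids = bias_mod.filter_vertices(pop, ve_min=-1.0)
        split = bias_mod.split_eccentricity(ids, pop)
        area_central = 4.0**2 - 0.2**2
        area_total = 8.0**2 - 0.2**2
        expected = area_central / area_total
        frac = split.group_a.size / ids.size
        assert frac == pytest.approx(expected, abs=0.01)

    def test_groups_disjoint_and_deterministic(self):
        pop = sm.sample_vertices("MT", 300, seed=2)
        ids = bias_mod.filter_vertices(pop)
        a = bias_mod.split_polar(ids, pop)
        b = bias_mod.split_polar(ids, pop)
        assert np.array_equal(a.group_a, b.group_a)
        assert np.intersect1d(a.group_a, a.group_b).size == 0


class TestBoldGroupMeans:
    def test_injected_radial_bias_recovered(self, pro):
        spec = sm.RoiSpec("MST", ecc_dist="uniform", ecc_params=(0.5, 7.5),
                          s_scale=0.0, g_ecc=0.0, g_rad=0.15, beta0=0.3)
        pop = sm.sample_vertices(spec, 800, seed=3)
        mat = make_session_matrix(pop, pro, n_runs=2, seed=4, mode="percent")
        split = bias_mod.split_polar(np.arange(pop.n_vertices), pop)
        rep = bias_mod.bold_group_means(mat, split, condition="stereoscopic")
        assert rep.difference == pytest.approx(0.15, abs=0.02)

    def test_sign_flips_with_coefficient(self, pro):
        spec = sm.RoiSpec("MST", ecc_dist="uniform", ecc_params=(0.5, 7.5),
                          s_scale=0.0, g_ecc=0.0, g_rad=-0.15, beta0=0.3)
        pop = sm.sample_vertices(spec, 800, seed=3)
        mat = make_session_matrix(pop, pro, n_runs=2, seed=4, mode="percent")
        split = bias_mod.split_polar(np.arange(pop.n_vertices), pop)
        rep = bias_mod.bold_group_means(mat, split, condition="stereoscopic")
        assert rep.difference == pytest.approx(-0.15, abs=0.02)

    def test_identical_groups_zero_difference(self, pro, one_run_schedule):
        pop = sm.sample_vertices("MT", 20, seed=5)
        run = sm.simulate_run(pop, one_run_schedule, pro, seed=6)
        mat = pre.single_trial_matrix(run, mode="percent")
        ids = np.arange(10)
        split = bias_mod.SubRoiSplit("polar", ids, ids + 10, 30.0, ("HM", "NHM"))
        with pytest.raises(ValueError):
            bias_mod.SubRoiSplit("polar", ids, ids, 30.0)  # must stay disjoint
        rep = bias_mod.bold_group_means(mat, split)
        assert np.isfinite(rep.difference)

    def test_empty_group_flagged_nan(self, pro, one_run_schedule):
        pop = sm.sample_vertices("MT", 6, seed=7)
        run = sm.simulate_run(pop, one_run_schedule, pro, seed=8)
        mat = pre.single_trial_matrix(run, mode="percent")
        split = bias_mod.SubRoiSplit("polar", np.arange(6), np.array([], int), 30.0)
        with pytest.warns(RuntimeWarning, match="empty"):
            rep = bias_mod.bold_group_means(mat, split)
        assert np.isnan(rep.difference)


class TestEccentricityFit:
    def test_zero_noise_slope_recovered_exactly(self, pro, one_run_schedule):
        spec = sm.RoiSpec("V1", ecc_dist="uniform", ecc_params=(0.5, 9.5),
                          s_scale=0.0, g_ecc=0.05, g_rad=0.0, beta0=0.3)
        pop = sm.sample_vertices(spec, 200, seed=9)
        run = sm.simulate_run(pop, one_run_schedule, pro,
                              sm.NoiseParams().zeroed(), seed=10)
        mat = pre.single_trial_matrix(run, mode="percent")
        slope = bias_mod.eccentricity_slope(mat, pop, condition="combined")
        assert slope == pytest.approx(0.05, abs=1e-6)

    def test_constant_eccentricity_rejected(self, pro, one_run_schedule):
        pop = toy_population([(3.0, 0, 0.5)] * 5)
        run = sm.simulate_run(pop, one_run_schedule, pro, seed=11)
        mat = pre.single_trial_matrix(run, mode="percent")
        with pytest.raises(ValueError, match="constant eccentricity"):
            bias_mod.eccentricity_slope(mat, pop)

    def test_null_slope_group_test_calibrated(self, pro):
        """g_ecc = 0: the group test is non-significant in >= 90% of seeds."""
        spec = sm.RoiSpec("V1", ecc_dist="uniform", ecc_params=(0.5, 9.5),
                          s_scale=0.0, g_ecc=0.0, g_rad=0.0, beta0=0.3)
        sched = sm.make_schedule(n_runs=1, seed=12)
        nonsig = 0
        n_seeds = 20
        for s in range(n_seeds):
            mats, pops = [], []
            for p in range(6):
                pop = sm.sample_vertices(spec, 80, seed=1000 + 10 * s + p)
                run = sm.simulate_run(pop, sched, pro, seed=2000 + 10 * s + p)
                mats.append(pre.single_trial_matrix(run, mode="percent"))
                pops.append(pop)
            rep = bias_mod.bold_eccentricity_fit(mats, pops, condition="combined",
                                                 method="per_participant")
            nonsig += rep.test.p_value >= 0.05
        assert nonsig >= 0.9 * n_seeds

    def test_toward_away_slopes_indistinguishable_without_interaction(self, pro):
        """g_int = 0: separate toward/away fits give matching slopes."""
        spec = sm.RoiSpec("V1", ecc_dist="uniform", ecc_params=(0.5, 9.5),
                          s_scale=0.0, g_ecc=0.05, g_rad=0.0, g_int=0.0, beta0=0.3)
        pop = sm.sample_vertices(spec, 300, seed=13)
        mat = make_session_matrix(pop, pro, n_runs=4, seed=14, mode="percent",
                                  noise=sm.NoiseParams(white_sd=0.2))
        s_toward = bias_mod.eccentricity_slope(
            mat.select(direction="toward"), pop, condition="combined")
        s_away = bias_mod.eccentricity_slope(
            mat.select(direction="away"), pop, condition="combined")
        assert s_toward == pytest.approx(s_away, abs=0.01)
        assert s_toward == pytest.approx(0.05, abs=0.01)

    def test_mixed_model_agrees_with_per_participant_fallback(self, pro):
        """Both inference routes agree in sign and significance."""
        spec = sm.RoiSpec("V1", ecc_dist="uniform", ecc_params=(0.5, 9.5),
                          s_scale=0.0, g_ecc=0.05, g_rad=0.0, beta0=0.3)
        sched = sm.make_schedule(n_runs=1, seed=15)
        noise = sm.NoiseParams(white_sd=0.2)
        mats, pops = [], []
        for p in range(6):
            pop = sm.sample_vertices(spec, 100, seed=300 + p)
            run = sm.simulate_run(pop, sched, pro, noise, seed=400 + p)
            mats.append(pre.single_trial_matrix(run, mode="percent"))
            pops.append(pop)
        mixed = bias_mod.bold_eccentricity_fit(mats, pops, condition="combined",
                                               method="mixed")
        fallback = bias_mod.bold_eccentricity_fit(mats, pops, condition="combined",
                                                  method="per_participant")
        assert np.sign(mixed.slope) == np.sign(fallback.slope) == 1.0
        assert mixed.test.p_value < 0.05 and fallback.test.p_value < 0.05
        assert mixed.meta["cohens_f2"] > 0


class TestEquatedSubRoiDecoding:
    def test_identical_signal_in_both_groups_gives_near_zero_bias(self, pro):
        """HM and NHM carry vertex-for-vertex identical tuning (independent
        noise): the equating procedure itself must not create a bias."""
        k = 40
        biases = []
        for s in range(10):
            rng = np.random.default_rng(800 + s)
            s_v = rng.normal(0, 0.10, k)
            table = pd.DataFrame({
                "roi": "MT",
                "ecc": np.tile(rng.uniform(0.5, 7.5, k), 2),
                "polar": np.concatenate([rng.uniform(-25, 25, k),
                                         rng.uniform(45, 135, k)]),
                "ve": 0.3, "tuning": "retinal_2d", "s_v": np.tile(s_v, 2),
                "g_ecc": 0.0, "g_rad": 0.0, "g_int": 0.0, "beta0": 0.3,
            })
            pop = synth.VertexPopulation(table, ecc_ref=4.0)
            mat = make_session_matrix(pop, pro, n_runs=10, seed=900 + s)
            split = bias_mod.split_polar(np.arange(pop.n_vertices), pop)
            assert split.group_a.size == split.group_b.size == k
            biases.append(bias_mod.equated_subroi_decoding(
                mat, split, condition="stereoscopic", n_resample=1, n_boot=40,
                seed=s).accuracy_bias)
        # centred on zero within Monte-Carlo error
        sem = np.std(biases, ddof=1) / np.sqrt(len(biases))
        assert abs(np.mean(biases)) < 2.0 * sem + 1e-9

    def test_hm_confined_signal_detected_across_participants(self):
        """Direction signal only in HM vertices -> positive HM-NHM bias."""
        spec_base = sm.RoiSpec("MT", ecc_dist="uniform", ecc_params=(0.5, 7.5),
                               s_scale=0.0, s_scale_hm=0.25, g_ecc=0.0,
                               g_rad=0.0, beta0=0.3)
        biases = []
        for p in range(8):
            pop = sm.sample_vertices(spec_base, 120, seed=600 + p)
            obs = sm.Observer(f"s{p}", "stereo_pro")
            mat = make_session_matrix(pop, obs, n_runs=3, seed=700 + p)
            split = bias_mod.split_polar(np.arange(pop.n_vertices), pop)
            rep = bias_mod.equated_subroi_decoding(
                mat, split, condition="stereoscopic", n_resample=4, n_boot=25,
                seed=p)
            assert rep.meta["equated_count"] == split.equated_count
            biases.append(rep.accuracy_bias)
        res = sm.wilcoxon_signed_rank(np.array(biases))
        assert np.mean(biases) > 0
        assert res.p_value < 0.05

    def test_small_group_skipped_with_warning(self, pro, one_run_schedule):
        pop = sm.sample_vertices("MT", 10, seed=18)
        run = sm.simulate_run(pop, one_run_schedule, pro, seed=19)
        mat = pre.single_trial_matrix(run)
        split = bias_mod.SubRoiSplit("polar", np.array([0]), np.arange(1, 10), 30.0)
        with pytest.warns(RuntimeWarning, match="skipping"):
            rep = bias_mod.equated_subroi_decoding(mat, split, n_resample=2,
                                                   n_boot=5, seed=20)
        assert rep.accuracy_bias is None
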