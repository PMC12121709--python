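"""Synthetic vertex populations, observers, schedules and BOLD simulation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as spstats

import stereomotion as sm
from stereomotion import synth


class TestSampleVertices:
    def test_uniform_spec_matches_target_distribution(self):
        spec = sm.RoiSpec("V1", ecc_dist="uniform", ecc_params=(1.0, 9.0))
        pop = sm.sample_vertices(spec, 1000, seed=0)
        ks = spstats.kstest(pop.table["ecc"], "uniform", args=(1.0, 8.0))
        assert ks.pvalue > 0.01

    def test_single_vertex_and_determinism(self):
        one = sm.sample_vertices("MT", 1, seed=5)
        assert one.n_vertices == 1
        a = sm.sample_vertices("FST", 200, seed=9)
        b = sm.sample_vertices("FST", 200, seed=9)
        assert a.table.equals(b.table)

    def test_truncation_and_bounds(self):
        pop = sm.sample_vertices("MST", 2000, seed=1)
        assert pop.table["ecc"].between(0, 10).all()
        assert pop.table["ve"].between(0, 1).all()
        assert pop.table["polar"].between(-180, 180).all()

    def test_hm_overrepresentation(self):
        spec = dataclasses.replace(sm.ROI_PRESETS["V1"], hm_weight=0.5)
        pop = sm.sample_vertices(spec, 4000, seed=2)
        frac_hm = pop.hm_mask().mean()
        # 1/3 baseline plus half the mass forced into the wedge
        assert frac_hm == pytest.approx(0.5 + 0.5 / 3, abs=0.04)

    def test_errors(self):
        with pytest.raises(ValueError):
            sm.sample_vertices("nope", 10)
        with pytest.raises(ValueError):
            sm.sample_vertices("MT", 0)


class TestHmWedge:
    @pytest.mark.parametrize("polar,expected", [
        (10.0, True), (45.0, False), (170.0, True), (-170.0, True),
        (30.0, True), (-90.0, False), (150.0, True), (120.0, False),
    ])
    def test_wedge_membership(self, polar, expected):
        assert synth.hm_wedge_mask(np.array([polar]))[0] == expected


class TestSchedule:
    def test_design_arithmetic(self):
        sched = sm.make_schedule(n_runs=10, seed=0)
        assert sched.n_trials == 400
        per_run = sched.table.groupby("run").size()
        assert (per_run == 40).all()
        counts = sched.table.groupby(["condition", "direction"]).size()
        assert len(counts) == 8 and (counts == 50).all()
        # onsets spaced 9 s, all windows inside the 360-TR run
        onsets = sched.table[sched.table["run"] == 0]["onset"].to_numpy()
        assert np.allclose(np.diff(np.sort(onsets)), 9.0)
        assert sched.table["onset"].max() + 8 < 360

    def test_onset_beyond_run_end_rejected(self):
        import pandas as pd
        bad = pd.DataFrame({"run": [0], "onset": [360.0], "condition": ["combined"],
                            "direction": ["toward"], "rotated": [False]})
        with pytest.raises(ValueError, match="beyond run end"):
            synth.TrialSchedule(bad)

    def test_roundtrip(self, tmp_path):
        sched = sm.make_schedule(n_runs=2, seed=3)
        sched.to_tsv(tmp_path / "sched.tsv")
        back = synth.TrialSchedule.from_tsv(tmp_path / "sched.tsv")
        assert back.table.equals(sched.table)


class TestPerceivedDirection:
    def test_rule_table(self, pro, struggler):
        assert sm.perceived_direction(pro, "stereoscopic", "toward") == "toward"
        assert sm.perceived_direction(pro, "combined", "away") == "away"
        assert sm.perceived_direction(struggler, "perspectiveL", "toward") == "toward"
        for obs in (pro, struggler):
            assert sm.perceived_direction(obs, "stereoscopic", "toward",
                                          rotated=True) == "none"

    def test_struggler_stereo_percept_is_a_coin_flip(self, struggler):
        rng = np.random.default_rng(0)
        n = 10**4
        hits = sum(
            sm.perceived_direction(struggler, "stereoscopic", "toward", rng=rng)
            == "toward" for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se


class TestBehavioralReport:
    def test_lapse_free_report_is_veridical(self, pro):
        rng = np.random.default_rng(1)
        assert sm.simulate_behavioral_report(pro, "perspectiveL", "away",
                                             rng=rng) == "away"

    def test_struggler_stereo_accuracy_is_chance(self, struggler):
        rng = np.random.default_rng(2)
        n = 10**4
        acc = np.mean([
            sm.simulate_behavioral_report(struggler, "stereoscopic", "toward",
                                          rng=rng) == "toward"
            for _ in range(n)])
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_lapse_rate_sets_accuracy(self, pro):
        lapsy = sm.Observer("s", group="stereo_pro", lapse=0.1)
        rng = np.random.default_rng(3)
        n = 4 * 10**4
        acc = np.mean([
            sm.simulate_behavioral_report(lapsy, "perspectiveR", "toward",
                                          rng=rng) == "toward"
            for _ in range(n)])
        assert acc == pytest.approx(0.9, abs=3 * np.sqrt(0.09 / n))


class TestTrialAmplitude:
    def test_baseline_only(self, pro):
        vertex = {"tuning": "retinal_2d", "ecc": 3.0, "polar": 10.0,
                  "s_v": 0.0, "g_ecc": 0.0, "g_rad": 0.0, "g_int": 0.0, "beta0": 0.7}
        amp = sm.trial_amplitude(vertex, "combined", "toward", observer=pro)
        assert amp == pytest.approx(0.7)

    def test_percept_vertex_silent_on_rotated_stereo(self, pro):
        vertex = {"tuning": "percept_3d", "ecc": 3.0, "polar": 10.0,
                  "s_v": 0.5, "g_ecc": 0.0, "g_rad": 0.0, "g_int": 0.0, "beta0": 0.2}
        amp = sm.trial_amplitude(vertex, "stereoscopic", "toward", rotated=True,
                                 observer=pro)
        assert amp == pytest.approx(0.2)  # direction term exactly 0

    def test_retinal_vertex_keeps_signal_under_rotation(self, pro):
        vertex = {"tuning": "retinal_2d", "ecc": 3.0, "polar": 10.0,
                  "s_v": 0.5, "g_ecc": 0.0, "g_rad": 0.0, "g_int": 0.0, "beta0": 0.2}
        toward = sm.trial_amplitude(vertex, "stereoscopic", "toward", rotated=True,
                                    observer=pro)
        away = sm.trial_amplitude(vertex, "stereoscopic", "away", rotated=True,
                                  observer=pro)
        assert toward - away == pytest.approx(1.0)

    def test_hm_offset_monte_carlo(self, pro, one_run_schedule):
        """g_rad = 0.15 shows up as the HM-NHM mean amplitude difference."""
        spec = sm.RoiSpec("MST", ecc_dist="uniform", ecc_params=(0.5, 9.5),
                          s_scale=0.0, g_ecc=0.0, g_rad=0.15, beta0=0.3)
        pop = sm.sample_vertices(spec, 10**4, seed=4)
        rng = np.random.default_rng(0)
        amps = sm.trial_amplitudes(pop, one_run_schedule.table, pro, rng)
        hm = pop.hm_mask()
        diff = amps[:, hm].mean() - amps[:, ~hm].mean()
        assert diff == pytest.approx(0.15, abs=1e-9)  # no noise in the equation

    def test_term_by_term_conservation(self, pro, one_run_schedule):
        """Each coefficient changes only its own term (vs brute-force equation)."""
        rng = np.random.default_rng(5)
        base = sm.RoiSpec("MT", ecc_dist="uniform", ecc_params=(1, 9),
                          s_scale=0.0, g_ecc=0.0, g_rad=0.0, g_int=0.0, beta0=0.4)
        pop0 = sm.sample_vertices(base, 50, seed=6)
        table = one_run_schedule.table
        a0 = sm.trial_amplitudes(pop0, table, pro, rng)
        assert np.allclose(a0, 0.4)
        for coef, column in [("g_ecc", 0.05), ("g_rad", 0.2), ("g_int", 0.03)]:
            pop = sm.sample_vertices(dataclasses.replace(base, **{coef: column}),
                                     50, seed=6)
            amps = sm.trial_amplitudes(pop, table, pro, rng)
            decc = pop.table["ecc"].to_numpy() - pop.ecc_ref
            hm = pop.hm_mask().astype(float)
            d = np.where(table["direction"] == "toward", 1.0, -1.0)[:, None]
            expected = {
                "g_ecc": 0.4 + column * decc[None, :] + 0 * d,
                "g_rad": 0.4 + column * hm[None, :] + 0 * d,
                "g_int": 0.4 + d * (column * decc[None, :]),
            }[coef]
            assert np.allclose(amps, expected, atol=1e-12)


class TestSimulateRun:
    def test_single_trial_noiseless_series_is_the_hrf(self, pro):
        import pandas as pd
        table = pd.DataFrame({"run": [0, 0], "onset": [0.0, 180.0],
                              "condition": ["combined"] * 2,
                              "direction": ["toward"] * 2, "rotated": [False] * 2})
        sched = synth.TrialSchedule(table)
        spec = sm.RoiSpec("V1", s_scale=0.0, g_ecc=0.0, g_rad=0.0, beta0=1.0)
        pop = sm.sample_vertices(spec, 3, seed=7)
        run = sm.simulate_run(pop, sched, pro, sm.NoiseParams().zeroed(), seed=0)
        hrf = sm.double_gamma_hrf(1.0)
        assert np.allclose(run.signal[:32, 0], hrf, atol=1e-10)
        assert int(np.argmax(run.signal[:20, 0])) == 5  # peak ~5-6 s post-onset
        assert run.signal.shape == (360, 3)

    def test_pure_ar1_noise_autocorrelation(self, pro, one_run_schedule):
        spec = sm.RoiSpec("V1", s_scale=0.0, g_ecc=0.0, g_rad=0.0, beta0=0.0)
        pop = sm.sample_vertices(spec, 200, seed=8)
        noise = sm.NoiseParams(white_sd=1.0, ar1=0.4, drift_linear=0.0,
                               drift_sin=0.0, global_sd=0.0, motion_sd=0.0)
        run = sm.simulate_run(pop, one_run_schedule, pro, noise, seed=9)
        x = run.signal - run.signal.mean(axis=0)
        lag1 = np.mean(np.sum(x[1:] * x[:-1], axis=0)
                       / np.sum(x * x, axis=0))
        assert lag1 == pytest.approx(0.4, abs=0.05)
        # stationary SD matches the requested magnitude
        assert run.signal.std() == pytest.approx(1.0, abs=0.05)

    def test_run_shape_and_determinism(self, pro, one_run_schedule):
        pop = sm.sample_vertices("MT", 40, seed=10)
        a = sm.simulate_run(pop, one_run_schedule, pro, seed=11)
        b = sm.simulate_run(pop, one_run_schedule, pro, seed=11)
        assert a.signal.shape == (360, 40)
        assert a.nuisance.shape == (360, 7)
        assert np.array_equal(a.signal, b.signal)
        # global channel is the vertex mean
        assert np.allclose(a.nuisance[:, -1], a.signal.mean(axis=1))

    def test_hdf5_roundtrip(self, pro, one_run_schedule, tmp_path):
        pop = sm.sample_vertices("FST", 10, seed=12)
        run = sm.simulate_run(pop, one_run_schedule, pro, seed=13)
        run.save_hdf5(tmp_path / "run.h5")
        back = synth.RunTimeSeries.load_hdf5(tmp_path / "run.h5")
        assert np.array_equal(back.signal, run.signal)
        assert np.array_equal(back.onsets, run.onsets)


class TestObserverValidation:
    def test_lapse_bounds(self):
        with pytest.raises(ValueError):
            sm.Observer("s", lapse=0.7)
        with pytest.raises(ValueError):
            sm.Observer("s", group="expert")
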