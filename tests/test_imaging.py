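"""Fluorescence/electrophysiology quantification and group statistics."""

import numpy as np
import pytest
from scipy import stats as sstats

from branchfield import imaging, synth


def make_recording(amp=0.2, n_trials=20, seed=0, **cfg_kw):
    cfg = synth.TrialConfig(n_trials=n_trials, **cfg_kw)
    data = synth.gen_imaging_trials(seed, {"bAP": amp}, cfg)
    return data["recordings"]["bAP"]


class TestTransientAmplitude:
    def test_constant_channels_give_zero(self):
        rec = imaging.FluorescenceRecording(
            np.full((3, 200), 100.0), np.full((3, 200), 500.0),
            rate=0.5, stim_ms=150.0)
        out = imaging.transient_amplitude(rec)
        assert out.amplitude == 0.0

    def test_recovers_known_amplitude_within_five_percent(self):
        rec = make_recording(amp=0.2, n_trials=20, seed=1)
        out = imaging.transient_amplitude(rec)
        assert out.amplitude == pytest.approx(0.2, rel=0.05)

    def test_invariant_to_trial_order(self):
        rec = make_recording(seed=2)
        out1 = imaging.transient_amplitude(rec).amplitude
        rec.g = rec.g[::-1].copy()
        rec.r = rec.r[::-1].copy()
        out2 = imaging.transient_amplitude(rec).amplitude
        assert out1 == pytest.approx(out2, rel=1e-9)

    def test_peak_time_outside_trace_rejected(self):
        rec = make_recording(seed=3)
        with pytest.raises(ValueError, match="outside"):
            imaging.transient_amplitude(rec, peak_time_ms=1e5)


class TestClassification:
    @pytest.mark.parametrize("amp,mode,label", [
        (0.2, "2p", "high"), (0.03, "2p", "low"), (0.07, "2p", "unclassified"),
        (0.35, "2p", "unclassified"),
        (0.2, "1p", "unclassified"),   # bands rescaled by the 1.75 factor
        (0.1, "1p", "high"), (0.01, "1p", "low"),
    ])
    def test_bands(self, amp, mode, label):
        assert imaging.classify_site(amp, mode) == label

    def test_pair_ratios_and_ranksum(self):
        rng = np.random.default_rng(0)
        rows = []
        # 12 within-segment pairs (ratio ~0.9) and 12 across-branch (~0.5)
        for k in range(24):
            across = k >= 12
            prox = 0.2 + 0.05 * rng.random()
            ratio = (0.5 if across else 0.9) + 0.05 * rng.standard_normal()
            rows += [
                {"site": f"p{k}", "dca_ap": prox, "distance_um": 100.0,
                 "segment_pair_id": k, "spans_branch_point": across},
                {"site": f"d{k}", "dca_ap": prox * ratio, "distance_um": 120.0,
                 "segment_pair_id": k, "spans_branch_point": across},
            ]
        # one excluded pair: proximal below the 0.1 floor
        rows += [
            {"site": "px", "dca_ap": 0.05, "distance_um": 100.0,
             "segment_pair_id": 99, "spans_branch_point": False},
            {"site": "dx", "dca_ap": 0.02, "distance_um": 120.0,
             "segment_pair_id": 99, "spans_branch_point": False},
        ]
        import pandas as pd

        out = imaging.classify_and_pair(pd.DataFrame(rows))
        assert out["excluded_pairs"] == [99]
        assert len(out["ratios"]) == 24
        rs = out["ranksum"]
        assert rs["median_across"] < rs["median_within"]
        assert rs["p"] < 0.01


class TestUepsp:
    def test_flat_trace_flags_peak(self):
        trial = imaging.VoltageTrial(np.full((4, 2000), -75.0), rate=20.0, event_ms=50.0)
        amp, peak_t = imaging.uepsp_metrics(trial)
        assert amp == 0.0 and np.isnan(peak_t)

    def test_recovers_synthetic_epsp(self):
        data = synth.gen_imaging_trials(5, {"uEPSP": 0.06})
        amp, peak_t = imaging.uepsp_metrics(data["voltage"]["uEPSP"])
        assert amp == pytest.approx(0.5, rel=0.1)
        assert 0 < peak_t <= 25.0

    def test_median_filter_removes_brief_artifact(self):
        rate = 20.0
        t = np.arange(0, 100.0, 1 / rate)
        v = -75.0 + 0.5 * np.clip((t - 50.0) / 15.0, 0, None) * np.exp(-(t - 50.0) / 15.0)
        v = np.tile(v, (3, 1))
        k = int(52.0 * rate)
        v[:, k:k + 8] += 10.0  # 0.4 ms artifact, wider than half the 1 ms window? no: 8 samples = 0.4 ms
        trial = imaging.VoltageTrial(v, rate=rate, event_ms=50.0)
        amp, _ = imaging.uepsp_metrics(trial)
        assert amp < 1.0  # artifact suppressed, EPSP-scale amplitude remains


class TestAmplification:
    def test_additive_signals_give_zero(self):
        assert imaging.amplification(0.1, 0.05, 0.15) == pytest.approx(0.0)

    def test_printed_example(self):
        assert imaging.amplification(0.02, 0.10, 0.30) == pytest.approx(0.18)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        a, u, p = rng.random(3)
        a2, u2, p2 = rng.random(3)
        assert imaging.amplification(a + a2, u + u2, p + p2) == pytest.approx(
            imaging.amplification(a, u, p) + imaging.amplification(a2, u2, p2))


class TestLoosePatch:
    def _trials(self, amp, seed, n=20, noise=0.1):
        rng = np.random.default_rng(seed)
        rate, dur, ev = 50.0, 10.0, 5.0
        t = np.arange(0, dur, 1 / rate)
        v = rng.normal(0, noise, (n, len(t)))
        v += amp * np.exp(-((t - ev - 0.3) / 0.15) ** 2)
        return imaging.VoltageTrial(v, rate=rate, event_ms=ev,
                                    configuration="loose-patch")

    def test_identical_configurations_cancel(self):
        a = self._trials(0.4, seed=7)
        b = imaging.VoltageTrial(a.v.copy(), a.rate, a.event_ms)
        assert imaging.loose_patch_amplitude(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_synthetic_spikelet(self):
        pre = self._trials(0.0, seed=8)
        sealed = self._trials(0.4, seed=9)
        amp = imaging.loose_patch_amplitude(pre, sealed)
        assert amp == pytest.approx(0.4, rel=0.15)

    def test_detects_every_true_spikelet(self):
        for seed in range(5):
            pre = self._trials(0.0, seed=20 + 2 * seed)
            sealed = self._trials(0.3, seed=21 + 2 * seed)
            assert imaging.loose_patch_amplitude(pre, sealed) > 0.1

    def test_requires_two_trials(self):
        one = imaging.VoltageTrial(np.zeros((1, 100)), 50.0, 1.0)
        with pytest.raises(ValueError, match="2 trials"):
            imaging.loose_patch_amplitude(one, one)


class TestConductionVelocity:
    def test_exact_noiseless_inversion(self):
        d = np.array([80.0, 150.0, 220.0, 290.0])
        out = imaging.conduction_velocity(d, latencies_ms=d / 150.0 + 0.3)
        assert out["velocity_um_per_ms"] == pytest.approx(150.0, rel=1e-12)
        assert out["r2"] == pytest.approx(1.0)

    def test_recovers_generator_velocity_within_ci(self):
        data = synth.gen_latency_data(seed=3, velocity=154.9, n_sites=20)
        out = imaging.conduction_velocity(data["distances_um"], data["latencies_ms"])
        # slope CI from the regression covers the true inverse velocity
        fit = sstats.linregress(data["distances_um"], data["latencies_ms"])
        t95 = sstats.t.ppf(0.975, len(data["distances_um"]) - 2)
        lo, hi = fit.slope - t95 * fit.stderr, fit.slope + t95 * fit.stderr
        assert lo <= 1 / 154.9 <= hi
        assert out["velocity_um_per_ms"] == pytest.approx(154.9, rel=0.05)

    def test_velocity_bias_small_across_seeds(self):
        ests = []
        for seed in range(30):
            d = synth.gen_latency_data(seed=seed, velocity=154.9, n_sites=20,
                                       jitter_sd_ms=0.1)
            ests.append(imaging.conduction_velocity(
                d["distances_um"], d["latencies_ms"])["velocity_um_per_ms"])
        assert np.mean(ests) == pytest.approx(154.9, rel=0.02)

    def test_requires_three_distinct_sites(self):
        with pytest.raises(ValueError, match="3 sites"):
            imaging.conduction_velocity([100.0, 200.0], latencies_ms=[1.0, 2.0])

    def test_unphysical_slope_flagged(self):
        d = np.array([80.0, 150.0, 220.0])
        out = imaging.conduction_velocity(d, latencies_ms=[2.0, 1.5, 1.0])
        assert out["unphysical"] and np.isnan(out["velocity_um_per_ms"])


class TestFwhm:
    def test_triangular_peak(self):
        t = np.linspace(0, 10, 1001)
        v = np.maximum(0, 1 - np.abs(t - 5))  # unit triangle, FWHM = 1
        assert imaging.fwhm(t, v) == pytest.approx(1.0, abs=0.02)

    def test_spatial_width_is_velocity_times_duration(self):
        assert imaging.bap_spatial_width(154.9, 0.94) == pytest.approx(145.6, abs=0.05)


class TestStaDffMap:
    def test_exact_on_noiseless_proportional_movie(self):
        data = synth.gen_sta_movie(seed=0, dff=0.1, noise_scale=0.0,
                                   background=False, n_spikes=5)
        out = imaging.sta_dff_map(data["movie"], data["spike_frames"])
        assert out["dff"] == pytest.approx(0.1, rel=1e-6)

    def test_recovers_truth_with_noise_and_background(self):
        data = synth.gen_sta_movie(seed=1, dff=0.15, n_spikes=100)
        out = imaging.sta_dff_map(data["movie"], data["spike_frames"])
        assert out["dff"] == pytest.approx(0.15, rel=0.10)

    def test_watershed_selects_high_df_structure(self):
        data = synth.gen_sta_movie(seed=2, dff=0.12, n_spikes=60)
        out = imaging.sta_dff_map(data["movie"], data["spike_frames"])
        # the selected region lies inside the true dendrite mask
        overlap = (out["region"] & data["mask"]).sum() / out["region"].sum()
        assert overlap > 0.9

    def test_background_only_movie_raises(self):
        rng = np.random.default_rng(0)
        movie = rng.normal(100.0, 1.0, (40, 16, 16))
        with pytest.raises(ValueError):
            imaging.sta_dff_map(movie, [10, 20, 30])

    def test_requires_spikes(self):
        data = synth.gen_sta_movie(seed=0, n_spikes=5)
        with pytest.raises(ValueError, match="spike"):
            imaging.sta_dff_map(data["movie"], [])


class TestGroupStats:
    def test_cohens_d_zero_for_identical_groups(self):
        a = np.arange(10.0)
        assert imaging.cohens_d(a, a.copy()) == 0.0

    def test_cohens_d_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        na, nb = len(a), len(b)
        sp = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
                     / (na + nb - 2))
        assert imaging.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp)

    def test_u_statistic_fully_separated_small_groups(self):
        out = imaging.group_stats([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert out["statistic"] == 9.0  # every one of the 3x3 comparisons won
        # exhaustive enumeration oracle
        u = sum(x > y for x in [4.0, 5.0, 6.0] for y in [1.0, 2.0, 3.0])
        assert out["statistic"] == u

    def test_mannwhitney_z_matches_normal_approximation(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 30), rng.normal(0.8, 1, 25)
        out = imaging.group_stats(a, b)
        p_from_z = 2 * sstats.norm.sf(abs(out["z"]))
        assert p_from_z == pytest.approx(out["p"], rel=0.05)

    def test_regression_record(self):
        x = np.arange(10.0)
        y = 3.0 * x + 1.0
        out = imaging.group_stats(x, y, test="regression")
        assert out["slope"] == pytest.approx(3.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            imaging.group_stats([1.0], [2.0, 3.0], test="ttest")
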