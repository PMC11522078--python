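"""Trace-cleaning chain: artifact masks, rejection rules, interpolation,
spline filtering, median binning, z-transform, baseline handling, features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilmath import preprocess as pp
from pupilmath.design import PhaseTimeline, TrialPlan, generate_problem_set


def make_trace(pupil, valid=None, part=None, t0=0.0):
    n = len(pupil)
    return pp.RawTrace(
        time_ms=t0 + np.arange(n) * pp.SAMPLE_MS,
        pupil_au=np.asarray(pupil, dtype=float),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
        part=np.ones(n, dtype=int) if part is None else np.asarray(part, int),
    )


class TestDetectArtifacts:
    def test_clean_constant_trace_unmasked(self):
        mask = pp.detect_artifacts(make_trace(np.full(2000, 4000.0)))
        assert not mask.any()

    def test_step_artifact_masked_with_100ms_margins(self):
        rng = np.random.default_rng(0)
        pupil = 4000 + rng.normal(0, 1.0, 3000)
        d = np.abs(np.diff(pupil))
        mad = np.median(np.abs(np.diff(pupil) - np.median(np.diff(pupil))))
        k = 1000  # t = 2000 ms
        pupil[k:] += 50 * mad * 16
        trace = make_trace(pupil)
        mask = pp.detect_artifacts(trace)
        t = trace.time_ms
        inside = (t >= 1900) & (t <= 2100)
        assert mask[inside].all()

    def test_tracker_flagged_blink_fully_masked(self, small_cohort):
        trace = next(iter(small_cohort.traces.values()))
        mask = pp.detect_artifacts(trace)
        blink = ~trace.valid
        if blink.any():
            assert mask[blink].mean() >= 0.95
            assert mask.sum() > blink.sum()  # extension adds margins

    def test_all_missing_trace_masked_entirely(self):
        trace = make_trace(np.zeros(100), valid=np.zeros(100, bool))
        assert pp.detect_artifacts(trace).all()


class TestRejectMissing:
    @pytest.mark.parametrize(
        "frac,expected", [(0.41, True), (0.40, False), (0.0, False)]
    )
    def test_strict_40_percent_rule(self, frac, expected):
        mask = np.zeros(100, dtype=bool)
        mask[: int(round(frac * 100))] = True
        assert pp.reject_missing(mask) is expected


class TestInterpolateGaps:
    def test_gap_on_linear_ramp_reconstructed_exactly(self):
        t = np.arange(500) * pp.SAMPLE_MS
        pupil = 4000 + 0.3 * t
        mask = np.zeros(500, bool)
        mask[200:260] = True
        corrupted = pupil.copy()
        corrupted[mask] = -1
        filled = pp.interpolate_gaps(make_trace(corrupted), mask)
        np.testing.assert_allclose(filled.pupil_au, pupil, rtol=1e-12)

    def test_edge_gap_filled_flat(self):
        pupil = np.array([99.0, 99.0, 5.0, 6.0, 7.0])
        mask = np.array([True, True, False, False, False])
        filled = pp.interpolate_gaps(make_trace(pupil), mask)
        np.testing.assert_allclose(filled.pupil_au[:2], 5.0)

    def test_random_masks_on_smooth_trace_below_noise_floor(self):
        rng = np.random.default_rng(1)
        t = np.arange(2000) * pp.SAMPLE_MS / 1000.0
        truth = 4000 + 150 * np.sin(2 * np.pi * 0.4 * t)
        for _ in range(5):
            mask = np.zeros(2000, bool)
            for start in rng.integers(50, 1900, 4):
                mask[start: start + rng.integers(5, 40)] = True
            corrupted = truth.copy()
            corrupted[mask] = 0.0
            filled = pp.interpolate_gaps(make_trace(corrupted), mask)
            assert np.max(np.abs(filled.pupil_au - truth)) < 1.0  # a.u.


class TestSmoothSpline:
    def test_straight_line_reproduced(self):
        t = np.arange(1000) * pp.SAMPLE_MS
        pupil = 4000 + 0.05 * t
        out = pp.smooth_spline(make_trace(pupil))
        np.testing.assert_allclose(out.pupil_au, pupil, rtol=1e-9)

    @pytest.mark.parametrize(
        "freq,check",
        [(10.0, lambda g: g <= 0.10), (0.5, lambda g: g >= 0.90)],
    )
    def test_frequency_response(self, freq, check):
        t_s = np.arange(0, 8, pp.SAMPLE_MS / 1000.0)
        pupil = np.sin(2 * np.pi * freq * t_s)
        out = pp.smooth_spline(make_trace(pupil * 1.0))
        mid = (t_s > 1) & (t_s < 7)
        gain = out.pupil_au[mid].std() / pupil[mid].std()
        assert check(gain)


class TestDownsampleMedian:
    def test_constant_trace(self):
        centers, vals, parts = pp.downsample_median(make_trace(np.full(500, 7.0)))
        assert np.allclose(vals, 7.0)
        assert np.allclose(np.diff(centers), 25.0)

    def test_median_of_known_bin(self):
        # one 25 ms bin holds samples {3, 9, 100, ...}: median decides
        pupil = np.array([3.0, 9.0, 100.0] * 5)[:12]
        trace = make_trace(pupil)
        _, vals, _ = pp.downsample_median(trace, bin_ms=24.0)
        first_bin = pupil[:12]
        assert vals[0] == np.median(first_bin)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_rebinning(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 400))
        pupil = rng.normal(4000, 100, n)
        trace = make_trace(pupil)
        centers, vals, _ = pp.downsample_median(trace)
        bins = np.floor(trace.time_ms / 25.0).astype(int)
        expected = {b: np.median(pupil[bins == b]) for b in np.unique(bins)}
        got = dict(zip(((centers - 12.5) / 25.0).round().astype(int), vals))
        assert got.keys() == expected.keys()
        for b in expected:
            assert got[b] == pytest.approx(expected[b])


class TestZTransform:
    def test_pooled_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        binned = {i: rng.normal(4000, 300, 50) for i in range(10)}
        z, mu, sd = pp.ztransform_participant(binned)
        pooled = np.concatenate(list(z.values()))
        assert pooled.mean() == pytest.approx(0.0, abs=1e-9)
        assert pooled.std() == pytest.approx(1.0, abs=1e-9)

    def test_affine_copies_give_identical_z_series(self):
        rng = np.random.default_rng(3)
        base = {i: rng.normal(0, 1, 40) for i in range(5)}
        scaled = {i: 3000 + 250 * v for i, v in base.items()}
        z1, *_ = pp.ztransform_participant(base)
        z2, *_ = pp.ztransform_participant(scaled)
        for i in base:
            np.testing.assert_allclose(z1[i], z2[i], atol=1e-9)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        binned = {i: rng.normal(4000, 200, 30) for i in range(4)}
        z, mu, sd = pp.ztransform_participant(binned)
        pooled = np.concatenate(list(binned.values()))
        assert mu == pytest.approx(pooled.mean())
        assert sd == pytest.approx(pooled.std())
        np.testing.assert_allclose(z[2], (binned[2] - pooled.mean()) / pooled.std())

    def test_zero_variance_names_participant(self):
        with pytest.raises(ValueError, match="p042"):
            pp.ztransform_participant({0: np.full(10, 5.0)}, "p042")


def _epoched(values, part=None, participant="p", idx=0):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return pp.EpochedTrial(
        participant, idx,
        bin_centers_ms=12.5 + 25.0 * np.arange(n),
        pupil=values,
        part=np.ones(n, int) if part is None else np.asarray(part, int),
    )


class TestBaselineAlign:
    def test_subtracts_baseline_mean(self):
        values = np.concatenate([np.full(30, 0.7), np.linspace(0.7, 2.0, 50)])
        out = pp.baseline_align(_epoched(values))
        assert out.baseline_z == pytest.approx(0.7)
        np.testing.assert_allclose(out.pupil[:30], 0.0, atol=1e-12)

    def test_flat_trial_becomes_zero(self):
        out = pp.baseline_align(_epoched(np.full(80, 1.3)))
        np.testing.assert_allclose(out.pupil, 0.0, atol=1e-12)

    def test_idempotent_after_first_application(self):
        rng = np.random.default_rng(5)
        once = pp.baseline_align(_epoched(rng.normal(0, 1, 100)))
        twice = pp.baseline_align(once)
        np.testing.assert_allclose(once.pupil, twice.pupil, atol=1e-12)
        assert twice.baseline_z == pytest.approx(once.baseline_z)

    def test_missing_first_baseline_rejects_trial(self):
        trial = _epoched(np.zeros(10))
        trial.bin_centers_ms = 800.0 + 25.0 * np.arange(10)  # starts after 750 ms
        assert pp.baseline_align(trial).rejected_baseline


class TestRejectExtremeBaseline:
    def test_outlier_rule_on_small_set(self):
        b = np.array([0.0, 0.0, 0.0, 0.0, 10.0])
        flags = pp.reject_extreme_baseline(b)
        outside = np.abs(b - b.mean()) > 2 * b.std(ddof=1)
        np.testing.assert_array_equal(flags, outside)

    def test_equal_baselines_reject_nothing(self):
        assert not pp.reject_extreme_baseline(np.full(20, 0.4)).any()

    def test_gaussian_tail_mass_near_4_6_percent(self):
        rng = np.random.default_rng(6)
        flags = pp.reject_extreme_baseline(rng.standard_normal(20000))
        assert flags.mean() == pytest.approx(0.0455, abs=0.01)


class TestFeatures:
    def _plan(self):
        return TrialPlan(0, generate_problem_set()[0], PhaseTimeline())

    def test_noiseless_peak_latency_recovered_within_one_bin(self):
        centers = 12.5 + 25.0 * np.arange(800)  # 0-20 s
        target_ms = 7000.0 + 5000.0
        values = np.exp(-((centers - target_ms) / 1500.0) ** 2)
        trial = _epoched(values)
        trial.bin_centers_ms = centers
        trial.plan = self._plan()
        f = pp.extract_features(trial)
        assert f.peak_latency_s == pytest.approx(5.0, abs=0.025)
        # bin centers straddle the true peak: value at 12.5 ms off-peak
        assert f.max_dilation_z == pytest.approx(1.0, abs=2e-4)

    def test_monotone_series_peaks_at_window_end(self):
        centers = 12.5 + 25.0 * np.arange(700)
        trial = _epoched(np.linspace(0, 1, 700))
        trial.bin_centers_ms = centers
        trial.plan = self._plan()
        f = pp.extract_features(trial)
        assert f.peak_latency_s == pytest.approx(
            (centers[-1] - 7000.0) / 1000.0, abs=1e-9
        )

    def test_empty_window_skipped(self):
        trial = _epoched(np.zeros(10))  # ends long before 7000 ms
        trial.plan = self._plan()
        assert pp.extract_features(trial) is None


class TestFullChain:
    def test_discard_rate_in_reported_ballpark(self, small_cohort):
        results = []
        for pid in small_cohort.participants["participant"]:
            trs = {t: tr for (p, t), tr in small_cohort.traces.items() if p == pid}
            plans = {t: small_cohort.plans[(pid, t)] for t in trs}
            results.append(pp.preprocess_participant(pid, trs, plans))
        qc = pp.qc_summary(results)
        # study-like artifact settings discard a few percent of trials
        assert 5.6 - 3.0 <= qc.attrs["mean"] <= 5.6 + 3.0

    def test_hard_trials_peak_later_than_easy(self, small_cohort):
        feats = []
        for pid in small_cohort.participants["participant"]:
            trs = {t: tr for (p, t), tr in small_cohort.traces.items() if p == pid}
            plans = {t: small_cohort.plans[(pid, t)] for t in trs}
            res = pp.preprocess_participant(pid, trs, plans)
            cues = small_cohort.trials.set_index(["participant", "trial"])["cue"]
            for f in res.features:
                feats.append((cues.loc[(pid, f.trial_index)], f.peak_latency_s))
        hard = [v for c, v in feats if c == "hard"]
        easy = [v for c, v in feats if c == "easy"]
        assert np.mean(hard) > np.mean(easy)
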