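"""Trace-cleaning chain: each step against hand arithmetic and the
brute-force oracle, plus pipeline-order properties."""

import numpy as np
import pytest

from pupileffort.cohort import Design, build_schedule, simulate_trace
from pupileffort.preprocess import (
    PreprocessConfig,
    UnusableTrialError,
    compute_baseline,
    detect_artifacts,
    exclude_trial,
    expand_margins,
    extract_ppd,
    interpolate_gaps,
    normalize_trace,
    preprocess_trial,
    smooth_trace,
)
from pupileffort.types import CleanTrace, PupilTrace

from _oracles import brute_expand, brute_interpolate, brute_mask, windowed_max


def make_trace(x, fs=120.0):
    x = np.asarray(x, dtype=float)
    return PupilTrace(timestamps=np.arange(x.size) / fs, diameters=x, fs=fs)


class TestDetectArtifacts:
    def test_single_outlier_on_constant_trace(self):
        x = np.full(200, 4.0)
        x[57] = 0.5
        mask = detect_artifacts(make_trace(x))
        assert mask[57]
        assert mask.sum() == 1

    def test_clean_trace_yields_empty_mask(self, rng):
        # samples within 3 MAD of the median by construction
        x = 4.0 + 0.01 * np.sin(np.linspace(0, 3, 500))
        assert not detect_artifacts(make_trace(x)).any()

    def test_injected_dropouts_match_bruteforce(self, rng):
        x = rng.normal(4.0, 0.15, 1000)
        idx = rng.choice(1000, size=10, replace=False)
        x[idx] = 0.0
        mask = detect_artifacts(make_trace(x))
        assert mask[idx].all()
        assert list(mask) == brute_mask(list(x))

    def test_all_missing_raises(self):
        with pytest.raises(UnusableTrialError):
            detect_artifacts(make_trace(np.full(10, np.nan)))


class TestExpandMargins:
    def test_empty_mask_unchanged(self):
        mask = np.zeros(50, dtype=bool)
        assert not expand_margins(mask, 120.0).any()

    def test_single_flag_at_120hz_covers_95_to_112(self):
        mask = np.zeros(500, dtype=bool)
        mask[100] = True
        out = expand_margins(mask, 120.0)
        assert set(np.flatnonzero(out)) == set(range(95, 113))

    def test_run_at_start_clips_at_zero(self):
        mask = np.zeros(40, dtype=bool)
        mask[:3] = True
        out = expand_margins(mask, 120.0)
        assert out[0]
        assert np.flatnonzero(out).min() == 0

    def test_matches_bruteforce_and_is_superset(self, rng):
        for _ in range(20):
            mask = rng.random(300) < 0.05
            out = expand_margins(mask, 120.0)
            assert list(out) == brute_expand(list(mask), 120.0)
            assert (out | mask == out).all()


class TestInterpolateGaps:
    def test_no_flags_is_identity(self, rng):
        x = rng.normal(4, 0.1, 100)
        tr = make_trace(x)
        clean = interpolate_gaps(tr, np.zeros(100, dtype=bool))
        assert np.array_equal(clean.diameters, x)
        assert clean.interp_fraction == 0.0

    def test_cubic_reproduces_cubic_polynomial(self):
        t = np.linspace(0, 1, 50)
        y = t ** 3
        mask = np.zeros(50, dtype=bool)
        mask[20:25] = True
        tr = PupilTrace(timestamps=t, diameters=y, fs=49.0)
        clean = interpolate_gaps(tr, mask)
        # natural spline end conditions leave a small but bounded error
        assert np.allclose(clean.diameters[20:25], y[20:25], atol=1e-4)

    def test_tail_gap_takes_last_valid_value(self):
        x = np.linspace(4.0, 5.0, 30)
        mask = np.zeros(30, dtype=bool)
        mask[27:] = True
        clean = interpolate_gaps(make_trace(x), mask)
        assert np.all(clean.diameters[27:] == x[26])

    def test_too_few_valid_samples_raises(self):
        x = np.full(10, 4.0)
        mask = np.ones(10, dtype=bool)
        mask[3] = False
        with pytest.raises(UnusableTrialError):
            interpolate_gaps(make_trace(x), mask)


class TestSmoothTrace:
    @staticmethod
    def _clean(x, fs=120.0):
        x = np.asarray(x, dtype=float)
        return CleanTrace(np.arange(x.size) / fs, x, fs,
                          np.zeros(x.size, dtype=bool))

    def test_constant_unchanged(self):
        out = smooth_trace(self._clean(np.full(100, 4.2)))
        assert np.allclose(out.diameters, 4.2)

    def test_impulse_becomes_1_over_13_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = smooth_trace(self._clean(x))       # window round(0.1*120)=12 -> 13
        assert np.allclose(out.diameters[44:57], 1.0 / 13.0)
        assert out.diameters[43] == 0.0 and out.diameters[57] == 0.0

    def test_linear_ramp_unchanged_everywhere(self):
        x = np.linspace(0, 1, 200)
        out = smooth_trace(self._clean(x))
        # symmetric (shrinking) windows preserve a line, including edges
        assert np.allclose(out.diameters, x, atol=1e-12)


class TestExclusionRule:
    @pytest.mark.parametrize("frac,included", [(0.45, False), (0.40, True), (0.0, True)])
    def test_boundary(self, frac, included):
        n = 100
        mask = np.zeros(n, dtype=bool)
        mask[: int(frac * n)] = True
        clean = CleanTrace(np.arange(n) / 120.0, np.full(n, 4.0), 120.0, mask)
        assert exclude_trial(clean) is included

    def test_monotone_in_flagged_samples(self):
        # once a trial is excluded, adding flagged samples never re-includes it
        n = 200
        included_so_far = True
        for k in range(0, n + 1, 10):
            mask = np.zeros(n, dtype=bool)
            mask[:k] = True
            clean = CleanTrace(np.arange(n) / 120.0, np.full(n, 4.0), 120.0, mask)
            inc = exclude_trial(clean)
            assert included_so_far or not inc
            included_so_far = inc


class TestBaselineAndNormalization:
    @staticmethod
    def _clean_events(x, fs=120.0, onset=2.0, prompt=6.0):
        from pupileffort.types import TrialEvents
        x = np.asarray(x, dtype=float)
        clean = CleanTrace(np.arange(x.size) / fs, x, fs, np.zeros(x.size, bool))
        ev = TrialEvents("T", 8.0, onset - 2.0, onset, prompt - 2.0, prompt)
        return clean, ev

    def test_constant_baseline(self):
        clean, ev = self._clean_events(np.full(1000, 4.0))
        assert compute_baseline(clean, ev) == pytest.approx(4.0)

    def test_ramp_baseline_is_midpoint(self):
        fs = 1000.0
        t = np.arange(int(8 * fs)) / fs
        x = np.where(t < 2.0, 3.0 + 0.5 * t, 4.0)
        clean = CleanTrace(t, x, fs, np.zeros(t.size, bool))
        from pupileffort.types import TrialEvents
        ev = TrialEvents("T", 8.0, 0.0, 2.0, 4.0, 6.0)
        assert compute_baseline(clean, ev) == pytest.approx(3.5, abs=1e-3)

    @pytest.mark.parametrize("obs,expected", [(4.4, 10.0), (4.0, 0.0), (3.6, -10.0)])
    def test_relative_change_identities(self, obs, expected):
        clean, ev = self._clean_events(np.full(1000, obs))
        _, rel = normalize_trace(clean, 4.0, ev)
        assert np.allclose(rel, expected)

    def test_linearity_in_observation(self, rng):
        x1 = rng.normal(4, 0.2, 1000)
        x2 = rng.normal(4, 0.2, 1000)
        a = 0.3
        c1, ev = self._clean_events(x1)
        c2, _ = self._clean_events(x2)
        cmix, _ = self._clean_events(a * x1 + (1 - a) * x2)
        _, r1 = normalize_trace(c1, 4.0, ev)
        _, r2 = normalize_trace(c2, 4.0, ev)
        _, rmix = normalize_trace(cmix, 4.0, ev)
        assert np.allclose(rmix, a * r1 + (1 - a) * r2)

    def test_nonpositive_baseline_rejected(self):
        clean, ev = self._clean_events(np.full(1000, 4.0))
        with pytest.raises(UnusableTrialError):
            normalize_trace(clean, 0.0, ev)


class TestExtractPpd:
    def test_zero_trace_gives_zero(self):
        assert extract_ppd(np.zeros(100)) == 0.0

    def test_post_prompt_excursion_excluded(self):
        # build rel trace where the true window max is 7.2 but a larger
        # excursion sits after the prompt
        fs = 100.0
        t = np.arange(int(10 * fs)) / fs
        rel = np.zeros(t.size)
        rel[(t >= 3.0) & (t < 3.1)] = 7.2
        rel[(t >= 8.5)] = 12.0
        lo, hi = 2.0, 8.0
        w = (t >= lo) & (t < hi)
        assert extract_ppd(rel[w]) == pytest.approx(7.2)
        assert extract_ppd(rel[w]) == pytest.approx(
            windowed_max(t, rel, lo, hi))

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            extract_ppd(np.array([]))


class TestPipelineProperties:
    def test_oracle_equivalence_on_random_traces(self, rng):
        """Mask, margins and interpolation match the brute-force reference
        sample-for-sample on randomized traces."""
        cfg = PreprocessConfig()
        for _ in range(25):
            n = int(rng.integers(200, 2000))
            x = rng.normal(4.0, 0.1, n)
            # smooth wander keeps most samples inside 3 MAD
            x += np.cumsum(rng.normal(0, 0.002, n))
            drop = rng.random(n) < 0.02
            x[drop] = np.nan
            out = rng.random(n) < 0.005
            x[out] = rng.choice([0.3, 9.0], size=out.sum())
            tr = make_trace(x)
            mask = detect_artifacts(tr, cfg)
            assert list(mask) == brute_mask(list(x))
            mask = expand_margins(mask, tr.fs, cfg)
            assert list(mask) == brute_expand(list(detect_artifacts(tr, cfg)), tr.fs)
            if (~mask).sum() >= 4:
                clean = interpolate_gaps(tr, mask)
                ref = brute_interpolate(tr.timestamps, np.nan_to_num(x, nan=0.0), mask)
                assert np.allclose(clean.diameters, ref, atol=1e-8)

    def test_detection_idempotent_on_artifact_free_trace(
            self, quiet_profile, noiseless_trace_cfg):
        sched = build_schedule(quiet_profile,
                               Design(lists_per_snr=1, sentences_per_list=2), seed=1)
        for tr_ev in sched[:6]:
            trace = simulate_trace(tr_ev, quiet_profile, seed=3,
                                   cfg=noiseless_trace_cfg)
            mask = expand_margins(detect_artifacts(trace), trace.fs)
            clean = smooth_trace(interpolate_gaps(trace, mask))
            re = detect_artifacts(
                PupilTrace(clean.timestamps, clean.diameters, clean.fs))
            assert not re.any()

    def test_roundtrip_recovers_known_peak(self, quiet_profile, one_trial,
                                           noiseless_trace_cfg):
        from pupileffort.cohort import effort_peak
        trace = simulate_trace(one_trial, quiet_profile, seed=0,
                               cfg=noiseless_trace_cfg)
        m = preprocess_trial(trace, one_trial)
        assert m.included
        assert m.ppd == pytest.approx(effort_peak(one_trial.snr, quiet_profile),
                                      abs=0.05)
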