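"""Pupil-trace cleaning, baseline correction and PPD extraction.

The cleaning chain, applied per trial in this fixed order:

1. artifact detection — a sample is flagged if missing or further than
   3 median absolute deviations (MAD, unscaled) from the median diameter of
   the trial recording;
2. margin expansion — 35 ms before and 100 ms after every flagged run are
   also discarded, to strip blink on/offsets;
3. cubic interpolation of flagged samples through the preserved ones
   (nearest-valid extension at the trace edges);
4. 100 ms centered running-average smoothing;
5. trial exclusion when over 40% of samples were interpolated;
6. baseline = mean smoothed diameter over the 2 s before sentence onset;
7. normalization: rel = (observation - baseline) / baseline * 100,
   restricted to [sentence_onset, prompt_time);
8. PPD = maximum of the normalized trace in that window.

Cleaned trials are aggregated per participant and SNR condition, aligned at
sentence onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .types import CleanTrace, ConditionTrace, PupilTrace, TrialEvents, TrialMetrics


@dataclass
class PreprocessConfig:
    mad_k: float = 3.0          # threshold in MADs
    mad_scale: float = 1.0      # 1.0 = raw MAD; 1.4826 for sigma-equivalent
    mad_floor_mm: float = 0.01  # threshold floor when MAD == 0
    pre_ms: float = 35.0        # margin before a flagged run
    post_ms: float = 100.0      # margin after a flagged run
    smooth_ms: float = 100.0    # running-average duration
    excl_frac: float = 0.40     # exclude when interp_fraction > this
    baseline_s: float = 2.0


class UnusableTrialError(ValueError):
    """Raised when a trial has too few valid samples to clean."""


# ---------------------------------------------------------------------------
# Step 1: artifact detection
# ---------------------------------------------------------------------------

def detect_artifacts(trace: PupilTrace, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Flag missing samples and MAD outliers.

    A sample is flagged iff it is missing (NaN) or deviates from the median
    of the valid samples by more than ``mad_k * MAD`` (raw, unscaled MAD by
    default).  When MAD collapses to 0 (near-constant trace) the threshold
    floor ``mad_floor_mm`` keeps ordinary samples unflagged.
    """
    cfg = cfg or PreprocessConfig()
    x = trace.diameters
    if x.size == 0:
        raise ValueError("empty trace")
    missing = ~np.isfinite(x)
    if missing.all():
        raise UnusableTrialError("all samples missing")
    valid = x[~missing]
    med = np.median(valid)
    mad = np.median(np.abs(valid - med)) * cfg.mad_scale
    thresh = max(cfg.mad_k * mad, cfg.mad_floor_mm)
    out = missing.copy()
    out[~missing] = np.abs(valid - med) > thresh
    return out


# ---------------------------------------------------------------------------
# Step 2: margin expansion
# ---------------------------------------------------------------------------

def expand_margins(mask: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Extend every maximal flagged run backward/forward by the blink margins.

    Backward extension is ``ceil(pre_ms/1000 * fs)`` samples, forward
    ``ceil(post_ms/1000 * fs)``, clipped at the trace edges.  The result is a
    superset of the input mask.
    """
    cfg = cfg or PreprocessConfig()
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if n == 0 or not mask.any():
        return mask.copy()
    back = math.ceil(cfg.pre_ms / 1000.0 * fs)
    fwd = math.ceil(cfg.post_ms / 1000.0 * fs)

    out = np.zeros(n, dtype=bool)
    padded = np.concatenate(([False], mask, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
    for s, e in zip(starts, ends):
        out[max(0, s - back):min(n, e + fwd)] = True
    return out


# ---------------------------------------------------------------------------
# Step 3: interpolation
# ---------------------------------------------------------------------------

def interpolate_gaps(trace: PupilTrace, mask: np.ndarray) -> CleanTrace:
    """Replace flagged samples by piecewise-cubic interpolation.

    Interior gaps are filled with a natural cubic spline through the
    preserved samples; gaps touching a trace edge take the nearest valid
    value (cubic extrapolation is unstable).  Falls back to linear
    interpolation when fewer than 4 preserved samples remain; fewer than 2
    makes the trial unusable.
    """
    mask = np.asarray(mask, dtype=bool)
    t, x = trace.timestamps, trace.diameters.copy()
    n_valid = int((~mask).sum())
    if n_valid < 2:
        raise UnusableTrialError("fewer than 2 valid samples")
    if mask.any():
        tv, xv = t[~mask], x[~mask]
        if n_valid >= 4:
            spline = CubicSpline(tv, xv, bc_type="natural")
            inner = mask & (t >= tv[0]) & (t <= tv[-1])
            x[inner] = spline(t[inner])
        else:
            x[mask] = np.interp(t[mask], tv, xv)
        x[mask & (t < tv[0])] = xv[0]     # edge gaps: nearest-valid extension
        x[mask & (t > tv[-1])] = xv[-1]
    return CleanTrace(timestamps=t, diameters=x, fs=trace.fs, interp_mask=mask.copy())


# ---------------------------------------------------------------------------
# Step 4: smoothing
# ---------------------------------------------------------------------------

def smooth_trace(clean: CleanTrace, cfg: PreprocessConfig | None = None) -> CleanTrace:
    """Centered running average of ``smooth_ms`` duration (window forced odd).

    Edge samples use symmetrically shrinking windows, so constant traces and
    interior samples of linear ramps pass through unchanged.
    """
    cfg = cfg or PreprocessConfig()
    w = int(round(cfg.smooth_ms / 1000.0 * clean.fs))
    if w % 2 == 0:
        w += 1
    h = w // 2
    x = clean.diameters
    n = x.size
    if h == 0 or n == 0:
        return CleanTrace(clean.timestamps, x.copy(), clean.fs, clean.interp_mask.copy())
    c = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    hw = np.minimum(h, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - hw, idx + hw + 1
    sm = (c[hi] - c[lo]) / (hi - lo)
    return CleanTrace(clean.timestamps, sm, clean.fs, clean.interp_mask.copy())


# ---------------------------------------------------------------------------
# Step 5–8: exclusion, baseline, normalization, PPD
# ---------------------------------------------------------------------------

def exclude_trial(clean: CleanTrace, cfg: PreprocessConfig | None = None) -> bool:
    """Included iff interpolated fraction <= 40% (strictly-over excludes)."""
    cfg = cfg or PreprocessConfig()
    return clean.interp_fraction <= cfg.excl_frac


def compute_baseline(clean: CleanTrace, events: TrialEvents,
                     cfg: PreprocessConfig | None = None) -> float:
    """Mean diameter over the half-open window [onset - baseline_s, onset)."""
    cfg = cfg or PreprocessConfig()
    t = clean.timestamps
    w = (t >= events.sentence_onset - cfg.baseline_s) & (t < events.sentence_onset)
    if not w.any():
        raise ValueError("baseline window not covered by trace")
    return float(clean.diameters[w].mean())


def normalize_trace(clean: CleanTrace, baseline: float, events: TrialEvents) -> tuple[np.ndarray, np.ndarray]:
    """Percent relative change on [sentence_onset, prompt_time).

    Returns (times, rel_trace) with
    rel = (observation - baseline) / baseline * 100.
    """
    if baseline <= 0:
        raise UnusableTrialError("non-positive baseline")
    t = clean.timestamps
    w = (t >= events.sentence_onset) & (t < events.prompt_time)
    rel = (clean.diameters[w] - baseline) / baseline * 100.0
    return t[w], rel


def extract_ppd(rel_trace: np.ndarray) -> float:
    """Peak pupil dilation: maximum of the normalized trace in the window."""
    rel_trace = np.asarray(rel_trace, dtype=float)
    if rel_trace.size == 0:
        raise ValueError("empty analysis window")
    return float(rel_trace.max())


# ---------------------------------------------------------------------------
# Per-trial pipeline
# ---------------------------------------------------------------------------

def preprocess_trial(trace: PupilTrace, events: TrialEvents,
                     cfg: PreprocessConfig | None = None) -> TrialMetrics:
    """Run the full fixed-order cleaning chain on one trial."""
    cfg = cfg or PreprocessConfig()
    mask = detect_artifacts(trace, cfg)
    mask = expand_margins(mask, trace.fs, cfg)
    clean = interpolate_gaps(trace, mask)
    clean = smooth_trace(clean, cfg)
    included = exclude_trial(clean, cfg)
    baseline = compute_baseline(clean, events, cfg)
    times, rel = normalize_trace(clean, baseline, events)
    ppd = extract_ppd(rel)
    return TrialMetrics(
        trial_id=events.trial_id,
        snr=events.snr,
        baseline=baseline,
        rel_times=times - events.sentence_onset,
        rel_trace=rel,
        ppd=ppd,
        interp_fraction=clean.interp_fraction,
        included=included,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_condition(metrics: list[TrialMetrics], snr: float) -> ConditionTrace | None:
    """Mean +/- SE trace across included trials of one SNR cell, onset-aligned.

    Trials differ in duration (sentences are unprocessed), so the mean at
    each aligned sample runs over the trials that still cover it.  With a
    single trial the SE is undefined and emitted as NaN.  Returns None for
    an empty cell.
    """
    cell = [m for m in metrics if m.included and m.snr == snr]
    if not cell:
        return None
    max_len = max(m.rel_trace.size for m in cell)
    fs_step = np.median(np.diff(cell[0].rel_times)) if cell[0].rel_times.size > 1 else 1.0
    stacked = np.full((len(cell), max_len), np.nan)
    for i, m in enumerate(cell):
        stacked[i, : m.rel_trace.size] = m.rel_trace
    n_per = np.sum(np.isfinite(stacked), axis=0)
    mean = np.nanmean(stacked, axis=0)
    import warnings as _warnings
    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(stacked, axis=0, ddof=1)
    se = np.where(n_per > 1, sd / np.sqrt(n_per), np.nan)
    t_rel = np.arange(max_len) * fs_step
    return ConditionTrace(snr=snr, t_rel=t_rel, mean_trace=mean, se_trace=se,
                          n_trials=len(cell))


def cell_mean_ppd(metrics: list[TrialMetrics]) -> pd.DataFrame:
    """Mean PPD per SNR over included trials (long frame: snr, ppd, n)."""
    rows = []
    for snr in sorted({m.snr for m in metrics}):
        cell = [m.ppd for m in metrics if m.included and m.snr == snr]
        rows.append((snr, float(np.mean(cell)) if cell else np.nan, len(cell)))
    return pd.DataFrame(rows, columns=["snr", "ppd", "n"])


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def preprocess_tables(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    cfg: PreprocessConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean every trial in a long samples table.

    ``samples`` columns: participant_id, trial_id, t, pupil_mm (empty =
    missing).  ``events`` columns as written by the cohort generator.
    Returns (trial_metrics, condition_traces) frames matching the documented
    CSV schemas.  Unusable trials (too few valid samples) are retained in
    trial_metrics with ``included = False`` and NaN metrics.
    """
    cfg = cfg or PreprocessConfig()
    ev_idx = events.set_index("trial_id")
    metric_rows = []
    cond_rows = []
    by_participant: dict[str, list[TrialMetrics]] = {}

    for (pid, tid), grp in samples.groupby(["participant_id", "trial_id"], sort=False):
        ev_row = ev_idx.loc[tid]
        ev = TrialEvents(
            trial_id=tid,
            snr=float(ev_row["snr"]),
            noise_onset=float(ev_row["noise_onset"]),
            sentence_onset=float(ev_row["sentence_onset"]),
            sentence_offset=float(ev_row["sentence_offset"]),
            prompt_time=float(ev_row["prompt_time"]),
        )
        t = grp["t"].to_numpy(dtype=float)
        x = grp["pupil_mm"].to_numpy(dtype=float)
        fs = 1.0 / np.median(np.diff(t))
        trace = PupilTrace(timestamps=t, diameters=x, fs=fs)
        try:
            m = preprocess_trial(trace, ev, cfg)
        except UnusableTrialError:
            m = TrialMetrics(trial_id=tid, snr=ev.snr, baseline=np.nan,
                             rel_times=np.array([]), rel_trace=np.array([]),
                             ppd=np.nan, interp_fraction=1.0, included=False)
        by_participant.setdefault(pid, []).append(m)
        metric_rows.append({
            "participant_id": pid, "trial_id": tid, "snr": m.snr,
            "baseline_mm": m.baseline, "interp_fraction": m.interp_fraction,
            "included": m.included, "ppd_pct": m.ppd,
        })

    for pid, ms in by_participant.items():
        for snr in sorted({m.snr for m in ms}):
            ct = aggregate_condition(ms, snr)
            if ct is None:
                continue
            cond_rows.append(pd.DataFrame({
                "participant_id": pid, "snr": snr, "t_rel": ct.t_rel,
                "mean_pct": ct.mean_trace, "se_pct": ct.se_trace,
                "n": ct.n_trials,
            }))

    trial_metrics = pd.DataFrame(metric_rows)
    condition_traces = (
        pd.concat(cond_rows, ignore_index=True) if cond_rows else
        pd.DataFrame(columns=["participant_id", "snr", "t_rel", "mean_pct", "se_pct", "n"])
    )
    return trial_metrics, condition_traces


def ppd_cell_means(trial_metrics: pd.DataFrame) -> pd.DataFrame:
    """participant x SNR mean PPD over included trials (long frame)."""
    inc = trial_metrics[trial_metrics["included"]]
    out = (
        inc.groupby(["participant_id", "snr"], as_index=False)["ppd_pct"]
        .mean()
        .rename(columns={"ppd_pct": "ppd"})
    )
    return out
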