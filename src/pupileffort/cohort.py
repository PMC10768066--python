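"""Synthetic cohort generator.

Emulates the study design the analysis pipeline assumes: 17 cochlear-implant
listeners x 6 SNR conditions (0–20 dB, 4 dB steps) x 40 sentence trials, with
a 2 s noise-only baseline before each sentence and 2 s of noise after its
offset.  Every generated quantity has known ground truth (stored in
``ParticipantProfile.latent``) so downstream stages can be tested by
parameter recovery.

Key generative choices
----------------------
* The expected peak pupil dilation (PPD) is an inverted-U Gaussian bump in
  SNR, ``amp * exp(-(snr - tip)^2 / (2 w^2))``, peaking at a
  participant-specific tipping point.
* The tipping point decreases with clinical word recognition
  (``tip = a - b * word_recognition + noise``, b > 0): better performers
  disengage at easier SNRs.  With the default word-recognition range
  (50–100%) tips fall in 10–20 dB, so the fitted quadratic coefficient is
  monotone in the tipping point.
* Keyword intelligibility is logistic in SNR with a participant-specific
  speech-reception threshold (SRT) and slope.
* Raw traces are baseline * (1 + r(t)) + noise, where r(t) is a gamma
  kernel convolved with the sentence-duration boxcar, scaled so its maximum
  inside the analysis window equals the expected PPD.  Blinks arrive as
  Poisson missing runs; occasional long artifact bursts reproduce realistic
  trial-exclusion rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BASELINE_S,
    POST_OFFSET_S,
    SNR_LEVELS,
    LatentParams,
    ParticipantProfile,
    PupilTrace,
    TrialEvents,
)

# ---------------------------------------------------------------------------
# Reference demographics of the emulated 17-listener CI cohort (as printed in
# the study's demographic table).  Columns: participant, age (years), sex,
# implanted ear, time of CI use (months).
# ---------------------------------------------------------------------------
REFERENCE_DEMOGRAPHICS = pd.DataFrame(
    {
        "participant": list(range(1, 18)),
        "age": [65, 60, 44, 65, 64, 69, 45, 52, 39, 45, 61, 53, 59, 27, 63, 48, 36],
        "sex": ["M", "F", "F", "F", "M", "F", "M", "F", "F", "M", "M", "M", "F", "F", "M", "F", "F"],
        "ear": ["RIGHT", "LEFT", "RIGHT", "LEFT", "LEFT", "LEFT", "LEFT", "RIGHT",
                "LEFT", "LEFT", "LEFT", "RIGHT", "RIGHT", "RIGHT", "LEFT", "RIGHT", "RIGHT"],
        "time_of_use": [32, 35, 42, 45, 32, 41, 32, 37, 35, 50, 51, 42, 39, 12, 58, 59, 42],
    }
)


@dataclass
class EffectConfig:
    """Generative effect sizes and noise levels for the synthetic cohort.

    The word-recognition -> tipping-point link is the central structure:
    ``tip_snr = tip_intercept - tip_slope * word_recognition + N(0, tip_noise_sd)``
    with ``tip_slope > 0`` (higher word recognition -> lower tipping point).
    ``zero_links`` severs every covariate link (for null calibration).
    """

    word_low: float = 50.0          # word-recognition range, % correct
    word_high: float = 100.0
    tip_intercept: float = 30.0     # dB
    tip_slope: float = 0.2          # dB per % word recognition; must be >= 0
    tip_noise_sd: float = 1.5       # dB
    srt_intercept: float = 20.0     # dB
    srt_slope: float = 0.18         # dB per % word recognition
    srt_noise_sd: float = 1.0       # dB
    intel_slope: float = 0.25       # logistic slope, per dB
    peak_amp_mean: float = 8.0      # percent PPD at the tipping point
    peak_amp_sd: float = 1.5
    curve_width_mean: float = 6.0   # dB
    curve_width_sd: float = 1.0
    qol_amp_link: float = 3.5       # QoL points per percent peak PPD
    qol_noise_sd: float = 9.0
    matrices_amp_link: float = -1.5  # items per percent peak PPD
    matrices_noise_sd: float = 3.0
    zero_links: bool = False
    bimodal_tips: tuple[float, float] | None = None
    # (low-word-group tip, high-word-group tip); overrides the linear link,
    # e.g. (4.0, 16.0) reversed — see tests — to build two-cluster cohorts.

    def validate(self) -> None:
        if self.tip_slope < 0 or self.tip_slope > 1.0:
            raise ValueError("tip_slope must lie in [0, 1] dB per percent")
        if min(self.tip_noise_sd, self.srt_noise_sd, self.qol_noise_sd,
               self.matrices_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.word_low < self.word_high <= 100:
            raise ValueError("word-recognition range must be within [0, 100]")
        if self.intel_slope <= 0:
            raise ValueError("intelligibility slope must be positive")


@dataclass
class TraceConfig:
    """Sampling and noise characteristics of simulated raw traces."""

    fs: float = 120.0               # Hz
    noise_sd: float = 0.03          # mm, white measurement noise
    drift_sd: float = 0.08          # mm, slow spontaneous fluctuation (hippus)
    drift_tau: float = 0.5          # s, smoothness of the slow fluctuation
    kernel_shape: float = 2.0       # gamma kernel shape
    kernel_scale: float = 0.9       # gamma kernel scale, s
    blink_dur_range: tuple[float, float] = (0.1, 0.3)   # s
    artifact_burst_prob: float = 0.12
    burst_frac_range: tuple[float, float] = (0.45, 0.70)
    pad_s: float = 0.0              # extra trace beyond [noise_onset, prompt]


@dataclass
class Design:
    """Trial-schedule layout: lists of sentences per SNR condition."""

    snr_levels: tuple = SNR_LEVELS
    lists_per_snr: int = 2
    sentences_per_list: int = 20
    sentence_dur_range: tuple[float, float] = (1.5, 3.0)  # s
    iti_s: float = 2.0              # gap between prompt and next noise onset
    n_keywords: int = 4

    @property
    def trials_per_snr(self) -> int:
        return self.lists_per_snr * self.sentences_per_list

    @property
    def n_trials(self) -> int:
        return len(self.snr_levels) * self.trials_per_snr


# ---------------------------------------------------------------------------
# Profile generation
# ---------------------------------------------------------------------------

def generate_profiles(
    n: int,
    config: EffectConfig | None = None,
    seed: int = 0,
) -> list[ParticipantProfile]:
    """Draw ``n`` synthetic participant profiles with known latent structure.

    Deterministic given ``seed``.  Covariates respect the profile invariants
    (bounded scores, >= 12 months CI use); the word-recognition <->
    tipping-point association has the configured sign and strength.
    """
    if n < 2:
        raise ValueError("need at least 2 participants")
    config = config or EffectConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    word = rng.uniform(config.word_low, config.word_high, size=n)
    if config.zero_links:
        tip = rng.uniform(10.0, 20.0, size=n)
        srt = config.srt_intercept - config.srt_slope * 75.0 \
            + rng.normal(0.0, max(config.srt_noise_sd, 1.0), size=n)
    elif config.bimodal_tips is not None:
        low_tip, high_tip = config.bimodal_tips
        med = np.median(word)
        tip = np.where(word > med, high_tip, low_tip).astype(float)
        srt = config.srt_intercept - config.srt_slope * word \
            + rng.normal(0.0, config.srt_noise_sd, size=n)
    else:
        tip = (config.tip_intercept - config.tip_slope * word
               + rng.normal(0.0, config.tip_noise_sd, size=n))
        srt = config.srt_intercept - config.srt_slope * word \
            + rng.normal(0.0, config.srt_noise_sd, size=n)
    tip = np.clip(tip, 0.0, 20.0)
    srt = np.clip(srt, 0.0, 18.0)

    peak_amp = np.clip(
        rng.normal(config.peak_amp_mean, config.peak_amp_sd, size=n), 2.0, None
    )
    width = np.clip(
        rng.normal(config.curve_width_mean, config.curve_width_sd, size=n), 3.0, None
    )

    if config.zero_links:
        qol = np.clip(rng.normal(65.0, 12.0, size=n), 0.0, 100.0)
        matrices = np.clip(np.round(rng.normal(22.0, 5.0, size=n)), 0, 36)
    else:
        qol = np.clip(
            65.0 + config.qol_amp_link * (peak_amp - config.peak_amp_mean)
            + rng.normal(0.0, config.qol_noise_sd, size=n), 0.0, 100.0
        )
        matrices = np.clip(
            np.round(22.0 + config.matrices_amp_link * (peak_amp - config.peak_amp_mean)
                     + rng.normal(0.0, config.matrices_noise_sd, size=n)), 0, 36
        )

    ages = rng.choice(REFERENCE_DEMOGRAPHICS["age"].to_numpy(), size=n, replace=True)
    ci_dur = np.clip(rng.normal(40.2, 11.1, size=n), 12.0, None)
    sex = np.where(rng.random(n) < 10.0 / 17.0, "F", "M")
    t_level = rng.normal(32.0, 6.0, size=n)
    smrt = np.clip(rng.normal(2.8, 1.2, size=n), 0.5, None)
    dprime = rng.normal(2.0, 0.8, size=n)
    stroop_int = np.clip(rng.normal(-0.04, 0.06, size=n), -1.0, 1.0)
    stroop_rt = np.clip(rng.normal(0.75, 0.12, size=n), 0.3, None)
    baseline_mm = np.clip(rng.normal(4.5, 0.5, size=n), 3.0, 6.5)
    blink_rate = rng.gamma(shape=4.0, scale=0.15 / 4.0, size=n)

    profiles = []
    for i in range(n):
        prof = ParticipantProfile(
            participant_id=f"P{i + 1:02d}",
            age=float(ages[i]),
            ci_duration=float(ci_dur[i]),
            sex=str(sex[i]),
            word_recognition=float(word[i]),
            t_level=float(t_level[i]),
            qol_total=float(qol[i]),
            matrices_correct=int(matrices[i]),
            stroop_interference=float(stroop_int[i]),
            stroop_control_rt=float(stroop_rt[i]),
            nback_dprime=float(dprime[i]),
            smrt_threshold=float(smrt[i]),
            latent=LatentParams(
                tip_snr=float(tip[i]),
                peak_amp=float(peak_amp[i]),
                curve_width=float(width[i]),
                srt=float(srt[i]),
                slope=config.intel_slope,
                baseline_mm=float(baseline_mm[i]),
                blink_rate=float(blink_rate[i]),
            ),
        )
        prof.validate()
        profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

def build_schedule(
    profile: ParticipantProfile,
    design: Design | None = None,
    seed: int = 0,
) -> list[TrialEvents]:
    """Build a randomized block schedule of trials for one participant.

    Blocks are (SNR, list) pairs in seed-randomized order; each block holds
    ``sentences_per_list`` trials.  With the default design this yields 240
    trials: 6 SNR levels x 2 lists x 20 sentences, 40 trials per SNR.
    """
    design = design or Design()
    if not design.snr_levels or design.lists_per_snr < 1 or design.sentences_per_list < 1:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)

    blocks = [(snr, k) for snr in design.snr_levels for k in range(design.lists_per_snr)]
    rng.shuffle(blocks)

    trials: list[TrialEvents] = []
    t = 0.0
    idx = 0
    lo, hi = design.sentence_dur_range
    for snr, _list_idx in blocks:
        for _ in range(design.sentences_per_list):
            idx += 1
            dur = rng.uniform(lo, hi)
            noise_onset = t
            sentence_onset = noise_onset + BASELINE_S
            sentence_offset = sentence_onset + dur
            prompt = sentence_offset + POST_OFFSET_S
            ev = TrialEvents(
                trial_id=f"{profile.participant_id}_T{idx:03d}",
                snr=float(snr),
                noise_onset=noise_onset,
                sentence_onset=sentence_onset,
                sentence_offset=sentence_offset,
                prompt_time=prompt,
                n_keywords=design.n_keywords,
            )
            ev.validate()
            trials.append(ev)
            t = prompt + design.iti_s
    return trials


# ---------------------------------------------------------------------------
# Generative psychometric functions
# ---------------------------------------------------------------------------

def effort_peak(snr: float, profile: ParticipantProfile) -> float:
    """Expected PPD (percent) at a given SNR: Gaussian inverted-U.

    Unimodal and symmetric about the participant's tipping point, equal to
    ``peak_amp`` exactly at ``snr == tip_snr``, strictly positive everywhere.
    """
    lat = profile.latent
    z = (np.asarray(snr, dtype=float) - lat.tip_snr) / lat.curve_width
    out = lat.peak_amp * np.exp(-0.5 * z * z)
    return float(out) if np.isscalar(snr) else out


def intelligibility(snr: float, profile: ParticipantProfile) -> float:
    """Probability of a keyword correct: logistic in SNR, 0.5 at the SRT."""
    lat = profile.latent
    if lat.slope <= 0:
        raise ValueError("intelligibility slope must be positive")
    from scipy.special import expit

    x = lat.slope * (np.asarray(snr, dtype=float) - lat.srt)
    out = expit(x)
    return float(out) if np.isscalar(snr) else out


def tlx_expected(snr: float, profile: ParticipantProfile) -> float:
    """Mean subjective-workload rating (0–100), decreasing in SNR."""
    return float(np.clip(78.0 - 2.0 * snr, 0.0, 100.0))


def simulate_behavior(
    trial: TrialEvents,
    profile: ParticipantProfile,
    seed: int = 0,
    tlx_noise_sd: float = 6.0,
) -> TrialEvents:
    """Fill keyword outcome and condition-level workload rating on a trial.

    ``keywords_correct ~ Binomial(n_keywords, intelligibility(snr))``.  The
    TLX rating is drawn once per (participant, SNR, seed) — a condition-level
    quantity repeated on every trial of that condition — as a noisy
    decreasing function of SNR clipped to [0, 100].
    """
    if trial.n_keywords < 1:
        raise ValueError("n_keywords must be >= 1")
    p = intelligibility(trial.snr, profile)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _stable_hash(trial.trial_id)])
    )
    correct = int(rng.binomial(trial.n_keywords, p))
    cond_rng = np.random.default_rng(
        np.random.SeedSequence([seed, _stable_hash(profile.participant_id), int(trial.snr)])
    )
    tlx = float(np.clip(
        tlx_expected(trial.snr, profile) + cond_rng.normal(0.0, tlx_noise_sd),
        0.0, 100.0,
    ))
    trial.keywords_correct = correct
    trial.tlx_score = tlx
    trial.validate()
    return trial


def _stable_hash(s: str) -> int:
    """Deterministic non-negative 32-bit hash of a string (process-stable)."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Raw trace simulation
# ---------------------------------------------------------------------------

def _response_kernel(trial: TrialEvents, t: np.ndarray, cfg: TraceConfig) -> np.ndarray:
    """Event-locked response shape: gamma kernel (x) sentence boxcar.

    Normalized so the maximum over the analysis window
    [sentence_onset, prompt_time) equals exactly 1 on the sample grid.
    """
    dt = 1.0 / cfg.fs
    tau = np.arange(0.0, 6.0 * cfg.kernel_shape * cfg.kernel_scale, dt)
    kernel = tau ** (cfg.kernel_shape - 1.0) * np.exp(-tau / cfg.kernel_scale)
    boxcar = ((t >= trial.sentence_onset) & (t < trial.sentence_offset)).astype(float)
    r = np.convolve(boxcar, kernel)[: t.size]
    window = (t >= trial.sentence_onset) & (t < trial.prompt_time)
    peak = r[window].max()
    if peak > 0:
        r = r / peak
    return r


def simulate_trace(
    trial: TrialEvents,
    profile: ParticipantProfile,
    seed: int = 0,
    cfg: TraceConfig | None = None,
) -> PupilTrace:
    """Simulate one trial's raw pupil trace, blinks and artifacts included.

    diameter(t) = baseline_mm * (1 + r(t) * effort_peak(snr)/100) + noise,
    with r(t) the normalized event-locked response, so the noiseless peak
    relative change inside the analysis window equals ``effort_peak`` exactly
    on the sample grid.  Blinks are Poisson-arriving NaN runs; a rare long
    artifact burst makes some trials fail the 40%-interpolated exclusion
    rule, as real recordings do.
    """
    cfg = cfg or TraceConfig()
    if cfg.fs <= 0:
        raise ValueError("sampling rate must be positive")
    lat = profile.latent
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _stable_hash(trial.trial_id), 7])
    )

    t0 = trial.noise_onset - cfg.pad_s
    t1 = trial.prompt_time + cfg.pad_s
    n = int(np.floor((t1 - t0) * cfg.fs)) + 1
    t = t0 + np.arange(n) / cfg.fs

    r = _response_kernel(trial, t, cfg) * (lat.peak_amp / 100.0) \
        if lat.peak_amp > 0 else np.zeros_like(t)
    amp_scale = effort_peak(trial.snr, profile) / lat.peak_amp if lat.peak_amp > 0 else 0.0
    d = lat.baseline_mm * (1.0 + r * amp_scale)
    if cfg.drift_sd > 0:
        # hippus-like slow fluctuation: smoothed white noise rescaled to
        # drift_sd; it dominates the trace's natural MAD, as in real pupil
        # recordings, so the evoked response is not an outlier
        w = rng.normal(0.0, 1.0, size=n)
        half = max(int(cfg.drift_tau * cfg.fs), 1)
        kern = np.exp(-0.5 * (np.arange(-3 * half, 3 * half + 1) / half) ** 2)
        kern /= kern.sum()
        slow = np.convolve(w, kern, mode="same")
        sd = slow.std()
        if sd > 0:
            d = d + slow * (cfg.drift_sd / sd)
    if cfg.noise_sd > 0:
        d = d + rng.normal(0.0, cfg.noise_sd, size=n)

    # Poisson blink dropouts
    dur_total = t1 - t0
    n_blinks = rng.poisson(lat.blink_rate * dur_total)
    for _ in range(n_blinks):
        start = rng.uniform(t0, t1)
        blink_dur = rng.uniform(*cfg.blink_dur_range)
        lo = np.searchsorted(t, start)
        hi = np.searchsorted(t, start + blink_dur)
        d[lo:hi] = np.nan

    # occasional long artifact burst (tracking loss)
    if cfg.artifact_burst_prob > 0 and rng.random() < cfg.artifact_burst_prob:
        frac = rng.uniform(*cfg.burst_frac_range)
        burst_n = int(frac * n)
        start_idx = rng.integers(0, max(n - burst_n, 1))
        d[start_idx:start_idx + burst_n] = np.nan

    return PupilTrace(timestamps=t, diameters=d, fs=cfg.fs)


# ---------------------------------------------------------------------------
# Fast PPD-level simulation (no raw traces)
# ---------------------------------------------------------------------------

def simulate_ppd_cells(
    profiles: list[ParticipantProfile],
    design: Design | None = None,
    ppd_noise_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial PPDs drawn directly from the effort curve, aggregated to
    participant x SNR cell means.

    Shortcut for model-level studies: trial PPD = effort_peak(snr) +
    N(0, ppd_noise_sd), averaged over ``trials_per_snr`` trials per cell.
    Returns a long DataFrame (participant_id, snr, ppd).
    """
    design = design or Design()
    rng = np.random.default_rng(seed)
    rows = []
    for prof in profiles:
        for snr in design.snr_levels:
            mu = effort_peak(snr, prof)
            trial_ppds = mu + rng.normal(0.0, ppd_noise_sd, size=design.trials_per_snr)
            rows.append((prof.participant_id, float(snr), float(trial_ppds.mean())))
    return pd.DataFrame(rows, columns=["participant_id", "snr", "ppd"])


# ---------------------------------------------------------------------------
# Table writers
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {k: v for k, v in asdict(p).items() if k != "latent"}
        row.update({f"latent_{k}": v for k, v in asdict(p.latent).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def events_to_frame(all_trials: dict[str, list[TrialEvents]]) -> pd.DataFrame:
    rows = []
    for pid, trials in all_trials.items():
        for tr in trials:
            row = asdict(tr)
            row["participant_id"] = pid
            rows.append(row)
    cols = ["participant_id", "trial_id", "snr", "noise_onset", "sentence_onset",
            "sentence_offset", "prompt_time", "n_keywords", "keywords_correct",
            "tlx_score"]
    return pd.DataFrame(rows)[cols]


def write_cohort(
    outdir: str | Path,
    profiles: list[ParticipantProfile],
    all_trials: dict[str, list[TrialEvents]],
    all_traces: dict[str, list[PupilTrace]] | None = None,
) -> None:
    """Write profiles.csv, events.csv and (optionally) samples.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles_to_frame(profiles).to_csv(outdir / "profiles.csv", index=False)
    events_to_frame(all_trials).to_csv(outdir / "events.csv", index=False)
    if all_traces is not None:
        parts = []
        for pid, traces in all_traces.items():
            trials = all_trials[pid]
            for tr, trace in zip(trials, traces):
                parts.append(pd.DataFrame({
                    "participant_id": pid,
                    "trial_id": tr.trial_id,
                    "t": trace.timestamps,
                    "pupil_mm": trace.diameters,
                }))
        # 10 significant digits keep 1/120 s steps strictly increasing even
        # after an hour of recording time
        pd.concat(parts, ignore_index=True).to_csv(
            outdir / "samples.csv", index=False, float_format="%.10g"
        )
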