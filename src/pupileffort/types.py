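"""Shared domain containers for the listening-effort pipeline.

The experiment these types describe: cochlear-implant (CI) listeners repeat
sentences embedded in speech-shaped noise at six signal-to-noise ratios
(0–20 dB in 4 dB steps) while an eye tracker records pupil diameter.  Each
trial has a 2 s noise-only baseline before the sentence, and the noise runs
for 2 s after the sentence offset before a verbal-response prompt.  The peak
pupil dilation (PPD) relative to the trial baseline indexes listening effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six task-difficulty conditions, in dB SNR.
SNR_LEVELS: tuple[int, ...] = (0, 4, 8, 12, 16, 20)

#: Noise-only lead-in before sentence onset, seconds.
BASELINE_S: float = 2.0

#: Noise tail after sentence offset before the response prompt, seconds.
POST_OFFSET_S: float = 2.0


@dataclass
class LatentParams:
    """Ground-truth simulation parameters for one synthetic participant.

    tip_snr
        SNR (dB) at which the participant's PPD-vs-SNR curve peaks — the
        "tipping point" beyond which effort/engagement declines.
    peak_amp
        PPD at the tipping point, in percent relative pupil-diameter change.
    curve_width
        Gaussian width (dB) of the inverted-U effort curve.
    srt
        Speech reception threshold: SNR (dB) of 50% keyword intelligibility.
    slope
        Logistic intelligibility slope, per dB.
    baseline_mm
        Resting pupil diameter, mm.
    blink_rate
        Poisson blink rate, events per second.
    """

    tip_snr: float
    peak_amp: float
    curve_width: float
    srt: float
    slope: float
    baseline_mm: float
    blink_rate: float


@dataclass
class ParticipantProfile:
    """Demographics, audiological and cognitive covariates for one listener."""

    participant_id: str
    age: float                    # years
    ci_duration: float            # months of CI use (inclusion requires >= 12)
    sex: str                      # "F" or "M"
    word_recognition: float       # % correct, disyllabic words in quiet [0, 100]
    t_level: float                # mean aided free-field threshold, dB HL
    qol_total: float              # NCIQ-style quality-of-life score [0, 100]
    matrices_correct: int         # progressive-matrices items correct
    stroop_interference: float    # incongruent minus congruent accuracy
    stroop_control_rt: float      # mean control-trial reaction time, s
    nback_dprime: float           # 2-back discriminability d'
    smrt_threshold: float         # spectral-ripple threshold, ripples/octave
    latent: LatentParams = None

    def validate(self) -> None:
        if not 0.0 <= self.word_recognition <= 100.0:
            raise ValueError("word_recognition outside [0, 100]")
        if not 0.0 <= self.qol_total <= 100.0:
            raise ValueError("qol_total outside [0, 100]")
        if self.ci_duration < 12:
            raise ValueError("ci_duration below the 12-month inclusion criterion")
        if self.latent is not None and self.latent.peak_amp <= 0:
            raise ValueError("peak_amp must be positive")


@dataclass
class TrialEvents:
    """Per-trial timeline and behavioral outcome.

    All times are in seconds from the start of the recording.  The timeline
    is rigid: noise_onset = sentence_onset − 2 s and
    prompt_time = sentence_offset + 2 s.
    """

    trial_id: str
    snr: float
    noise_onset: float
    sentence_onset: float
    sentence_offset: float
    prompt_time: float
    n_keywords: int = 4
    keywords_correct: int | None = None
    tlx_score: float | None = None

    def validate(self) -> None:
        if abs((self.sentence_onset - self.noise_onset) - BASELINE_S) > 1e-9:
            raise ValueError("noise_onset must precede sentence_onset by 2 s")
        if abs((self.prompt_time - self.sentence_offset) - POST_OFFSET_S) > 1e-9:
            raise ValueError("prompt_time must follow sentence_offset by 2 s")
        if self.keywords_correct is not None and not (
            0 <= self.keywords_correct <= self.n_keywords
        ):
            raise ValueError("keywords_correct outside [0, n_keywords]")


@dataclass
class PupilTrace:
    """One trial's pupil-diameter time series.

    Missing samples (blinks, dropouts) are NaN in ``diameters``.
    """

    timestamps: np.ndarray   # seconds, strictly increasing, nominally uniform
    diameters: np.ndarray    # mm, NaN = missing
    fs: float                # Hz

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.timestamps.shape != self.diameters.shape:
            raise ValueError("timestamps and diameters must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class CleanTrace:
    """A fully-interpolated trace plus bookkeeping of what was filled in."""

    timestamps: np.ndarray
    diameters: np.ndarray        # mm, no NaN remaining
    fs: float
    interp_mask: np.ndarray      # True where the value was discarded-then-filled

    @property
    def interp_fraction(self) -> float:
        return float(np.mean(self.interp_mask))


@dataclass
class TrialMetrics:
    """Baseline-corrected outcome of one trial."""

    trial_id: str
    snr: float
    baseline: float              # mm
    rel_times: np.ndarray        # s, restricted to [sentence_onset, prompt_time)
    rel_trace: np.ndarray        # percent relative change per sample
    ppd: float                   # percent, max of rel_trace in the window
    interp_fraction: float
    included: bool


@dataclass
class ConditionTrace:
    """Across-trial mean trace for one participant x SNR cell, onset-aligned."""

    snr: float
    t_rel: np.ndarray            # seconds from sentence onset
    mean_trace: np.ndarray       # percent
    se_trace: np.ndarray         # percent; NaN where n == 1
    n_trials: int


@dataclass
class ShapeParams:
    """Per-participant psychometric-shape summary of PPD versus SNR.

    Coefficients come from an OLS quadratic fit on coded SNR
    x = (snr − 10) / 10, so quad_coef < 0 reads directly as an inverted U.
    """

    participant_id: str
    mean_ppd: float
    linear_coef: float
    quad_coef: float


@dataclass
class LRTResult:
    """Likelihood-ratio test of a nested model comparison."""

    chi2: float
    df: int
    p: float


@dataclass
class ModelFit:
    """A fitted (generalized) mixed model with its nested-model test."""

    fixed_effects: "pandas.DataFrame"   # columns: term, beta, se, z, p
    lrt: LRTResult | dict
    family: str                          # "linear" or "logistic"
    formula_descr: str
    contrasts: "pandas.DataFrame | None" = None
    warnings: list = field(default_factory=list)


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    method: str          # "pearson" or "spearman"
    statistic: float     # r or rho
    test_stat: float     # t (Pearson) or S (Spearman)
    p: float
    p_adj: float
    n: int
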