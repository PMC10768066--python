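# Methods

This note documents the models, numerical choices and known limits of the
`pupileffort` pipeline.

## Experimental structure being modeled

Each trial: speech-shaped masking noise starts 2 s before a Spanish
HINT-style sentence (the noise-only window is the pupil baseline), continues
2 s past the sentence offset (letting the task-evoked dilation peak), then a
prompt cues the verbal response. Six SNR conditions (0, 4, 8, 12, 16, 20 dB)
are presented in randomized blocks of 20 sentences, two blocks per
condition: 240 trials per listener. Noise level is fixed (65 dB SPL) and
room luminance is treated as constant, so luminance-driven pupil changes are
out of scope.

## Synthetic cohort

The generator produces data with exactly the statistical structure the
analysis assumes, so every downstream stage is testable by parameter
recovery against stored latent ground truth.

**Effort curve.** Expected PPD at a given SNR is a Gaussian bump
`A exp(-(snr - t)^2 / (2 w^2))`: unimodal, symmetric, strictly positive,
maximal (`A`, percent units, default mean 8 ± 1.5) at the tipping point
`t`, with width `w` (default 6 ± 1 dB). The literature motivates only "an
inverted U with a participant-specific tipping point"; the Gaussian is the
simplest smooth shape with interpretable parameters, and any similar
unimodal form would serve.

**Covariate links.** Word recognition in quiet is uniform on 50–100%
(matching the performance range of typical study cohorts). The tipping
point is `t = 30 - 0.2 * word + N(0, 1.5)` dB, clipped to [0, 20]: better
performers disengage at easier (lower) SNRs, and tips fall in 10–20 dB.
That range matters: the per-participant quadratic coefficient fitted on the
symmetric 0–20 dB grid is a symmetric function of the tip about 10 dB
(mirror-image curves share the quadratic term), so only a tip range on one
side of 10 dB makes the quadratic coefficient monotone in the tip and hence
correlated with word recognition. On 10–20 dB the coefficient rises from its
most negative value (tip 10, centred inverted U) towards positive (tip 20,
convex tail), reproducing the negative word-recognition ↔ quadratic-term
association. An optional bimodal mode pins the two word groups' tips at
chosen values (e.g. 16 vs 4 dB) for interaction studies, and a null mode
severs every link for calibration. Quality of life is linked positively and
nonverbal-matrices scores negatively to peak amplitude; the remaining
covariates (age — sampled from the reference demographic table — CI
duration, aided thresholds, Stroop, d', SMRT) are independent draws in
plausible clinical ranges.

**Intelligibility and workload.** Keyword correctness is
`Binomial(4, logistic(slope * (snr - srt)))` with slope 0.25/dB and an SRT
decreasing in word recognition; subjective workload is `78 - 2*snr` plus
condition-level Gaussian noise (SD 6), clipped to [0, 100] and shared by all
trials of a condition, as a block-administered questionnaire would be.

**Raw traces.** 120 Hz (configurable; the nominal rate of the consumer eye
tracker class involved). Diameter is
`baseline_mm * (1 + r(t) * PPD/100) + slow(t) + noise(t)` where `r(t)` is a
gamma kernel (shape 2, scale 0.9 s) convolved with the sentence boxcar and
renormalized so its maximum over [onset, prompt) equals exactly 1 **on the
sample grid** — this makes the noiseless generator→pipeline round trip exact
up to smoothing (measured max error ~0.005 percentage points). `slow(t)` is
a hippus-like fluctuation (Gaussian-smoothed white noise, SD 0.08 mm,
0.5 s correlation scale). It is essential for realism of the artifact
detector: real recordings' median absolute deviation is dominated by slow
spontaneous fluctuation, and without it the evoked response itself becomes a
">3 MAD" outlier. White measurement noise has SD 0.03 mm. Blinks arrive as
a Poisson process (participant-specific rate, mean 0.15/s) deleting
100–300 ms runs; with probability 0.12 a trial additionally loses a
contiguous 45–70% block (tracking loss), which makes the >40% exclusion
rule remove ~12–14% of trials, matching the exclusion rate reported for
this kind of recording.

**What the generator does not emulate:** luminance and arousal effects,
pupil-size floor/ceiling nonlinearity, day-to-day session effects, gaze- or
confidence-dependent data quality, and serial dependence of behavior across
trials. Passing recovery tests therefore shows the *pipeline* is correct
under the stated generative assumptions, not that those assumptions exhaust
real data.

## Preprocessing

Fixed order per trial: detect → expand margins → interpolate → smooth →
exclude → baseline → normalize → PPD.

* **Detection:** flagged iff missing or `|x - median| > max(3 * MAD, 0.01 mm)`,
  with the *unscaled* MAD (no 1.4826 factor — the rule is stated in MAD
  units, not sigma-equivalents; the scale factor is configurable) computed
  per trial segment (robust to slow drift; per-session is a config away).
  The 0.01 mm floor keeps near-constant traces from flagging everything.
* **Margins:** each flagged run grows by ceil(0.035·fs) samples backward and
  ceil(0.100·fs) forward, clipped at the edges (blink on/offset artifacts).
* **Interpolation:** natural cubic spline through preserved samples; edge
  gaps take the nearest valid value (cubic extrapolation is unstable);
  fewer than 4 valid samples falls back to linear, fewer than 2 marks the
  trial unusable. The whole detect/expand/interpolate chain is verified
  sample-for-sample against a brute-force reference implementation.
* **Smoothing:** centered running average, window `round(0.1*fs)` forced
  odd (13 samples at 120 Hz), symmetric shrinking windows at the edges (so
  lines pass through unchanged).
* **Exclusion:** interpolated fraction strictly greater than 0.40 excludes;
  exactly 0.40 is kept.
* **Baseline:** mean smoothed diameter over the half-open window
  [onset − 2 s, onset). Smoothing precedes the baseline because baseline
  correction operates on the cleaned signal.
* **Normalization / PPD:** `rel = (x - baseline)/baseline * 100` on
  [onset, prompt); PPD is its maximum there, excluding post-prompt
  (verbalization) arousal. All windows are half-open on the right; times
  are seconds from recording start.
* **Aggregation:** per participant x SNR, onset-aligned; sentences vary in
  duration, so each aligned sample averages the trials that still cover it.
  SE with n = 1 is undefined and emitted as missing.

## Group models

* **Condition model:** `ppd ~ C(snr) + (1 | participant)` via statsmodels
  MixedLM — REML for reported coefficients, full ML for likelihood-ratio
  tests (SNR factor vs intercept-only, df 5). All 15 pairwise condition
  contrasts are Wald z tests on the fixed-effect covariance, deliberately
  uncorrected (they are descriptive post-hocs).
* **Polynomial model:** linear + quadratic terms on coded SNR
  `x = (snr - 10)/10` (raw centered coding, not orthogonal polynomials, so
  the quadratic sign reads directly as U vs inverted U); sequential 1-df
  LRTs (linear vs intercept, quadratic vs linear).
* **Accuracy model:** random-intercept binomial-logit GLMM fitted by
  maximum likelihood with *adaptive* Gauss–Hermite quadrature (25 nodes
  recentered/rescaled at each participant's conditional mode — non-adaptive
  quadrature is badly biased when per-participant posteriors are narrow).
  Verified against lme4::glmer (nAGQ 25) to four decimals on a fixture.
  All-correct/all-wrong outcomes raise a separation error rather than
  returning a meaningless fit.
* **Workload model:** ratings rescaled to (0,1) with the boundary shrink
  `(y(n-1)+0.5)/n`, logit-transformed, then the same linear mixed machinery;
  effects are log-odds shifts in relative workload.
* **Numerical robustness:** statsmodels' default optimizer can end on a
  singular Hessian or report infinite likelihood at the
  zero-random-variance boundary; fits fall back through Powell and
  Nelder–Mead and reject non-finite likelihoods. Exactly-degenerate inputs
  (zero residual variance, e.g. noise-free constructed data) are recognized
  by an OLS residual check and handled in the analytic limit: the LRT is 0
  if the reduced model is also exact, unbounded otherwise, with exact
  coefficients and zero SEs reported alongside a degeneracy warning.
* **Per-participant shape:** mean PPD and OLS quadratic coefficients from
  the (up to) six condition means — not trial-level data — with ≥3 cells
  required for coefficients; missing cells propagate.
* **Word-group analysis:** median split on word recognition (ties join the
  lower group); interaction tested by ML LRT of `C(snr)*group` vs
  `C(snr)+group` (df 5); per-group condition models; Welch t-tests confirm
  the groups do not differ on other covariates.

## Scoring battery

* **SMRT staircase:** 1-up/1-down on ripple density, start 0.5 RPO, step
  0.2 RPO, reference 20 RPO; the level at which the direction changed is
  logged as the reversal; stop at 10 reversals (or a 150-trial safeguard,
  with a 0.1 RPO floor — hardware cannot present negative density);
  threshold = mean of the last six reversals. A 1-up/1-down rule targets
  the 50% point; simulated logistic observers are recovered with mean
  error well under one step.
* **d':** `z(H) - z(F)` with the log-linear correction (+0.5 per cell, +1
  per denominator) applied *always*, keeping d' finite at perfect rates and
  continuous across the count grid.
* **Stroop:** interference = mean accuracy (proportion, invariant to block
  counts) on incongruent minus congruent trials; control reaction time is
  the control-block mean.
* **NASA-TLX:** `sum(weight_i * rating_i)/15` with the six pairwise-choice
  weights; **NCIQ:** 1–5 item scores mapped to 0–100, subdomain = mean over
  applicable items ("not applicable" excluded), global = mean of available
  subdomains. Reverse keying is accepted as an explicit per-item table and
  off by default, with the choice recorded in the output.

## Association battery

Twelve factors (age, CI duration, word recognition, T-level, QoL, mean TLX,
sentence accuracy in noise, matrices, Stroop interference, Stroop control
RT, d', SMRT) against two shape parameters (mean PPD, quadratic
coefficient). Method selection: Spearman if either variable is
bounded/ordinal (percent scales, proportions, item counts) or fails a
Shapiro–Wilk screen at alpha 0.05; Pearson otherwise. Pearson reports the t
statistic; Spearman reports `S = (1 - rho)(n^3 - n)/6` with midrank ties.

For n ≤ 30 the Spearman p-value comes from a cached one-million-draw
permutation null (fixed internal seed, deterministic) rather than the t
approximation: at n = 17 the t approximation inflates the
Bonferroni-relevant tail by ~33% (P(p < 0.05/24) ≈ 0.0028 instead of
0.0021), which would push the familywise error past its nominal level. With
the permutation null, 1,000 null cohorts give a raw p < 0.05 rate of ~5.1%
and a Bonferroni (m = 24) familywise error of ~5.0%.

The Bonferroni family defaults to m = 24 (the full grid) and is recorded in
every output row, because the choice decides which entries survive
correction. The per-group moderated regressions (shape on Stroop/d' within
word groups) are plain OLS, flagged `exploratory_uncorrected` in the output.

## Pipeline and reproducibility

One global seed fans out into per-stage substreams
(`SeedSequence([seed, k])`), so any stage can be re-run in isolation and
two runs with equal configuration are byte-identical. Every configurable
parameter lands in `manifest.json` together with per-stage row counts and
the excluded-trial fraction. All artifacts are plain CSV/JSON; the report
is regenerated from them alone. Default problem sizes (17 participants,
240 trials, 120 Hz; 25-seed recovery sweeps and 400 null cohorts in the
acceptance script, 50 seeds and 1,000 cohorts in the acceptance tests) were
chosen to keep a complete run at desk scale — under a minute for the
pipeline, about a minute for the script.

## Known limitations

* The evoked-response kernel, inverted-U form and all covariate link
  strengths are modeling choices, not estimates from data; only their
  qualitative structure is anchored in the literature.
* PPD as a max statistic is upward-biased under noise; the bias is shared
  across conditions and so cancels in shape comparisons, but absolute PPD
  levels exceed the generative peak slightly.
* Random effects are intercept-only; random slopes, crossed effects and
  full-time-course (growth-curve) models are out of scope, as are peak
  latency and baseline-diameter analyses.
* The mm scale of synthetic traces is nominal; the emulated tracker class
  does not measure absolute diameter in hardware.
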