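# pupileffort

Pupillometric listening-effort analysis for cochlear-implant (CI)
speech-in-noise experiments.

## The problem

CI listeners report high listening effort in noise even when speech
recognition succeeds. The standard objective index of effort is the
**peak pupil dilation (PPD)**: the maximum task-evoked, baseline-normalized
pupil-diameter change during a sentence-recognition trial. In normal-hearing
and hearing-impaired listeners the PPD-vs-difficulty curve is an inverted U —
effort rises with task demand until a "tipping point" where listeners
disengage — but in CI users the location of that tipping point varies
strongly across individuals, tracking clinical word recognition: when
per-listener curves peak at different signal-to-noise ratios (SNRs), the
group-mean curve flattens and the group-level quadratic trend vanishes.

`pupileffort` implements the full computational chain needed to study this:

* **`pupileffort.cohort`** — a synthetic-cohort generator with known ground
  truth: 17 listeners x 6 SNR conditions (0–20 dB in 4 dB steps) x 40
  sentence trials, raw 120 Hz pupil traces with blinks and artifact bursts,
  logistic intelligibility, workload ratings, and covariates linked to a
  participant-specific tipping point `t_i`. The expected PPD is
  `A_i * exp(-(snr - t_i)^2 / (2 w_i^2))` and the tipping point decreases
  with word recognition.
* **`pupileffort.preprocess`** — trial cleaning: 3-MAD artifact detection,
  35/100 ms margin expansion, cubic interpolation, 100 ms smoothing,
  exclusion of trials with >40% interpolated samples, 2 s pre-onset
  baseline, normalization `(x - baseline)/baseline * 100`, and PPD
  extraction over [sentence onset, response prompt).
* **`pupileffort.models`** — random-intercept mixed models of PPD, keyword
  accuracy (logistic, adaptive Gauss–Hermite quadrature) and workload vs
  SNR, with likelihood-ratio tests and pairwise Wald-z contrasts;
  per-participant shape parameters (mean PPD, linear/quadratic coefficients
  on coded SNR `x = (snr - 10)/10`); word-recognition median-split
  interaction analysis.
* **`pupileffort.scoring`** — the individual-differences battery: 1-up/1-down
  spectral-ripple (SMRT) staircase with last-six-reversal thresholds, 2-back
  d' with log-linear correction, Stroop interference, weighted NASA-TLX,
  NCIQ quality-of-life scoring.
* **`pupileffort.associations`** — the 12-factor x 2-shape-parameter
  correlation battery (Pearson for continuous variables, Spearman for
  bounded/ordinal or non-normal ones, small-n Spearman p from a permutation
  null), Bonferroni correction, Welch t-tests, exploratory per-group
  moderated regressions.
* **`pupileffort.pipeline` / CLI** — seeded, manifest-logged orchestration
  of simulate → preprocess → score → analyze → report, all artifacts as
  plain CSV/JSON.

## Worked example

```bash
pupileffort run-all --seed 42 --outdir demo
```

runs the full default experiment (17 participants, 240 trials each, 120 Hz
traces) in under a minute and writes `profiles.csv`, `events.csv`,
`samples.csv`, `trial_metrics.csv`, `condition_traces.csv`,
`cognitive_scores.csv`, `shape_params.csv`, `model_summaries.json`,
`correlation_table.csv`, `report.md` and `manifest.json` into `demo/`.
The run above logs

```
preprocess: 4080 trials, 13.1% excluded
```

(trials with more than 40% interpolated samples are dropped) and the report
contains, among others, the group PPD curve:

| SNR (dB) | mean PPD (%) | SE | n |
|---|---|---|---|
| 0 | 9.72 | 0.81 | 17 |
| 4 | 10.62 | 0.87 | 17 |
| 8 | 12.40 | 0.99 | 17 |
| 12 | 13.96 | 0.84 | 17 |
| 16 | 14.22 | 1.06 | 17 |
| 20 | 12.78 | 0.83 | 17 |

with model summaries (from `model_summaries.json`): SNR condition effect on
PPD chi2 = 30.3 (df 5, p < 0.001), quadratic trend chi2 = 7.8 (df 1,
p = 0.005, negative coefficient — an inverted U), accuracy and workload
effects both p < 0.001. Because this seed's cohort spans tipping points from
~10 to ~20 dB, the high-word-recognition group's PPD peaks at a lower SNR
(12 dB) than the low group's (16 dB), and the SNR x wordgroup interaction is
significant (chi2 = 29.9, df 5, p < 0.001) — the qualitative signature the
pipeline is built to detect. Each stage can also be run separately
(`pupileffort simulate|preprocess|score|analyze|report`) with `--config`
pointing to a YAML file of overrides.

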