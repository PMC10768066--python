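"""End-to-end orchestration: simulate -> preprocess -> score -> analyze -> report.

Every stage reads and writes plain delimited text under one run directory,
so any stage can be re-run or inspected in isolation.  A manifest records
the package version, the full configuration, and per-stage row counts
(including the fraction of trials excluded by the 40%-interpolated rule).
One global seed is fanned out into independent per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Design,
    EffectConfig,
    TraceConfig,
    build_schedule,
    events_to_frame,
    generate_profiles,
    profiles_to_frame,
    simulate_behavior,
    simulate_trace,
    write_cohort,
)
from .models import (
    fit_accuracy_model,
    fit_condition_model,
    fit_polynomial_model,
    fit_tlx_model,
    shape_table,
    wordgroup_analysis,
)
from .preprocess import PreprocessConfig, ppd_cell_means, preprocess_tables
from .associations import correlation_table, moderated_regressions
from .scoring import logistic_observer, run_staircase, smrt_threshold

log = logging.getLogger("pupileffort")


def substream(seed: int, idx: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; all of it lands in the manifest."""

    seed: int = 0
    n_participants: int = 17
    design: Design = field(default_factory=Design)
    effects: EffectConfig = field(default_factory=EffectConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bonferroni_m: int = 24
    outdir: str = "pupileffort_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from a flat or nested key-value YAML file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if key in ("design", "effects", "trace", "preprocess") and isinstance(val, dict):
                sub = getattr(cfg, key)
                for k2, v2 in val.items():
                    if not hasattr(sub, k2):
                        raise KeyError(f"unknown {key} option: {k2}")
                    if isinstance(v2, list):
                        v2 = tuple(v2)
                    setattr(sub, k2, v2)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise KeyError(f"unknown config option: {key}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> dict:
    """Generate cohort, schedules, behavior and raw traces; write the three
    input tables (profiles.csv, events.csv, samples.csv)."""
    outdir = Path(cfg.outdir)
    seed = substream(cfg.seed, 1)
    profiles = generate_profiles(cfg.n_participants, cfg.effects, seed=seed)
    all_trials, all_traces = {}, {}
    for i, prof in enumerate(profiles):
        sched = build_schedule(prof, cfg.design, seed=substream(seed, 100 + i))
        for tr in sched:
            simulate_behavior(tr, prof, seed=seed)
        all_trials[prof.participant_id] = sched
        all_traces[prof.participant_id] = [
            simulate_trace(tr, prof, seed=seed, cfg=cfg.trace) for tr in sched
        ]
    write_cohort(outdir, profiles, all_trials, all_traces)
    n_trials = sum(len(v) for v in all_trials.values())
    log.info("simulate: %d participants, %d trials", len(profiles), n_trials)
    return {"participants": len(profiles), "trials": n_trials}


def stage_preprocess(cfg: RunConfig) -> dict:
    """Clean all traces; write trial_metrics.csv and condition_traces.csv."""
    outdir = Path(cfg.outdir)
    samples = pd.read_csv(outdir / "samples.csv")
    events = pd.read_csv(outdir / "events.csv")
    trial_metrics, condition_traces = preprocess_tables(samples, events, cfg.preprocess)
    trial_metrics.to_csv(outdir / "trial_metrics.csv", index=False)
    condition_traces.to_csv(outdir / "condition_traces.csv", index=False,
                            float_format="%.6g")
    excluded_frac = 1.0 - trial_metrics["included"].mean()
    log.info("preprocess: %d trials, %.1f%% excluded",
             len(trial_metrics), 100 * excluded_frac)
    return {"trials": int(len(trial_metrics)),
            "excluded_fraction": float(excluded_frac)}


def stage_score(cfg: RunConfig) -> dict:
    """Assemble per-participant covariates; write cognitive_scores.csv and
    behavior_summaries.csv.

    The SMRT threshold is re-measured by running the adaptive staircase
    against a logistic observer centred on each profile's latent threshold;
    the remaining cognitive covariates come from the profile table.
    """
    outdir = Path(cfg.outdir)
    seed = substream(cfg.seed, 2)
    profiles = pd.read_csv(outdir / "profiles.csv")
    events = pd.read_csv(outdir / "events.csv")

    measured = []
    for i, row in profiles.iterrows():
        state = run_staircase(logistic_observer(row["smrt_threshold"]),
                              seed=substream(seed, i))
        measured.append(smrt_threshold(state))
    scores = profiles[[
        "participant_id", "age", "ci_duration", "word_recognition", "t_level",
        "qol_total", "matrices_correct", "stroop_interference",
        "stroop_control_rt", "nback_dprime",
    ]].copy()
    scores["smrt_threshold"] = measured
    scores.to_csv(outdir / "cognitive_scores.csv", index=False)

    behav = events.groupby("participant_id").apply(
        lambda g: pd.Series({
            "sentence_correct": g["keywords_correct"].sum() / g["n_keywords"].sum(),
            "tlx_mean": g.groupby("snr")["tlx_score"].first().mean(),
        }),
        include_groups=False,
    ).reset_index()
    behav.to_csv(outdir / "behavior_summaries.csv", index=False)
    log.info("score: %d participants", len(scores))
    return {"participants": int(len(scores))}


def _modelfit_to_dict(fit) -> dict:
    lrt = fit.lrt
    if isinstance(lrt, dict):
        lrt_d = {k: dataclasses.asdict(v) for k, v in lrt.items()}
    else:
        lrt_d = dataclasses.asdict(lrt)
    return {
        "family": fit.family,
        "formula": fit.formula_descr,
        "fixed_effects": fit.fixed_effects.to_dict(orient="records"),
        "lrt": lrt_d,
        "contrasts": (fit.contrasts.to_dict(orient="records")
                      if fit.contrasts is not None else None),
        "warnings": fit.warnings,
    }


def stage_analyze(cfg: RunConfig) -> dict:
    """Fit the group models, shape parameters and the correlation battery."""
    outdir = Path(cfg.outdir)
    events = pd.read_csv(outdir / "events.csv")
    trial_metrics = pd.read_csv(outdir / "trial_metrics.csv")
    scores = pd.read_csv(outdir / "cognitive_scores.csv")
    behav = pd.read_csv(outdir / "behavior_summaries.csv")

    cell_means = ppd_cell_means(trial_metrics)
    cond_fit = fit_condition_model(cell_means)
    poly_fit = fit_polynomial_model(cell_means)
    acc_fit = fit_accuracy_model(events.rename(columns={})[
        ["participant_id", "snr", "keywords_correct", "n_keywords"]])
    tlx_ratings = (events.groupby(["participant_id", "snr"], as_index=False)
                   ["tlx_score"].first().rename(columns={"tlx_score": "tlx"}))
    tlx_fit = fit_tlx_model(tlx_ratings)

    shapes = shape_table(cell_means)
    wg = wordgroup_analysis(shapes, scores, cell_means)
    shapes_out = shapes.merge(wg.groups, on="participant_id")
    shapes_out.to_csv(outdir / "shape_params.csv", index=False)

    corr = correlation_table(scores, shapes, behav, m=cfg.bonferroni_m)
    corr.to_csv(outdir / "correlation_table.csv", index=False)
    modreg = moderated_regressions(shapes, scores, wg.groups)
    modreg.to_csv(outdir / "moderated_regressions.csv", index=False)
    wg.covariate_tests.to_csv(outdir / "wordgroup_covariate_tests.csv", index=False)

    summaries = {
        "ppd_condition": _modelfit_to_dict(cond_fit),
        "ppd_polynomial": _modelfit_to_dict(poly_fit),
        "accuracy": _modelfit_to_dict(acc_fit),
        "tlx": _modelfit_to_dict(tlx_fit),
        "wordgroup_interaction": _modelfit_to_dict(wg.interaction),
        "wordgroup_per_group": {g: _modelfit_to_dict(f)
                                for g, f in wg.per_group.items()},
    }
    (outdir / "model_summaries.json").write_text(json.dumps(summaries, indent=2))
    log.info("analyze: %d correlation cells, %d shape rows",
             len(corr), len(shapes))
    return {"correlation_cells": int(len(corr)), "participants": int(len(shapes))}


def stage_report(cfg: RunConfig, plots: bool = False) -> dict:
    """Render a human-readable summary from the saved CSVs alone."""
    outdir = Path(cfg.outdir)
    report = render_report(outdir, plots=plots)
    (outdir / "report.md").write_text(report)
    return {"report_chars": len(report)}


def render_report(run_dir: str | Path, plots: bool = False) -> str:
    """Build the report text from a completed run directory.

    Depends only on the saved CSV/JSON artifacts, so a report regenerated
    from the same directory is identical.
    """
    run_dir = Path(run_dir)
    events = pd.read_csv(run_dir / "events.csv")
    trial_metrics = pd.read_csv(run_dir / "trial_metrics.csv")
    shapes = pd.read_csv(run_dir / "shape_params.csv")
    corr = pd.read_csv(run_dir / "correlation_table.csv")

    lines = ["# Listening-effort pipeline report", ""]
    excl = 1.0 - trial_metrics["included"].mean()
    lines += [f"Trials: {len(trial_metrics)}; excluded by the >40% "
              f"interpolation rule: {100 * excl:.1f}%", ""]

    def _per_snr(df, value, label):
        g = df.groupby("snr")[value]
        mean, sd, n = g.mean(), g.std(ddof=1), g.count()
        se = sd / np.sqrt(n)
        out = [f"## {label} by SNR", "", "| SNR (dB) | mean | SE | n |",
               "|---|---|---|---|"]
        for snr in mean.index:
            se_txt = f"{se[snr]:.3f}" if n[snr] > 1 else ""
            out.append(f"| {snr:g} | {mean[snr]:.3f} | {se_txt} | {n[snr]} |")
        out.append("")
        return out

    acc = events.assign(prop=events["keywords_correct"] / events["n_keywords"])
    acc_pp = acc.groupby(["participant_id", "snr"], as_index=False)["prop"].mean()
    lines += _per_snr(acc_pp, "prop", "Keyword proportion correct")

    tlx_pp = (events.groupby(["participant_id", "snr"], as_index=False)
              ["tlx_score"].first())
    lines += _per_snr(tlx_pp, "tlx_score", "NASA-TLX rating")

    cm = (trial_metrics[trial_metrics["included"]]
          .groupby(["participant_id", "snr"], as_index=False)["ppd_pct"].mean())
    lines += _per_snr(cm, "ppd_pct", "Peak pupil dilation (%)")

    lines += ["## PPD by SNR per word-recognition group", ""]
    cm_g = cm.merge(shapes[["participant_id", "wordgroup"]], on="participant_id")
    for g, sub in cm_g.groupby("wordgroup"):
        lines += _per_snr(sub, "ppd_pct", f"PPD (%), wordgroup = {g}")

    lines += ["## Correlation battery", "",
              "| factor | target | method | statistic | p | p_adj | sig |",
              "|---|---|---|---|---|---|---|"]
    for _, row in corr.iterrows():
        lines.append(
            f"| {row['factor']} | {row['target']} | {row['method']} | "
            f"{row['statistic']:.3f} | {row['p']:.4f} | {row['p_adj']:.4f} | "
            f"{'*' if row['significant'] else ''} |")
    lines.append("")

    if plots:
        _render_figures(run_dir, cm_g)
    return "\n".join(lines)


def _render_figures(run_dir: Path, cm_g: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = run_dir / "figures"
    figdir.mkdir(exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, (g, sub) in zip(axes, cm_g.groupby("wordgroup")):
        agg = sub.groupby("snr")["ppd_pct"].agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], fmt="o-")
        ax.set_title(f"wordgroup = {g}")
        ax.set_xlabel("SNR (dB)")
    axes[0].set_ylabel("PPD (%)")
    fig.tight_layout()
    fig.savefig(figdir / "ppd_by_group.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

STAGES = ("simulate", "preprocess", "score", "analyze", "report")


def run_pipeline(cfg: RunConfig, plots: bool = False) -> dict:
    """Run all stages in order; write manifest.json; return the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": cfg.to_dict(), "stages": {}}
    for name in STAGES:
        fn = {
            "simulate": stage_simulate,
            "preprocess": stage_preprocess,
            "score": stage_score,
            "analyze": stage_analyze,
            "report": lambda c: stage_report(c, plots=plots),
        }[name]
        try:
            manifest["stages"][name] = fn(cfg)
        except Exception:
            log.exception("stage %r failed", name)
            raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
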