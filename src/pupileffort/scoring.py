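"""Individual-difference batteries: SMRT staircase, d-prime, Stroop, TLX, NCIQ.

These scorers turn raw task logs into the per-participant covariates used by
the association analysis:

* spectral-ripple discrimination (SMRT): adaptive 1-up/1-down staircase on
  ripple density, threshold = mean of the last six reversals (RPO);
* 2-back working memory: signal-detection d' with a log-linear correction;
* Stroop color-word: accuracy interference (incongruent minus congruent)
  and mean control-trial reaction time;
* NASA-TLX: pairwise-weighted average of the six subscale ratings;
* NCIQ quality of life: six 10-item subdomains on a 5-point scale mapped to
  0-100, with "not applicable" items excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# SMRT adaptive staircase
# ---------------------------------------------------------------------------

@dataclass
class StaircaseState:
    """1-up/1-down adaptive track on ripple density (ripples per octave).

    A correct response makes the task harder (target density steps up toward
    the fixed 20-RPO reference); an incorrect response steps it down.  The
    track stops after 10 reversals (or a trial-count safeguard); the level
    logged at each reversal is the one at which the direction changed.
    """

    target_rpo: float = 0.5
    reference_rpo: float = 20.0
    step: float = 0.2
    floor: float = 0.1
    max_reversals: int = 10
    max_trials: int = 150
    reversals: list = field(default_factory=list)
    trial_log: list = field(default_factory=list)   # (target_rpo, correct)
    _direction: int = 0                             # +1 up, -1 down, 0 none yet

    @property
    def terminated(self) -> bool:
        return (len(self.reversals) >= self.max_reversals
                or len(self.trial_log) >= self.max_trials)


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial (mutates and returns the state)."""
    if state.terminated:
        raise RuntimeError("staircase already terminated")
    state.trial_log.append((state.target_rpo, bool(correct)))
    direction = 1 if correct else -1
    if state._direction != 0 and direction != state._direction:
        state.reversals.append(state.target_rpo)    # pre-change level
    state._direction = direction
    new = state.target_rpo + direction * state.step
    state.target_rpo = max(state.floor, min(new, state.reference_rpo))
    return state


def smrt_threshold(state: StaircaseState) -> float:
    """Mean of the last six reversal levels, in RPO; NaN when incomplete."""
    if len(state.reversals) < 6:
        return float("nan")
    return float(np.mean(state.reversals[-6:]))


def run_staircase(
    p_correct,
    seed: int = 0,
    start: float = 0.5,
    step: float = 0.2,
) -> StaircaseState:
    """Run a staircase against a stochastic observer.

    ``p_correct(target_rpo)`` gives the probability of a correct response;
    the 1-up/1-down rule converges on the density where that probability
    crosses 50%.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState(target_rpo=start, step=step)
    while not state.terminated:
        correct = rng.random() < p_correct(state.target_rpo)
        staircase_step(state, correct)
    return state


def logistic_observer(theta: float, slope: float = 4.0):
    """Observer whose accuracy falls logistically with ripple density,
    crossing 50% at ``theta`` RPO."""
    from scipy.special import expit

    def p_correct(target_rpo: float) -> float:
        return float(expit(-slope * (target_rpo - theta)))
    return p_correct


# ---------------------------------------------------------------------------
# N-back d-prime
# ---------------------------------------------------------------------------

def nback_dprime(hits: int, misses: int, false_alarms: int,
                 correct_rejections: int) -> float:
    """Signal-detection d' = z(H) - z(F) with the log-linear correction.

    The correction (add 0.5 to each cell, 1 to each denominator) is applied
    unconditionally, keeping d' finite at perfect hit/false-alarm rates and
    continuous across the count grid.
    """
    if min(hits, misses, false_alarms, correct_rejections) < 0:
        raise ValueError("counts must be non-negative")
    n_targets = hits + misses
    n_nontargets = false_alarms + correct_rejections
    if n_targets == 0 or n_nontargets == 0:
        raise ValueError("need at least one target and one non-target")
    h = (hits + 0.5) / (n_targets + 1.0)
    f = (false_alarms + 0.5) / (n_nontargets + 1.0)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


# ---------------------------------------------------------------------------
# Stroop color-word
# ---------------------------------------------------------------------------

def stroop_scores(trials: pd.DataFrame) -> tuple[float, float]:
    """(interference, control_rt) from per-trial Stroop data.

    ``trials`` columns: block_type in {congruent, incongruent, control},
    correct (0/1), rt (s).  Interference = mean accuracy on incongruent
    minus congruent trials (typically <= 0); control_rt = mean reaction time
    on control trials.
    """
    needed = {"congruent", "incongruent", "control"}
    present = set(trials["block_type"].unique())
    if not needed <= present:
        raise ValueError(f"missing block types: {sorted(needed - present)}")
    by = trials.groupby("block_type")
    interference = float(by["correct"].mean()["incongruent"]
                         - by["correct"].mean()["congruent"])
    control_rt = float(by["rt"].mean()["control"])
    return interference, control_rt


# ---------------------------------------------------------------------------
# NASA-TLX
# ---------------------------------------------------------------------------

TLX_SUBSCALES = ("mental", "physical", "temporal", "performance", "effort",
                 "frustration")


def tlx_weighted_score(weights, ratings) -> float:
    """Weighted workload: sum(weight_i * rating_i) / 15.

    ``weights`` are the six pairwise-comparison win counts (sum 15);
    ``ratings`` the six subscale ratings in [0, 100].
    """
    weights = np.asarray(weights, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if weights.size != 6 or ratings.size != 6:
        raise ValueError("six subscales required")
    if weights.sum() != 15:
        raise ValueError("pairwise weights must sum to 15")
    if ratings.min() < 0 or ratings.max() > 100:
        raise ValueError("ratings must lie in [0, 100]")
    return float(np.dot(weights, ratings) / 15.0)


# ---------------------------------------------------------------------------
# NCIQ
# ---------------------------------------------------------------------------

NCIQ_SUBDOMAINS = ("basic_sound", "advanced_sound", "speech_production",
                   "self_esteem", "activity", "social_interaction")


def nciq_scores(
    responses: np.ndarray,
    reverse_keyed: np.ndarray | None = None,
) -> dict:
    """Score a 6-subdomain x 10-item questionnaire on a 1–5 scale.

    ``responses``: 6 x 10 array of item answers in {1..5}, NaN = "not
    applicable".  Items are mapped linearly to {0, 25, 50, 75, 100};
    subdomain scores are means over applicable items, and the global score
    is the mean of available subdomains.  ``reverse_keyed`` (same shape,
    boolean) flips flagged items (answer -> 6 - answer); the default applies
    no reversal, and the output records that choice.
    """
    resp = np.asarray(responses, dtype=float)
    if resp.shape != (6, 10):
        raise ValueError("expected a 6 x 10 response array")
    valid = np.isfinite(resp)
    if valid.any() and (np.nanmin(resp) < 1 or np.nanmax(resp) > 5):
        raise ValueError("responses must lie in {1..5} or NaN")
    if reverse_keyed is not None:
        rk = np.asarray(reverse_keyed, dtype=bool)
        resp = np.where(rk & valid, 6.0 - resp, resp)
    item_scores = (resp - 1.0) * 25.0
    out = {}
    sub_means = []
    for i, name in enumerate(NCIQ_SUBDOMAINS):
        row = item_scores[i]
        if np.isfinite(row).any():
            val = float(np.nanmean(row))
        else:
            val = float("nan")     # all items not-applicable
        out[name] = val
        sub_means.append(val)
    out["global"] = float(np.nanmean(sub_means))
    out["reverse_keying_applied"] = reverse_keyed is not None
    return out


# ---------------------------------------------------------------------------
# CSV-level driver
# ---------------------------------------------------------------------------

def score_task_tables(task_dir: str | Path) -> pd.DataFrame:
    """Score per-task raw logs into a cognitive_scores table.

    Reads whichever of nback_trials.csv, stroop_trials.csv,
    tlx_responses.csv, nciq_responses.csv and smrt_log.csv exist under
    ``task_dir``, each keyed by participant_id, and returns one row per
    participant with the derived scores.
    """
    task_dir = Path(task_dir)
    frames: dict[str, pd.Series] = {}

    fp = task_dir / "nback_trials.csv"
    if fp.exists():
        nb = pd.read_csv(fp)
        frames["nback_dprime"] = nb.groupby("participant_id").apply(
            lambda g: nback_dprime(int(g["hits"].sum()), int(g["misses"].sum()),
                                   int(g["false_alarms"].sum()),
                                   int(g["correct_rejections"].sum())),
            include_groups=False,
        )

    fp = task_dir / "stroop_trials.csv"
    if fp.exists():
        st = pd.read_csv(fp)
        res = st.groupby("participant_id").apply(
            lambda g: pd.Series(stroop_scores(g),
                                index=["stroop_interference", "stroop_control_rt"]),
            include_groups=False,
        )
        frames["stroop_interference"] = res["stroop_interference"]
        frames["stroop_control_rt"] = res["stroop_control_rt"]

    fp = task_dir / "tlx_responses.csv"
    if fp.exists():
        tlx = pd.read_csv(fp)
        frames["tlx_overall"] = tlx.groupby("participant_id").apply(
            lambda g: tlx_weighted_score(
                g.sort_values("subscale")["weight"].to_numpy(),
                g.sort_values("subscale")["rating"].to_numpy()),
            include_groups=False,
        )

    fp = task_dir / "nciq_responses.csv"
    if fp.exists():
        nc = pd.read_csv(fp)
        frames["qol_total"] = nc.groupby("participant_id").apply(
            lambda g: nciq_scores(
                g.sort_values(["subdomain", "item"])["response"]
                .to_numpy().reshape(6, 10))["global"],
            include_groups=False,
        )

    fp = task_dir / "smrt_log.csv"
    if fp.exists():
        sm = pd.read_csv(fp)

        def _thr(g):
            st_ = StaircaseState()
            for correct in g.sort_values("trial")["correct"]:
                if st_.terminated:
                    break
                staircase_step(st_, bool(correct))
            return smrt_threshold(st_)

        frames["smrt_threshold"] = sm.groupby("participant_id").apply(
            _thr, include_groups=False)

    if not frames:
        raise FileNotFoundError(f"no task tables found under {task_dir}")
    return pd.DataFrame(frames).rename_axis("participant_id").reset_index()
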