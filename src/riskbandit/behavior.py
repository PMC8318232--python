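"""Behavioural analyses for bandit cohorts (real or synthetic).

The battery mirrors a standard analysis of condition-specific risk
preferences: an inclusion criterion based on late-block accuracy, a binned
accuracy trace, t-tests on risk preferences within and between the two
matched-mean conditions, and a test of whether value preferences emerge
faster over trials than risk preferences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task import (
    CONDITION_BOTH_HIGH,
    CONDITION_BOTH_LOW,
    CONDITION_DIFFERENT,
    STIMULI,
    SessionData,
)

__all__ = [
    "INCLUSION_THRESHOLD",
    "inclusion_filter",
    "accuracy_trace",
    "condition_tests",
    "emergence_test",
    "analyze_cohort",
    "CohortAnalysis",
]

#: Strictly-greater-than accuracy required on late different-condition trials.
INCLUSION_THRESHOLD = 0.65
#: "Late" means within-block trial number above this (second half of a block).
LATE_TRIAL_CUTOFF = 60

HIGH_VALUE_IDS = {i for i, s in STIMULI.items() if s.value_class == "high"}
RISKY_IDS = {i for i, s in STIMULI.items() if s.risk_class == "risky"}

#: Per-trial clip for logistic slopes (per-trial log-odds change); fits that
#: hit it are flagged as separated.
SLOPE_CLIP = 1.0


def _high_value_chosen(trials: pd.DataFrame) -> pd.Series:
    return trials["choice"].isin(HIGH_VALUE_IDS)


def inclusion_filter(session: SessionData) -> bool:
    """Did the participant understand the task?

    Included iff the proportion of high-value choices on different-condition
    trials in the second half of each block (trials 61-120, pooled over
    blocks) strictly exceeds 65%.
    """
    t = session.trials
    late = t[(t["condition"] == CONDITION_DIFFERENT) & (t["trial"] > LATE_TRIAL_CUTOFF)]
    if len(late) == 0:
        warnings.warn(
            f"participant {session.participant_id}: no late different-"
            f"condition trials; treated as excluded"
        )
        return False
    return _high_value_chosen(late).mean() > INCLUSION_THRESHOLD


def accuracy_trace(
    sessions: list[SessionData], bin_width: int = 10, n_trials_per_block: int = 120
) -> pd.DataFrame:
    """Binned accuracy (high-value choice in the different condition).

    Trials are binned by within-block trial number; participant means are
    computed first, then the cohort mean and the SE over participant means.
    """
    if n_trials_per_block % bin_width != 0:
        raise ValueError(f"bin_width {bin_width} must divide {n_trials_per_block}")
    edges = np.arange(0, n_trials_per_block + bin_width, bin_width)
    per_participant = []
    for s in sessions:
        t = s.condition_trials(CONDITION_DIFFERENT).copy()
        t["bin"] = pd.cut(t["trial"], edges, labels=False)
        t["correct"] = _high_value_chosen(t)
        per_participant.append(t.groupby("bin")["correct"].mean())
    mat = pd.DataFrame(per_participant)
    out = pd.DataFrame(
        {
            "bin_start": edges[:-1] + 1,
            "bin_end": edges[1:],
            "mean": mat.mean(axis=0),
            "se": mat.std(axis=0, ddof=1) / np.sqrt(mat.notna().sum(axis=0)),
        }
    )
    return out.reset_index(drop=True)


def _risk_preference(session: SessionData, condition: str) -> float:
    t = session.condition_trials(condition)
    if len(t) == 0:
        return float("nan")
    return float(t["choice"].isin(RISKY_IDS).mean())


def condition_tests(sessions: list[SessionData]) -> dict[str, dict[str, float]]:
    """Risk-preference tests over a cohort (two-tailed throughout).

    Returns, keyed by contrast: the paired t-test of both-high vs both-low
    per-participant risk preferences, and one-sample t-tests of each
    condition's preference against indifference (0.5).
    """
    bh = np.array([_risk_preference(s, CONDITION_BOTH_HIGH) for s in sessions])
    bl = np.array([_risk_preference(s, CONDITION_BOTH_LOW) for s in sessions])
    ok = ~np.isnan(bh) & ~np.isnan(bl)
    if ok.sum() < 2:
        raise ValueError("need at least two participants with defined preferences")
    bh, bl = bh[ok], bl[ok]

    def _pack(t, p, df, kind):
        t = float(t) if np.isfinite(t) else 0.0
        p = float(p) if np.isfinite(p) else 1.0
        return {"t": t, "p": p, "df": int(df), "test": kind}

    with np.errstate(invalid="ignore", divide="ignore"):
        t_pair, p_pair = stats.ttest_rel(bh, bl)
        t_bh, p_bh = stats.ttest_1samp(bh, 0.5)
        t_bl, p_bl = stats.ttest_1samp(bl, 0.5)
    n = len(bh)
    return {
        "both_high_vs_both_low": _pack(t_pair, p_pair, n - 1, "paired two-tailed"),
        "both_high_vs_chance": _pack(t_bh, p_bh, n - 1, "one-sample two-tailed"),
        "both_low_vs_chance": _pack(t_bl, p_bl, n - 1, "one-sample two-tailed"),
        "mean_difference": {"value": float(np.mean(bh - bl)), "n": n},
    }


def _preferred_indicator(trials: pd.DataFrame) -> pd.Series:
    """Code each choice as 'preferred' (1) or not (0).

    Value decisions (different condition): the high-value option.  Risk
    decisions: the asymptotically preferred option -- risky in both-high,
    safe in both-low.
    """
    cond = trials["condition"]
    risky = trials["choice"].isin(RISKY_IDS)
    high = _high_value_chosen(trials)
    out = pd.Series(np.nan, index=trials.index)
    out[cond == CONDITION_DIFFERENT] = high[cond == CONDITION_DIFFERENT].astype(float)
    out[cond == CONDITION_BOTH_HIGH] = risky[cond == CONDITION_BOTH_HIGH].astype(float)
    out[cond == CONDITION_BOTH_LOW] = (~risky[cond == CONDITION_BOTH_LOW]).astype(float)
    return out


def _logistic_slope(y: np.ndarray, x: np.ndarray) -> tuple[float, bool]:
    """Per-trial slope of a logistic trend fit; clipped under separation."""
    if len(np.unique(y)) < 2:  # constant response: no trend information
        return 0.0, False
    X = sm.add_constant(x.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            slope = float(res.params[1])
        except Exception:
            slope = np.sign(np.corrcoef(x, y)[0, 1]) * SLOPE_CLIP
    if not np.isfinite(slope) or abs(slope) > SLOPE_CLIP:
        return float(np.clip(slope, -SLOPE_CLIP, SLOPE_CLIP)), True
    return slope, False


def emergence_test(sessions: list[SessionData]) -> dict:
    """Do value preferences emerge faster than risk preferences?

    For each participant, a logistic trend of preferred choice on
    within-block trial number is fitted separately for value decisions
    (different condition) and risk decisions (both-high/both-low).  The
    per-participant slope differences (value minus risk) are tested against
    zero with a two-tailed t-test.
    """
    diffs, flagged = [], 0
    value_slopes, risk_slopes = [], []
    for s in sessions:
        t = s.trials
        pref = _preferred_indicator(t)
        is_value = t["condition"] == CONDITION_DIFFERENT
        sv, f1 = _logistic_slope(
            pref[is_value].to_numpy(), t.loc[is_value, "trial"].to_numpy()
        )
        sr, f2 = _logistic_slope(
            pref[~is_value].to_numpy(), t.loc[~is_value, "trial"].to_numpy()
        )
        flagged += int(f1 or f2)
        value_slopes.append(sv)
        risk_slopes.append(sr)
        diffs.append(sv - sr)
    diffs = np.array(diffs)
    if np.std(diffs, ddof=1) == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_1samp(diffs, 0.0)
    return {
        "t": float(t_stat),
        "p": float(p),
        "df": len(diffs) - 1,
        "mean_value_slope": float(np.mean(value_slopes)),
        "mean_risk_slope": float(np.mean(risk_slopes)),
        "mean_slope_difference": float(np.mean(diffs)),
        "n_flagged_separation": flagged,
        "test": "one-sample two-tailed on per-participant slope differences",
    }


@dataclass
class CohortAnalysis:
    """Full behavioural report for one cohort."""

    n_total: int
    included_ids: list[str]
    excluded_ids: list[str]
    accuracy: pd.DataFrame
    risk_summaries: pd.DataFrame
    tests: dict = field(default_factory=dict)
    emergence: dict = field(default_factory=dict)


def analyze_cohort(sessions: list[SessionData], apply_filter: bool = True) -> CohortAnalysis:
    """Run the full battery: filter, accuracy trace, risk tests, emergence."""
    included = [s for s in sessions if not apply_filter or inclusion_filter(s)]
    excluded = [s for s in sessions if s not in included]
    if len(included) < 2:
        raise ValueError(
            f"only {len(included)} participants pass the inclusion criterion"
        )
    summaries = pd.DataFrame(
        {
            "participant": [s.participant_id for s in included],
            "p_risky_both_high": [
                _risk_preference(s, CONDITION_BOTH_HIGH) for s in included
            ],
            "p_risky_both_low": [
                _risk_preference(s, CONDITION_BOTH_LOW) for s in included
            ],
        }
    )
    summaries["difference"] = (
        summaries["p_risky_both_high"] - summaries["p_risky_both_low"]
    )
    return CohortAnalysis(
        n_total=len(sessions),
        included_ids=[s.participant_id for s in included],
        excluded_ids=[s.participant_id for s in excluded],
        accuracy=accuracy_trace(included),
        risk_summaries=summaries,
        tests=condition_tests(included),
        emergence=emergence_test(included),
    )
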