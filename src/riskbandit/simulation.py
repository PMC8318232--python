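"""Cohort-level simulation studies of risk preferences.

Given per-participant parameter sets for a model, many replicate synthetic
experiments are generated and summarised as: per-participant risk
preferences in the two matched-mean conditions, their difference (the
effect size of interest), within-block risk-preference traces, and a 2-D
kernel density over the (both-high, both-low) preference plane.

Aggregation order matters and is fixed throughout: replicate experiments
are averaged first within each simulated participant, then across
participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import RISKY_IDS
from .models import get_model, simulate_session
from .task import (
    CONDITION_BOTH_HIGH,
    CONDITION_BOTH_LOW,
    SessionData,
    build_schedule,
)

__all__ = [
    "simulate_experiments",
    "risk_preference",
    "risk_trace",
    "effect_size",
    "preference_density",
    "RiskTrace",
    "PreferenceDensity",
]

DEFAULT_SMOOTHING_WINDOW = 20


def simulate_experiments(
    model,
    parameter_sets: list[dict[str, float]],
    n_reps: int = 50,
    seed: int | None = None,
    n_blocks: int = 4,
    reps_per_pair: int = 10,
) -> list[list[SessionData]]:
    """Simulate ``n_reps`` full experiments, one session per parameter set.

    Returns a list over replicates, each a list of sessions (one per
    simulated participant, in parameter-set order).  Fully reproducible
    from ``seed``.
    """
    model = get_model(model) if isinstance(model, str) else model
    rng = np.random.default_rng(seed)
    experiments = []
    for rep in range(n_reps):
        cohort = []
        for i, params in enumerate(parameter_sets):
            s = int(rng.integers(2**31))
            schedule = build_schedule(n_blocks, reps_per_pair, seed=s)
            session, _ = simulate_session(
                model, params, schedule=schedule, seed=s + 1,
                participant_id=f"p{i:03d}",
            )
            cohort.append(session)
        experiments.append(cohort)
    return experiments


def risk_preference(session: SessionData, condition: str) -> float:
    """Fraction of the condition's trials on which the risky option was
    chosen; NaN if the session has no such trials."""
    t = session.condition_trials(condition)
    if len(t) == 0:
        return float("nan")
    return float(t["choice"].isin(RISKY_IDS).mean())


@dataclass
class RiskTrace:
    condition: str
    trial: np.ndarray  # within-block position, 1..n
    mean: np.ndarray  # smoothed cohort mean risky-choice probability
    se: np.ndarray  # SE across participants (of the unsmoothed means)
    window: int


def _participant_position_trace(
    sessions: list[SessionData], condition: str, n_positions: int
) -> np.ndarray:
    """Risky-choice indicator per within-block position for one participant,
    averaged over blocks (and NaN where the position never showed the
    condition), stacked over replicate sessions and averaged."""
    per_rep = np.full((len(sessions), n_positions), np.nan)
    for k, session in enumerate(sessions):
        t = session.condition_trials(condition)
        risky = t["choice"].isin(RISKY_IDS).astype(float)
        grouped = risky.groupby(t["trial"]).mean()
        per_rep[k, grouped.index.to_numpy() - 1] = grouped.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(per_rep, axis=0)


def risk_trace(
    experiments: list[list[SessionData]],
    condition: str,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    n_positions: int = 120,
) -> RiskTrace:
    """Within-block time course of risk preference for a simulated cohort.

    For each participant the risky-choice indicator is averaged over
    replicate experiments per within-block position; the cohort mean of
    those participant traces is then smoothed with a centred moving average
    (window shrinks at the edges rather than padding).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n_participants = len(experiments[0])
    traces = np.vstack(
        [
            _participant_position_trace(
                [rep[i] for rep in experiments], condition, n_positions
            )
            for i in range(n_participants)
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(traces, axis=0)
        se = np.nanstd(traces, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(traces), axis=0)
        )
    smoothed = (
        pd.Series(mean).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return RiskTrace(
        condition=condition,
        trial=np.arange(1, n_positions + 1),
        mean=smoothed,
        se=se,
        window=window,
    )


def effect_size(experiments: list[list[SessionData]]) -> dict:
    """Condition difference in risk preference, p(risky|BH) - p(risky|BL).

    Replicates are averaged within participant first; returns the cohort
    mean, SE over participant means, and the per-participant values.
    """
    n_participants = len(experiments[0])
    per_participant = np.full(n_participants, np.nan)
    bh_means = np.full(n_participants, np.nan)
    bl_means = np.full(n_participants, np.nan)
    for i in range(n_participants):
        reps = [rep[i] for rep in experiments]
        bh = np.array([risk_preference(s, CONDITION_BOTH_HIGH) for s in reps])
        bl = np.array([risk_preference(s, CONDITION_BOTH_LOW) for s in reps])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            bh_means[i] = np.nanmean(bh)
            bl_means[i] = np.nanmean(bl)
        per_participant[i] = bh_means[i] - bl_means[i]
    return {
        "mean": float(np.nanmean(per_participant)),
        "se": float(
            np.nanstd(per_participant, ddof=1)
            / np.sqrt(np.sum(~np.isnan(per_participant)))
        ),
        "per_participant": per_participant,
        "both_high_mean": float(np.nanmean(bh_means)),
        "both_low_mean": float(np.nanmean(bl_means)),
    }


@dataclass
class PreferenceDensity:
    x: np.ndarray  # grid over p(risky | both-high)
    y: np.ndarray  # grid over p(risky | both-low)
    density: np.ndarray  # shape (len(y), len(x))
    levels: np.ndarray
    contours: list[np.ndarray]  # polyline vertex arrays, one per contour piece
    bandwidth: float | str


def preference_density(
    points: np.ndarray,
    grid_size: int = 101,
    n_levels: int = 8,
    bandwidth_floor: float = 0.02,
) -> PreferenceDensity:
    """2-D Gaussian kernel density of (both-high, both-low) risk preferences.

    Bandwidth follows Silverman's rule; degenerate inputs (all points
    identical along an axis) fall back to an isotropic kernel with a fixed
    floor bandwidth, with a warning.  Contour levels are spaced over the
    density's own value range, matching per-distribution scaling.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n, 2) array with n >= 2 preference pairs")
    x = np.linspace(0.0, 1.0, grid_size)
    y = np.linspace(0.0, 1.0, grid_size)
    xx, yy = np.meshgrid(x, y)
    grid = np.vstack([xx.ravel(), yy.ravel()])
    try:
        kde = stats.gaussian_kde(pts.T, bw_method="silverman")
        density = kde(grid).reshape(grid_size, grid_size)
        bandwidth: float | str = "silverman"
    except np.linalg.LinAlgError:
        warnings.warn(
            "degenerate preference cloud; using fixed-bandwidth isotropic kernel"
        )
        h = bandwidth_floor
        d2 = (
            (grid[0][:, None] - pts[:, 0]) ** 2
            + (grid[1][:, None] - pts[:, 1]) ** 2
        )
        density = (
            np.exp(-0.5 * d2 / h**2).sum(axis=1)
            / (len(pts) * 2 * np.pi * h**2)
        ).reshape(grid_size, grid_size)
        bandwidth = h
    levels = np.linspace(0.0, density.max(), n_levels + 2)[1:-1]
    contours = _contour_polylines(x, y, density, levels)
    return PreferenceDensity(
        x=x, y=y, density=density, levels=levels, contours=contours,
        bandwidth=bandwidth,
    )


def _contour_polylines(x, y, z, levels) -> list[np.ndarray]:
    import contourpy

    gen = contourpy.contour_generator(x=x, y=y, z=z)
    out = []
    for lev in levels:
        for line in gen.lines(lev):
            out.append(np.asarray(line))
    return out
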