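"""Twelve trial-by-trial learning-and-choice models for the bandit task.

All models are variants of a delta-rule (Rescorla-Wagner) learner over the
four stimulus values Q, combined with a softmax choice rule.  The variants
differ along four orthogonal axes, encoded as flags on :class:`ModelSpec`:

* ``utility_family`` -- rewards may pass through a nonlinear utility before
  entering the outcome prediction error (exponential family for concave /
  convex curvature, sign-preserving power family for s-shaped / inverse
  s-shaped curvature).
* ``rate_rule`` -- the learning rate may depend on prediction-error valence
  (``valence``), on whether the chosen arm is risky or safe (``variance``),
  or on surprise |delta|^k (``attention``).
* ``pe_scaling`` -- the outcome prediction error may be divided by a learned
  spread estimate S before driving updates (adaptive-coding model).
* ``risk_gate`` -- the spread S of each shown option may be added to its
  action value with weight tanh(omega * gate); the gating signal is the
  stimulus prediction error (PEIRS), the pair-mean reward prediction (PIRS)
  or the previous trial's outcome prediction error (OEIRS).

State is reset at every block boundary (a fresh stimulus set is used per
block): values to Q0 = 50, spreads to S0, and the carried-over outcome
prediction error (OEIRS) to 0.  Only the chosen stimulus's value and spread
are updated on a trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .task import (
    STIMULI,
    SESSION_COLUMNS,
    SessionData,
    build_schedule,
    sample_reward,
)

__all__ = [
    "ModelSpec",
    "MODELS",
    "MODEL_NAMES",
    "softmax_probabilities",
    "outcome_prediction_error",
    "stimulus_prediction_error",
    "utility_transform",
    "effective_learning_rate",
    "scaled_outcome_pe",
    "value_update",
    "spread_update",
    "action_activations",
    "simulate_session",
    "replay_session",
    "session_log_likelihood",
]

Q0 = 50.0  # initial value estimate, middle of the reward range
UTILITY_SCALE = 50.0  # sigma in the utility transforms
UTILITY_SHIFT = 50.0  # m (reference point) in the utility transforms
S_FLOOR = 1e-3  # spread floor for the scaled-PE model (keeps delta/S defined)

RISKY_IDS = (1, 3)  # odd stimulus ids have sd 20
TRACE_COLUMNS = (
    ["block", "trial", "stim_left", "stim_right", "choice", "reward"]
    + [f"Q{i}" for i in range(1, 5)]
    + [f"S{i}" for i in range(1, 5)]
    + ["delta_stim", "p_left", "p_choice", "delta_out", "delta_out_scaled"]
)


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one model: free parameters plus behaviour flags."""

    name: str
    params: tuple[str, ...]
    utility_family: str = "identity"  # identity | concave | convex | s | inverse-s
    rate_rule: str = "fixed"  # fixed | valence | variance | attention
    pe_scaling: bool = False
    risk_gate: str = "none"  # none | stimulus-pe | prediction | prev-outcome-pe
    defaults: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.params)

    @property
    def has_spread(self) -> bool:
        return self.pe_scaling or self.risk_gate != "none"


_GATED = dict(params=("alpha_q", "alpha_s", "beta", "omega", "s0"))

#: Registry of the twelve models, addressable by their field names.
MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        ModelSpec(
            "RW",
            ("alpha", "beta"),
            defaults={"alpha": 0.3, "beta": 0.2},
        ),
        ModelSpec(
            "concave-UTIL",
            ("alpha", "beta", "k_concave"),
            utility_family="concave",
            defaults={"alpha": 0.3, "beta": 0.2, "k_concave": 0.5},
        ),
        ModelSpec(
            "convex-UTIL",
            ("alpha", "beta", "k_convex"),
            utility_family="convex",
            defaults={"alpha": 0.3, "beta": 0.2, "k_convex": -0.5},
        ),
        ModelSpec(
            "s-shaped-UTIL",
            ("alpha", "beta", "k_s_shaped"),
            utility_family="s",
            defaults={"alpha": 0.3, "beta": 0.2, "k_s_shaped": 0.7},
        ),
        ModelSpec(
            "inverse-s-UTIL",
            ("alpha", "beta", "k_inverse_s"),
            utility_family="inverse-s",
            defaults={"alpha": 0.3, "beta": 0.2, "k_inverse_s": 1.4},
        ),
        ModelSpec(
            "pos-neg-RATES",
            ("alpha_pos", "alpha_neg", "beta"),
            rate_rule="valence",
            defaults={"alpha_pos": 0.35, "alpha_neg": 0.25, "beta": 0.2},
        ),
        ModelSpec(
            "variance-RATES",
            ("alpha_risky", "alpha_safe", "beta"),
            rate_rule="variance",
            defaults={"alpha_risky": 0.25, "alpha_safe": 0.35, "beta": 0.2},
        ),
        ModelSpec(
            "attention-RATES",
            ("alpha", "k_attention", "beta"),
            rate_rule="attention",
            defaults={"alpha": 0.3, "k_attention": 0.2, "beta": 0.2},
        ),
        ModelSpec(
            "scaled-PE",
            ("alpha_q", "alpha_s", "beta", "s0"),
            pe_scaling=True,
            defaults={"alpha_q": 0.3, "alpha_s": 0.1, "beta": 0.2, "s0": 10.0},
        ),
        ModelSpec(
            "PEIRS",
            **_GATED,
            risk_gate="stimulus-pe",
            defaults={
                "alpha_q": 0.3,
                "alpha_s": 0.1,
                "beta": 0.2,
                "omega": 0.5,
                "s0": 10.0,
            },
        ),
        ModelSpec(
            "PIRS",
            **_GATED,
            risk_gate="prediction",
            defaults={
                "alpha_q": 0.3,
                "alpha_s": 0.1,
                "beta": 0.2,
                "omega": 0.5,
                "s0": 10.0,
            },
        ),
        ModelSpec(
            "OEIRS",
            **_GATED,
            risk_gate="prev-outcome-pe",
            defaults={
                "alpha_q": 0.3,
                "alpha_s": 0.1,
                "beta": 0.2,
                "omega": 0.5,
                "s0": 10.0,
            },
        ),
    ]
}

MODEL_NAMES: list[str] = list(MODELS)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {MODEL_NAMES}") from None


# ---------------------------------------------------------------------------
# Primitive operations


def softmax_probabilities(activations, beta: float) -> np.ndarray:
    """Softmax over the shown options' activations: p_i ∝ exp(beta * A_i)."""
    a = np.asarray(activations, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite activations: {a}")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    z = beta * (a - a.max())
    e = np.exp(z)
    return e / e.sum()


def outcome_prediction_error(r: float, q_chosen: float) -> float:
    """Reward prediction error at outcome: received minus expected reward."""
    return r - q_chosen


def stimulus_prediction_error(
    q: np.ndarray, pair: tuple[int, int], mode: str = "stimulus-pe"
) -> float:
    """Reward prediction error at stimulus onset.

    In ``stimulus-pe`` mode this is the mean learned value of the shown pair
    minus the mean over all four values (the change in reward expectation
    when the options appear).  In ``prediction`` mode it is the pair mean
    itself (the reward prediction, not its error).
    """
    q = np.asarray(q, dtype=float)
    a, b = pair
    pair_mean = 0.5 * (q[a - 1] + q[b - 1])
    if mode == "stimulus-pe":
        return float(pair_mean - q.mean())
    if mode == "prediction":
        return float(pair_mean)
    raise ValueError(f"unknown stimulus-PE mode {mode!r}")


def utility_transform(
    r: float,
    family: str,
    k: float | None = None,
    sigma: float = UTILITY_SCALE,
    m: float = UTILITY_SHIFT,
) -> float:
    """Subjective utility of a reward of ``r`` points.

    With z = (r - m)/sigma:

    * ``concave``/``convex``: U = m + sigma * (1 - exp(-k z)) / k, with
      k > 0 concave and k < 0 convex;
    * ``s``/``inverse-s``: U = m + sigma * sign(z) |z|^k, with k in [0, 1]
      s-shaped and k > 1 inverse s-shaped;
    * ``identity``: U = r.
    """
    if family == "identity":
        return float(r)
    z = (r - m) / sigma
    if family == "concave":
        if k is None or k <= 0:
            raise ValueError(f"concave utility requires k > 0, got {k}")
        return m + sigma * -np.expm1(-k * z) / k
    if family == "convex":
        if k is None or k >= 0:
            raise ValueError(f"convex utility requires k < 0, got {k}")
        return m + sigma * -np.expm1(-k * z) / k
    if family == "s":
        if k is None or not 0.0 <= k <= 1.0:
            raise ValueError(f"s-shaped utility requires k in [0,1], got {k}")
        return m + sigma * np.sign(z) * abs(z) ** k
    if family == "inverse-s":
        if k is None or k < 1.0:
            raise ValueError(f"inverse-s utility requires k >= 1, got {k}")
        return m + sigma * np.sign(z) * abs(z) ** k
    raise ValueError(f"unknown utility family {family!r}")


def effective_learning_rate(
    model: ModelSpec, params: dict[str, float], delta: float, chosen: int
) -> float:
    """Learning rate applied to this trial's update, per the model's rule."""
    if model.rate_rule == "fixed":
        return params.get("alpha", params.get("alpha_q"))
    if model.rate_rule == "valence":
        # delta == 0 produces a zero update either way; use alpha_pos.
        return params["alpha_pos"] if delta >= 0 else params["alpha_neg"]
    if model.rate_rule == "variance":
        return (
            params["alpha_risky"] if chosen in RISKY_IDS else params["alpha_safe"]
        )
    if model.rate_rule == "attention":
        if delta == 0.0:  # zero surprise -> zero update; avoids 0**k, k < 0
            return 0.0
        return params["alpha"] * abs(delta) ** params["k_attention"]
    raise ValueError(f"unknown rate rule {model.rate_rule!r}")


def scaled_outcome_pe(r: float, q_chosen: float, s_chosen: float) -> float:
    """Outcome prediction error in units of the learned spread."""
    if s_chosen <= 0:
        raise ValueError(f"spread must be positive for scaling, got {s_chosen}")
    return (r - q_chosen) / s_chosen


def value_update(q: np.ndarray, chosen: int, alpha_eff: float, delta: float) -> None:
    """In-place delta-rule update of the chosen stimulus's value."""
    q[chosen - 1] += alpha_eff * delta


def spread_update(
    s: np.ndarray, chosen: int, alpha_s: float, delta: float, scaled: bool = False
) -> None:
    """In-place spread update of the chosen stimulus.

    Plain form tracks the mean absolute prediction error,
    S <- S + alpha_s (|delta| - S); the scaled form drives |delta~| to 1,
    S <- S + alpha_s (|delta~| - 1), floored at a small positive value.
    """
    i = chosen - 1
    if scaled:
        s[i] = max(s[i] + alpha_s * (abs(delta) - 1.0), S_FLOOR)
    else:
        s[i] += alpha_s * (abs(delta) - s[i])


def action_activations(
    q: np.ndarray,
    s: np.ndarray | None,
    pair: tuple[int, int],
    model: ModelSpec,
    params: dict[str, float],
    gate: float,
) -> np.ndarray:
    """Action values of the shown pair: A_i = Q_i + tanh(omega*gate) * S_i.

    For models without a risk gate the activation is just Q_i.
    """
    idx = [pair[0] - 1, pair[1] - 1]
    a = q[idx].astype(float).copy()
    if model.risk_gate != "none":
        a += np.tanh(params["omega"] * gate) * s[idx]
    return a


def _gate_signal(
    model: ModelSpec, q: np.ndarray, pair: tuple[int, int], prev_pe: float
) -> float:
    if model.risk_gate == "stimulus-pe":
        return stimulus_prediction_error(q, pair, "stimulus-pe")
    if model.risk_gate == "prediction":
        return stimulus_prediction_error(q, pair, "prediction")
    if model.risk_gate == "prev-outcome-pe":
        return prev_pe
    return 0.0


def _check_params(model: ModelSpec, params: dict[str, float]) -> dict[str, float]:
    missing = [p for p in model.params if p not in params]
    if missing:
        raise ValueError(f"model {model.name} missing parameters {missing}")
    return {p: float(params[p]) for p in model.params}


# ---------------------------------------------------------------------------
# Trial loop (readable reference implementation; a compiled kernel with the
# same recursion backs the fitting hot path, see _kernels.py)


def _trial_step(model, params, q, s, pair, choice, reward, prev_pe):
    """Shared per-trial recursion; mutates q and s, returns trace scalars."""
    gate = _gate_signal(model, q, pair, prev_pe)
    acts = action_activations(q, s, pair, model, params, gate)
    probs = softmax_probabilities(acts, params["beta"])
    k_util = next(
        (params[p] for p in params if p.startswith("k_") and p != "k_attention"),
        None,
    )
    u = utility_transform(reward, model.utility_family, k_util)
    delta = outcome_prediction_error(u, q[choice - 1])
    if model.pe_scaling:
        delta_scaled = scaled_outcome_pe(u, q[choice - 1], s[choice - 1])
        value_update(q, choice, params["alpha_q"], delta_scaled)
        spread_update(s, choice, params["alpha_s"], delta_scaled, scaled=True)
    else:
        alpha_eff = effective_learning_rate(model, params, delta, choice)
        delta_scaled = np.nan
        value_update(q, choice, alpha_eff, delta)
        if model.risk_gate != "none":
            spread_update(s, choice, params["alpha_s"], delta)
    return gate, probs, delta, delta_scaled


def simulate_session(
    model: ModelSpec | str,
    params: dict[str, float],
    schedule: pd.DataFrame | None = None,
    seed: int | None = None,
    participant_id: str = "sim",
) -> tuple[SessionData, pd.DataFrame]:
    """Simulate one participant: sample choices and rewards trial by trial.

    Returns the session (choices/rewards in the standard trial table) and a
    latent trace with pre-choice Q and S, the gating signal, choice
    probabilities and prediction errors for every trial.
    """
    model = get_model(model) if isinstance(model, str) else model
    params = _check_params(model, params)
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = build_schedule(seed=rng.integers(2**31))

    q = np.full(4, Q0)
    s = np.full(4, params.get("s0", 0.0))
    prev_pe = 0.0
    current_block = None
    rows, trace = [], []
    for t in schedule.itertuples(index=False):
        if t.block != current_block:  # new stimulus set: reset latent state
            current_block = t.block
            q[:] = Q0
            s[:] = params.get("s0", 0.0)
            prev_pe = 0.0
        pair = (t.stim_left, t.stim_right)
        q_pre, s_pre = q.copy(), s.copy()
        # choice is sampled from the softmax before the outcome is revealed
        gate = _gate_signal(model, q, pair, prev_pe)
        acts = action_activations(q, s, pair, model, params, gate)
        probs = softmax_probabilities(acts, params["beta"])
        choice = pair[0] if rng.random() < probs[0] else pair[1]
        reward = sample_reward(STIMULI[choice], rng)
        _, probs, delta, delta_scaled = _trial_step(
            model, params, q, s, pair, choice, reward, prev_pe
        )
        prev_pe = delta
        p_choice = probs[0] if choice == pair[0] else probs[1]
        rows.append(
            (t.block, t.trial, pair[0], pair[1], t.condition, choice, reward)
        )
        trace.append(
            [t.block, t.trial, pair[0], pair[1], choice, reward]
            + list(q_pre)
            + list(s_pre)
            + [gate, probs[0], p_choice, delta, delta_scaled]
        )
    trials = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    trace_df = pd.DataFrame(trace, columns=TRACE_COLUMNS)
    session = SessionData(participant_id=participant_id, trials=trials, rng_seed=seed)
    return session, trace_df


def replay_session(
    model: ModelSpec | str, params: dict[str, float], session: SessionData
) -> pd.DataFrame:
    """Replay the latent recursion against recorded choices and rewards.

    Returns the same latent trace as :func:`simulate_session`; the total
    log-likelihood is ``np.log(trace["p_choice"]).sum()``.
    """
    model = get_model(model) if isinstance(model, str) else model
    params = _check_params(model, params)
    q = np.full(4, Q0)
    s = np.full(4, params.get("s0", 0.0))
    prev_pe = 0.0
    current_block = None
    trace = []
    for t in session.trials.itertuples(index=False):
        if t.block != current_block:
            current_block = t.block
            q[:] = Q0
            s[:] = params.get("s0", 0.0)
            prev_pe = 0.0
        pair = (t.stim_left, t.stim_right)
        if t.choice not in pair:
            raise ValueError(
                f"recorded choice {t.choice} not in shown pair {pair}"
            )
        q_pre, s_pre = q.copy(), s.copy()
        gate, probs, delta, delta_scaled = _trial_step(
            model, params, q, s, pair, int(t.choice), float(t.reward), prev_pe
        )
        prev_pe = delta
        p_choice = probs[0] if t.choice == pair[0] else probs[1]
        trace.append(
            [t.block, t.trial, pair[0], pair[1], t.choice, t.reward]
            + list(q_pre)
            + list(s_pre)
            + [gate, probs[0], p_choice, delta, delta_scaled]
        )
    return pd.DataFrame(trace, columns=TRACE_COLUMNS)


def session_log_likelihood(
    model: ModelSpec | str, params: dict[str, float], session: SessionData
) -> float:
    """Total log-likelihood of the recorded choices under the model.

    Uses the compiled replay kernel; identical (to floating-point accuracy)
    to summing log p_choice over :func:`replay_session`.
    """
    model = get_model(model) if isinstance(model, str) else model
    params = _check_params(model, params)
    arrays = _kernels.session_arrays(session)
    return float(_kernels.replay_loglik(*arrays, *_kernels.kernel_args(model, params)))
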