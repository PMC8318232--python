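"""Compiled likelihood kernel.

Model fitting evaluates the session log-likelihood thousands of times per
optimisation, so the trial recursion is duplicated here as a flat numeric
loop and JIT-compiled with numba.  The readable reference implementation
lives in :mod:`riskbandit.models`; the two are held identical by tests.

Flag encoding (must match ``kernel_args``):

* utility family: 0 identity, 1 exponential (sign of k gives concave vs
  convex), 2 sign-preserving power (k < 1 s-shaped, k > 1 inverse-s)
* rate rule: 0 fixed, 1 valence, 2 variance (risky/safe), 3 attention
* risk gate: 0 none, 1 stimulus PE, 2 pair-mean prediction, 3 previous
  trial's outcome PE
"""

from __future__ import annotations

import math

import numpy as np

try:  # numba is an optional accelerator; the kernel also runs as plain Python
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

Q0 = 50.0
S_FLOOR = 1e-3
_LOG_FLOOR = 1e-300

_FAMILY_CODE = {"identity": 0, "concave": 1, "convex": 1, "s": 2, "inverse-s": 2}
_RATE_CODE = {"fixed": 0, "valence": 1, "variance": 2, "attention": 3}
_GATE_CODE = {"none": 0, "stimulus-pe": 1, "prediction": 2, "prev-outcome-pe": 3}


def session_arrays(session):
    """Pack a session's trials into flat arrays for the kernel."""
    t = session.trials
    block = t["block"].to_numpy(np.int64)
    block_start = np.empty(len(block), dtype=np.bool_)
    block_start[0] = True
    block_start[1:] = block[1:] != block[:-1]
    return (
        t["stim_left"].to_numpy(np.int64) - 1,
        t["stim_right"].to_numpy(np.int64) - 1,
        t["choice"].to_numpy(np.int64) - 1,
        t["reward"].to_numpy(np.float64),
        block_start,
    )


def kernel_args(model, params):
    """Map a model spec + natural-space parameter dict to kernel scalars."""
    alpha1 = params.get("alpha", params.get("alpha_q", params.get("alpha_pos")))
    if alpha1 is None:
        alpha1 = params.get("alpha_risky", 0.0)
    alpha2 = params.get("alpha_neg", params.get("alpha_safe", 0.0))
    k_shape = 0.0
    for name in ("k_concave", "k_convex", "k_s_shaped", "k_inverse_s", "k_attention"):
        if name in params:
            k_shape = params[name]
    return (
        _FAMILY_CODE[model.utility_family],
        _RATE_CODE[model.rate_rule],
        1 if model.pe_scaling else 0,
        _GATE_CODE[model.risk_gate],
        float(alpha1),
        float(alpha2),
        float(params.get("alpha_s", 0.0)),
        float(params["beta"]),
        float(params.get("omega", 0.0)),
        float(k_shape),
        float(params.get("s0", 0.0)),
    )


@njit(cache=True)
def replay_loglik(
    left,
    right,
    choice,
    reward,
    block_start,
    family,
    rate_rule,
    pe_scaling,
    gate_rule,
    alpha1,
    alpha2,
    alpha_s,
    beta,
    omega,
    k_shape,
    s0,
):
    q = np.empty(4)
    s = np.empty(4)
    prev_pe = 0.0
    loglik = 0.0
    for t in range(left.shape[0]):
        if block_start[t]:
            for i in range(4):
                q[i] = Q0
                s[i] = s0
            prev_pe = 0.0
        a = left[t]
        b = right[t]
        c = choice[t]

        # gating signal and activations
        if gate_rule == 1:
            gate = 0.5 * (q[a] + q[b]) - 0.25 * (q[0] + q[1] + q[2] + q[3])
        elif gate_rule == 2:
            gate = 0.5 * (q[a] + q[b])
        elif gate_rule == 3:
            gate = prev_pe
        else:
            gate = 0.0
        if gate_rule != 0:
            w = math.tanh(omega * gate)
            act_a = q[a] + w * s[a]
            act_b = q[b] + w * s[b]
        else:
            act_a = q[a]
            act_b = q[b]

        # softmax probability of the recorded choice (max-subtracted)
        m = act_a if act_a > act_b else act_b
        ea = math.exp(beta * (act_a - m))
        eb = math.exp(beta * (act_b - m))
        p = (ea if c == a else eb) / (ea + eb)
        if p < _LOG_FLOOR:
            p = _LOG_FLOOR
        loglik += math.log(p)

        # utility of the outcome
        r = reward[t]
        if family == 1:
            z = (r - 50.0) / 50.0
            u = 50.0 - 50.0 * math.expm1(-k_shape * z) / k_shape
        elif family == 2:
            z = (r - 50.0) / 50.0
            if z >= 0.0:
                u = 50.0 + 50.0 * z**k_shape
            else:
                u = 50.0 - 50.0 * (-z) ** k_shape
        else:
            u = r

        delta = u - q[c]
        prev_pe = delta
        if pe_scaling == 1:
            d_scaled = delta / s[c]
            q[c] += alpha1 * d_scaled
            s_new = s[c] + alpha_s * (abs(d_scaled) - 1.0)
            s[c] = s_new if s_new > S_FLOOR else S_FLOOR
        else:
            if rate_rule == 1:
                a_eff = alpha1 if delta >= 0.0 else alpha2
            elif rate_rule == 2:
                a_eff = alpha1 if (c == 0 or c == 2) else alpha2
            elif rate_rule == 3:
                # zero surprise yields a zero update; avoids 0**k for k < 0
                a_eff = 0.0 if delta == 0.0 else alpha1 * abs(delta) ** k_shape
            else:
                a_eff = alpha1
            q[c] += a_eff * delta
            if gate_rule != 0:
                s[c] += alpha_s * (abs(delta) - s[c])
    return loglik
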