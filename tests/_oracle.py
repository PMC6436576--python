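"""Brute-force reference for the belief-state model on tiny tasks.

Everything here is computed by direct recursion over future draw
continuations with plain Python floats and ``math`` — no arrays, no
backward-induction table — so it can serve as an independent oracle for the
dynamic-programming solver on a small draw cap.
"""

import math

_IDX = {"DG": 0, "DB": 1, "S": 2}


def posterior_gold(n_d, n_g, q):
    like_g = math.comb(n_d, n_g) * q**n_g * (1 - q) ** (n_d - n_g)
    like_b = math.comb(n_d, n_g) * (1 - q) ** n_g * q ** (n_d - n_g)
    return like_g / (like_g + like_b)


def q_values(n_d, n_g, cap, q, reward, cs, T, mode):
    """Action values (DG, DB, S or None) by explicit recursion."""
    p = posterior_gold(n_d, n_g, q)
    q_dg = reward * p - reward * (1 - p)
    q_db = -q_dg
    if n_d == cap:
        return [q_dg, q_db, None]
    p_up = p * q + (1 - p) * (1 - q)  # predictive probability of a gold fish
    v_up = state_value(n_d + 1, n_g + 1, cap, q, reward, cs, T, mode)
    v_dn = state_value(n_d + 1, n_g, cap, q, reward, cs, T, mode)
    return [q_dg, q_db, -cs + p_up * v_up + (1 - p_up) * v_dn]


def choice_probs(qv, T):
    avail = [x for x in qv if x is not None]
    m = max(avail)
    w = [math.exp((x - m) / T) if x is not None else 0.0 for x in qv]
    s = sum(w)
    return [x / s for x in w]


def state_value(n_d, n_g, cap, q, reward, cs, T, mode):
    qv = q_values(n_d, n_g, cap, q, reward, cs, T, mode)
    if mode == "max":
        return max(x for x in qv if x is not None)
    p = choice_probs(qv, T)
    return sum(pi * x for pi, x in zip(p, qv) if x is not None)


def trial_logprob(colors, actions, cap, q, reward, cs, T):
    """Log probability of an action sequence, step probabilities enumerated
    directly from the recursion (softmax value backup)."""
    n_g = 0
    total = 0.0
    for step, (color, action) in enumerate(zip(colors, actions), start=1):
        n_g += color == "g"
        qv = q_values(step, n_g, cap, q, reward, cs, T, "softmax")
        total += math.log(choice_probs(qv, T)[_IDX[action]])
    return total
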