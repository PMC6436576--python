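"""Belief-state decision model of the sampling task.

The observable state after ``n_d`` draws of which ``n_g`` were gold is the
sufficient statistic ``s = (n_d, n_g)``; the belief over lakes is its
Bernoulli posterior under equiprobable priors.  Three actions are available:
declare the gold lake, declare the black lake, or pay the sampling cost and
see another fish (not available at the draw cap, where a binary declaration
is forced).

Action values follow the standard optimal-stopping recursion: declaring is
worth the expected payoff under the current posterior,

    Q(D_G; s) = R_C * P(G|s) - C_W * P(B|s),

and sampling is worth the predictive expectation of the next state's value
minus the cost of the next draw,

    Q(D_S; s) = -C_S + sum_{L} P(L|s) sum_{s'} V(s') P(s'|L).

Value tables are filled by backward induction from the cap.  The state value
is either the maximum action value (an ideal, deterministically maximising
agent) or the softmax-choice expectation ``V(s) = sum_a q_a p(a|q)`` with
``p(a|q) ∝ exp(q_a / T)`` (a noisy agent with decision temperature ``T``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import ACTIONS, BlockSpec, FishSequence, TaskConfig, TrialRecord

__all__ = [
    "SubjectParams",
    "ValueTable",
    "PolicyStats",
    "posterior_gold",
    "declare_values",
    "action_probabilities",
    "solve_value_table",
    "declare_threshold",
    "policy_outcome_exact",
    "ideal_policy_stats",
    "simulate_agent",
]

_A_DG, _A_DB, _A_S = 0, 1, 2  # action-axis layout of q-value triples


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject behavioural parameters.

    ``cs`` is the subjective cost, in points, of each additional fish (taken
    constant within a block; high values produce early declarations) and
    ``temperature`` the softmax decision noise (high values drive choices
    toward uniform).
    """

    cs: float
    temperature: float

    def __post_init__(self) -> None:
        if self.cs < 0:
            raise ValueError("cs must be non-negative")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


def posterior_gold(n_d, n_g, majority_prob: float = 0.6):
    """Posterior probability of the mainly-gold lake after ``n_g`` gold fish
    in ``n_d`` draws, under equiprobable lake priors.

    Reduces to ``1 / (1 + r**(n_d - 2*n_g))`` with odds ``r = q/(1-q)``:
    only the colour difference matters.  Accepts scalars or arrays.
    """
    n_d = np.asarray(n_d)
    n_g = np.asarray(n_g)
    if np.any(n_g < 0) or np.any(n_g > n_d):
        raise ValueError("need 0 <= n_g <= n_d")
    r = majority_prob / (1.0 - majority_prob)
    out = 1.0 / (1.0 + r ** (n_d - 2.0 * n_g))
    return float(out) if out.ndim == 0 else out


def declare_values(n_d, n_g, block: BlockSpec, config: TaskConfig):
    """Action values of declaring gold resp. black at state ``(n_d, n_g)``."""
    p = posterior_gold(n_d, n_g, config.majority_prob)
    q_dg = block.reward_correct * p - block.cost_wrong * (1.0 - p)
    q_db = block.reward_correct * (1.0 - p) - block.cost_wrong * p
    return q_dg, q_db


def action_probabilities(q, temperature: float):
    """Softmax choice probabilities ``p(a) ∝ exp(q_a / T)``.

    ``q`` is a triple (declare-gold, declare-black, sample); a NaN entry
    marks an unavailable action (sampling at the draw cap) and receives
    probability zero, so the forced final choice is a binary softmax.
    Normalisation is max-shifted to avoid overflow.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    q = np.asarray(q, dtype=float)
    avail = ~np.isnan(q)
    if not avail.any():
        raise ValueError("no available action")
    if not np.all(np.isfinite(q[avail])):
        raise ValueError("action values must be finite")
    z = np.full_like(q, -np.inf)
    z[avail] = (q[avail] - q[avail].max()) / temperature
    w = np.exp(z)
    return w / w.sum()


@dataclass
class ValueTable:
    """Backed-up action and state values over all reachable states of a block.

    ``Q[n_d, n_g]`` holds ``(Q_DG, Q_DB, Q_DS)`` and ``V[n_d, n_g]`` the
    state value, for ``1 <= n_d <= draw_cap`` and ``0 <= n_g <= n_d``
    (invalid states are NaN, as is ``Q_DS`` at the cap where sampling is not
    an option).  ``mode`` records how ``V`` was backed up: ``"max"`` for the
    deterministic maximiser, ``"softmax"`` for the noisy agent.
    """

    majority_prob: float
    draw_cap: int
    mode: str
    temperature: float | None
    Q: np.ndarray
    V: np.ndarray

    def q_values(self, n_d: int, n_g: int) -> np.ndarray:
        if not (1 <= n_d <= self.draw_cap and 0 <= n_g <= n_d):
            raise ValueError(f"state ({n_d}, {n_g}) outside the table")
        return self.Q[n_d, n_g]

    def greedy_action(self, n_d: int, n_g: int) -> str:
        """Deterministic-max policy with ties broken in favour of sampling.

        Preferring to sample on exact ties reproduces the zero-cost ideal
        agent, which keeps sampling to the cap even though declaring early
        would have equal value.  A declare/declare tie falls to ``DG`` (its
        accuracy contribution is scored by the 0.5 posterior, so the label
        choice is immaterial).
        """
        q = self.q_values(n_d, n_g)
        best_declare = max(q[_A_DG], q[_A_DB])
        # Zero-cost sample/declare ties are exact in real arithmetic but the
        # backup perturbs them by ~1 ulp, so compare with a small tolerance.
        tol = 1e-9 * max(1.0, abs(best_declare))
        if not np.isnan(q[_A_S]) and q[_A_S] >= best_declare - tol:
            return "S"
        return "DG" if q[_A_DG] >= q[_A_DB] else "DB"

    def action_probs(self, n_d: int, n_g: int, temperature: float | None = None) -> np.ndarray:
        """Softmax probabilities over (DG, DB, S) at a state."""
        T = temperature if temperature is not None else self.temperature
        if T is None:
            raise ValueError("a temperature is required for action probabilities")
        return action_probabilities(self.q_values(n_d, n_g), T)


def solve_value_table(
    block: BlockSpec,
    config: TaskConfig,
    mode: str = "max",
    temperature: float | None = None,
    subjective_cost: float | None = None,
) -> ValueTable:
    """Solve the value table of one block by backward induction.

    The cost of sampling at state ``n_d`` is the cost of the ``n_d+1``-th
    draw under the block's objective schedule, or the constant
    ``subjective_cost`` when fitting a subject's perceived cost.  ``mode`` is
    ``"max"`` (Bellman backup, ideal agent) or ``"softmax"`` (expected value
    under softmax choice with ``temperature``, the generative model of real
    agents).
    """
    if mode not in ("max", "softmax"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "softmax" and not (temperature is not None and temperature > 0):
        raise ValueError("softmax mode requires temperature > 0")
    cap, q = config.draw_cap, config.majority_prob
    Q = np.full((cap + 1, cap + 1, 3), np.nan)
    V = np.full((cap + 1, cap + 1), np.nan)
    for n_d in range(cap, 0, -1):
        ng = np.arange(n_d + 1)
        p = posterior_gold(n_d, ng, q)
        qv = np.full((n_d + 1, 3), np.nan)
        qv[:, _A_DG] = block.reward_correct * p - block.cost_wrong * (1.0 - p)
        qv[:, _A_DB] = block.reward_correct * (1.0 - p) - block.cost_wrong * p
        if n_d < cap:
            cost = subjective_cost if subjective_cost is not None else block.cost_of_draw(n_d + 1)
            p_next_g = p * q + (1.0 - p) * (1.0 - q)  # predictive colour mixture
            qv[:, _A_S] = -cost + p_next_g * V[n_d + 1, ng + 1] + (1.0 - p_next_g) * V[n_d + 1, ng]
        if mode == "max":
            V[n_d, : n_d + 1] = np.nanmax(qv, axis=1)
        else:
            lp = np.where(np.isnan(qv), -np.inf, qv)
            lp = (lp - np.nanmax(qv, axis=1, keepdims=True)) / temperature
            w = np.exp(lp)
            w /= w.sum(axis=1, keepdims=True)
            V[n_d, : n_d + 1] = np.sum(np.where(w > 0, w * np.nan_to_num(qv), 0.0), axis=1)
        Q[n_d, : n_d + 1] = qv
    return ValueTable(q, cap, mode, temperature, Q, V)


def declare_threshold(table: ValueTable, cap_margin: int = 2) -> int | None:
    """Smallest absolute colour difference at which declaring is strictly
    better than sampling in *every* state with that difference, ignoring
    states within ``cap_margin`` draws of the cap (where the shrinking
    horizon deflates the value of sampling).  ``None`` if no such difference
    exists.
    """
    cap = table.draw_cap
    for diff in range(0, cap + 1):
        found = False
        ok = True
        for n_d in range(1, cap - cap_margin + 1):
            if (n_d - diff) % 2 or diff > n_d:
                continue
            for n_g in {(n_d + diff) // 2, (n_d - diff) // 2}:
                q = table.Q[n_d, n_g]
                found = True
                if not max(q[_A_DG], q[_A_DB]) > q[_A_S]:
                    ok = False
        if found and ok:
            return diff
    return None


@dataclass(frozen=True)
class PolicyStats:
    """Realised (or exact) behaviour of a policy in one block."""

    block_id: int
    mean_dtd: float
    mean_accuracy: float  # posterior of the declared lake at declaration
    frac_correct: float
    total_points: float


def _declaration(table: ValueTable, n_d: int, n_g: int) -> tuple[str, float, float]:
    """Declared lake, posterior accuracy, and correctness weight vs lake G.

    A declare/declare tie (possible only at posterior 0.5) is scored as the
    0.5 posterior rather than a coin flip.
    """
    q = table.Q[n_d, n_g]
    p = posterior_gold(n_d, n_g, table.majority_prob)
    if np.isclose(q[_A_DG], q[_A_DB]):
        return "G", 0.5, 0.5
    if q[_A_DG] > q[_A_DB]:
        return "G", p, 1.0
    return "B", 1.0 - p, 0.0


def policy_outcome_exact(table: ValueTable, config: TaskConfig) -> dict:
    """Exact outcome statistics of the greedy policy over i.i.d. sequences.

    Propagates the state distribution forward conditional on the true lake
    being gold (the black-lake case is symmetric) and absorbs probability
    mass wherever the deterministic-max policy declares.  Returns the
    probability the declared lake is correct, the expected posterior of the
    declared lake, and the expected draws to decision.
    """
    q = config.majority_prob
    cap = config.draw_cap
    mass = np.zeros(cap + 2)
    mass[1] = q  # first fish gold
    mass[0] = 1.0 - q
    p_correct = exp_post = exp_dtd = 0.0
    for n_d in range(1, cap + 1):
        nxt = np.zeros(cap + 2)
        for n_g in range(n_d + 1):
            m = mass[n_g]
            if m == 0.0:
                continue
            if n_d < cap and table.greedy_action(n_d, n_g) == "S":
                # next colour is gold w.p. q, conditional on the true lake being G
                nxt[n_g + 1] += m * q
                nxt[n_g] += m * (1.0 - q)
            else:
                declared, post, corr = _declaration(table, n_d, n_g)
                p_correct += m * corr
                exp_post += m * post
                exp_dtd += m * n_d
        mass = nxt
    return {"p_correct": p_correct, "mean_accuracy": exp_post, "mean_dtd": exp_dtd}


def _run_greedy(table: ValueTable, seq: FishSequence) -> tuple[int, str, float, float]:
    """Run the deterministic policy on one sequence.

    Returns (dtd, declared lake, posterior accuracy, correctness in {0, 0.5, 1}).
    """
    n_g = 0
    for n_d, color in enumerate(seq.colors, start=1):
        n_g += color == "g"
        if n_d == table.draw_cap or table.greedy_action(n_d, n_g) != "S":
            declared, post, _ = _declaration(table, n_d, n_g)
            if post == 0.5:
                corr = 0.5
            else:
                corr = 1.0 if declared == seq.true_lake else 0.0
            return n_d, declared, post, corr
    raise ValueError("sequence shorter than the policy demands")


def ideal_policy_stats(
    blocks: list[BlockSpec],
    sequences: list[FishSequence],
    config: TaskConfig,
) -> list[PolicyStats]:
    """Behaviour of the ideal (deterministic-max) agent per block.

    The same sequences are played in every block, as in the task.  Accuracy
    is reported as the mean posterior of the declared lake (the headline
    metric) alongside the fraction of correct declarations; points use each
    block's payoff including its sampling charges.
    """
    out = []
    for block in blocks:
        table = solve_value_table(block, config, mode="max")
        dtds, posts, corrs, points = [], [], [], []
        for seq in sequences:
            dtd, declared, post, corr = _run_greedy(table, seq)
            dtds.append(dtd)
            posts.append(post)
            corrs.append(corr)
            win = block.reward_correct if corr == 1.0 else -block.cost_wrong
            if corr == 0.5:
                win = 0.5 * block.reward_correct - 0.5 * block.cost_wrong
            sampling = sum(block.cost_of_draw(k) for k in range(2, dtd + 1))
            points.append(win - sampling)
        out.append(
            PolicyStats(
                block_id=block.block_id,
                mean_dtd=float(np.mean(dtds)),
                mean_accuracy=float(np.mean(posts)),
                frac_correct=float(np.mean(corrs)),
                total_points=float(np.sum(points)),
            )
        )
    return out


def simulate_agent(
    params: SubjectParams,
    blocks: list[BlockSpec],
    sequences,
    config: TaskConfig,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "agent",
    group: str = "sim",
) -> list[TrialRecord]:
    """Simulate a noisy subject over all blocks and sequences.

    The subject's value table is solved in softmax mode with their constant
    subjective cost ``params.cs`` in place of the objective schedule and
    their temperature in the backup; each step then samples an action from
    the softmax probabilities (binary at the draw cap).  ``sequences`` is a
    mapping ``block_id -> list[FishSequence]`` or a single list shared by all
    blocks.  Fully reproducible under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables: dict[tuple[float, float], ValueTable] = {}
    records = []
    for block in blocks:
        key = (block.reward_correct, block.cost_wrong)
        if key not in tables:
            tables[key] = solve_value_table(
                block, config, mode="softmax",
                temperature=params.temperature, subjective_cost=params.cs,
            )
        table = tables[key]
        seqs = sequences[block.block_id] if isinstance(sequences, dict) else sequences
        for t_idx, seq in enumerate(seqs, start=1):
            n_g = 0
            actions = []
            for n_d, color in enumerate(seq.colors, start=1):
                n_g += color == "g"
                p = table.action_probs(n_d, n_g)
                a = ("DG", "DB", "S")[rng.choice(3, p=p)]
                actions.append(a)
                if a != "S":
                    break
            records.append(
                TrialRecord(
                    subject_id=subject_id,
                    group=group,
                    block_id=block.block_id,
                    trial=t_idx,
                    colors=seq.colors[: len(actions)],
                    actions=tuple(actions),
                    true_lake=seq.true_lake,
                )
            )
    return records
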