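"""Hierarchical estimation of cost and temperature distributions.

The likelihood of a subject's trial is the product over decision steps of
the softmax probabilities of the recorded actions, computed from a value
table solved with the subject's constant subjective sampling cost CS in
place of the objective schedule.  Because every fitted block carries the
same nominal ±100 payoff and the subjective cost is constant, a single
table per (CS, T) serves all fitted blocks.  Block 4's escalating schedule
is outside the model's assumptions and is excluded from fitting by default.

Group-level inference follows the empirical-Bayes random-effects scheme
standard in behavioural model fitting:

* **E step** — per-subject posterior weights over a dense 2-D grid of
  (CS, T) nodes: data likelihood times the current gamma priors, quadrature
  weighted and normalised.
* **M step** — weighted maximum-likelihood refit of independent gamma
  distributions for CS and T across subjects (Newton's method on the shape
  via the digamma equation, moment matching as fallback), reported as mean
  and variance.

Iteration continues to ``n_iter`` (default 30, with early stopping when the
relative change of the marginal log likelihood falls below ``tol``).  Model
comparison between a single combined parameter population and separate
per-group populations uses the integrated BIC: minus twice the summed log
integrated (prior-weighted mean, not maximum) likelihoods plus ``k ln N``
with ``k`` the number of group-level parameters (4 combined, 8 separate)
and ``N`` the total number of recorded decision steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp, polygamma

from .pomdp import SubjectParams, posterior_gold  # noqa: F401  (re-exported surface)
from .synth import GammaMoments
from .task import Dataset, TaskConfig, TrialRecord

__all__ = [
    "SubjectParams",
    "ParamGrid",
    "GroupPrior",
    "FitResult",
    "IBICReport",
    "trial_loglik",
    "em_fit",
    "ibic",
    "individual_estimates",
]

_A_INDEX = {"DG": 0, "DB": 1, "S": 2}


@dataclass(frozen=True)
class GroupPrior:
    """Fitted gamma population distributions of one group."""

    cs: GammaMoments
    temperature: GammaMoments


@dataclass
class ParamGrid:
    """Log-spaced quadrature grid over (CS, T).

    The E step and the integrated likelihoods are computed by midpoint
    quadrature on this grid; ``cs_weights``/``t_weights`` are the linear
    cell widths.  Solved log step-probability tables are cached per
    (draw_cap, majority_prob, reward) so repeated fits reuse them.
    """

    cs_nodes: np.ndarray
    t_nodes: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.cs_nodes = np.asarray(self.cs_nodes, dtype=float)
        self.t_nodes = np.asarray(self.t_nodes, dtype=float)
        for name, nodes in (("cs", self.cs_nodes), ("t", self.t_nodes)):
            if nodes.ndim != 1 or len(nodes) < 2 or np.any(np.diff(nodes) <= 0):
                raise ValueError(f"{name} nodes must be strictly increasing, length >= 2")
        if self.cs_nodes[0] < 0 or self.t_nodes[0] <= 0:
            raise ValueError("CS nodes must be >= 0 and T nodes > 0")

    @classmethod
    def default(
        cls,
        n_cs: int = 50,
        n_t: int = 50,
        cs_bounds: tuple[float, float] = (1e-4, 100.0),
        t_bounds: tuple[float, float] = (0.05, 50.0),
    ) -> "ParamGrid":
        return cls(
            np.geomspace(cs_bounds[0], cs_bounds[1], n_cs),
            np.geomspace(t_bounds[0], t_bounds[1], n_t),
        )

    @staticmethod
    def _cell_widths(nodes: np.ndarray) -> np.ndarray:
        edges = np.concatenate([[nodes[0]], np.sqrt(nodes[1:] * nodes[:-1]), [nodes[-1]]])
        return np.diff(edges)

    @property
    def cs_weights(self) -> np.ndarray:
        return self._cell_widths(self.cs_nodes)

    @property
    def t_weights(self) -> np.ndarray:
        return self._cell_widths(self.t_nodes)

    @property
    def log_quad_weights(self) -> np.ndarray:
        """log(w_cs * w_t), shape (n_cs, n_t)."""
        return np.log(self.cs_weights)[:, None] + np.log(self.t_weights)[None, :]

    def log_step_probs(self, config: TaskConfig, reward: float = 100.0) -> np.ndarray:
        """Log softmax action probabilities at every grid node and state.

        Shape ``(n_cs, n_t, cap+1, cap+1, 3)`` indexed by ``[ci, ti, n_d,
        n_g, action]`` with actions ordered (DG, DB, S); unavailable actions
        are ``-inf``.  Solved once per task geometry by a vectorised
        backward induction with the softmax state-value backup.
        """
        key = (config.draw_cap, config.majority_prob, float(reward))
        if key not in self._cache:
            self._cache[key] = _grid_log_policy(self.cs_nodes, self.t_nodes, config, reward)
        return self._cache[key]

    def coverage(self, prior: GroupPrior) -> float:
        """Fraction of a prior's probability mass inside the grid bounds."""
        from scipy import stats

        cov = 1.0
        for moments, nodes in ((prior.cs, self.cs_nodes), (prior.temperature, self.t_nodes)):
            d = stats.gamma(moments.shape, scale=moments.scale)
            cov = min(cov, d.cdf(nodes[-1]) - d.cdf(nodes[0]))
        return float(cov)


def _grid_log_policy(cs_nodes, t_nodes, config: TaskConfig, reward: float) -> np.ndarray:
    """Vectorised softmax-mode backward induction over a (CS, T) grid."""
    q = config.majority_prob
    cap = config.draw_cap
    ncs, nt = len(cs_nodes), len(t_nodes)
    CS = cs_nodes[:, None, None]
    T = t_nodes[None, :, None, None]
    logp = np.full((ncs, nt, cap + 1, cap + 1, 3), -np.inf)
    V_next = np.zeros((ncs, nt, cap + 2))
    for n_d in range(cap, 0, -1):
        ng = np.arange(n_d + 1)
        p = posterior_gold(n_d, ng, q)
        qv = np.empty((ncs, nt, n_d + 1, 3))
        qv[..., 0] = reward * (2.0 * p - 1.0)
        qv[..., 1] = -qv[..., 0]
        if n_d == cap:
            qv[..., 2] = -np.inf
        else:
            p_next_g = p * q + (1.0 - p) * (1.0 - q)
            qv[..., 2] = -CS + p_next_g * V_next[:, :, ng + 1] + (1.0 - p_next_g) * V_next[:, :, ng]
        m = np.max(qv, axis=-1, keepdims=True)
        z = (qv - m) / T
        lse = logsumexp(z, axis=-1, keepdims=True)
        lp = z - lse
        w = np.exp(lp)
        V = np.sum(np.where(w > 0.0, w * np.where(np.isfinite(qv), qv, 0.0), 0.0), axis=-1)
        logp[:, :, n_d, ng, :] = lp
        V_next.fill(0.0)
        V_next[:, :, : n_d + 1] = V
    return logp


def _record_steps(record: TrialRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_d, n_g, action-index) arrays for every decision step of a trial."""
    n_g = np.cumsum([c == "g" for c in record.colors])
    n_d = np.arange(1, record.dtd + 1)
    acts = np.array([_A_INDEX[a] for a in record.actions])
    return n_d, n_g, acts


def trial_loglik(
    record: TrialRecord,
    params: SubjectParams,
    block,
    config: TaskConfig,
    reward: float | None = None,
) -> float:
    """Log probability of one trial's action sequence under (CS, T).

    Sums ``ln p(action | q(s), T)`` over steps with the subject's CS in the
    sampling backup; the forced declaration at the draw cap is a binary
    softmax.  ``reward`` defaults to the block's reward (its magnitude sets
    the scale on which CS and T are interpretable).
    """
    from .pomdp import solve_value_table
    from .task import BlockSpec

    if reward is not None:
        block = BlockSpec(block.block_id, reward, reward, block.cost_schedule)
    table = solve_value_table(
        block, config, mode="softmax",
        temperature=params.temperature, subjective_cost=params.cs,
    )
    total = 0.0
    n_d, n_g, acts = _record_steps(record)
    for d, g, a in zip(n_d, n_g, acts):
        p = table.action_probs(int(d), int(g))
        if p[a] <= 0.0:
            return -np.inf
        total += float(np.log(p[a]))
    return total


def _subject_logliks(dataset: Dataset, grid: ParamGrid, config: TaskConfig,
                     blocks=(1, 2, 3), reward: float = 100.0):
    """Per-subject log likelihood over all grid nodes.

    Returns (subject ids, group labels, logL array of shape (n, ncs, nt),
    decision-step counts per subject).  Step observations are aggregated to
    (state, action) counts first, so the cost is one gather per distinct
    state-action pair.
    """
    logp = grid.log_step_probs(config, reward)
    data = dataset.filter_blocks(blocks)
    if not len(data):
        raise ValueError(f"no trials in blocks {tuple(blocks)}")
    ids: list[str] = []
    groups: dict[str, str] = {}
    counts: dict[str, dict[tuple[int, int, int], int]] = {}
    for rec in data:
        if rec.subject_id not in counts:
            ids.append(rec.subject_id)
            counts[rec.subject_id] = {}
            groups[rec.subject_id] = rec.group
        c = counts[rec.subject_id]
        for d, g, a in zip(*_record_steps(rec)):
            key = (int(d), int(g), int(a))
            c[key] = c.get(key, 0) + 1
    n = len(ids)
    logL = np.empty((n, len(grid.cs_nodes), len(grid.t_nodes)))
    n_steps = np.empty(n, dtype=int)
    for i, sid in enumerate(ids):
        keys = np.array(list(counts[sid]))
        w = np.array(list(counts[sid].values()), dtype=float)
        lp = logp[:, :, keys[:, 0], keys[:, 1], keys[:, 2]]
        logL[i] = lp @ w
        n_steps[i] = int(w.sum())
    return ids, [groups[s] for s in ids], logL, n_steps


def _fit_gamma_weighted(mean_x: float, mean_logx: float, var_x: float) -> GammaMoments:
    """Gamma ML fit from expected sufficient statistics.

    Solves ``ln k - psi(k) = ln(mean) - mean(ln x)`` by Newton iteration;
    when the statistic is non-positive (possible with heavily shrunken
    posteriors) falls back to moment matching.
    """
    s = np.log(mean_x) - mean_logx
    if not np.isfinite(s) or s <= 1e-8:
        # posterior mass concentrated on a single grid node: the shape is
        # unbounded, so fall back to the (floored) moment estimate
        var = max(var_x, _momvar_floor(mean_x))
        return GammaMoments(mean_x, var)
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = np.log(k) - digamma(k) - s
        fp = 1.0 / k - polygamma(1, k)
        k_new = k - f / fp if fp != 0.0 else k
        if k_new <= 0:
            k_new = k / 2.0
        k_new = float(np.clip(k_new, 1e-8, 1e8))
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    k = float(np.clip(k, 1e-8, 1e8))
    scale = mean_x / k
    return GammaMoments(k * scale, k * scale**2)


def _momvar_floor(mean_x: float) -> float:
    return max(1e-12, (1e-6 * mean_x) ** 2)


def _log_prior_on_grid(prior: GroupPrior, grid: ParamGrid) -> np.ndarray:
    return (
        prior.cs.logpdf(grid.cs_nodes)[:, None]
        + prior.temperature.logpdf(grid.t_nodes)[None, :]
        + grid.log_quad_weights
    )


@dataclass
class FitResult:
    """Outcome of a hierarchical EM fit.

    ``priors`` maps group label (or ``"all"`` for a combined fit) to the
    fitted :class:`GroupPrior`; ``subject_summaries`` holds per-subject
    posterior mean/median/IQR of CS and T under the final empirical prior;
    ``ll`` is the final total marginal log likelihood and ``trace`` its
    per-iteration values per group.
    """

    grouping: str
    priors: dict[str, GroupPrior]
    subject_summaries: pd.DataFrame
    ll: float
    ll_by_group: dict[str, float]
    trace: dict[str, list[float]]
    blocks: tuple[int, ...]
    n_steps: int

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "blocks": list(self.blocks),
            "n_steps": self.n_steps,
            "ll": self.ll,
            "priors": {
                g: {
                    "cs_mean": p.cs.mean, "cs_variance": p.cs.variance,
                    "t_mean": p.temperature.mean, "t_variance": p.temperature.variance,
                }
                for g, p in self.priors.items()
            },
            "trace": self.trace,
            "subjects": self.subject_summaries.to_dict(orient="records"),
        }


def _weighted_quantile(nodes: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return np.array([nodes[np.searchsorted(cdf, q, side="left").clip(0, len(nodes) - 1)] for q in qs])


def _em_single_group(logL: np.ndarray, grid: ParamGrid, ids, n_iter: int, tol: float):
    """EM for one population; returns (GroupPrior, trace, posterior weights)."""
    log_quad = grid.log_quad_weights
    log_prior = log_quad - logsumexp(log_quad)  # uninformative start: flat on the grid
    trace: list[float] = []
    W = None
    prior = None
    for it in range(n_iter):
        log_post = logL + log_prior[None, :, :]
        logZ = logsumexp(log_post, axis=(1, 2))
        bad = np.where(~np.isfinite(logZ))[0]
        if bad.size:
            raise ValueError(
                f"subject {ids[bad[0]]} has zero posterior mass on the grid; "
                "widen the CS/T grid bounds"
            )
        W = np.exp(log_post - logZ[:, None, None])
        ll = float(logZ.sum())
        trace.append(ll)
        if it >= 2 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            break
        # M step: expected sufficient statistics, averaged over subjects
        w_cs = W.sum(axis=2)
        w_t = W.sum(axis=1)
        cs, t = grid.cs_nodes, grid.t_nodes
        e_cs, e_logcs, e_cs2 = (w_cs @ cs), (w_cs @ np.log(cs)), (w_cs @ cs**2)
        e_t, e_logt, e_t2 = (w_t @ t), (w_t @ np.log(t)), (w_t @ t**2)
        prior = GroupPrior(
            cs=_fit_gamma_weighted(e_cs.mean(), e_logcs.mean(),
                                   e_cs2.mean() - e_cs.mean() ** 2),
            temperature=_fit_gamma_weighted(e_t.mean(), e_logt.mean(),
                                            e_t2.mean() - e_t.mean() ** 2),
        )
        log_prior = _log_prior_on_grid(prior, grid)
    if prior is None:  # n_iter == 0 degenerate guard
        raise ValueError("n_iter must be >= 1")
    return prior, trace, W


def _summaries_frame(ids, groups, W, grid: ParamGrid) -> pd.DataFrame:
    rows = []
    for i, sid in enumerate(ids):
        w_cs = W[i].sum(axis=1)
        w_t = W[i].sum(axis=0)
        cs_q = _weighted_quantile(grid.cs_nodes, w_cs, (0.25, 0.5, 0.75))
        t_q = _weighted_quantile(grid.t_nodes, w_t, (0.25, 0.5, 0.75))
        rows.append(
            {
                "subject_id": sid,
                "group": groups[i],
                "cs_mean": float(w_cs @ grid.cs_nodes),
                "cs_median": float(cs_q[1]),
                "cs_iqr": float(cs_q[2] - cs_q[0]),
                "t_mean": float(w_t @ grid.t_nodes),
                "t_median": float(t_q[1]),
                "t_iqr": float(t_q[2] - t_q[0]),
            }
        )
    return pd.DataFrame(rows)


def em_fit(
    dataset: Dataset,
    config: TaskConfig | None = None,
    grouping: str = "combined",
    grid: ParamGrid | None = None,
    blocks=(1, 2, 3),
    reward: float = 100.0,
    n_iter: int = 30,
    tol: float = 1e-6,
) -> FitResult:
    """Fit group gamma distributions over (CS, T) by hierarchical EM.

    ``grouping`` is ``"combined"`` (one population for everyone) or
    ``"by-label"`` (an independent population per group label).  The fit
    pools the trials of ``blocks``; fit a single block by passing e.g.
    ``blocks=(1,)``.  The marginal log likelihood is non-decreasing over
    iterations (within numerical tolerance) and is traced per group.
    """
    config = config or TaskConfig()
    grid = grid or ParamGrid.default()
    ids, groups, logL, n_steps = _subject_logliks(dataset, grid, config, blocks, reward)
    if grouping == "combined":
        members = {"all": list(range(len(ids)))}
    elif grouping == "by-label":
        members = {}
        for i, g in enumerate(groups):
            members.setdefault(g, []).append(i)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    priors: dict[str, GroupPrior] = {}
    traces: dict[str, list[float]] = {}
    ll_by_group: dict[str, float] = {}
    W_full = np.empty_like(logL)
    for label, idx in members.items():
        prior, trace, W = _em_single_group(
            logL[idx], grid, [ids[i] for i in idx], n_iter, tol
        )
        priors[label] = prior
        traces[label] = trace
        ll_by_group[label] = trace[-1]
        W_full[idx] = W
    return FitResult(
        grouping=grouping,
        priors=priors,
        subject_summaries=_summaries_frame(ids, groups, W_full, grid),
        ll=float(sum(ll_by_group.values())),
        ll_by_group=ll_by_group,
        trace=traces,
        blocks=tuple(blocks),
        n_steps=int(n_steps.sum()),
    )


@dataclass(frozen=True)
class IBICReport:
    """Integrated-BIC comparison of combined vs separate group populations.

    ``difference = ibic_combined - ibic_separate``; a positive difference
    prefers modelling the groups separately, a negative one the single
    combined population.
    """

    ibic_combined: float
    ibic_separate: float
    n_steps: int
    k_combined: int = 4
    k_separate: int = 8

    @property
    def difference(self) -> float:
        return self.ibic_combined - self.ibic_separate

    @property
    def preferred(self) -> str:
        return "separate" if self.difference > 0 else "combined"

    def to_dict(self) -> dict:
        return {
            "ibic_combined": self.ibic_combined,
            "ibic_separate": self.ibic_separate,
            "difference": self.difference,
            "preferred": self.preferred,
            "n_steps": self.n_steps,
            "k_combined": self.k_combined,
            "k_separate": self.k_separate,
        }


def ibic(
    dataset: Dataset,
    grid: ParamGrid,
    fit_combined: FitResult,
    fit_separate: FitResult,
    config: TaskConfig | None = None,
    blocks=(1, 2, 3),
    reward: float = 100.0,
) -> IBICReport:
    """Integrated BIC of the combined and separate fits on one dataset.

    Per-subject integrated likelihoods are grid quadratures of the data
    likelihood against the relevant fitted empirical prior (the same
    quadrature as the E step, so the comparison is deterministic), and the
    complexity penalty counts group-level parameters against the total
    number of recorded decision steps ``N``.
    """
    config = config or TaskConfig()
    if fit_combined.grouping != "combined" or fit_separate.grouping != "by-label":
        raise ValueError("pass a combined fit and a by-label fit, in that order")
    if fit_combined.blocks != tuple(blocks) or fit_separate.blocks != tuple(blocks):
        raise ValueError("fits were not produced on the requested blocks")
    ids, groups, logL, n_steps = _subject_logliks(dataset, grid, config, blocks, reward)
    N = int(n_steps.sum())
    if N != fit_combined.n_steps or N != fit_separate.n_steps:
        raise ValueError("fits were produced on a different dataset")

    def total_neg2(fit: FitResult) -> float:
        tot = 0.0
        for i, sid in enumerate(ids):
            prior = fit.priors["all"] if fit.grouping == "combined" else fit.priors[groups[i]]
            tot += float(logsumexp(logL[i] + _log_prior_on_grid(prior, grid)))
        return -2.0 * tot

    k_c = 4 * len(fit_combined.priors)
    k_s = 4 * len(fit_separate.priors)
    return IBICReport(
        ibic_combined=total_neg2(fit_combined) + k_c * np.log(N),
        ibic_separate=total_neg2(fit_separate) + k_s * np.log(N),
        n_steps=N,
        k_combined=k_c,
        k_separate=k_s,
    )


def individual_estimates(dataset: Dataset, combined_fit: FitResult) -> pd.DataFrame:
    """Per-subject (CS, T) posterior summaries under the combined prior.

    Forcing a single population is an over-conservative but stern basis for
    subsequent between-group tests (Mann–Whitney on CS, t test on T,
    Spearman correlations against covariates); those tests live in
    :mod:`costedbeads.summaries`.  Estimates are invariant to the row order
    of the input file.
    """
    if combined_fit.grouping != "combined":
        raise ValueError("individual estimates require a combined fit")
    order = {s: i for i, s in enumerate(dataset.subjects)}
    df = combined_fit.subject_summaries.copy()
    return df.sort_values(by="subject_id", key=lambda s: s.map(order)).reset_index(drop=True)
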