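# Methods

## Model

Behaviour in the fish/beads task is modelled as a partially observable
Markov decision process whose observable state after `n_d` draws with `n_g`
gold fish is `s = (n_d, n_g)`; the posterior over the two lakes under
equiprobable priors is `P(G|s) = 1/(1 + r^(n_d − 2 n_g))` with odds
`r = q/(1−q)` and majority probability `q`. Declaring is worth
`R_C·P(correct|s) − C_W·P(wrong|s)`; sampling is worth the predictive
expectation of the next state's value minus the cost of the next draw.
Values are backed up from the draw cap (where a declaration is forced and
only the two declare actions enter) down to the first fish, either as the
Bellman maximum (the ideal agent) or as the softmax-choice expectation
`V(s) = Σ_a Q(a;s) p(a|s)` with `p(a|s) ∝ exp(Q(a;s)/T)` (the generative
model of real agents). Assumptions worth making explicit:

- Two lakes only, symmetric ratios, no discounting, equiprobable priors.
- The first fish of every trial is shown unconditionally, so decisions
  start at `n_d = 1` and DTD ≥ 1.
- The forced final choice renormalises the softmax over the two declare
  actions.
- For fitting, a subject's *subjective* cost CS is constant within a block
  and replaces the objective schedule; the ideal agent uses the objective
  schedule (in which the cost of sampling at state `n_d` is the cost of
  the `n_d+1`-th draw).
- The feedback-only block carries the same nominal ±100 payoff as the
  win/loss block, since CS and T are only interpretable relative to the
  reward scale and the same likelihood is applied to all fitted blocks.
  The escalating-cost block violates the constant-subjective-cost
  assumption and is excluded from fitting.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| `majority_prob` | probability | 0.6 | lake colour ratio P(g\|G) = P(b\|B) |
| `draw_cap` | draws | 20 | forced declaration point |
| `R_C = C_W` | points | 100 | symmetric payoff of a declaration |
| `C_S(n)` | points | per block: 0; 0; 5 after the first; 5·(n−1) | objective cost of the n-th draw |
| CS | points/draw | subject-level | subjective sampling cost; high ⇒ early declaration |
| T | points | subject-level | softmax temperature; high ⇒ uniform actions |

## Reference (ideal-agent) results

Solving the deterministic tables reproduces the analytic benchmarks the
tests and the acceptance script check: zero-cost blocks sample all 20 fish
with full-sequence accuracy 0.835 (the posterior at 12/20 majority fish);
the flat 5-point cost makes declaring optimal exactly at colour difference
2 away from the cap, correct with probability 0.692 by exact forward
enumeration (the uncapped ±2 gambler's-ruin value is 9/13 ≈ 0.6923; the
20-draw cap shifts it by ~1.3e-4); the escalating schedule stops after one
fish with accuracy 0.6. Deterministic ties are resolved in favour of
sampling — at zero cost sampling and declaring tie exactly wherever both
successor states imply the same declaration, and preferring to sample
reproduces the sample-to-the-cap ideal behaviour — and a forced
declaration at posterior 0.5 is scored as accuracy 0.5 rather than a coin
flip. Note the stochastic softmax agent has no such tie-break: at zero
cost it stops on tied extreme-evidence paths with probability ≈ 1/2 per
step, so even a near-deterministic (low-T, CS = 0) simulated subject
occasionally declares before the cap. That is a property of the softmax
choice rule, not a solver artefact.

## Synthetic cohorts

The generator emulates the study design: two groups of 31 subjects, four
blocks of 10 trials, pseudo-random 60:40 sequences fixed per trial and
shared by every subject (exact 12/8 colour multisets by default), and
subject-level (CS, T) drawn from independent per-group gamma distributions
parameterised by mean and variance. The default group distributions are
the fitted no-explicit-cost condition values (control: CS 1.9·10⁻³ /
2.0·10⁻⁶, T 3.4 / 13; psychosis: CS 1.7 / 13, T 4.2 / 13). Per-subject
random streams are keyed by (group, subject, purpose), so enlarging a
cohort leaves existing subjects' data unchanged. An optional scalar
covariate with a chosen Gaussian-copula rank correlation to true CS
supports correlation pipelines.

What the generator does *not* emulate: within-subject adaptation of CS or
T across blocks (each simulated subject carries one (CS, T) everywhere,
whereas real subjects sharply reduce sampling when costs rise), feedback
learning across trials, and clinical covariates beyond the optional
scalar. Passing recovery tests therefore show that the estimator works
when the model is true, not that the model captures block-wise adaptation.

## Estimation

The E step evaluates each subject's likelihood on a log-spaced grid
(default 50 × 50 nodes, CS ∈ [10⁻⁴, 10²], T ∈ [0.05, 50]) by one
vectorised backward induction per node, cached per task geometry; because
all fitted blocks share the ±100 payoff and CS is constant, one table grid
serves Blocks 1–3 jointly. Posterior weights are likelihood × gamma priors
× midpoint quadrature weights, normalised. The M step refits each gamma by
weighted maximum likelihood (Newton on the shape via the digamma equation,
moment matching when the concentration degenerates to a single node). The
first iteration starts from a flat-on-the-grid prior; 30 iterations with
early stopping at relative marginal-log-likelihood change < 10⁻⁶. The
marginal log likelihood is non-decreasing from the first gamma-prior
iteration onward and is traced.

Integrated likelihoods for the iBIC reuse the same grid quadrature (no
fresh Monte Carlo, so the comparison is deterministic), and `N` in the
`k ln N` penalty counts recorded decision steps, stated in the report so
per-subject or per-trial alternatives can be compared. Grid truncation:
heavy-tailed CS priors (gamma shape ≪ 1) place some mass below the
smallest CS node; costs that small are behaviourally indistinguishable
from zero, so the truncation is inert — `ParamGrid.coverage` reports the
enclosed mass.

CS is fitted on a non-negative support throughout; published
individual-level cost summaries are sometimes printed with a negative
sign convention, which is not reproduced here.

## Numerical choices

- Softmax probabilities via max-shifted exponentials; value backups in
  double precision; unavailable actions carry −∞ log probability.
- Greedy-policy sample/declare comparisons use a 10⁻⁹ relative tolerance,
  since exact zero-cost ties are perturbed by ~1 ulp in the backup.
- Weighted posterior quantiles are taken on the grid nodes (step CDF).
- Degenerate inputs: single-subject datasets run (prior-dominated
  posteriors); identical-subject cohorts drive the fitted variance to the
  moment floor; a zero between-subject-variance ICC is reported as NaN.

## Problem sizes

Tests and the acceptance script run at the study's scale: 31-subject
groups, 10 trials per block, the full 21 × 21 state table. The
model-selection and recovery checks use a 40 × 30 grid and 20 seeded
replicates of 31 × 30-trial cohorts (~1 s per simulate-fit cycle); unit
tests use smaller cohorts and grids.

## Known limitations

- Recovering the *population* mean of a heavy-tailed CS distribution from
  31 subjects is dominated by cohort sampling noise (sd of the cohort mean
  is ≈ √(var/31)), and very small or very large CS values are censored by
  the task (all map to sample-to-cap or declare-immediately behaviour), so
  group-mean recovery is accurate only up to those limits.
- The combined-vs-separate iBIC decision at n = 31 + 31 is reliable when
  fits pool Blocks 1–3; on a single block the evidence for separation is
  marginal when only CS (not T) differs between groups.
- The gamma family is awkward for costs indistinguishable from zero (the
  fitted control-like CS distribution collapses toward the grid floor); a
  point mass at zero plus a continuous component would be a natural
  extension.
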