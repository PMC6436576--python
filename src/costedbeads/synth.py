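"""Synthetic cohorts with the hierarchical structure the fitting assumes.

Subject-level cost-of-sampling and temperature parameters are drawn from
independent per-group gamma distributions, parameterised — as is customary
in this literature — by mean and variance rather than shape and scale.  The
default cohort mirrors the study design: two groups of 31 subjects labelled
``control`` and ``psychosis``, four blocks of 10 trials with predetermined
exact-ratio fish sequences shared by every subject, and group distributions
set to the fitted no-explicit-cost condition values (control: CS mean
1.9e-3, variance 2.0e-6, T mean 3.4, variance 13; psychosis: CS mean 1.7,
variance 13, T mean 4.2, variance 13).

A master seed is split into independent per-subject streams, so enlarging a
group leaves the existing subjects' data untouched.  Optionally a scalar
"symptom" covariate with a chosen rank correlation to the true CS is
injected through a Gaussian copula, for exercising correlation pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pomdp import SubjectParams, simulate_agent
from .task import BlockSpec, Dataset, FishSequence, TaskConfig, default_blocks, generate_sequences

__all__ = [
    "GammaMoments",
    "GroupSpec",
    "CohortSpec",
    "sample_cohort",
    "simulate_dataset",
]

_VAR_FLOOR = 1e-12  # avoids degenerate densities for near-deterministic groups


@dataclass(frozen=True)
class GammaMoments:
    """A gamma distribution given by its mean and variance.

    Shape and scale are recovered as ``shape = mean**2 / variance`` and
    ``scale = variance / mean``.  Variances below ``1e-12`` are floored.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError("mean must be positive")
        if not self.variance > 0:
            raise ValueError("variance must be positive")
        object.__setattr__(self, "variance", max(float(self.variance), _VAR_FLOOR))

    @property
    def shape(self) -> float:
        return self.mean**2 / self.variance

    @property
    def scale(self) -> float:
        return self.variance / self.mean

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)

    def logpdf(self, x):
        return stats.gamma.logpdf(x, self.shape, scale=self.scale)

    def ppf(self, u):
        return stats.gamma.ppf(u, self.shape, scale=self.scale)


@dataclass(frozen=True)
class GroupSpec:
    """One group of a cohort: its size and parameter distributions."""

    label: str
    n_subjects: int
    cs: GammaMoments
    temperature: GammaMoments

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Complete description of a simulated study.

    ``sequence_seed`` fixes the predetermined fish sequences (shared across
    all subjects, one set per block); ``covariate_rho`` optionally injects a
    per-subject scalar with that Gaussian-copula correlation to the true CS.
    """

    groups: tuple[GroupSpec, ...]
    config: TaskConfig = field(default_factory=TaskConfig)
    blocks: tuple[BlockSpec, ...] | None = None
    exact_ratio: bool = True
    sequence_seed: int = 0
    covariate_rho: float | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("a cohort needs at least one group")
        if self.blocks is None:
            object.__setattr__(self, "blocks", tuple(default_blocks(self.config)))
        if self.covariate_rho is not None and not -1.0 < self.covariate_rho < 1.0:
            raise ValueError("covariate_rho must lie in (-1, 1)")

    @classmethod
    def default(cls, **overrides) -> "CohortSpec":
        """Two groups of 31 subjects with the default group distributions."""
        groups = (
            GroupSpec("control", 31, GammaMoments(1.9e-3, 2.0e-6), GammaMoments(3.4, 13.0)),
            GroupSpec("psychosis", 31, GammaMoments(1.7, 13.0), GammaMoments(4.2, 13.0)),
        )
        return cls(groups=groups, **overrides)


def sample_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw per-subject parameters for every group of the cohort.

    Returns a frame with columns ``subject_id, group, cs, temperature`` (and
    ``covariate`` when requested).  Each subject consumes an independent
    child stream of the master seed.
    """
    streams = _subject_streams(spec, seed)
    rows = []
    for (sid, grp, rng) in streams:
        group = next(g for g in spec.groups if g.label == grp)
        if spec.covariate_rho is not None:
            rho = spec.covariate_rho
            z1, z2 = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            cs = float(group.cs.ppf(stats.norm.cdf(z1)))
            cov = float(z2)
        else:
            cs = float(group.cs.sample(rng))
            cov = np.nan
        t = float(group.temperature.sample(rng))
        rows.append((sid, grp, cs, max(t, 1e-6), cov))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "cs", "temperature", "covariate"])
    if spec.covariate_rho is None:
        df = df.drop(columns=["covariate"])
    return df


def _subject_streams(spec: CohortSpec, seed, purpose: int = 0):
    """Independent per-subject streams keyed by (group, subject, purpose).

    Explicit spawn keys make each stream a pure function of the master seed
    and the subject's position, so growing a group does not perturb anyone
    else's draws.  ``purpose`` 0 is parameter sampling, 1 behaviour.
    """
    entropy = 0 if seed is None else seed
    out = []
    for gi, group in enumerate(spec.groups):
        for i in range(group.n_subjects):
            sid = f"{group.label}-{i + 1:02d}"
            ss = np.random.SeedSequence(entropy, spawn_key=(gi, i, purpose))
            out.append((sid, group.label, np.random.default_rng(ss)))
    return out


def block_sequences(spec: CohortSpec) -> dict[int, list[FishSequence]]:
    """The predetermined per-block sequences, identical for all subjects."""
    seq_rng = np.random.default_rng(np.random.SeedSequence(spec.sequence_seed))
    return {
        b.block_id: generate_sequences(
            spec.config, spec.config.n_trials_per_block, spec.exact_ratio, seed=seq_rng
        )
        for b in spec.blocks
    }


def simulate_dataset(spec: CohortSpec, seed: int | None = None) -> tuple[Dataset, pd.DataFrame]:
    """Simulate a full cohort: one trial record per subject × block × trial.

    Parameters are drawn with :func:`sample_cohort` from the same master
    seed, so the returned ground-truth table and dataset are consistent.
    The fish sequences come from ``spec.sequence_seed`` alone and are shared
    by every subject, as in the task.
    """
    truth = sample_cohort(spec, seed)
    sequences = block_sequences(spec)
    sim_streams = {sid: rng for sid, _, rng in _subject_streams(spec, seed, purpose=1)}
    records = []
    for row in truth.itertuples(index=False):
        params = SubjectParams(cs=row.cs, temperature=row.temperature)
        rng = sim_streams[row.subject_id]
        records.extend(
            simulate_agent(
                params, list(spec.blocks), sequences, spec.config,
                seed=rng, subject_id=row.subject_id, group=row.group,
            )
        )
    return Dataset(records), truth
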