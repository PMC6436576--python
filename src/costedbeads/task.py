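"""Fish/beads information-sampling task: configuration, stimuli and trial records.

Two lakes hold gold and black fish in complementary ratios (60:40 by
default).  On every trial a series of fish is drawn from one, unknown, lake;
after each fish the subject either samples another one or declares the lake.
Four blocks vary the payoff structure: feedback only, symmetric win/loss
(±100 points), a flat 5-point cost per extra fish, and an escalating cost
(0, 5, 10, ... points for successive draws).

This module holds the task definition (:class:`TaskConfig`,
:class:`BlockSpec`), the stimulus generator (:func:`generate_sequences`,
producing the pseudo-random fish sequences that are shared by all subjects),
the per-trial data container (:class:`TrialRecord`, :class:`Dataset`) and a
plain-text CSV interchange format (:func:`read_trials`,
:func:`write_trials`).

CSV dialect
-----------
One row per decision step, comma separated, UTF-8, mandatory header::

    subject_id,group,block,trial,step,fish_color,action[,true_lake]

``fish_color`` is ``g``/``b``; ``action`` is ``S`` (sample another fish),
``DG`` (declare the mainly-gold lake) or ``DB`` (declare the mainly-black
lake).  The optional ``true_lake`` column (``G``/``B``) carries the
generating lake for simulated data so that a written file round-trips; files
without it load with unknown ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ACTIONS",
    "TaskConfig",
    "BlockSpec",
    "FishSequence",
    "TrialRecord",
    "Dataset",
    "default_blocks",
    "generate_sequences",
    "read_trials",
    "write_trials",
]

#: Action codes: sample again, declare gold lake, declare black lake.
ACTIONS = ("S", "DG", "DB")

_CSV_COLUMNS = ["subject_id", "group", "block", "trial", "step", "fish_color", "action"]


@dataclass(frozen=True)
class TaskConfig:
    """Global task parameters.

    Parameters
    ----------
    majority_prob:
        Probability that a drawn fish matches its lake's majority colour,
        ``P(g|G) = P(b|B)``.  Must lie in (0.5, 1).
    draw_cap:
        Maximum number of fish a subject may see on one trial; at the cap a
        declaration is forced.
    n_trials_per_block:
        Number of trials per block (same predetermined sequences for every
        subject).
    lake_labels:
        Labels of the (majority-gold, majority-black) lakes.
    """

    majority_prob: float = 0.6
    draw_cap: int = 20
    n_trials_per_block: int = 10
    lake_labels: tuple[str, str] = ("G", "B")

    def __post_init__(self) -> None:
        if not 0.5 < self.majority_prob < 1.0:
            raise ValueError(f"majority_prob must be in (0.5, 1), got {self.majority_prob}")
        if self.draw_cap < 1:
            raise ValueError("draw_cap must be >= 1")
        if self.n_trials_per_block < 1:
            raise ValueError("n_trials_per_block must be >= 1")
        if len(self.lake_labels) != 2 or len(set(self.lake_labels)) != 2:
            raise ValueError("lake_labels must be two distinct labels")


@dataclass(frozen=True)
class BlockSpec:
    """Payoff schedule of one task block.

    ``cost_schedule[n-1]`` is the cost, in points, of seeing the *n*-th fish
    of a trial.  The first fish of every trial is shown unconditionally, so
    ``cost_schedule[0]`` never enters the value recursion; it is kept for
    bookkeeping (it is 0 in every standard block).
    """

    block_id: int
    reward_correct: float
    cost_wrong: float
    cost_schedule: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.reward_correct < 0 or self.cost_wrong < 0:
            raise ValueError("reward_correct and cost_wrong must be non-negative")
        if any(c < 0 for c in self.cost_schedule):
            raise ValueError("sampling costs must be non-negative")
        object.__setattr__(self, "cost_schedule", tuple(float(c) for c in self.cost_schedule))

    def cost_of_draw(self, n: int) -> float:
        """Cost of the ``n``-th fish of a trial (1-based)."""
        if not 1 <= n <= len(self.cost_schedule):
            raise IndexError(f"draw index {n} outside schedule of length {len(self.cost_schedule)}")
        return self.cost_schedule[n - 1]


def default_blocks(config: TaskConfig | None = None) -> list[BlockSpec]:
    """The four standard blocks of the task.

    Block 1 gives correct/incorrect feedback only; for modelling purposes it
    carries the same nominal ±100 payoff as Block 2, since the cost and
    temperature parameters are only interpretable relative to the reward
    scale and the same likelihood is applied to it.  Block 2 wins or loses
    100 points.  Block 3 additionally charges 5 points for every fish after
    the first.  Block 4 charges an escalating 0, 5, 10, ... points for
    successive fish.
    """
    config = config or TaskConfig()
    cap = config.draw_cap
    zeros = (0.0,) * cap
    flat5 = (0.0,) + (5.0,) * (cap - 1)
    escal = tuple(5.0 * n for n in range(cap))
    return [
        BlockSpec(1, 100.0, 100.0, zeros, label="feedback only"),
        BlockSpec(2, 100.0, 100.0, zeros, label="win/loss ±100"),
        BlockSpec(3, 100.0, 100.0, flat5, label="flat 5-point cost"),
        BlockSpec(4, 100.0, 100.0, escal, label="escalating cost"),
    ]


@dataclass(frozen=True)
class FishSequence:
    """A predetermined sequence of fish colours drawn from one lake."""

    true_lake: str
    colors: str  # e.g. "ggbgb...", length == draw_cap
    exact_ratio: bool = False

    def __post_init__(self) -> None:
        if self.true_lake not in ("G", "B"):
            raise ValueError(f"true_lake must be 'G' or 'B', got {self.true_lake!r}")
        if set(self.colors) - {"g", "b"}:
            raise ValueError("colors must contain only 'g'/'b'")

    def __len__(self) -> int:
        return len(self.colors)


def generate_sequences(
    config: TaskConfig,
    n: int,
    exact_ratio: bool = True,
    seed: int | np.random.Generator | None = None,
) -> list[FishSequence]:
    """Generate ``n`` fish sequences, half from each lake.

    ``n // 2`` sequences come from each lake (an odd remainder is assigned
    at random) and their order is shuffled, mimicking the pseudo-randomised
    lake order of the task.  With ``exact_ratio`` the colour multiset of
    every sequence is constrained to exactly ``round(majority_prob *
    draw_cap)`` majority-colour fish in a random permutation; otherwise
    colours are i.i.d. draws from the lake's ratio.  A fixed ``seed`` gives
    identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cap, q = config.draw_cap, config.majority_prob
    lakes = ["G"] * (n // 2) + ["B"] * (n // 2)
    if n % 2:
        lakes.append("G" if rng.random() < 0.5 else "B")
    lakes = list(rng.permutation(lakes))
    n_major = int(round(q * cap))
    out = []
    for lake in lakes:
        major, minor = ("g", "b") if lake == "G" else ("b", "g")
        if exact_ratio:
            pool = [major] * n_major + [minor] * (cap - n_major)
            colors = "".join(rng.permutation(pool))
        else:
            colors = "".join(major if u < q else minor for u in rng.random(cap))
        out.append(FishSequence(lake, colors, exact_ratio=exact_ratio))
    return out


@dataclass(frozen=True)
class TrialRecord:
    """Observed actions of one trial.

    ``colors`` holds the fish actually seen (length equals the number of
    steps); every action before the last is ``S`` and the last is a
    declaration (``DG``/``DB``) — at the draw cap the declaration is forced.
    """

    subject_id: str
    group: str
    block_id: int
    trial: int
    colors: str
    actions: tuple[str, ...]
    true_lake: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(self.actions))
        if len(self.actions) != len(self.colors):
            raise ValueError("colors and actions must have equal length")
        if not self.actions:
            raise ValueError("a trial must contain at least one step")
        if any(a != "S" for a in self.actions[:-1]):
            raise ValueError("every action before the last must be 'S'")
        if self.actions[-1] not in ("DG", "DB"):
            raise ValueError("the last action must be a declaration ('DG'/'DB')")
        if set(self.colors) - {"g", "b"}:
            raise ValueError("colors must contain only 'g'/'b'")

    @property
    def dtd(self) -> int:
        """Draws to decision: number of fish seen before declaring."""
        return len(self.actions)

    @property
    def declared_lake(self) -> str:
        return "G" if self.actions[-1] == "DG" else "B"

    @property
    def n_gold(self) -> int:
        """Gold fish among those seen."""
        return self.colors.count("g")

    @property
    def correct(self) -> bool | None:
        if self.true_lake is None:
            return None
        return self.declared_lake == self.true_lake


@dataclass
class Dataset:
    """An ordered collection of :class:`TrialRecord`."""

    records: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Dataset) and self.records == other.records

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def group_of(self, subject_id: str) -> str:
        for r in self.records:
            if r.subject_id == subject_id:
                return r.group
        raise KeyError(subject_id)

    def filter_blocks(self, block_ids: Iterable[int]) -> "Dataset":
        wanted = set(block_ids)
        return Dataset([r for r in self.records if r.block_id in wanted])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for k, (color, action) in enumerate(zip(r.colors, r.actions), start=1):
                rows.append(
                    (r.subject_id, r.group, r.block_id, r.trial, k, color, action,
                     "" if r.true_lake is None else r.true_lake)
                )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS + ["true_lake"])


def write_trials(dataset: Dataset, path) -> None:
    """Write a dataset in the documented one-row-per-step CSV dialect."""
    dataset.to_frame().to_csv(path, index=False)


def read_trials(path, config: TaskConfig | None = None) -> Dataset:
    """Read a trial CSV, validating structure row by row.

    Malformed rows (missing columns, actions after a declaration, draw counts
    exceeding the cap, non-contiguous steps) are rejected with the offending
    1-based file row number (header = row 1).
    """
    config = config or TaskConfig()
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "true_lake": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    if df.empty:
        return Dataset([])
    df = df.copy()
    df["_row"] = df.index + 2  # 1-based file rows, after the header
    has_lake = "true_lake" in df.columns
    records: list[TrialRecord] = []
    for (sid, grp, blk, trial), g in df.groupby(
        ["subject_id", "group", "block", "trial"], sort=False
    ):
        g = g.sort_values("step")
        steps = g["step"].to_numpy()
        rows = g["_row"].to_numpy()
        if steps[0] != 1 or not np.array_equal(steps, np.arange(1, len(steps) + 1)):
            raise ValueError(
                f"row {rows[0]}: steps of subject {sid} block {blk} trial {trial} "
                "are not contiguous from 1"
            )
        actions = list(g["action"])
        bad = [a for a in actions if a not in ACTIONS]
        if bad:
            raise ValueError(f"row {rows[0]}: unknown action {bad[0]!r}")
        declared_at = next((i for i, a in enumerate(actions) if a != "S"), None)
        if declared_at is None:
            raise ValueError(f"row {rows[-1]}: trial ends without a declaration")
        if declared_at != len(actions) - 1:
            raise ValueError(
                f"row {rows[declared_at + 1]}: action after the declaration at step "
                f"{declared_at + 1}"
            )
        if len(actions) > config.draw_cap:
            raise ValueError(
                f"row {rows[config.draw_cap]}: trial exceeds the draw cap of {config.draw_cap}"
            )
        lake = None
        if has_lake:
            vals = set(str(v) for v in g["true_lake"].fillna("") if str(v))
            if vals - {"G", "B", "nan"}:
                raise ValueError(f"row {rows[0]}: invalid true_lake value")
            lake = vals.pop() if vals else None
        records.append(
            TrialRecord(
                subject_id=str(sid),
                group=str(grp),
                block_id=int(blk),
                trial=int(trial),
                colors="".join(g["fish_color"]),
                actions=tuple(actions),
                true_lake=lake,
            )
        )
    return Dataset(records)
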