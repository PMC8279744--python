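"""Construction of the 2 x 3 Latin-square visual-world design.

The experiment crosses two visually derived occupation stereotypes
(female/male, an intrinsic property of each display) with three verbally
conveyed action stereotypes (female/male/neutral). Each item additionally
has a female- and a male-agent sentence version, giving six within-item
variants (3 actions x 2 agent genders) that rotate across six presentation
lists. Because occupation stereotype alternates along the item order, every
list contains exactly ``n_items / 6`` trials in each occupation x action
analysis cell, and female and male agents are exactly balanced per list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACTIONS = ("female", "male", "neutral")
GENDERS = ("female", "male")
N_LISTS = 6

#: within-item variants rotated by the Latin square, in rotation order:
#: (action stereotype, agent gender)
VARIANTS = (
    ("female", "female"),
    ("male", "female"),
    ("neutral", "female"),
    ("female", "male"),
    ("male", "male"),
    ("neutral", "male"),
)


class DesignError(ValueError):
    """A requested design violates a structural constraint."""


class ConstraintError(DesignError):
    """Pseudo-randomization constraints cannot be satisfied."""


@dataclass(frozen=True)
class ConditionCell:
    """One cell of the design: occupation x action, plus the agent named."""

    occupation_stereotype: str
    action_stereotype: str
    agent_gender: str

    def __post_init__(self) -> None:
        if self.occupation_stereotype not in GENDERS:
            raise DesignError(f"bad occupation stereotype {self.occupation_stereotype!r}")
        if self.action_stereotype not in ACTIONS:
            raise DesignError(f"bad action stereotype {self.action_stereotype!r}")
        if self.agent_gender not in GENDERS:
            raise DesignError(f"bad agent gender {self.agent_gender!r}")


@dataclass(frozen=True)
class Item:
    item_id: int
    occupation_id: int
    occupation_stereotype: str
    #: the three action variants every item supports
    actions: tuple[str, ...] = ACTIONS


@dataclass(frozen=True)
class ItemSet:
    """Occupations, experimental items and fillers of one experiment."""

    occupations: tuple[tuple[int, str], ...]  # (occupation id, stereotype)
    items: tuple[Item, ...]
    fillers: tuple[int, ...]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_fillers(self) -> int:
        return len(self.fillers)


@dataclass(frozen=True)
class Trial:
    """One row of a presentation list; ``cell`` is None for fillers."""

    trial_type: str  # "experimental" | "filler"
    trial_id: int
    cell: ConditionCell | None = None
    position: int | None = None


@dataclass
class PresentationList:
    list_id: int
    trials: list[Trial] = field(default_factory=list)

    @property
    def experimental(self) -> list[Trial]:
        return [t for t in self.trials if t.trial_type == "experimental"]

    @property
    def fillers(self) -> list[Trial]:
        return [t for t in self.trials if t.trial_type == "filler"]


def build_item_set(n_occupations: int, displays_per_occupation: int, n_fillers: int) -> ItemSet:
    """Build a balanced item set.

    Occupation stereotypes alternate female/male along the occupation order,
    so items (ordered occupation-major within each display round) alternate
    occupation stereotype — the property the Latin-square rotation relies on
    to balance the analysis cells.
    """
    if n_occupations < 2 or n_occupations % 2 != 0:
        raise DesignError(
            f"n_occupations must be even and >= 2 to balance stereotypes, got {n_occupations}"
        )
    if displays_per_occupation < 1:
        raise DesignError("displays_per_occupation must be >= 1")
    if n_fillers < 1:
        raise DesignError("n_fillers must be >= 1")

    occupations = tuple((k + 1, GENDERS[k % 2]) for k in range(n_occupations))
    items = []
    item_id = 0
    for d in range(displays_per_occupation):
        for occ_id, stereo in occupations:
            item_id += 1
            items.append(Item(item_id=item_id, occupation_id=occ_id, occupation_stereotype=stereo))
    n_items = len(items)
    # fillers live in a disjoint id space
    fillers = tuple(range(n_items + 1, n_items + 1 + n_fillers))
    return ItemSet(occupations=occupations, items=tuple(items), fillers=fillers)


def latin_square_lists(item_set: ItemSet) -> list[PresentationList]:
    """Assign the six within-item variants across six lists by cyclic rotation.

    Item ``i`` (0-based) on list ``l`` (0-based) receives variant
    ``VARIANTS[(i + l) % 6]``. Across the six lists every item passes through
    all six (action, agent-gender) variants exactly once; within a list each
    variant covers ``n_items / 6`` items, and — because occupation stereotype
    alternates with ``i`` — each occupation x action cell does too.
    """
    if item_set.n_items % N_LISTS != 0:
        raise DesignError(
            f"number of items ({item_set.n_items}) must be divisible by {N_LISTS}"
        )
    lists = []
    for l in range(N_LISTS):
        trials = []
        for i, item in enumerate(item_set.items):
            action, agent = VARIANTS[(i + l) % N_LISTS]
            cell = ConditionCell(
                occupation_stereotype=item.occupation_stereotype,
                action_stereotype=action,
                agent_gender=agent,
            )
            trials.append(Trial("experimental", item.item_id, cell))
        for fid in item_set.fillers:
            trials.append(Trial("filler", fid))
        lists.append(PresentationList(list_id=l + 1, trials=trials))
    return lists


def _sample_gap_composition(n_exp: int, n_fill: int, rng: np.random.Generator) -> list[int]:
    """Sample, exactly uniformly, a composition of ``n_exp`` into ``n_fill``
    gaps of size 0..2 (the number of experimental trials after each filler).

    Counts are computed by dynamic programming; each gap size is then drawn
    proportionally to the number of completions, which yields the uniform
    distribution over valid compositions (hence over valid trial orders once
    identities are shuffled independently).
    """
    max_run = 2
    # counts[j][k]: ways to place k trials into j remaining gaps
    counts = np.zeros((n_fill + 1, n_exp + 1), dtype=float)
    counts[0, 0] = 1.0
    for j in range(1, n_fill + 1):
        for g in range(max_run + 1):
            counts[j, g:] += counts[j - 1, : n_exp + 1 - g]
    if counts[n_fill, n_exp] == 0:
        raise ConstraintError(
            f"cannot place {n_exp} experimental trials with only {n_fill} fillers "
            f"(needs at least {-(-n_exp // max_run)})"
        )
    gaps = []
    remaining = n_exp
    for j in range(n_fill, 0, -1):
        weights = np.array(
            [counts[j - 1, remaining - g] if remaining - g >= 0 else 0.0 for g in range(max_run + 1)]
        )
        g = int(rng.choice(max_run + 1, p=weights / weights.sum()))
        gaps.append(g)
        remaining -= g
    return gaps


def randomize_presentation(plist: PresentationList, seed: int) -> PresentationList:
    """Pseudo-randomize trial order: first trial a filler, never more than two
    experimental trials in a row. Reproducible under ``seed``; uniform over
    all orders satisfying the constraints."""
    rng = np.random.default_rng(seed)
    exps = list(plist.experimental)
    fills = list(plist.fillers)
    if not fills:
        raise ConstraintError("at least one filler is required to lead the session")
    gaps = _sample_gap_composition(len(exps), len(fills), rng)
    rng.shuffle(exps)
    rng.shuffle(fills)
    ordered: list[Trial] = []
    ei = 0
    for f, g in zip(fills, gaps):
        ordered.append(f)
        ordered.extend(exps[ei : ei + g])
        ei += g
    trials = [
        Trial(t.trial_type, t.trial_id, t.cell, position=pos + 1)
        for pos, t in enumerate(ordered)
    ]
    return PresentationList(list_id=plist.list_id, trials=trials)


_FLIP = {"female": "male", "male": "female", "neutral": "neutral"}


def mirror_item_set(item_set: ItemSet) -> ItemSet:
    """Relabel genders: every occupation stereotype flips."""
    return ItemSet(
        occupations=tuple((i, _FLIP[g]) for i, g in item_set.occupations),
        items=tuple(
            Item(it.item_id, it.occupation_id, _FLIP[it.occupation_stereotype])
            for it in item_set.items
        ),
        fillers=item_set.fillers,
    )


def mirror_lists(lists: list[PresentationList]) -> list[PresentationList]:
    """Relabel genders in every condition cell (occupation, action, agent)."""
    out = []
    for pl in lists:
        trials = [
            Trial(
                t.trial_type,
                t.trial_id,
                ConditionCell(
                    _FLIP[t.cell.occupation_stereotype],
                    _FLIP[t.cell.action_stereotype],
                    _FLIP[t.cell.agent_gender],
                )
                if t.cell
                else None,
                t.position,
            )
            for t in pl.trials
        ]
        out.append(PresentationList(pl.list_id, trials))
    return out


# ---------------------------------------------------------------------------
# serialization

def lists_to_frame(lists: list[PresentationList]) -> pd.DataFrame:
    rows = []
    for pl in lists:
        for t in pl.trials:
            rows.append(
                {
                    "list_id": pl.list_id,
                    "position": t.position,
                    "trial_type": t.trial_type,
                    "item_id": t.trial_id,
                    "occupation_stereotype": t.cell.occupation_stereotype if t.cell else "",
                    "action_stereotype": t.cell.action_stereotype if t.cell else "",
                    "agent_gender": t.cell.agent_gender if t.cell else "",
                }
            )
    return pd.DataFrame(rows)


def design_descriptor(item_set: ItemSet) -> dict:
    return {
        "n_occupations": len(item_set.occupations),
        "n_items": item_set.n_items,
        "n_fillers": item_set.n_fillers,
        "n_lists": N_LISTS,
        "actions": list(ACTIONS),
        "variants": [list(v) for v in VARIANTS],
    }


def write_design(item_set: ItemSet, lists: list[PresentationList], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lists_to_frame(lists).to_csv(out / "lists.tsv", sep="\t", index=False)
    (out / "design.json").write_text(json.dumps(design_descriptor(item_set), indent=2))
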