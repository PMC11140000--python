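"""Study-design bookkeeping.

A study is a full factorial of developmental stages x feeding groups x
replicates, one sequencing library per cell-replicate. Library identifiers
are the stable join key used by every downstream table and follow the
``<stage>_<group>_r<k>`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

#: The feeding timepoints of the reference design, in temporal order.
DEFAULT_GROUPS = ("UF", "FED6h", "FED12h", "FED24h", "FED5d")
#: Immature developmental stages of the reference design.
DEFAULT_STAGES = ("larva", "nymph1", "nymph2")


@dataclass(frozen=True)
class Library:
    library_id: str
    stage: str
    group: str
    replicate: int


@dataclass
class StudyDesign:
    stages: tuple
    groups: tuple
    replicates_per_cell: int
    libraries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("library ids are not unique")
        from collections import Counter

        cells = Counter((lib.stage, lib.group) for lib in self.libraries)
        expected = {(s, g) for s in self.stages for g in self.groups}
        if set(cells) != expected:
            raise ValueError("libraries do not cover every (stage, group) cell")
        bad = {c for c, n in cells.items() if n != self.replicates_per_cell}
        if bad:
            raise ValueError(f"cells without {self.replicates_per_cell} replicates: {sorted(bad)}")
        groups_seen = {lib.group for lib in self.libraries}
        if groups_seen != set(self.groups):
            raise ValueError("library group labels do not match declared groups")

    @property
    def library_ids(self) -> list:
        return [lib.library_id for lib in self.libraries]

    def cell(self, stage: str, group: str) -> list:
        """Library ids of one (stage, group) cell, replicate order."""
        return [
            lib.library_id
            for lib in self.libraries
            if lib.stage == stage and lib.group == group
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.library_id, l.stage, l.group, l.replicate) for l in self.libraries],
            columns=["library_id", "stage", "group", "replicate"],
        )

    def to_file(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
        required = {"library_id", "stage", "group", "replicate"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: design table needs columns {sorted(required)}")
        stages = tuple(dict.fromkeys(df["stage"]))
        groups = tuple(dict.fromkeys(df["group"]))
        reps = df.groupby(["stage", "group"], sort=False).size()
        libraries = [
            Library(r.library_id, r.stage, r.group, int(r.replicate))
            for r in df.itertuples(index=False)
        ]
        return cls(stages, groups, int(reps.iloc[0]), libraries)


def build_design(
    stages: Sequence[str] = DEFAULT_STAGES,
    groups: Sequence[str] = DEFAULT_GROUPS,
    replicates_per_cell: int = 3,
) -> StudyDesign:
    """Enumerate libraries stage-major, then group, then replicate.

    The enumeration is deterministic: two calls with equal arguments yield
    identical library tables.
    """
    if not stages or not groups:
        raise ValueError("stages and groups must be non-empty")
    if replicates_per_cell < 1:
        raise ValueError("replicates_per_cell must be >= 1")
    if len(set(stages)) != len(stages):
        raise ValueError("duplicate stage labels")
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group labels")
    libraries = [
        Library(f"{s}_{g}_r{k}", s, g, k)
        for s in stages
        for g in groups
        for k in range(1, replicates_per_cell + 1)
    ]
    return StudyDesign(tuple(stages), tuple(groups), replicates_per_cell, libraries)
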