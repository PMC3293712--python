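"""The pooling hierarchy: groups ⊃ pools ⊃ technical replicates.

A pooled-DNA case-control study assays each physical DNA pool on several
replicate arrays.  :class:`PoolDesign` records which replicate array belongs
to which pool and which pool belongs to which phenotype group, and is the
single source of truth for that nesting throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import DesignError, ValidationError

#: Column names of the on-disk design table.
DESIGN_COLUMNS = ("Replicate", "Pool", "Group")


@dataclass(frozen=True)
class PoolDesign:
    """Nesting of technical replicates within pools within two groups.

    Parameters
    ----------
    groups:
        The two phenotype group labels, ordered (case first, control second).
    pool_to_group:
        Mapping from pool id to its group label.
    replicate_to_pool:
        Mapping from replicate id (the ``sample_id`` appearing in pooled
        intensity tables) to its pool id.
    """

    groups: tuple[str, str]
    pool_to_group: Mapping[str, str] = field(default_factory=dict)
    replicate_to_pool: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) != 2 or len(set(self.groups)) != 2:
            raise DesignError(
                f"a pool design needs exactly 2 distinct groups, got {self.groups!r}"
            )
        known = set(self.groups)
        for pool, grp in self.pool_to_group.items():
            if grp not in known:
                raise DesignError(f"pool {pool!r} maps to unknown group {grp!r}")
        for rep, pool in self.replicate_to_pool.items():
            if pool not in self.pool_to_group:
                raise DesignError(f"replicate {rep!r} maps to unknown pool {pool!r}")
        for grp in self.groups:
            n = sum(1 for g in self.pool_to_group.values() if g == grp)
            if n < 2:
                raise DesignError(f"group {grp!r} has {n} pool(s); at least 2 required")
        pools_with_reps = set(self.replicate_to_pool.values())
        empty = sorted(set(self.pool_to_group) - pools_with_reps)
        if empty:
            raise DesignError(f"pool(s) without any replicate: {empty}")

    # -- accessors ---------------------------------------------------------

    @property
    def case_group(self) -> str:
        return self.groups[0]

    @property
    def control_group(self) -> str:
        return self.groups[1]

    @property
    def replicate_ids(self) -> list[str]:
        return sorted(self.replicate_to_pool)

    def pools_in_group(self, group: str) -> list[str]:
        return sorted(p for p, g in self.pool_to_group.items() if g == group)

    def group_of_replicate(self, replicate_id: str) -> str:
        return self.pool_to_group[self.replicate_to_pool[replicate_id]]

    def to_frame(self) -> pd.DataFrame:
        """Long table with one row per replicate: replicate_id, pool_id, group."""
        rows = [
            (rep, pool, self.pool_to_group[pool])
            for rep, pool in sorted(self.replicate_to_pool.items())
        ]
        return pd.DataFrame(rows, columns=["replicate_id", "pool_id", "group"])

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, groups: tuple[str, str] | None = None
    ) -> "PoolDesign":
        """Build a design from a (replicate_id, pool_id, group) table.

        When ``groups`` is not given, group order follows first appearance in
        the table (the case group is expected to be listed first).
        """
        required = {"replicate_id", "pool_id", "group"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"design table missing column(s): {sorted(missing)}")
        if frame["replicate_id"].duplicated().any():
            dups = frame.loc[frame["replicate_id"].duplicated(), "replicate_id"]
            raise ValidationError(f"duplicate replicate id(s): {sorted(set(dups))}")
        pg = frame.drop_duplicates(["pool_id", "group"])
        if pg["pool_id"].duplicated().any():
            dups = pg.loc[pg["pool_id"].duplicated(), "pool_id"]
            raise ValidationError(
                f"pool(s) assigned to more than one group: {sorted(set(dups))}"
            )
        if groups is None:
            seen = list(dict.fromkeys(frame["group"]))
            if len(seen) != 2:
                raise DesignError(
                    f"design table must contain exactly 2 groups, found {seen}"
                )
            groups = (seen[0], seen[1])
        return cls(
            groups=groups,
            pool_to_group=dict(zip(pg["pool_id"], pg["group"])),
            replicate_to_pool=dict(zip(frame["replicate_id"], frame["pool_id"])),
        )
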