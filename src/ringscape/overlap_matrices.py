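"""Shared-voxel overlap matrices between RSN masks and reference atlases.

The topographical-similarity unit throughout is the raw count of voxels two
binary footprints have in common.  Normalized variants (per-row fractions)
are available as an option but the counts are what downstream clustering
consumes.

Also implements the Brodmann bookkeeping used by the anatomical analyses:
merging small adjacent areas into 28 extended regions, and grouping areas
into the 7 anatomo-functional Brodmann-area families (BAFs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import BinaryMask, ReferenceAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapMatrix",
    "shared_voxels",
    "build_overlap_matrix",
    "regroup_brodmann",
    "brodmann_families",
    "BRODMANN_MERGES",
    "BAF_MEMBERS",
]

#: extended-region merges: starred name -> constituent BA numbers
BRODMANN_MERGES: dict[str, tuple[int, ...]] = {
    "20*": (20, 38),
    "41*": (41, 42),
    "28*": (28, 34, 35, 36),
    "32*": (32, 24, 25),
    "23*": (23, 29, 30, 31),
}

#: Brodmann-area families: BAF name -> constituent BA numbers
BAF_MEMBERS: dict[str, tuple[int, ...]] = {
    "BAF1": (10, 11),           # anterior frontal
    "BAF2": (8, 9, 46),         # superior frontal
    "BAF3": (44, 45, 47),       # inferior frontal
    "BAF4": (23, 32),           # cingular (posterior / anterior)
    "BAF5": (41, 42, 21, 22, 37),  # temporal auditory
    "BAF6": (2, 3, 4, 5, 6),    # central somatomotor
    "BAF7": (17, 18, 19),       # occipital visual
}


@dataclass
class OverlapMatrix:
    """Integer shared-voxel counts: RSN ranks (rows) x reference units (cols)."""

    row_labels: list
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match labels")
        if np.any(counts < 0):
            raise ValidationError("overlap counts must be non-negative")
        self.counts = counts.astype(np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=self.col_labels
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OverlapMatrix":
        return cls(list(df.index), [str(c) for c in df.columns], df.to_numpy())

    def normalized(self) -> np.ndarray:
        """Rows rescaled to fractions; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals


def shared_voxels(a: BinaryMask, b: BinaryMask) -> int:
    """Number of voxels true in both masks."""
    if a.grid != b.grid:
        raise ValidationError("masks live on different grids")
    return int(np.count_nonzero(a.values & b.values))


def build_overlap_matrix(rsns, atlas: ReferenceAtlas) -> OverlapMatrix:
    """Full counts matrix between ranked RSN masks and every atlas unit.

    ``rsns`` is a sequence of objects exposing ``rank`` and ``mask``
    (:class:`~ringscape.group_rsn.RsnClass` satisfies this), or of
    ``(label, BinaryMask)`` pairs.
    """
    pairs = []
    for item in rsns:
        if isinstance(item, tuple):
            pairs.append(item)
        else:
            pairs.append((item.rank, item.mask))
    if not pairs or len(atlas) == 0:
        raise ValidationError("need at least one RSN and one atlas unit")
    grid = pairs[0][1].grid
    for _, mask in pairs:
        if mask.grid != grid:
            raise ValidationError("RSN masks on different grids")
    if atlas.grid != grid:
        raise ValidationError("atlas grid differs from RSN grid")

    # stack unit masks once; each row is then a single vectorized AND+sum
    unit_stack = np.stack([m.values for _, m in atlas.units])  # (U, x, y, z)
    counts = np.empty((len(pairs), len(atlas)), dtype=np.int64)
    for i, (_, mask) in enumerate(pairs):
        counts[i] = (unit_stack & mask.values).sum(axis=(1, 2, 3))
    return OverlapMatrix([lbl for lbl, _ in pairs], atlas.names, counts)


def _ba_number(name: str) -> int | None:
    if name.startswith("BA") and name[2:].isdigit():
        return int(name[2:])
    return None


def regroup_brodmann(ba_atlas: ReferenceAtlas) -> ReferenceAtlas:
    """Merge small adjacent Brodmann areas into extended (starred) regions.

    Exactly the five published merges are applied (mask unions, starred
    names); every other unit passes through unchanged.  Idempotent: an atlas
    already containing a starred unit keeps it as-is.
    """
    merged_members = {
        ba: star for star, bas in BRODMANN_MERGES.items() for ba in bas
    }
    names = set(ba_atlas.names)
    missing = []
    for star, bas in BRODMANN_MERGES.items():
        if star in names:
            continue  # merge already applied
        missing.extend(f"BA{k}" for k in bas if f"BA{k}" not in names)
    if missing:
        raise ConfigurationError(
            f"cannot regroup: missing input units {sorted(missing)}"
        )

    out: list[tuple[str, BinaryMask]] = []
    done: set[str] = set()
    for name, mask in ba_atlas.units:
        num = _ba_number(name)
        if num is not None and num in merged_members:
            star = merged_members[num]
            if star in done:
                continue
            union = mask
            for k in BRODMANN_MERGES[star]:
                if f"BA{k}" != name:
                    union = union.union(ba_atlas[f"BA{k}"])
            out.append((star, union))
            done.add(star)
        else:
            out.append((name, mask))
    return ReferenceAtlas(ba_atlas.grid, out)


def brodmann_families(ba_atlas: ReferenceAtlas) -> ReferenceAtlas:
    """Group Brodmann areas into the 7 anatomo-functional families BAF1..BAF7.

    Accepts either a raw BA atlas or one already passed through
    :func:`regroup_brodmann`: a required BA number is looked up first as its
    own unit (``BA23``) and otherwise inside the starred region containing it
    (``23*``).  Areas in no family are excluded (logged).
    """
    star_of = {ba: star for star, bas in BRODMANN_MERGES.items() for ba in bas}
    names = set(ba_atlas.names)

    def unit_for(num: int) -> str | None:
        if f"BA{num}" in names:
            return f"BA{num}"
        star = star_of.get(num)
        if star is not None and star in names:
            return star
        return None

    units: list[tuple[str, BinaryMask]] = []
    used: set[str] = set()
    for baf, members in sorted(BAF_MEMBERS.items()):
        sources = []
        missing = []
        for num in members:
            src = unit_for(num)
            if src is None:
                missing.append(f"BA{num}")
            else:
                sources.append(src)
        if missing:
            raise ConfigurationError(
                f"{baf} requires missing Brodmann areas {missing}"
            )
        mask = ba_atlas[sources[0]]
        for src in sources[1:]:
            mask = mask.union(ba_atlas[src])
        used.update(sources)
        units.append((baf, mask))

    leftovers = [n for n in ba_atlas.names if n not in used]
    if leftovers:
        logger.info("Brodmann units outside every family: %s", leftovers)
    return ReferenceAtlas(ba_atlas.grid, units)
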