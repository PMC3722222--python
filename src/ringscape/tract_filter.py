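"""Filter streamlines by ring masks: keep fibers ending within a ring.

Only the termini of a streamline are tested — the first and last points —
so the result does not depend on how densely the path is sampled in
between.  A world point is inside the mask when its nearest voxel center
is true (the package-wide containment convention).  ``both`` endpoint mode
is the default reading of "fibers which end within rings"; ``either`` is
provided because the phrasing admits the looser reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import BinaryMask, Streamline

__all__ = ["FilterSummary", "filter_streamlines"]

MODES = ("both", "either")


@dataclass
class FilterSummary:
    n_input: int
    n_kept: int
    mode: str

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "mode": self.mode}


def filter_streamlines(
    lines: list[Streamline], mask: BinaryMask, mode: str = "both"
) -> tuple[list[Streamline], FilterSummary]:
    """Keep streamlines whose endpoint(s) fall in true voxels of ``mask``."""
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if not lines:
        return [], FilterSummary(0, 0, mode)
    endpoints = np.array([[l.points[0], l.points[-1]] for l in lines])
    first_in = mask.contains_points(endpoints[:, 0, :])
    last_in = mask.contains_points(endpoints[:, 1, :])
    keep = (first_in & last_in) if mode == "both" else (first_in | last_in)
    kept = [l for l, k in zip(lines, keep) if k]
    return kept, FilterSummary(len(lines), len(kept), mode)
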