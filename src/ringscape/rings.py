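"""Cortical-family assignment and ring-topology diagnostics.

The clustered RSNs fall into two families: a sensorimotor family (VSA —
visual / somatomotor / auditory) whose footprint forms one continuous ring
of alternating sectors around an associative parietal "island", and an
association family (PTF — parieto-temporo-frontal) that is discontinuous
over the cortical mantle.  RSNs whose overlap mass is balanced between the
two families, or that switch family between the functional and anatomical
clusterings, are flagged ``intermediate``.

Geometric claims are tested voxelwise on binary masks: connected-component
counts (6- or 26-connectivity), enclosure of an island by a ring within a
domain (flood-fill: the island's free component must not reach the grid
bounding-box faces), mirror symmetry about a midline axis (Dice), and the
cyclic adjacency of ordered ring sectors (minimum reportable cycle
length 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io_formats import BinaryMask
from .cluster_models import ClusteringResult
from .overlap_matrices import OverlapMatrix

__all__ = [
    "FamilyModel",
    "RingReport",
    "ClusteringView",
    "assign_families",
    "footprint_continuity",
    "enclosure_test",
    "symmetry_score",
    "sector_cycle",
    "find_sector_cycle",
    "ring_report",
]

VSA = "VSA"
PTF = "PTF"
INTERMEDIATE = "intermediate"


@dataclass
class ClusteringView:
    """One clustering of the RSNs with the matrix it was computed from and
    the subset of reference units flagged sensorimotor."""

    name: str
    clustering: ClusteringResult
    matrix: OverlapMatrix
    sensory_units: set[str]

    def __post_init__(self) -> None:
        unknown = self.sensory_units - set(self.matrix.col_labels)
        if unknown:
            raise ValidationError(
                f"view {self.name!r}: sensory units not in matrix: {sorted(unknown)}"
            )


@dataclass
class FamilyModel:
    """Cluster- and RSN-level family labels plus per-RSN balance scores."""

    family_of_cluster: dict[tuple[str, int], str]
    rsn_family: dict[str, str]
    balance_scores: dict[str, float]
    margin: float = 0.30

    @property
    def intermediate_rsns(self) -> list[str]:
        return sorted(
            (r for r, f in self.rsn_family.items() if f == INTERMEDIATE),
            key=_label_key,
        )

    @property
    def n_specialized(self) -> int:
        return sum(f != INTERMEDIATE for f in self.rsn_family.values())


def _label_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


def _sensory_fraction(counts_row: np.ndarray, sensory_idx: np.ndarray) -> float:
    total = counts_row.sum()
    if total == 0:
        return 0.5  # no overlap mass: maximally ambiguous
    return float(counts_row[sensory_idx].sum() / total)


def assign_families(views: list[ClusteringView], margin: float = 0.30) -> FamilyModel:
    """Label clusters and RSNs as VSA / PTF / intermediate across views.

    Within each view a cluster is VSA when the majority of its rows' overlap
    mass lies on sensory-flagged units, else PTF.  An RSN is intermediate
    when its own sensory-vs-association mass fractions differ by less than
    ``margin`` in some view, or when two views put its cluster in different
    families.  Family labels are invariant to cluster-id permutation.
    """
    if len(views) < 2:
        raise ValidationError("need at least two clustering views")
    rsn_sets = [set(v.clustering.assignment) for v in views]
    if any(s != rsn_sets[0] for s in rsn_sets[1:]):
        raise ValidationError("views cover different RSN sets")
    rsns = sorted(rsn_sets[0], key=_label_key)

    family_of_cluster: dict[tuple[str, int], str] = {}
    per_view_family: dict[str, list[str]] = {r: [] for r in rsns}
    balance: dict[str, float] = {r: np.inf for r in rsns}

    for view in views:
        cols = view.matrix.col_labels
        sensory_idx = np.array(
            [i for i, c in enumerate(cols) if c in view.sensory_units], dtype=int
        )
        row_of = {str(lbl): i for i, lbl in enumerate(view.matrix.row_labels)}
        missing = [r for r in rsns if r not in row_of]
        if missing:
            raise ValidationError(
                f"view {view.name!r}: matrix lacks rows {missing}"
            )
        counts = view.matrix.counts
        for cid in sorted(set(view.clustering.assignment.values())):
            members = view.clustering.members(cid)
            mass = counts[[row_of[m] for m in members]].sum(axis=0)
            frac = _sensory_fraction(mass, sensory_idx)
            family_of_cluster[(view.name, cid)] = VSA if frac > 0.5 else PTF
        for r in rsns:
            fam = family_of_cluster[(view.name, view.clustering.assignment[r])]
            per_view_family[r].append(fam)
            f = _sensory_fraction(counts[row_of[r]], sensory_idx)
            balance[r] = min(balance[r], abs(2 * f - 1))

    rsn_family: dict[str, str] = {}
    for r in rsns:
        discordant = len(set(per_view_family[r])) > 1
        if discordant or balance[r] < margin:
            rsn_family[r] = INTERMEDIATE
        else:
            rsn_family[r] = per_view_family[r][0]
    return FamilyModel(family_of_cluster, rsn_family, balance, margin)


# ---------------------------------------------------------------------------
# voxel topology


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValidationError("connectivity must be 6 or 26")


def footprint_continuity(mask: BinaryMask, connectivity: int = 6) -> int:
    """Number of connected components of the mask."""
    if mask.size == 0:
        raise ValidationError("empty mask has no components")
    _, n = ndimage.label(mask.values, structure=_structure(connectivity))
    return int(n)


def enclosure_test(
    vsa: BinaryMask, island: BinaryMask, domain: BinaryMask, connectivity: int = 6
) -> bool:
    """Is the island sealed off from the domain boundary by the ring?

    True iff the connected component of ``domain \\ vsa`` containing the
    island never reaches the domain's boundary, where the boundary is the
    set of domain voxels lying on the grid bounding-box faces.  With a
    flat-slab domain inset along z this reproduces the sheet intuition: an
    unbroken annulus encloses its center, a breached one does not.
    """
    if vsa.grid != island.grid or vsa.grid != domain.grid:
        raise ValidationError("masks live on different grids")
    if (vsa.values & island.values).any():
        raise ValidationError("island overlaps the ring mask")
    if island.size == 0:
        raise ValidationError("empty island")
    free = domain.values & ~vsa.values
    labels, _ = ndimage.label(free, structure=_structure(connectivity))
    island_labels = set(np.unique(labels[island.values])) - {0}
    if not island_labels:
        raise ValidationError("island lies outside the free domain")

    faces = np.zeros(domain.grid.shape, dtype=bool)
    for ax in range(3):
        sl0 = [slice(None)] * 3
        sl0[ax] = 0
        sl1 = [slice(None)] * 3
        sl1[ax] = -1
        faces[tuple(sl0)] = True
        faces[tuple(sl1)] = True
    boundary_labels = set(np.unique(labels[faces & domain.values])) - {0}
    return not (island_labels & boundary_labels)


def symmetry_score(mask: BinaryMask, midline_axis: int = 0) -> float:
    """Dice overlap between a mask and its mirror about the axis mid-plane."""
    if not 0 <= midline_axis <= 2:
        raise ValidationError("midline_axis must be 0, 1 or 2")
    if mask.size == 0:
        raise ValidationError("empty mask has undefined symmetry")
    mirrored = np.flip(mask.values, axis=midline_axis)
    inter = np.count_nonzero(mask.values & mirrored)
    return 2.0 * inter / (mask.size + int(mirrored.sum()))


def _adjacent(a: BinaryMask, b: BinaryMask, connectivity: int) -> bool:
    dil = ndimage.binary_dilation(a.values, structure=_structure(connectivity))
    return bool((dil & b.values).any())


def sector_cycle(
    sectors: list[tuple[str, BinaryMask]], connectivity: int = 6
) -> list[str]:
    """Validate that the given sector order closes into a cycle.

    Returns the ordering iff every consecutive pair (including last-first)
    is voxel-adjacent and there are at least 3 sectors; otherwise [].
    """
    names = [n for n, _ in sectors]
    for i, (_, a) in enumerate(sectors):
        for _, b in sectors[i + 1 :]:
            if (a.values & b.values).any():
                raise ValidationError("sectors overlap")
    if len(sectors) < 3:
        return []
    for i in range(len(sectors)):
        a = sectors[i][1]
        b = sectors[(i + 1) % len(sectors)][1]
        if not _adjacent(a, b, connectivity):
            return []
    return names


def find_sector_cycle(
    sectors: list[tuple[str, BinaryMask]], connectivity: int = 6
) -> list[str]:
    """Derive a cyclic ordering from sector adjacency, if one exists.

    The sectors form a ring exactly when their adjacency graph is a single
    cycle (connected, every sector adjacent to exactly two others); the
    traversal order is then returned, starting from the first sector.
    """
    if len(sectors) < 3:
        return []
    adj: dict[str, set[str]] = {n: set() for n, _ in sectors}
    for i, (na, a) in enumerate(sectors):
        for nb, b in sectors[i + 1 :]:
            if (a.values & b.values).any():
                raise ValidationError("sectors overlap")
            if _adjacent(a, b, connectivity):
                adj[na].add(nb)
                adj[nb].add(na)
    if any(len(nbrs) != 2 for nbrs in adj.values()):
        return []
    start = sectors[0][0]
    order = [start]
    prev, cur = None, start
    while True:
        nxt = sorted(adj[cur] - ({prev} if prev else set()))[0]
        if nxt == start:
            break
        order.append(nxt)
        prev, cur = cur, nxt
        if len(order) > len(sectors):
            return []
    return order if len(order) == len(sectors) else []


@dataclass
class RingReport:
    """Topological diagnostics of the two family footprints."""

    n_components_vsa: int
    n_components_ptf: int
    enclosure_found: bool
    sector_cycle: list[str]
    symmetry: dict[str, float]
    connectivity: int = 6

    def to_dict(self) -> dict:
        return {
            "n_components_vsa": self.n_components_vsa,
            "n_components_ptf": self.n_components_ptf,
            "enclosure_found": self.enclosure_found,
            "sector_cycle": list(self.sector_cycle),
            "symmetry": dict(self.symmetry),
            "connectivity": self.connectivity,
        }


def ring_report(
    vsa_mask: BinaryMask,
    ptf_mask: BinaryMask,
    island: BinaryMask,
    domain: BinaryMask,
    sectors: list[tuple[str, BinaryMask]],
    connectivity: int = 6,
    midline_axis: int = 0,
) -> RingReport:
    """Assemble the full topological report for two family footprints."""
    return RingReport(
        n_components_vsa=footprint_continuity(vsa_mask, connectivity),
        n_components_ptf=footprint_continuity(ptf_mask, connectivity),
        enclosure_found=enclosure_test(vsa_mask, island, domain, connectivity),
        sector_cycle=find_sector_cycle(sectors, connectivity),
        symmetry={
            VSA: symmetry_score(vsa_mask, midline_axis),
            PTF: symmetry_score(ptf_mask, midline_axis),
        },
        connectivity=connectivity,
    )
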