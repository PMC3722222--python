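"""Group RSN extraction: cluster spatial components across subjects.

Two-step group identification: per-subject spatial ICA (see
:mod:`ringscape.subject_ica`) produces component maps; here those maps are
agglomerated across subjects by average-linkage hierarchical clustering on
(1 - Pearson similarity).  Each resulting class is scored by its
representativeness R — the fraction of subjects contributing a component —
and classes with R above a threshold (default 10%) are retained as the
group's RSNs, ranked by decreasing R.  A class's group map is the voxelwise
one-sample t statistic over its member z-maps, thresholded by
Benjamini-Hochberg FDR into a binary mask.

RSN sets extracted from two populations can be matched greedily by mask
overlap; the per-pair similarity rate is the Jaccard index in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import StatisticsError, ValidationError
from .io_formats import BinaryMask
from .subject_ica import ComponentMap

__all__ = [
    "RsnClass",
    "MatchResult",
    "spatial_similarity",
    "cluster_components",
    "select_representative",
    "group_tmap",
    "match_populations",
    "extract_group_rsns",
]


@dataclass
class RsnClass:
    """A cross-subject class of component maps (candidate RSN)."""

    members: dict[str, ComponentMap]
    n_subjects: int
    creation_index: int
    components: list[ComponentMap] = field(default_factory=list)
    tmap: np.ndarray | None = None
    mask: BinaryMask | None = None
    rank: int | None = None

    @property
    def representativeness(self) -> float:
        return len(self.members) / self.n_subjects

    @property
    def mask_size(self) -> int:
        return self.mask.size if self.mask is not None else 0


def spatial_similarity(a: ComponentMap, b: ComponentMap) -> float:
    """Pearson correlation of two z-maps over the shared brain mask."""
    if a.mask.grid != b.mask.grid or not np.array_equal(a.mask.values, b.mask.values):
        raise ValidationError("component maps have different grids or brain masks")
    va, vb = a.in_brain, b.in_brain
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        raise ValidationError("constant map has undefined spatial similarity")
    return float(np.corrcoef(va, vb)[0, 1])


def _zmap_matrix(components: list[ComponentMap]) -> np.ndarray:
    ref = components[0].mask
    for c in components:
        if c.mask.grid != ref.grid or not np.array_equal(c.mask.values, ref.values):
            raise ValidationError("components do not share one brain mask")
    return np.stack([c.in_brain for c in components])


def cluster_components(
    components: list[ComponentMap], cut_similarity: float = 0.25
) -> list[RsnClass]:
    """Average-linkage agglomeration of all subjects' maps into classes.

    The tree is cut where linkage distance exceeds ``1 - cut_similarity``.
    Every component belongs to exactly one pre-threshold class; when a
    subject contributes several components to a class, only the one most
    similar to the class centroid counts as the subject's membership.
    """
    if not components:
        raise ValidationError("no components to cluster")
    subjects = sorted({c.subject_id for c in components})
    if len(subjects) < 2:
        raise ValidationError("need components from at least 2 subjects")
    if not 0.0 < cut_similarity < 1.0:
        raise ValidationError("cut_similarity must be in (0, 1)")

    Z = _zmap_matrix(components)
    if len(components) == 1:
        labels = np.array([1])
    else:
        sim = np.corrcoef(Z)
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        tree = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(tree, t=1.0 - cut_similarity, criterion="distance")

    classes: list[RsnClass] = []
    for idx, lab in enumerate(sorted(set(labels))):
        sel = np.flatnonzero(labels == lab)
        comps = [components[i] for i in sel]
        centroid = Z[sel].mean(axis=0)
        members: dict[str, ComponentMap] = {}
        best: dict[str, float] = {}
        for comp, row in zip(comps, Z[sel]):
            c_sd = row.std()
            score = (
                float(np.corrcoef(row, centroid)[0, 1])
                if c_sd > 0 and centroid.std() > 0
                else -np.inf
            )
            if score > best.get(comp.subject_id, -np.inf):
                best[comp.subject_id] = score
                members[comp.subject_id] = comp
        classes.append(
            RsnClass(
                members=members,
                n_subjects=len(subjects),
                creation_index=idx,
                components=comps,
            )
        )
    return classes


def select_representative(
    classes: list[RsnClass], n_subjects: int, min_R: float = 0.10
) -> list[RsnClass]:
    """Retain classes with R >= ``min_R`` and rank them by decreasing R.

    Ties break by larger mask size, then lower class creation index.
    """
    if not 0.0 < min_R <= 1.0:
        raise ValidationError("min_R must be in (0, 1]")
    for cls in classes:
        cls.n_subjects = n_subjects
    kept = [c for c in classes if c.representativeness >= min_R]
    kept.sort(key=lambda c: (-c.representativeness, -c.mask_size, c.creation_index))
    for rank, cls in enumerate(kept, start=1):
        cls.rank = rank
    return kept


def group_tmap(cls: RsnClass, q: float = 0.05) -> BinaryMask:
    """One-sample t over member z-maps, BH-FDR thresholded at level ``q``.

    One-sided alternative (mean > 0).  Zero-variance voxels are handled
    deterministically: p = 0 when the mean is strictly positive, p = 0.5 at
    zero, p = 1 when negative — so noiseless fixtures threshold sensibly.
    Stores the t-map and the surviving-voxel mask on the class.
    """
    if len(cls.members) < 2:
        raise StatisticsError("group t-map needs at least 2 member maps")
    maps = list(cls.members.values())
    brain = maps[0].mask
    Z = np.stack([m.in_brain for m in maps])
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)

    t = np.zeros_like(mean)
    p = np.ones_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = stats.t.sf(t[ok], df=n - 1)
    degen = ~ok
    t[degen & (mean > 0)] = np.inf
    p[degen & (mean > 0)] = 0.0
    p[degen & (mean == 0)] = 0.5
    p[degen & (mean < 0)] = 1.0

    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")

    tvol = np.zeros(brain.grid.shape)
    tvol[brain.values] = t
    mvol = np.zeros(brain.grid.shape, dtype=bool)
    mvol[brain.values] = reject
    cls.tmap = tvol
    cls.mask = BinaryMask(brain.grid, mvol)
    return cls.mask


@dataclass
class MatchResult:
    """Greedy one-to-one matching of two ranked RSN sets."""

    pairs: list[tuple[int, int, float]]  # (rankA, rankB, Jaccard %)
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def mean_rate(self) -> float:
        return float(np.mean([r for _, _, r in self.pairs])) if self.pairs else 0.0


def match_populations(rsnsA: list[RsnClass], rsnsB: list[RsnClass]) -> MatchResult:
    """Match two populations' RSNs by decreasing mask Jaccard overlap."""
    if not rsnsA or not rsnsB:
        raise ValidationError("both RSN lists must be non-empty")
    grid = rsnsA[0].mask.grid
    for cls in rsnsA + rsnsB:
        if cls.mask is None:
            raise ValidationError("all RSNs must carry thresholded masks")
        if cls.mask.grid != grid:
            raise ValidationError("populations live on different grids")

    jac = np.zeros((len(rsnsA), len(rsnsB)))
    for i, a in enumerate(rsnsA):
        for j, b in enumerate(rsnsB):
            inter = np.count_nonzero(a.mask.values & b.mask.values)
            union = np.count_nonzero(a.mask.values | b.mask.values)
            jac[i, j] = inter / union if union else 0.0

    order = np.dstack(np.unravel_index(np.argsort(-jac, axis=None), jac.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i, j in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        pairs.append((rsnsA[i].rank, rsnsB[j].rank, 100.0 * jac[i, j]))
        if len(used_a) == len(rsnsA) or len(used_b) == len(rsnsB):
            break
    unmatched_a = [c.rank for k, c in enumerate(rsnsA) if k not in used_a]
    unmatched_b = [c.rank for k, c in enumerate(rsnsB) if k not in used_b]
    return MatchResult(pairs, unmatched_a, unmatched_b)


def extract_group_rsns(
    components: list[ComponentMap],
    n_subjects: int,
    cut_similarity: float = 0.25,
    min_R: float = 0.10,
    q: float = 0.05,
) -> list[RsnClass]:
    """End-to-end step 2: cluster, threshold the multi-member classes, rank."""
    classes = cluster_components(components, cut_similarity)
    for cls in classes:
        if len(cls.members) >= 2:
            group_tmap(cls, q)
    return select_representative(classes, n_subjects, min_R)
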