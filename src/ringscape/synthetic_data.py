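"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators cover the whole pipeline:

* :func:`make_phantom_atlas` — a toy cortical parcellation in which one
  family of parcels forms a closed ring of adjacent sectors enclosing an
  "island" parcel, while a second family is spatially scattered.  This is
  the planted analogue of the dual-ring corticotopy (a contiguous
  sensorimotor ring vs. a discontinuous association family).
* :func:`simulate_subjects` — multi-subject 4D series in which each planted
  network (a spatial footprint) appears in a Bernoulli-sampled fraction of
  subjects, contributing footprint x random time course x amplitude on top
  of i.i.d. Gaussian noise.  The exact inclusion table is returned so that
  group-level recovery has a target.
* :func:`fixture_overlap_matrix` — integer overlap-count matrices with a
  planted block structure (Poisson ``high_mean`` inside a cluster's column
  signature, ``low_mean`` outside).

The package also bundles three reference cluster-membership tables for the
30 cortical resting-state networks — as grouped by their overlap with task
based networks (``tbn``), with 28 extended Brodmann areas (``ba``) and with
the 7 Brodmann-area families (``baf``) — accessible through
:func:`load_membership_table` and :func:`build_reference_fixture`.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import BinaryMask, ReferenceAtlas, VolumeGrid
from .overlap_matrices import OverlapMatrix

__all__ = [
    "NetworkSpec",
    "MembershipTable",
    "RingLayout",
    "make_phantom_atlas",
    "phantom_domain",
    "phantom_families",
    "phantom_network_specs",
    "simulate_subjects",
    "fixture_overlap_matrix",
    "load_membership_table",
    "build_reference_fixture",
    "SENSORY_MODALITIES",
]

SENSORY_MODALITIES = frozenset({"visual", "somatomotor", "auditory"})


@dataclass(frozen=True)
class NetworkSpec:
    """A planted network: spatial footprint, population prevalence, amplitude."""

    name: str
    footprint: BinaryMask
    prevalence: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.footprint.size == 0:
            raise ValidationError(f"network {self.name!r} has an empty footprint")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")


@dataclass
class MembershipTable:
    """Named clusters of RSN labels, with a modality tag per cluster.

    ``columns`` optionally pins each cluster to an explicit set of reference
    columns for :func:`fixture_overlap_matrix` (required when clusters
    outnumber columns, where disjoint blocks are impossible).
    Duplicated rows (a label in two clusters) are kept and flagged, never
    silently dropped.
    """

    clusters: dict[int, list[str]]
    modality: dict[int, str] = field(default_factory=dict)
    columns: dict[int, list[str]] = field(default_factory=dict)

    @property
    def rows(self) -> list[str]:
        seen: dict[str, None] = {}
        for members in self.clusters.values():
            for m in members:
                seen.setdefault(m, None)
        return list(seen)

    @property
    def duplicates(self) -> dict[str, list[int]]:
        where: dict[str, list[int]] = {}
        for cid, members in self.clusters.items():
            for m in members:
                where.setdefault(m, []).append(cid)
        return {m: cids for m, cids in where.items() if len(cids) > 1}

    def resolve(self, resolution: dict[str, int] | None = None) -> "MembershipTable":
        """Return a duplicate-free table, keeping each flagged row only in the
        cluster named by ``resolution``."""
        dups = self.duplicates
        if not dups:
            return self
        resolution = resolution or {}
        unresolved = sorted(set(dups) - set(resolution))
        if unresolved:
            raise ValidationError(
                f"rows present in several clusters with no resolution: {unresolved}"
            )
        clusters = {
            cid: [
                m
                for m in members
                if m not in dups or resolution[m] == cid
            ]
            for cid, members in self.clusters.items()
        }
        return MembershipTable(clusters, dict(self.modality), dict(self.columns))

    def assignment(self) -> dict[str, int]:
        """label -> cluster id; raises if duplicates are unresolved."""
        if self.duplicates:
            raise ValidationError(
                f"unresolved duplicate rows: {sorted(self.duplicates)}"
            )
        return {
            m: cid for cid, members in self.clusters.items() for m in members
        }


# ---------------------------------------------------------------------------
# phantom atlas


@dataclass(frozen=True)
class RingLayout:
    """Geometry of the toy parcellation (all lengths in voxels).

    The ring is an annulus in the (x, y) plane split into ``n_sectors``
    angular sectors, confined to the z slab ``[z_min, z_max]``; the island
    fills the annulus hole; scattered parcels sit in mirror-symmetric pairs
    outside the ring.  The x mid-plane is the symmetry axis.
    """

    n_sectors: int = 6
    inner_radius: float = 4.0
    outer_radius: float = 7.0
    island_radius: float = 2.0
    n_scattered: int = 2
    scattered_radius: float = 1.3
    z_min: int = 0
    z_max: int | None = None  # inclusive; None -> last slice


def make_phantom_atlas(
    grid: VolumeGrid, layout: RingLayout = RingLayout(), seed: int = 0
) -> ReferenceAtlas:
    """Build the ring/island/scattered toy parcellation on ``grid``.

    Deterministic given the layout (the seed is accepted for interface
    uniformity with the other generators).  Parcels are pairwise disjoint;
    ring sectors form a single cycle of pairwise face-adjacent parcels
    enclosing the island; scattered parcels are mutually non-adjacent.
    """
    nx, ny, nz = grid.shape
    z_max = layout.z_max if layout.z_max is not None else nz - 1
    if not (0 <= layout.z_min <= z_max < nz):
        raise ConfigurationError("z slab outside the grid")
    if layout.n_sectors == 1 and layout.n_scattered == 0 and layout.island_radius <= 0:
        # degenerate single-parcel layout covering the whole grid
        full = np.ones(grid.shape, dtype=bool)
        return ReferenceAtlas(grid, [("sector1", BinaryMask(grid, full))])
    if layout.n_sectors < 3:
        raise ConfigurationError("a ring needs at least 3 sectors")
    if not layout.inner_radius < layout.outer_radius:
        raise ConfigurationError("inner radius must be below outer radius")
    if not layout.island_radius < layout.inner_radius - 1:
        raise ConfigurationError("island must be separated from the ring")

    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.hypot(ii - cx, jj - cy)
    theta = np.mod(np.arctan2(jj - cy, ii - cx), 2 * np.pi)
    in_slab = np.zeros(nz, dtype=bool)
    in_slab[layout.z_min : z_max + 1] = True

    def extrude(plane: np.ndarray) -> np.ndarray:
        vol = np.zeros(grid.shape, dtype=bool)
        vol[:, :, in_slab] = plane[:, :, None]
        return vol

    units: list[tuple[str, BinaryMask]] = []
    annulus = (r >= layout.inner_radius) & (r <= layout.outer_radius)
    sector_idx = np.floor(theta / (2 * np.pi / layout.n_sectors)).astype(int)
    sector_idx = np.clip(sector_idx, 0, layout.n_sectors - 1)
    for s in range(layout.n_sectors):
        plane = annulus & (sector_idx == s)
        vol = extrude(plane)
        if vol.sum() < 2:
            raise ConfigurationError(
                f"grid too small: ring sector {s + 1} has {int(vol.sum())} voxels"
            )
        units.append((f"sector{s + 1}", BinaryMask(grid, vol)))

    if layout.island_radius > 0:
        island = extrude(r <= layout.island_radius)
        if island.sum() < 2:
            raise ConfigurationError("grid too small for the island parcel")
        units.append(("island", BinaryMask(grid, island)))

    if layout.n_scattered:
        if layout.n_scattered % 2:
            raise ConfigurationError(
                "scattered parcels come in mirror-symmetric pairs (even count)"
            )
        centers = _scattered_centers(
            nx, ny, layout.n_scattered, layout.outer_radius, cx, cy
        )
        occupied = np.zeros((nx, ny), dtype=bool)
        occupied |= r <= layout.outer_radius
        for k, (px, py) in enumerate(centers):
            blob = np.hypot(ii - px, jj - py) <= layout.scattered_radius
            if blob.sum() < 2 or (blob & _dilate2d(occupied)).any():
                raise ConfigurationError(
                    f"no room for scattered parcel {k + 1} on this grid"
                )
            occupied |= blob
            units.append((f"scattered{k + 1}", BinaryMask(grid, extrude(blob))))

    return ReferenceAtlas(grid, units)


def _scattered_centers(nx, ny, n, outer_radius, cx, cy):
    """Mirror-symmetric pairs of blob centers in the corners of the plane."""
    corners_y = [1.5, ny - 2.5]
    centers = []
    for pair in range(n // 2):
        y = corners_y[pair % len(corners_y)]
        centers.append((1.5, y))
        centers.append((nx - 2.5, y))
    return centers[:n]


def _dilate2d(plane: np.ndarray) -> np.ndarray:
    out = plane.copy()
    out[1:, :] |= plane[:-1, :]
    out[:-1, :] |= plane[1:, :]
    out[:, 1:] |= plane[:, :-1]
    out[:, :-1] |= plane[:, 1:]
    return out


def phantom_domain(grid: VolumeGrid, layout: RingLayout = RingLayout()) -> BinaryMask:
    """The toy 'cortex' domain: the full (x, y) extent of the layout's z slab."""
    nz = grid.shape[2]
    z_max = layout.z_max if layout.z_max is not None else nz - 1
    vol = np.zeros(grid.shape, dtype=bool)
    vol[:, :, layout.z_min : z_max + 1] = True
    return BinaryMask(grid, vol)


def phantom_families(atlas: ReferenceAtlas) -> dict[str, list[str]]:
    """Planted family membership: ring sectors vs island + scattered parcels."""
    vsa = [n for n in atlas.names if n.startswith("sector")]
    ptf = [n for n in atlas.names if n.startswith(("island", "scattered"))]
    return {"VSA": vsa, "PTF": ptf}


def phantom_network_specs(
    atlas: ReferenceAtlas, prevalence: float = 0.8, amplitude: float = 1.0
) -> list[NetworkSpec]:
    """One planted network per phantom parcel, all at the same prevalence."""
    return [
        NetworkSpec(name, mask, prevalence, amplitude)
        for name, mask in atlas.units
    ]


# ---------------------------------------------------------------------------
# subject simulation


def simulate_subjects(
    networks: list[NetworkSpec],
    n_subjects: int,
    n_timepoints: int,
    noise_sd: float,
    seed: int,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Simulate per-subject 4D series and the exact network-inclusion table.

    Subject ``s`` includes network ``n`` with independent probability
    ``prevalence_n``; an included network adds
    ``amplitude * footprint x unit-variance i.i.d. normal time course``.
    Gaussian noise of sd ``noise_sd`` is added at every voxel/timepoint, so
    an amplitude-1 network on top of ``noise_sd = 1`` noise has per-voxel
    SNR (signal variance over noise variance) of 1.
    """
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    if n_timepoints < 10:
        raise ValidationError("need at least 10 timepoints")
    if not networks:
        raise ValidationError("need at least one network")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    grid = networks[0].footprint.grid
    for net in networks:
        if net.footprint.grid != grid:
            raise ValidationError(f"network {net.name!r} is on a different grid")

    rng = np.random.default_rng(seed)
    presence = pd.DataFrame(
        rng.random((n_subjects, len(networks))) < [n.prevalence for n in networks],
        index=[f"sub{s:03d}" for s in range(n_subjects)],
        columns=[n.name for n in networks],
    )
    series: list[np.ndarray] = []
    for s in range(n_subjects):
        vol = rng.normal(0.0, noise_sd, size=grid.shape + (n_timepoints,)) \
            if noise_sd > 0 else np.zeros(grid.shape + (n_timepoints,))
        for net in networks:
            if presence.iloc[s][net.name]:
                tc = rng.standard_normal(n_timepoints)
                vol[net.footprint.values, :] += net.amplitude * tc
            else:
                rng.standard_normal(n_timepoints)  # keep stream alignment
        series.append(vol)
    return series, presence


# ---------------------------------------------------------------------------
# fixture overlap matrices


def fixture_overlap_matrix(
    table: MembershipTable,
    n_columns: int,
    high_mean: float,
    low_mean: float,
    seed: int,
    resolution: dict[str, int] | None = None,
    col_names: list[str] | None = None,
) -> OverlapMatrix:
    """Block-structured Poisson counts matrix encoding planted memberships.

    Entry (r, c) ~ Poisson(``high_mean``) when column ``c`` belongs to the
    column signature of r's cluster, Poisson(``low_mean``) otherwise.  By
    default clusters receive disjoint contiguous column blocks; when the
    table pins explicit (possibly overlapping, necessarily distinct) column
    signatures via ``table.columns`` those are used instead.
    """
    if not high_mean > low_mean >= 0:
        raise ValidationError("need high_mean > low_mean >= 0")
    table = table.resolve(resolution) if table.duplicates else table
    assignment = table.assignment()
    cluster_ids = list(table.clusters)

    if table.columns:
        if col_names is None:
            seen: dict[str, None] = {}
            for cid in cluster_ids:
                for c in table.columns.get(cid, []):
                    seen.setdefault(c, None)
            col_names = list(seen)
        if len(col_names) != n_columns:
            raise ValidationError(
                f"column signatures span {len(col_names)} columns, expected {n_columns}"
            )
        col_index = {c: i for i, c in enumerate(col_names)}
        blocks = {}
        for cid in cluster_ids:
            sig = table.columns.get(cid)
            if not sig:
                raise ValidationError(f"cluster {cid} has no column signature")
            blocks[cid] = [col_index[c] for c in sig]
        signatures = [tuple(sorted(blocks[cid])) for cid in cluster_ids]
        if len(set(signatures)) != len(signatures):
            raise ValidationError("cluster column signatures must be distinct")
    else:
        if n_columns < len(cluster_ids):
            raise ValidationError(
                f"{len(cluster_ids)} clusters cannot occupy disjoint blocks of "
                f"{n_columns} columns; supply explicit column signatures"
            )
        base, extra = divmod(n_columns, len(cluster_ids))
        blocks, start = {}, 0
        for k, cid in enumerate(cluster_ids):
            width = base + (1 if k < extra else 0)
            blocks[cid] = list(range(start, start + width))
            start += width
        if col_names is None:
            mod_abbrev = {"visual": "vis", "somatomotor": "som",
                          "auditory": "aud", "association": "asc"}
            col_names = []
            for cid in cluster_ids:
                tag = mod_abbrev.get(table.modality.get(cid, ""), "unit")
                for j in blocks[cid]:
                    col_names.append(f"col{j + 1:02d}_{tag}")

    rng = np.random.default_rng(seed)
    rows = table.rows
    counts = rng.poisson(low_mean, size=(len(rows), n_columns))
    for i, row in enumerate(rows):
        for j in blocks[assignment[row]]:
            counts[i, j] = rng.poisson(high_mean)
    return OverlapMatrix(rows, list(col_names), counts)


# ---------------------------------------------------------------------------
# bundled reference fixtures

#: duplicate rows in the BAF table are kept in their singleton clusters
DEFAULT_BAF_RESOLUTION = {"18": 3, "20": 4}

_FIXTURE_COLUMNS = {"tbn": 18, "ba": 28, "baf": 7}
_BAF_COLUMN_ORDER = [f"BAF{k}" for k in range(1, 8)]
_BAF_MODALITY = {
    "BAF1": "association", "BAF2": "association", "BAF3": "association",
    "BAF4": "association", "BAF5": "auditory", "BAF6": "somatomotor",
    "BAF7": "visual",
}


def load_membership_table(which: str) -> MembershipTable:
    """Load a bundled membership table: ``tbn``, ``ba`` or ``baf``.

    The ``baf`` table is returned raw, including its two duplicated rows
    (18 and 20); resolve them with :data:`DEFAULT_BAF_RESOLUTION` or an
    explicit map.
    """
    if which not in _FIXTURE_COLUMNS:
        raise ConfigurationError(f"unknown membership table {which!r}")
    ref = resources.files("ringscape.data") / f"{which}_clusters.tsv"
    df = pd.read_csv(ref, sep="\t", dtype=str).fillna("")
    clusters, modality, columns = {}, {}, {}
    for _, row in df.iterrows():
        cid = int(row["cluster"])
        clusters[cid] = [m.strip() for m in row["members"].split(",") if m.strip()]
        modality[cid] = row["modality"]
        if row["columns"]:
            columns[cid] = [c.strip() for c in row["columns"].split(",")]
    return MembershipTable(clusters, modality, columns)


def build_reference_fixture(
    which: str,
    seed: int,
    high_mean: float = 500.0,
    low_mean: float = 10.0,
) -> tuple[OverlapMatrix, set[str], MembershipTable]:
    """Fixture matrix + sensory column set + (resolved) membership table."""
    table = load_membership_table(which)
    resolution = DEFAULT_BAF_RESOLUTION if which == "baf" else None
    col_names = _BAF_COLUMN_ORDER if which == "baf" else None
    matrix = fixture_overlap_matrix(
        table,
        _FIXTURE_COLUMNS[which],
        high_mean,
        low_mean,
        seed,
        resolution=resolution,
        col_names=col_names,
    )
    if which == "baf":
        sensory = {c for c in matrix.col_labels if _BAF_MODALITY[c] in SENSORY_MODALITIES}
    else:
        sensory = {c for c in matrix.col_labels if not c.endswith("_asc")}
    resolved = table.resolve(resolution) if table.duplicates else table
    return matrix, sensory, resolved
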