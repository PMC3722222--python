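"""End-to-end demo pipeline on the synthetic phantom.

simulate -> per-subject ICA -> group RSNs -> overlap matrices -> mixture and
community clustering -> family assignment -> ring topology -> tract filter.

Every stage takes an explicit seed derived from the config, so an identical
config yields an identical machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io_formats, rings, synthetic_data, tract_filter
from .cluster_models import (
    concordance_accuracy,
    detect_communities,
    em_mixture_cluster,
    profile_graph,
)
from .errors import ConfigurationError
from .group_rsn import extract_group_rsns
from .io_formats import BinaryMask, ReferenceAtlas, VolumeGrid
from .overlap_matrices import build_overlap_matrix
from .subject_ica import decompose_subject
from .synthetic_data import RingLayout

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the demo pipeline, with reproducible per-stage seeds."""

    grid_shape: tuple[int, int, int] = (16, 16, 8)
    z_min: int = 1
    z_max: int = 6
    n_sectors: int = 6
    n_scattered: int = 2
    n_subjects: int = 30
    n_timepoints: int = 60
    noise_sd: float = 1.0
    prevalence: float = 0.8
    amplitude: float = 1.0
    K: int = 10
    cut_similarity: float = 0.25
    min_R: float = 0.10
    q: float = 0.05
    max_components: int = 12
    restarts: int = 10
    margin: float = 0.30
    connectivity: int = 6
    n_streamlines: int = 200
    seed_simulate: int = 11
    seed_ica: int = 12
    seed_cluster: int = 13
    seed_tracts: int = 14
    write_subjects: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["grid_shape"] = list(data["grid_shape"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage; write artifacts and return the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}

    # --- simulate -----------------------------------------------------------
    t0 = _stage("simulate")
    grid = VolumeGrid(config.grid_shape, np.eye(4))
    layout = RingLayout(
        n_sectors=config.n_sectors,
        n_scattered=config.n_scattered,
        z_min=config.z_min,
        z_max=config.z_max,
    )
    atlas = synthetic_data.make_phantom_atlas(grid, layout, config.seed_simulate)
    domain = synthetic_data.phantom_domain(grid, layout)
    families = synthetic_data.phantom_families(atlas)
    networks = synthetic_data.phantom_network_specs(
        atlas, config.prevalence, config.amplitude
    )
    series, presence = synthetic_data.simulate_subjects(
        networks,
        config.n_subjects,
        config.n_timepoints,
        config.noise_sd,
        config.seed_simulate,
    )
    io_formats.write_atlas(out / "phantom_atlas", atlas)
    io_formats.write_mask(out / "domain.nii.gz", domain)
    presence.to_csv(out / "presence.tsv", sep="\t")
    if config.write_subjects:
        for sid, vol in zip(presence.index, series):
            io_formats.write_volume(out / f"{sid}.nii.gz", grid, vol)
    timers["simulate"] = time.perf_counter() - t0

    # --- per-subject ICA ----------------------------------------------------
    t0 = _stage("ica")
    brain = BinaryMask(grid, domain.values)
    components = []
    for s, (sid, vol) in enumerate(zip(presence.index, series)):
        components.extend(
            decompose_subject(
                vol, brain, config.K, config.seed_ica + s, subject_id=sid
            )
        )
    timers["ica"] = time.perf_counter() - t0

    # --- group RSNs ---------------------------------------------------------
    t0 = _stage("group")
    rsns = extract_group_rsns(
        components,
        config.n_subjects,
        cut_similarity=config.cut_similarity,
        min_R=config.min_R,
        q=config.q,
    )
    rsns = [c for c in rsns if c.mask is not None and c.mask.size > 0]
    manifest_rows = [
        {
            "rank": c.rank,
            "R": c.representativeness,
            "n_members": len(c.members),
            "mask_size": c.mask_size,
        }
        for c in rsns
    ]
    io_formats.write_report(out / "rsn_manifest.json", {"rsns": manifest_rows})
    for c in rsns:
        io_formats.write_mask(out / f"rsn_{c.rank}.nii.gz", c.mask)
    timers["group"] = time.perf_counter() - t0
    if not rsns:
        raise ConfigurationError("pipeline found no representative RSNs")

    # --- overlap matrices ---------------------------------------------------
    t0 = _stage("overlap")
    fine = build_overlap_matrix(rsns, atlas)
    coarse_units = []
    ring_union = atlas[families["VSA"][0]]
    for name in families["VSA"][1:]:
        ring_union = ring_union.union(atlas[name])
    coarse_units.append(("ring", ring_union))
    coarse_units.append(("island", atlas["island"]))
    scattered = [n for n in families["PTF"] if n.startswith("scattered")]
    if scattered:
        sc_union = atlas[scattered[0]]
        for name in scattered[1:]:
            sc_union = sc_union.union(atlas[name])
        coarse_units.append(("scattered", sc_union))
    coarse_atlas = ReferenceAtlas(grid, coarse_units)
    coarse = build_overlap_matrix(rsns, coarse_atlas)
    fine.to_dataframe().to_csv(out / "rsn_x_parcel.tsv", sep="\t")
    coarse.to_dataframe().to_csv(out / "rsn_x_family.tsv", sep="\t")
    timers["overlap"] = time.perf_counter() - t0

    # --- clustering ---------------------------------------------------------
    t0 = _stage("cluster")
    max_k = min(config.max_components, fine.counts.shape[0])
    em_fine = em_mixture_cluster(fine, max_k, config.restarts, config.seed_cluster)
    em_coarse = em_mixture_cluster(coarse, max_k, config.restarts, config.seed_cluster)
    graph = profile_graph(fine)
    communities = detect_communities(graph)
    concordance = concordance_accuracy(em_fine, communities)
    timers["cluster"] = time.perf_counter() - t0

    # --- families + ring topology ------------------------------------------
    t0 = _stage("rings")
    sensory_fine = set(families["VSA"])
    view_fine = rings.ClusteringView("parcels", em_fine, fine, sensory_fine)
    view_coarse = rings.ClusteringView("families", em_coarse, coarse, {"ring"})
    model = rings.assign_families([view_fine, view_coarse], config.margin)

    def union_mask(ranks: list[str]) -> BinaryMask | None:
        sel = [c for c in rsns if str(c.rank) in ranks]
        if not sel:
            return None
        m = sel[0].mask
        for c in sel[1:]:
            m = m.union(c.mask)
        return m

    vsa_ranks = [r for r, f in model.rsn_family.items() if f == rings.VSA]
    ptf_ranks = [r for r, f in model.rsn_family.items() if f == rings.PTF]
    vsa_mask = union_mask(vsa_ranks)
    ptf_mask = union_mask(ptf_ranks)
    sectors = [(n, atlas[n]) for n in families["VSA"]]

    planted_vsa = ring_union
    planted_ptf = atlas[families["PTF"][0]]
    for name in families["PTF"][1:]:
        planted_ptf = planted_ptf.union(atlas[name])
    planted_report = rings.ring_report(
        planted_vsa, planted_ptf, atlas["island"], domain, sectors,
        config.connectivity,
    )
    recovered_report = None
    if vsa_mask is not None and ptf_mask is not None:
        island_free = BinaryMask(grid, atlas["island"].values & ~vsa_mask.values)
        if island_free.size:
            recovered_report = rings.RingReport(
                n_components_vsa=rings.footprint_continuity(
                    vsa_mask, config.connectivity
                ),
                n_components_ptf=rings.footprint_continuity(
                    ptf_mask, config.connectivity
                ),
                enclosure_found=rings.enclosure_test(
                    vsa_mask, island_free, domain, config.connectivity
                ),
                sector_cycle=rings.find_sector_cycle(sectors, config.connectivity),
                symmetry={
                    rings.VSA: rings.symmetry_score(vsa_mask),
                    rings.PTF: rings.symmetry_score(ptf_mask),
                },
                connectivity=config.connectivity,
            )
        io_formats.write_mask(out / "family_vsa.nii.gz", vsa_mask)
        io_formats.write_mask(out / "family_ptf.nii.gz", ptf_mask)
    timers["rings"] = time.perf_counter() - t0

    # --- tracts -------------------------------------------------------------
    t0 = _stage("tracts")
    rng = np.random.default_rng(config.seed_tracts)
    domain_idx = np.argwhere(domain.values)
    picks = rng.integers(0, len(domain_idx), size=(config.n_streamlines, 2))
    lines = []
    for a, b in picks:
        p0 = grid.voxel_to_world(domain_idx[a])[0]
        p1 = grid.voxel_to_world(domain_idx[b])[0]
        if np.all(p0 == p1):
            continue
        mid = (p0 + p1) / 2 + rng.normal(0, 0.1, 3)
        lines.append(io_formats.Streamline(np.vstack([p0, mid, p1])))
    tract_counts = {}
    for fam_name, fam_mask in (("VSA", planted_vsa), ("PTF", planted_ptf)):
        _, summary = tract_filter.filter_streamlines(lines, fam_mask, mode="both")
        tract_counts[fam_name] = summary.to_dict()
    io_formats.write_streamlines(out / "tracts.trk", lines, grid)
    timers["tracts"] = time.perf_counter() - t0

    summary = {
        "config_digest": config.digest(),
        "n_components_total": len(components),
        "n_retained_rsns": len(rsns),
        "rsn_manifest": manifest_rows,
        "n_clusters_parcels": em_fine.n_clusters,
        "n_clusters_families": em_coarse.n_clusters,
        "n_communities": communities.n_communities,
        "modularity_q": communities.modularity_q,
        "concordance_accuracy": concordance.accuracy,
        "rsn_family": model.rsn_family,
        "intermediate_rsns": model.intermediate_rsns,
        "ring_report_planted": planted_report.to_dict(),
        "ring_report_recovered": (
            recovered_report.to_dict() if recovered_report else None
        ),
        "tract_counts": tract_counts,
    }
    io_formats.write_report(out / "summary.json", summary)
    manifest = {
        "parameters": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "stage_seconds": {k: round(v, 3) for k, v in timers.items()},
    }
    io_formats.write_report(out / "manifest.json", manifest)
    return summary
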