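import numpy as np
import pytest

from conftest import random_mask
from oracles import connected_components_bfs
from ringscape import rings
from ringscape.cluster_models import ClusteringResult
from ringscape.errors import ValidationError
from ringscape.io_formats import BinaryMask, VolumeGrid
from ringscape.overlap_matrices import OverlapMatrix
from ringscape.synthetic_data import build_reference_fixture


def clustering_from_table(table):
    assign = {m: cid for cid, members in table.clusters.items() for m in members}
    return ClusteringResult(
        assign, len(table.clusters), np.zeros((len(assign), 1)), 0.0, list(assign)
    )


def reference_views(seed=1):
    views = []
    for which in ("tbn", "ba", "baf"):
        matrix, sensory, table = build_reference_fixture(which, seed=seed)
        views.append(
            rings.ClusteringView(
                which, clustering_from_table(table), matrix, sensory
            )
        )
    return views


class TestAssignFamilies:
    def test_reference_memberships_reproduce_published_split(self):
        model = rings.assign_families(reference_views())
        assert model.intermediate_rsns == ["1", "23", "27"]
        assert model.n_specialized == 27
        # and the published family sense: sensory TBN clusters are VSA
        assert model.family_of_cluster[("tbn", 1)] == rings.VSA
        assert model.family_of_cluster[("tbn", 6)] == rings.PTF
        assert model.rsn_family["2"] == rings.VSA
        assert model.rsn_family["13"] == rings.PTF

    def test_all_sensory_views_give_all_vsa(self):
        rows = ["1", "2", "3"]
        m = OverlapMatrix(rows, ["vis", "aud"], np.array([[9, 1], [8, 2], [7, 3]]))
        cr = ClusteringResult({r: 1 for r in rows}, 1, np.zeros((3, 1)), 0.0, rows)
        views = [
            rings.ClusteringView("a", cr, m, {"vis", "aud"}),
            rings.ClusteringView("b", cr, m, {"vis", "aud"}),
        ]
        model = rings.assign_families(views)
        assert all(f == rings.VSA for f in model.rsn_family.values())
        assert model.intermediate_rsns == []

    def test_cluster_id_permutation_invariance(self):
        views1 = reference_views()
        model1 = rings.assign_families(views1)
        views2 = reference_views()
        # permute cluster ids in the first view
        cr = views2[0].clustering
        perm = {cid: 100 - cid for cid in set(cr.assignment.values())}
        views2[0].clustering = ClusteringResult(
            {r: perm[c] for r, c in cr.assignment.items()},
            cr.n_clusters,
            cr.responsibilities,
            cr.log_evidence,
            cr.row_labels,
        )
        model2 = rings.assign_families(views2)
        assert model1.rsn_family == model2.rsn_family

    def test_balanced_row_is_intermediate_by_margin(self):
        rows = ["1", "2"]
        counts = np.array([[50, 50], [95, 5]])  # row 1 perfectly balanced
        m = OverlapMatrix(rows, ["vis", "asc"], counts)
        cr = ClusteringResult({"1": 1, "2": 1}, 1, np.zeros((2, 1)), 0.0, rows)
        views = [
            rings.ClusteringView("a", cr, m, {"vis"}),
            rings.ClusteringView("b", cr, m, {"vis"}),
        ]
        model = rings.assign_families(views, margin=0.30)
        assert model.rsn_family["1"] == rings.INTERMEDIATE
        assert model.rsn_family["2"] == rings.VSA

    def test_mismatched_rsn_sets_rejected(self):
        views = reference_views()
        bad = views[1].clustering.assignment.copy()
        bad.pop("1")
        views[1].clustering = ClusteringResult(
            bad, 7, np.zeros((29, 1)), 0.0, list(bad)
        )
        with pytest.raises(ValidationError):
            rings.assign_families(views)


class TestFootprintContinuity:
    def test_solid_block_is_one_component(self):
        grid = VolumeGrid((5, 5, 3), np.eye(4))
        vol = np.zeros(grid.shape, dtype=bool)
        vol[1:4, 1:4, 1] = True
        assert rings.footprint_continuity(BinaryMask(grid, vol)) == 1

    def test_gap_splits_under_6_connectivity(self):
        grid = VolumeGrid((7, 5, 3), np.eye(4))
        vol = np.zeros(grid.shape, dtype=bool)
        vol[0:2, 1:4, 1] = True
        vol[3:5, 1:4, 1] = True
        assert rings.footprint_continuity(BinaryMask(grid, vol), 6) == 2

    def test_diagonal_touch_merges_only_under_26(self):
        grid = VolumeGrid((4, 4, 3), np.eye(4))
        vol = np.zeros(grid.shape, dtype=bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        mask = BinaryMask(grid, vol)
        assert rings.footprint_continuity(mask, 6) == 2
        assert rings.footprint_continuity(mask, 26) == 1

    def test_matches_flood_fill_oracle_on_random_masks(self, small_grid):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = random_mask(small_grid, rng, density=0.35)
            if mask.size == 0:
                continue
            for conn in (6, 26):
                assert rings.footprint_continuity(mask, conn) == \
                    connected_components_bfs(mask.values, conn)

    def test_phantom_family_unions(self, phantom):
        _, _, atlas, _ = phantom
        vsa = atlas["sector1"]
        for n in [f"sector{k}" for k in range(2, 7)]:
            vsa = vsa.union(atlas[n])
        ptf = atlas["island"].union(atlas["scattered1"]).union(atlas["scattered2"])
        assert rings.footprint_continuity(vsa, 6) == 1
        assert rings.footprint_continuity(ptf, 6) >= 2

    def test_empty_mask_rejected(self, small_grid):
        empty = BinaryMask(small_grid, np.zeros(small_grid.shape, dtype=bool))
        with pytest.raises(ValidationError):
            rings.footprint_continuity(empty)


def annulus_scene(breach=False):
    grid = VolumeGrid((11, 11, 5), np.eye(4))
    ii, jj = np.meshgrid(np.arange(11), np.arange(11), indexing="ij")
    r = np.hypot(ii - 5, jj - 5)
    ring2d = (r >= 2.5) & (r <= 4.5)
    if breach:
        ring2d[5, 7:10] = False
    ring = np.zeros(grid.shape, dtype=bool)
    ring[:, :, 1:4] = ring2d[:, :, None]
    blob = np.zeros(grid.shape, dtype=bool)
    blob[5, 5, 1:4] = True
    domain = np.zeros(grid.shape, dtype=bool)
    domain[:, :, 1:4] = True
    return (
        BinaryMask(grid, ring),
        BinaryMask(grid, blob),
        BinaryMask(grid, domain),
    )


class TestEnclosure:
    def test_annulus_encloses_center(self):
        ring, blob, domain = annulus_scene()
        assert rings.enclosure_test(ring, blob, domain) is True

    def test_breached_annulus_does_not(self):
        ring, blob, domain = annulus_scene(breach=True)
        assert rings.enclosure_test(ring, blob, domain) is False

    def test_phantom_ring_encloses_island(self, phantom):
        _, _, atlas, domain = phantom
        vsa = atlas["sector1"]
        for n in [f"sector{k}" for k in range(2, 7)]:
            vsa = vsa.union(atlas[n])
        assert rings.enclosure_test(vsa, atlas["island"], domain) is True

    def test_island_overlapping_ring_rejected(self):
        ring, _, domain = annulus_scene()
        with pytest.raises(ValidationError):
            rings.enclosure_test(ring, ring, domain)


class TestSymmetry:
    def test_mirror_symmetric_mask(self, small_grid):
        vol = np.zeros(small_grid.shape, dtype=bool)
        vol[1, 2, 1] = vol[6, 2, 1] = True  # mirror pair about x mid-plane
        assert rings.symmetry_score(BinaryMask(small_grid, vol), 0) == 1.0

    def test_one_sided_mask_scores_zero(self, small_grid):
        vol = np.zeros(small_grid.shape, dtype=bool)
        vol[0:3] = True
        assert rings.symmetry_score(BinaryMask(small_grid, vol), 0) == 0.0

    def test_equals_brute_force_dice(self, small_grid):
        rng = np.random.default_rng(1)
        mask = random_mask(small_grid, rng)
        got = rings.symmetry_score(mask, 0)
        mirrored = mask.values[::-1, :, :]
        inter = int((mask.values & mirrored).sum())
        want = 2 * inter / (int(mask.values.sum()) + int(mirrored.sum()))
        assert got == pytest.approx(want)


class TestSectorCycle:
    def _sectors(self, phantom):
        _, _, atlas, _ = phantom
        return [(n, atlas[n]) for n in [f"sector{k}" for k in range(1, 7)]]

    def test_phantom_sectors_in_layout_order(self, phantom):
        sectors = self._sectors(phantom)
        assert rings.sector_cycle(sectors) == [s for s, _ in sectors]
        assert rings.find_sector_cycle(sectors) == [s for s, _ in sectors]

    def test_removing_a_sector_breaks_the_cycle(self, phantom):
        sectors = self._sectors(phantom)
        assert rings.sector_cycle(sectors[:5]) == []
        assert rings.find_sector_cycle(sectors[:5]) == []

    def test_two_sectors_below_minimum_cycle_length(self, phantom):
        sectors = self._sectors(phantom)
        assert rings.sector_cycle(sectors[:2]) == []

    def test_overlapping_sectors_rejected(self, phantom):
        sectors = self._sectors(phantom)
        with pytest.raises(ValidationError):
            rings.sector_cycle([sectors[0], sectors[0]])

    def test_full_ring_report(self, phantom):
        _, _, atlas, domain = phantom
        sectors = self._sectors(phantom)
        vsa = atlas["sector1"]
        for n in [f"sector{k}" for k in range(2, 7)]:
            vsa = vsa.union(atlas[n])
        ptf = atlas["island"].union(atlas["scattered1"]).union(atlas["scattered2"])
        report = rings.ring_report(vsa, ptf, atlas["island"], domain, sectors)
        assert report.n_components_vsa == 1
        assert report.n_components_ptf >= 2
        assert report.enclosure_found is True
        assert len(report.sector_cycle) == 6
        assert report.symmetry[rings.VSA] == 1.0
        assert report.symmetry[rings.PTF] == 1.0
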