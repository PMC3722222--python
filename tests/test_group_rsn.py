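import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from oracles import bh_reject_by_definition
from ringscape.errors import StatisticsError, ValidationError
from ringscape.group_rsn import (
    RsnClass,
    cluster_components,
    group_tmap,
    match_populations,
    select_representative,
    spatial_similarity,
)
from ringscape.io_formats import BinaryMask, VolumeGrid
from ringscape.subject_ica import ComponentMap


GRID = VolumeGrid((6, 6, 3), np.eye(4))
BRAIN = BinaryMask(GRID, np.ones(GRID.shape, dtype=bool))


def comp(subject, values, index=1):
    """ComponentMap from raw in-brain values (z-scored here)."""
    v = np.asarray(values, dtype=float)
    z = (v - v.mean()) / v.std()
    vol = np.zeros(GRID.shape)
    vol[BRAIN.values] = z
    return ComponentMap(subject, index, vol, BRAIN)


def random_map(subject, rng, index=1):
    return comp(subject, rng.standard_normal(GRID.n_voxels), index)


class TestSpatialSimilarity:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        m = random_map("s1", rng)
        assert spatial_similarity(m, m) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        rng = np.random.default_rng(1)
        m = random_map("s1", rng)
        neg = ComponentMap("s1", 2, -m.zmap, BRAIN)
        assert spatial_similarity(m, neg) == pytest.approx(-1.0)

    def test_perfect_linear_relation(self):
        # maps supported on 5 voxels, values (1..5) vs (2,4,6,8,10)
        small = VolumeGrid((5, 1, 1), np.eye(4))
        mask = BinaryMask(small, np.ones(small.shape, dtype=bool))

        def mk(vals):
            vol = np.array(vals, dtype=float).reshape(small.shape)
            z = (vol - vol.mean()) / vol.std()
            return ComponentMap("s", 1, z, mask)

        a = mk([1, 2, 3, 4, 5])
        b = mk([2, 4, 6, 8, 10])
        assert spatial_similarity(a, b) == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        other_grid = VolumeGrid((4, 4, 2), np.eye(4))
        other_mask = BinaryMask(other_grid, np.ones(other_grid.shape, dtype=bool))
        a = random_map("s1", rng)
        b = ComponentMap("s2", 1, np.zeros(other_grid.shape), other_mask)
        with pytest.raises(ValidationError):
            spatial_similarity(a, b)


class TestClusterComponents:
    def test_identical_maps_give_one_class_full_R(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(GRID.n_voxels)
        comps = [comp("s1", base), comp("s2", base)]
        classes = cluster_components(comps)
        assert len(classes) == 1
        assert classes[0].representativeness == 1.0

    def test_two_orthogonal_networks_across_10_subjects(self):
        rng = np.random.default_rng(4)
        a = np.zeros(GRID.n_voxels)
        a[:30] = 1.0
        b = np.zeros(GRID.n_voxels)
        b[60:90] = 1.0
        comps = []
        for s in range(10):
            comps.append(comp(f"s{s}", a + 0.01 * rng.standard_normal(a.size), 1))
            comps.append(comp(f"s{s}", b + 0.01 * rng.standard_normal(b.size), 2))
        classes = cluster_components(comps, cut_similarity=0.25)
        assert len(classes) == 2
        for cls in classes:
            assert len(cls.members) == 10
            indices = {c.index for c in cls.members.values()}
            assert len(indices) == 1  # each class is one planted network

    def test_high_cut_isolates_every_component(self):
        rng = np.random.default_rng(5)
        comps = [random_map(f"s{i}", rng) for i in range(6)]
        classes = cluster_components(comps, cut_similarity=0.999)
        assert len(classes) == 6

    def test_one_member_per_subject(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(GRID.n_voxels)
        comps = [
            comp("s1", base + 0.01 * rng.standard_normal(base.size), 1),
            comp("s1", base + 0.01 * rng.standard_normal(base.size), 2),
            comp("s2", base + 0.01 * rng.standard_normal(base.size), 1),
        ]
        classes = cluster_components(comps)
        assert len(classes) == 1
        assert set(classes[0].members) == {"s1", "s2"}
        assert len(classes[0].components) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            cluster_components([])


class TestSelectRepresentative:
    def _cls(self, n_members, n_subjects, idx=0):
        rng = np.random.default_rng(idx)
        members = {f"s{i}": random_map(f"s{i}", rng) for i in range(n_members)}
        return RsnClass(members, n_subjects, idx)

    def test_ten_percent_rule_keeps_20_of_198(self):
        cls = self._cls(20, 198)
        kept = select_representative([cls], 198, min_R=0.10)
        assert kept == [cls]
        assert cls.representativeness == pytest.approx(20 / 198)

    def test_ten_percent_rule_drops_19_of_198(self):
        cls = self._cls(19, 198)
        assert select_representative([cls], 198, min_R=0.10) == []

    def test_ranks_by_decreasing_R(self):
        classes = [self._cls(5, 20, 0), self._cls(15, 20, 1), self._cls(10, 20, 2)]
        kept = select_representative(classes, 20, min_R=0.10)
        assert [c.rank for c in kept] == [1, 2, 3]
        assert [len(c.members) for c in kept] == [15, 10, 5]

    def test_rank_ties_break_by_creation_index(self):
        classes = [self._cls(5, 20, 1), self._cls(5, 20, 0)]
        kept = select_representative(classes, 20, min_R=0.10)
        assert [c.creation_index for c in kept] == [0, 1]

    def test_subject_order_invariance_of_R(self):
        cls = self._cls(7, 20)
        r1 = cls.representativeness
        cls.members = dict(reversed(list(cls.members.items())))
        assert cls.representativeness == r1


class TestGroupTmap:
    def test_degenerate_identical_members(self):
        base = np.zeros(GRID.n_voxels)
        base[:20] = 2.0
        vol = np.zeros(GRID.shape)
        vol[BRAIN.values] = base
        members = {
            s: ComponentMap(s, 1, vol, BRAIN) for s in ("s1", "s2", "s3")
        }
        cls = RsnClass(members, 3, 0)
        mask = group_tmap(cls, q=0.05)
        got = mask.values[BRAIN.values]
        np.testing.assert_array_equal(got, base > 0)

    def test_null_class_false_discoveries_bounded(self):
        rng = np.random.default_rng(7)
        members = {f"s{i}": random_map(f"s{i}", rng) for i in range(10)}
        cls = RsnClass(members, 10, 0)
        mask = group_tmap(cls, q=0.05)
        # under the global null the BH FDR bound caps the *expected* rejected
        # fraction at q; allow generous Monte-Carlo headroom
        assert mask.size / GRID.n_voxels <= 0.05 + 0.05

    def test_single_member_rejected(self):
        rng = np.random.default_rng(8)
        cls = RsnClass({"s1": random_map("s1", rng)}, 5, 0)
        with pytest.raises(StatisticsError):
            group_tmap(cls)

    @given(
        pvals=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
        q=st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_definition_oracle(self, pvals, q):
        ours = multipletests(pvals, alpha=q, method="fdr_bh")[0]
        oracle = bh_reject_by_definition(pvals, q)
        np.testing.assert_array_equal(ours, oracle)

    def test_bh_hand_worked_example(self):
        reject = multipletests([0.01, 0.02, 0.03, 0.20, 0.90], alpha=0.05,
                               method="fdr_bh")[0]
        np.testing.assert_array_equal(reject, [True, True, True, False, False])


def _rsn_from_mask(values, rank, n_subjects=10):
    rng = np.random.default_rng(rank)
    members = {f"s{i}": random_map(f"s{i}", rng) for i in range(5)}
    cls = RsnClass(members, n_subjects, rank)
    cls.mask = BinaryMask(GRID, values)
    cls.rank = rank
    return cls


class TestMatchPopulations:
    def _population(self, shift=0):
        rsns = []
        for r in range(1, 4):
            vol = np.zeros(GRID.shape, dtype=bool)
            vol[(r - 1) * 2 : (r - 1) * 2 + 2, shift : shift + 3, :] = True
            rsns.append(_rsn_from_mask(vol, r))
        return rsns

    def test_identity_match_rate_100(self):
        a = self._population()
        b = self._population()
        res = match_populations(a, b)
        assert sorted((x, y) for x, y, _ in res.pairs) == [(1, 1), (2, 2), (3, 3)]
        assert all(rate == pytest.approx(100.0) for _, _, rate in res.pairs)

    def test_disjoint_masks_rate_0(self):
        a = self._population(shift=0)
        b = self._population(shift=3)
        res = match_populations(a, b)
        assert all(rate == 0.0 for _, _, rate in res.pairs)

    def test_shifted_populations_beat_permuted_control(self):
        rng = np.random.default_rng(9)
        a = self._population()
        b = self._population()
        # jitter population B masks slightly
        for cls in b:
            noise = rng.random(GRID.shape) < 0.05
            cls.mask = BinaryMask(GRID, cls.mask.values ^ noise)
        matched = match_populations(a, b).mean_rate
        # permuted control: misalign the pairing deliberately
        b_perm = [b[1], b[2], b[0]]
        for new_rank, cls in enumerate(b_perm, start=1):
            cls.rank = new_rank
        control = np.mean(
            [
                100.0
                * np.count_nonzero(x.mask.values & y.mask.values)
                / np.count_nonzero(x.mask.values | y.mask.values)
                for x, y in zip(a, b_perm)
            ]
        )
        assert matched > control

    def test_leftovers_reported(self):
        a = self._population()
        res = match_populations(a, a[:2])
        assert len(res.pairs) == 2
        assert res.unmatched_a == [3]
        assert res.unmatched_b == []
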