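"""Partition-similarity indices, split-half resampling, and K selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connparc.stability import (StabilityReport, cramers_v, dice_matched,
                                interhemispheric_similarity, nmi, select_k,
                                split_half_stability)
from connparc.synthetic import (make_planted_truth, make_seed_geometry,
                                simulate_connectivity)
from connparc.parcellation import Parcellation


class TestNmi:
    def test_relabeling_invariant(self):
        assert nmi([1, 1, 2, 2], [2, 2, 1, 1]) == pytest.approx(1.0)

    def test_independent_partitions_zero(self):
        assert nmi([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_hand_computed_entropy_oracle(self):
        # contingency of [1,1,2,2] vs [1,1,1,2] is [[2,0],[1,1]]
        p = np.array([[2, 0], [1, 1]]) / 4.0
        pa, pb = p.sum(1), p.sum(0)
        mi = sum(p[i, j] * np.log(p[i, j] / (pa[i] * pb[j]))
                 for i in range(2) for j in range(2) if p[i, j] > 0)
        ha = -(pa * np.log(pa)).sum()
        hb = -(pb * np.log(pb)).sum()
        expected = 2 * mi / (ha + hb)
        assert nmi([1, 1, 2, 2], [1, 1, 1, 2]) == pytest.approx(expected)

    def test_degenerate_single_cluster_conventions(self):
        assert nmi([1, 1, 1], [1, 1, 1]) == pytest.approx(1.0)
        assert nmi([1, 1, 1], [1, 2, 2]) == pytest.approx(0.0)


class TestDiceMatched:
    def test_identical_and_label_swapped(self):
        assert dice_matched([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)
        assert dice_matched([1, 1, 2, 2], [2, 2, 1, 1]) == pytest.approx(1.0)

    def test_brute_force_matching_optimum(self):
        # both possible matchings enumerated by hand: the Hungarian optimum
        # pairs (1<->1, 2<->2): dice = mean(2*2/(2+3), 2*1/(2+1)) = 11/15
        a, b = [1, 1, 2, 2], [1, 1, 1, 2]
        def dice_pair(x, y, i, j):
            x, y = np.asarray(x), np.asarray(y)
            inter = np.sum((x == i) & (y == j))
            return 2 * inter / (np.sum(x == i) + np.sum(y == j))
        m1 = np.mean([dice_pair(a, b, 1, 1), dice_pair(a, b, 2, 2)])
        m2 = np.mean([dice_pair(a, b, 1, 2), dice_pair(a, b, 2, 1)])
        assert dice_matched(a, b) == pytest.approx(max(m1, m2))
        assert dice_matched(a, b) == pytest.approx(11 / 15)

    def test_unequal_cluster_counts_rejected(self):
        with pytest.raises(ValueError):
            dice_matched([1, 1, 2, 2], [1, 1, 1, 1])


class TestCramersV:
    def test_perfect_association(self):
        assert cramers_v([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_independence_zero(self):
        assert cramers_v([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_chi_square_oracle(self):
        # contingency [[3,1],[1,3]]: expected 2 everywhere, chi2 = 4*(1/2) = 2,
        # V = sqrt(2 / (8*1)) = 0.5
        a = [1] * 4 + [2] * 4
        b = [1, 1, 1, 2, 1, 2, 2, 2]
        assert cramers_v(a, b) == pytest.approx(0.5)

    def test_single_cluster_conventions(self):
        assert cramers_v([1, 1, 1], [1, 1, 1]) == pytest.approx(1.0)
        assert cramers_v([1, 1, 1], [1, 2, 1]) == pytest.approx(0.0)


@st.composite
def partition_pairs(draw):
    n = draw(st.integers(min_value=2, max_value=30))
    a = draw(st.lists(st.integers(1, 4), min_size=n, max_size=n))
    b = draw(st.lists(st.integers(1, 4), min_size=n, max_size=n))
    return np.array(a), np.array(b)


class TestIndexProperties:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(partition_pairs())
    def test_symmetry_range_and_permutation_invariance(self, pair):
        a, b = pair
        for index in (nmi, cramers_v):
            v = index(a, b)
            assert 0.0 <= v <= 1.0 + 1e-12
            assert index(b, a) == pytest.approx(v)
            # relabeling either side leaves the index unchanged
            remap = np.array([0, 3, 1, 4, 2])
            assert index(remap[a], b) == pytest.approx(v)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(partition_pairs())
    def test_dice_properties_when_defined(self, pair):
        a, b = pair
        if len(np.unique(a)) != len(np.unique(b)):
            return
        v = dice_matched(a, b)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert dice_matched(b, a) == pytest.approx(v)
        assert dice_matched(a, a) == pytest.approx(1.0)


def _report_from_curve(curve: dict) -> StabilityReport:
    table = pd.DataFrame({
        "nmi_mean": curve, "dice_mean": curve, "cramers_v_mean": curve})
    table.index.name = "k"
    return StabilityReport(table=table, n_repeats=1)


class TestSelectK:
    def test_unique_interior_peak(self):
        rep = _report_from_curve({2: 0.6, 3: 0.9, 4: 0.7, 5: 0.5})
        assert select_k(rep) == 3
        assert not rep.flagged

    def test_monotone_decreasing_endpoint_flagged(self):
        rep = _report_from_curve({2: 0.9, 3: 0.8, 4: 0.7, 5: 0.6})
        assert select_k(rep) == 2
        assert rep.flagged

    def test_flat_curve_falls_back_to_global_max(self):
        rep = _report_from_curve({2: 0.5, 3: 0.5, 4: 0.5})
        assert select_k(rep) == 2
        assert rep.flagged

    def test_requires_three_k_values(self):
        rep = _report_from_curve({2: 0.5, 3: 0.6})
        with pytest.raises(ValueError):
            select_k(rep)


class TestSplitHalf:
    def test_noiseless_planted_data_fully_reproducible(self, small_geometry,
                                                       noiseless_subjects):
        truth, subjects = noiseless_subjects
        idx = small_geometry.indices("left")
        left = [c.subset(idx) for c in subjects]
        rep = split_half_stability(left, k_range=range(2, 5), n_repeats=3,
                                   rng_seed=0)
        assert rep.table.loc[3, "nmi_mean"] == pytest.approx(1.0)
        assert rep.table.loc[3, "dice_mean"] == pytest.approx(1.0)

    def test_pure_noise_below_planted_structure(self, small_geometry,
                                                small_truth):
        rng = np.random.default_rng(0)
        from connparc.parcellation import ConnectivityProfileMatrix

        idx = small_geometry.indices("left")
        structured = [c.subset(idx) for c in simulate_connectivity(
            small_geometry, small_truth, 6, streams_per_voxel=2000, rng_seed=1)]
        noise = [ConnectivityProfileMatrix(
            counts=rng.poisson(30.0, size=(len(idx), 90)).astype(float),
            seed_ids=np.arange(len(idx)), target_ids=np.arange(90))
            for _ in range(6)]
        rep_s = split_half_stability(structured, k_range=range(2, 5),
                                     n_repeats=5, rng_seed=2)
        rep_n = split_half_stability(noise, k_range=range(2, 5),
                                     n_repeats=5, rng_seed=2)
        assert (rep_n.table.loc[3, "nmi_mean"]
                < rep_s.table.loc[3, "nmi_mean"])

    def test_too_few_subjects_rejected(self, small_subjects):
        with pytest.raises(ValueError):
            split_half_stability(small_subjects[:3])

    def test_k_range_exceeding_voxels_rejected(self, small_subjects):
        with pytest.raises(ValueError):
            split_half_stability(small_subjects, k_range=range(2, 100))


class TestInterhemispheric:
    def test_mirror_symmetric_parcellation_scores_one(self, small_geometry,
                                                      small_truth):
        li = small_geometry.indices("left")
        ri = small_geometry.indices("right")
        left = Parcellation(labels=small_truth.labels_true[li], k=3,
                            hemisphere="left")
        right = Parcellation(labels=small_truth.labels_true[ri], k=3,
                             hemisphere="right")
        v = interhemispheric_similarity(left, right, small_geometry)
        assert v == pytest.approx(1.0)

    def test_independent_random_parcellations_near_zero(self):
        geo = make_seed_geometry(300, rng_seed=0)
        rng = np.random.default_rng(1)
        n = 300
        left = Parcellation(labels=np.r_[1, 2, 3, rng.integers(1, 4, n - 3)],
                            k=3, hemisphere="left")
        right = Parcellation(labels=np.r_[1, 2, 3, rng.integers(1, 4, n - 3)],
                             k=3, hemisphere="right")
        assert interhemispheric_similarity(left, right, geo) < 0.05
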