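import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonotrace.clonotyping import CloneAssignment, assign_expansion_level
from clonotrace.repertoire_stats import (CloneFrequencyTable, ClonotypeSet,
                                         GroupPreferenceMatrix, UndefinedStatisticError,
                                         VGeneUsageTable, clonality, jaccard_index,
                                         pairwise_transition_index, repertoire_metrics,
                                         roe, shannon_entropy, top_n_frequency,
                                         transition_matrix, vgene_log2fc)


def table(counts, stratum="s"):
    return CloneFrequencyTable(stratum, {f"c{i}": c for i, c in enumerate(counts)})


def assignment_from_members(members: dict[str, list[str]]) -> CloneAssignment:
    cell_to_clone = {b: cid for cid, bs in members.items() for b in bs}
    return assign_expansion_level(CloneAssignment("TCR", cell_to_clone, members))


class TestShannonEntropy:
    def test_uniform_four_clones(self):
        assert shannon_entropy(table([1, 1, 1, 1])) == pytest.approx(2.0)

    def test_single_clone(self):
        assert shannon_entropy(table([17])) == 0.0

    def test_half_quarter_quarter(self):
        assert shannon_entropy(table([2, 1, 1])) == pytest.approx(1.5)

    def test_empty_errors(self):
        with pytest.raises(UndefinedStatisticError):
            table([])

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            CloneFrequencyTable("s", {"a": 0})

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=30))
    def test_entropy_bounds(self, counts):
        t = table(counts)
        h = shannon_entropy(t)
        assert -1e-12 <= h <= math.log2(t.n_clones) + 1e-12


class TestClonality:
    @pytest.mark.parametrize("n", [2, 3, 10, 100, 1000])
    def test_uniform_is_zero(self, n):
        assert clonality(table([1] * n)) == pytest.approx(0.0, abs=1e-12)

    def test_single_clone_is_one(self):
        assert clonality(table([5])) == 1.0

    def test_nine_to_one(self):
        # H(0.9, 0.1) = 0.46899..., clonality = 0.53100...
        assert clonality(table([9, 1])) == pytest.approx(0.5310, abs=1e-4)

    def test_concentration_monotonicity(self):
        # moving mass onto one clone never decreases clonality
        values = [clonality(table([10 + k, 10 - k, 10, 10])) for k in range(0, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    @given(st.lists(st.integers(1, 30), min_size=1, max_size=20))
    def test_range(self, counts):
        assert 0.0 <= clonality(table(counts)) <= 1.0


class TestJaccard:
    def c(self, ids):
        return ClonotypeSet("s", frozenset(ids))

    def test_identical(self):
        assert jaccard_index(self.c("abc"), self.c("abc")) == 1.0

    def test_disjoint(self):
        assert jaccard_index(self.c("ab"), self.c("cd")) == 0.0

    def test_half(self):
        assert jaccard_index(self.c("abc"), self.c("bcd")) == 0.5

    def test_both_empty_error(self):
        with pytest.raises(UndefinedStatisticError):
            jaccard_index(self.c(""), self.c(""))

    def test_brute_force_equivalence(self, rng):
        universe = [f"clone{i}" for i in range(30)]
        for _ in range(200):
            a = {u for u in universe if rng.random() < 0.4}
            b = {u for u in universe if rng.random() < 0.4}
            if not (a | b):
                continue
            expected = len(a & b) / len(a | b)
            assert jaccard_index(ClonotypeSet("a", frozenset(a)),
                                 ClonotypeSet("b", frozenset(b))) == expected

    def test_expanded_only_sets(self):
        a = assignment_from_members({"big": ["x", "y"], "single": ["z"]})
        s = ClonotypeSet.from_assignment(a, expanded_only=True)
        assert s.clone_ids == frozenset({"big"})


class TestTopNFrequency:
    def test_single_clone(self):
        assert top_n_frequency(table([5]), 20) == 1.0

    def test_uniform_100(self):
        assert top_n_frequency(table([1] * 100), 20) == pytest.approx(0.2)

    def test_hand_sum(self):
        assert top_n_frequency(table([50, 30, 10, 5, 5]), 2) == pytest.approx(0.8)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_n_frequency(table([1]), 0)


class TestRoe:
    def test_equal_table_all_ones(self):
        obs = pd.DataFrame(np.full((3, 4), 7), index=list("abc"), columns=list("wxyz"))
        result = roe(obs)
        assert np.allclose(result.roe.to_numpy(), 1.0)

    def test_2x2_worked_example(self):
        obs = pd.DataFrame([[30, 10], [10, 30]], index=["c1", "c2"], columns=["g1", "g2"])
        result = roe(obs)
        assert np.allclose(result.expected.to_numpy(), 20.0)
        assert np.allclose(result.roe.to_numpy(), [[1.5, 0.5], [0.5, 1.5]])

    def test_single_group_column(self):
        obs = pd.DataFrame({"g": [5, 10, 3]}, index=list("abc"))
        assert np.allclose(roe(obs).roe.to_numpy(), 1.0)

    def test_expected_sums_match_observed(self, rng):
        obs = pd.DataFrame(rng.integers(0, 50, size=(5, 4)) + 1)
        result = roe(obs)
        assert result.expected.to_numpy().sum() == pytest.approx(obs.to_numpy().sum())

    def test_count_weighted_mean_is_one(self, rng):
        # weighting clusters by their total cell counts, the mean R within
        # any group is exactly 1
        for _ in range(100):
            obs = pd.DataFrame(rng.integers(0, 40, size=(6, 3)) + 1)
            result = roe(obs)
            row_weights = obs.sum(axis=1) / obs.to_numpy().sum()
            for g in obs.columns:
                assert (row_weights * result.roe[g]).sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            roe(pd.DataFrame([[1, -1]]))


class TestTransitionIndex:
    def test_confined_clones_zero(self):
        a = assignment_from_members({"k1": ["a1", "a2"], "k2": ["b1", "b2"]})
        labels = {"a1": "i", "a2": "i", "b1": "j", "b2": "j"}
        assert pairwise_transition_index(a, labels, "i", "j").ptran == 0.0

    def test_perfect_split_one(self):
        a = assignment_from_members({"k": ["x1", "x2"]})
        labels = {"x1": "i", "x2": "j"}
        assert pairwise_transition_index(a, labels, "i", "j").ptran == 1.0

    def test_mixed_worked_example(self):
        # clone A split 2:2, clone B 4:0 -> (4/8)*1 + (4/8)*0 = 0.5
        a = assignment_from_members({
            "A": ["a1", "a2", "a3", "a4"],
            "B": ["b1", "b2", "b3", "b4"],
        })
        labels = {"a1": "i", "a2": "i", "a3": "j", "a4": "j",
                  "b1": "i", "b2": "i", "b3": "i", "b4": "i"}
        assert pairwise_transition_index(a, labels, "i", "j").ptran == pytest.approx(0.5)

    def test_symmetry(self, rng):
        members = {f"k{k}": [f"c{k}_{m}" for m in range(rng.integers(1, 8))]
                   for k in range(10)}
        a = assignment_from_members(members)
        labels = {b: ["i", "j", "k"][rng.integers(0, 3)]
                  for bs in members.values() for b in bs}
        tij = pairwise_transition_index(a, labels, "i", "j")
        tji = pairwise_transition_index(a, labels, "j", "i")
        assert tij.ptran == pytest.approx(tji.ptran)

    def test_brute_force_equivalence(self, rng):
        for _ in range(20):
            members = {f"k{k}": [f"c{k}_{m}" for m in range(rng.integers(1, 10))]
                       for k in range(int(rng.integers(2, 50)))}
            a = assignment_from_members(members)
            labels = {b: ["i", "j", "z"][rng.integers(0, 3)]
                      for bs in members.values() for b in bs}
            # independent brute-force accumulation
            num, den = 0.0, 0
            for bs in members.values():
                ni = sum(labels[b] == "i" for b in bs)
                nj = sum(labels[b] == "j" for b in bs)
                m = ni + nj
                if m == 0:
                    continue
                h = 0.0
                for nk in (ni, nj):
                    if nk:
                        h -= (nk / m) * math.log2(nk / m)
                num += m * h
                den += m
            if den == 0:
                with pytest.raises(UndefinedStatisticError):
                    pairwise_transition_index(a, labels, "i", "j")
                continue
            t = pairwise_transition_index(a, labels, "i", "j")
            assert t.ptran == pytest.approx(num / den)

    def test_no_cells_error(self):
        a = assignment_from_members({"k": ["x"]})
        with pytest.raises(UndefinedStatisticError):
            pairwise_transition_index(a, {"x": "elsewhere"}, "i", "j")

    def test_same_cluster_rejected(self):
        a = assignment_from_members({"k": ["x"]})
        with pytest.raises(ValueError):
            pairwise_transition_index(a, {"x": "i"}, "i", "i")

    def test_matrix_symmetric(self, rng):
        members = {f"k{k}": [f"c{k}_{m}" for m in range(3)] for k in range(6)}
        a = assignment_from_members(members)
        labels = {b: ["i", "j", "k"][rng.integers(0, 3)]
                  for bs in members.values() for b in bs}
        mat = transition_matrix(a, labels)
        assert mat.equals(mat.T)


class TestVGeneUsage:
    def test_frequencies_sum_to_one(self):
        usage = VGeneUsageTable.from_gene_lists(
            {"A": ["v1"] * 3 + ["v2"] * 7, "B": ["v1", "v2", "v3"]})
        sums = usage.frequencies.sum(axis=0)
        assert np.allclose(sums, 1.0)

    def test_identical_usage_zero_fc(self):
        usage = VGeneUsageTable.from_gene_lists(
            {"A": ["v1"] * 5 + ["v2"] * 5, "B": ["v1"] * 5 + ["v2"] * 5})
        fc = vgene_log2fc(usage, "A", "B")
        assert np.allclose(fc.to_numpy(), 0.0)

    def test_worked_example(self):
        # gene present 20/100 in A vs 10/100 in B over K=10 genes
        genes_a = ["g0"] * 20 + [f"g{i}" for i in range(1, 10) for _ in range(9)][:80]
        genes_b = ["g0"] * 10 + [f"g{i}" for i in range(1, 10) for _ in range(10)]
        usage = VGeneUsageTable.from_gene_lists({"A": genes_a, "B": genes_b})
        assert usage.counts.shape[0] == 10
        assert usage.counts["A"].sum() == 100 and usage.counts["B"].sum() == 100
        fc = vgene_log2fc(usage, "A", "B", pseudocount=0.5)
        expected = math.log2((20.5 / 105) / (10.5 / 105))
        assert fc["g0"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.965, abs=1e-3)

    def test_absent_gene_finite(self):
        usage = VGeneUsageTable.from_gene_lists(
            {"A": ["v1"] * 5 + ["v2"] * 5, "B": ["v2"] * 10})
        fc = vgene_log2fc(usage, "A", "B")
        assert np.isfinite(fc["v1"]) and fc["v1"] > 0

    def test_empty_group_error(self):
        usage = VGeneUsageTable.from_gene_lists({"A": ["v1"], "B": ["v1"]})
        with pytest.raises(ValueError):
            vgene_log2fc(usage, "A", "C")


class TestDirectionalSeparation:
    def test_heavy_tail_has_higher_clonality_and_top20(self, rng):
        # heavier-tailed clone sizes -> higher clonality and top-20 frequency
        wins_clon, wins_top = 0, 0
        n_rep = 100
        for _ in range(n_rep):
            flat = rng.geometric(0.9, size=150)
            heavy = rng.zipf(1.6, size=60)
            t_flat = table(flat.tolist(), "HD")
            t_heavy = table(np.minimum(heavy, 200).tolist(), "Act")
            wins_clon += clonality(t_heavy) > clonality(t_flat)
            wins_top += top_n_frequency(t_heavy) > top_n_frequency(t_flat)
        assert wins_clon >= 0.95 * n_rep
        assert wins_top >= 0.95 * n_rep


def test_repertoire_metrics_bundle():
    m = repertoire_metrics(table([2, 1, 1], "donor1"))
    assert m.entropy_bits == pytest.approx(1.5)
    assert m.n_clones == 3
    assert m.total_cells == 4
    assert 0 <= m.clonality <= 1
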