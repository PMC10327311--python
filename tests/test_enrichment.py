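import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix
from dropqc.enrichment import (
    NOISE_LABEL,
    RankedCell,
    assign_cells,
    auc_score,
    enrich,
    rank_cell,
    select_threshold,
)
from dropqc.reference_sets import GeneSet, ReferenceGeneSetCollection


def brute_force_auc(order, set_indices, max_rank):
    """Literal recovery-curve integration: step through ranks 1..T counting
    set genes, sum the running hit count, divide by the best possible sum."""
    in_set = set(set_indices)
    hits = area = 0
    for r in range(1, max_rank + 1):
        if order[r - 1] in in_set:
            hits += 1
        area += hits
    best = sum(min(r, len(in_set)) for r in range(1, max_rank + 1))
    return area / best


def ranked_from_order(order):
    order = np.asarray(order)
    return RankedCell(order=order, n_detected=len(order))


class TestRankCell:
    def test_descending_counts_with_ties_in_middle(self):
        ranked = rank_cell(np.array([5, 0, 2, 2]), rng_seed=1)
        assert ranked.order[0] == 0            # highest count first
        assert set(ranked.order[1:3]) == {2, 3}  # tied pair in positions 2-3
        assert ranked.order[3] == 1            # zero last
        assert ranked.n_detected == 3

    def test_no_ties_is_seed_independent(self):
        a = rank_cell(np.array([7, 3, 1]), rng_seed=1)
        b = rank_cell(np.array([7, 3, 1]), rng_seed=999)
        assert a.order.tolist() == b.order.tolist() == [0, 1, 2]

    def test_same_seed_reproduces_permutation(self):
        counts = np.zeros(50)
        counts[:5] = 3
        a = rank_cell(counts, rng_seed=42)
        b = rank_cell(counts, rng_seed=42)
        assert (a.order == b.order).all()

    def test_all_zero_cell_is_valid_but_undetected(self):
        ranked = rank_cell(np.zeros(10), rng_seed=0)
        assert sorted(ranked.order) == list(range(10))
        assert ranked.n_detected == 0


class TestAucScore:
    def test_worked_example_two_hits_in_top_five(self):
        # N=10, T=5, set genes at ranks 1 and 4: area 7 over best 9
        order = [7, 0, 1, 8, 2, 3, 4, 5, 6, 9]
        score = auc_score(ranked_from_order(order), {7, 8}, max_rank=5)
        assert score == pytest.approx(7 / 9)

    def test_top_packed_set_scores_one(self):
        order = list(range(10))
        assert auc_score(ranked_from_order(order), {0, 1, 2}, 5) == 1.0

    def test_set_outside_top_t_scores_zero(self):
        order = list(range(10))
        assert auc_score(ranked_from_order(order), {8, 9}, 5) == 0.0

    def test_matches_brute_force_on_random_instances(self):
        """Oracle equivalence over 200 random small instances."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            t = int(rng.integers(1, min(n, 20) + 1))
            order = rng.permutation(n)
            k = int(rng.integers(1, n + 1))
            s = set(rng.choice(n, size=k, replace=False).tolist())
            got = auc_score(ranked_from_order(order), s, t)
            assert got == pytest.approx(brute_force_auc(order, s, t))

    def test_promoting_a_set_gene_never_decreases_score(self):
        """Monotonicity over 1000 random single-gene promotions."""
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            t = int(rng.integers(1, n))
            order = list(rng.permutation(n))
            k = int(rng.integers(1, n))
            s = set(rng.choice(n, size=k, replace=False).tolist())
            before = auc_score(ranked_from_order(order), s, t)
            # move one set gene to a strictly better rank
            positions = [i for i, g in enumerate(order) if g in s and i > 0]
            if not positions:
                continue
            p = int(rng.choice(positions))
            q = int(rng.integers(0, p))
            gene = order.pop(p)
            order.insert(q, gene)
            after = auc_score(ranked_from_order(order), s, t)
            assert after >= before

    @given(st.integers(2, 30), st.integers(0, 10**9), st.integers(0, 10**9))
    def test_score_depends_only_on_the_ranking(self, n, seed, scale_seed):
        """Count values are irrelevant given the same permutation."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        t = max(1, n // 3)
        s = set(rng.choice(n, size=max(1, n // 4), replace=False).tolist())
        a = auc_score(ranked_from_order(order), s, t)
        b = auc_score(ranked_from_order(order.copy()), s, t)
        assert 0.0 <= a <= 1.0
        assert a == b


class TestSelectThreshold:
    def test_separates_two_planted_modes(self):
        rng = np.random.default_rng(0)
        v = np.clip(np.concatenate([rng.normal(0.1, 0.02, 500),
                                    rng.normal(0.7, 0.02, 500)]), 0, 1)
        thr, method = select_threshold(v)
        assert method == "bimodal"
        assert 0.25 < thr < 0.55
        # exhaustive-scan oracle: some cut must separate the planted labels;
        # the selected one misclassifies at most 2%
        labels = np.array([0] * 500 + [1] * 500)
        mis = ((v[labels == 0] > thr).sum() + (v[labels == 1] <= thr).sum())
        assert mis / 1000 <= 0.02

    def test_constant_vector_lets_no_cell_pass(self):
        v = np.full(100, 0.3)
        thr, method = select_threshold(v)
        assert method == "fallback_3sigma"
        assert thr == pytest.approx(0.3)
        assert not (v > thr).any()

    def test_unimodal_input_takes_three_sigma_fallback(self):
        rng = np.random.default_rng(1)
        v = np.clip(rng.normal(0.2, 0.05, 1000), 0, 1)
        thr, method = select_threshold(v)
        assert method == "fallback_3sigma"
        assert (v > thr).mean() <= 0.01  # normal tail beyond 3 sigma

    def test_tiny_sample_uses_fallback(self):
        thr, method = select_threshold([0.1, 0.9] * 3)
        assert method == "fallback_3sigma"


class TestAssignCells:
    def make(self, rows, thresholds):
        auc = pd.DataFrame(rows).T
        return auc, pd.Series(thresholds)

    def test_argmax_among_passing_sets(self):
        auc, thr = self.make({"cell1": {"T": 0.8, "B": 0.3}},
                             {"T": 0.4, "B": 0.4})
        assert assign_cells(auc, thr)["cell1"] == "T"

    def test_below_every_threshold_is_noise(self):
        auc, thr = self.make({"cell1": {"T": 0.2, "B": 0.3}},
                             {"T": 0.4, "B": 0.4})
        assert assign_cells(auc, thr)["cell1"] == NOISE_LABEL

    def test_exact_tie_takes_lexicographically_smallest(self):
        auc, thr = self.make({"cell1": {"Tcell": 0.6, "Bcell": 0.6}},
                             {"Tcell": 0.4, "Bcell": 0.4})
        assert assign_cells(auc, thr)["cell1"] == "Bcell"

    def test_noise_exactly_when_candidate_set_empty(self):
        """Exhaustive check on random matrices."""
        rng = np.random.default_rng(9)
        auc = pd.DataFrame(rng.random((40, 4)), columns=list("ABCD"))
        thr = pd.Series(rng.random(4), index=list("ABCD"))
        labels = assign_cells(auc, thr)
        for i in auc.index:
            passing = auc.loc[i] > thr
            assert (labels[i] == NOISE_LABEL) == (not passing.any())
            if passing.any():
                assert passing[labels[i]]


class TestEnrich:
    def collection(self):
        return ReferenceGeneSetCollection(sets=[
            GeneSet("S1", ("G0", "G1")), GeneSet("S2", ("G2", "G3"))])

    def test_whole_feature_space_set_scores_one_everywhere(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.poisson(2.0, size=(6, 30)))
        coll = ReferenceGeneSetCollection(
            sets=[GeneSet("All", tuple(f"G{i}" for i in range(6)))])
        res = enrich(m, coll, max_rank_fraction=0.5, seed=0)
        assert (res.auc["All"] == 1.0).all()

    def test_same_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.poisson(1.0, size=(20, 40)))
        coll = self.collection()
        a = enrich(m, coll, seed=3)
        b = enrich(m, coll, seed=3)
        assert a.auc.equals(b.auc)
        assert a.assignment.equals(b.assignment)
        assert a.thresholds.equals(b.thresholds)

    def test_no_matching_sets_is_a_hard_error(self):
        m = make_matrix(np.ones((4, 12)))
        coll = ReferenceGeneSetCollection(
            sets=[GeneSet("S", ("NOPE1", "NOPE2"))])
        with pytest.raises(ValueError, match="symbol"):
            enrich(m, coll)

    def test_auc_matrix_bounded_and_max_rank_recorded(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.poisson(1.0, size=(40, 25)))
        res = enrich(m, self.collection(), max_rank_fraction=0.1, seed=0)
        assert res.max_rank == 4  # ceil(0.1 * 40)
        assert ((res.auc.to_numpy() >= 0) & (res.auc.to_numpy() <= 1)).all()

    def test_excluded_sets_never_scored(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.poisson(1.0, size=(10, 20)))
        coll = ReferenceGeneSetCollection(sets=[
            GeneSet("Good", ("G0", "G1")),
            GeneSet("Gone", ("X1", "X2", "X3"))])
        res = enrich(m, coll)
        assert list(res.auc.columns) == ["Good"]
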