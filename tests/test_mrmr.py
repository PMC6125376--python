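import numpy as np
import pytest

from oasig import (
    DiscretizedMatrix,
    SyntheticSpec,
    discretize_matrix,
    encode_labels,
    entropy,
    generate_cohort,
    mrmr_rank,
    mutual_information,
    quantile_normalize,
    redundancy,
    relevance,
)

from conftest import naive_mi, naive_mrmr


def _dm(columns, gene_ids=None):
    codes = np.column_stack(columns).astype(np.int8)
    genes = gene_ids or [f"g{i}" for i in range(codes.shape[1])]
    samples = [f"s{i}" for i in range(codes.shape[0])]
    return DiscretizedMatrix(codes, genes, samples)


class TestRelevanceRedundancy:
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])

    def test_perfect_partition_is_one_bit(self):
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert relevance(g, self.labels) == pytest.approx(1.0)

    def test_independent_gene_has_zero_relevance(self):
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        assert relevance(g, self.labels) == 0.0

    def test_empty_selected_set_has_zero_redundancy(self):
        assert redundancy(np.array([0, 1, 0, 1]), []) == 0.0

    def test_redundancy_with_own_copy_is_entropy(self):
        g = np.array([0, 1, 0, 1, 0, 1])
        assert redundancy(g, [g.copy()]) == pytest.approx(1.0)
        assert redundancy(g, [g.copy()]) == pytest.approx(entropy(g))

    def test_redundancy_is_mean_of_pairwise_mi(self):
        g = np.array([0, 0, 1, 1, 2, 2])
        s1 = np.array([0, 1, 1, 0, 2, 2])
        s2 = np.array([1, 1, 0, 0, 0, 1])
        expected = (naive_mi(list(g), list(s1)) + naive_mi(list(g), list(s2))) / 2
        assert redundancy(g, [s1, s2]) == pytest.approx(expected, abs=1e-12)


class TestMrmrRank:
    def test_first_pick_is_argmax_relevance_and_scores_relevance(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        weak = np.array([0, 1, 0, 1, 0, 1, 1, 1])
        strong = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        dm = _dm([weak, strong], ["weak", "strong"])
        rk = mrmr_rank(dm, labels, 2)
        assert rk.gene_ids[0] == "strong"
        assert rk.entries[0].score == pytest.approx(relevance(strong, labels))

    def test_redundant_copy_is_deferred(self):
        # A and its exact copy tie on relevance; once A is selected the copy
        # pays its full entropy in redundancy, so the weaker-but-novel B is
        # ranked second: A, B, A-copy.
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        A = np.array([0, 0, 0, 1, 0, 1, 1, 1])  # relevance 0.1887, H(A)=1
        B = np.array([0, 0, 0, 0, 0, 0, 0, 1])  # relevance 0.1379, I(B,A)=0.1379
        dm = _dm([A, A.copy(), B], ["A", "Acopy", "B"])
        rk = mrmr_rank(dm, labels, 3)
        assert rk.gene_ids == ["A", "B", "Acopy"]
        # step-2 score of B = relevance - I(B, A)
        assert rk.entries[1].score == pytest.approx(
            relevance(B, labels) - mutual_information(B, A), abs=1e-12
        )

    def test_ties_broken_by_input_gene_order(self):
        labels = np.array([0, 0, 1, 1])
        g = np.array([0, 0, 1, 1])
        dm = _dm([g, g.copy()], ["first", "second"])
        assert mrmr_rank(dm, labels, 2).gene_ids == ["first", "second"]

    @pytest.mark.parametrize("top_n", [0, -1, 9])
    def test_top_n_bounds(self, top_n):
        dm = _dm([np.array([0, 1, 0, 1])] * 3)
        with pytest.raises(ValueError):
            mrmr_rank(dm, np.array([0, 1, 0, 1]), top_n)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_genes = rng.integers(2, 9)
            n_samples = rng.integers(4, 21)
            codes = rng.integers(0, 3, size=(n_samples, n_genes))
            labels = rng.integers(0, 2, size=n_samples)
            dm = _dm(list(codes.T))
            got = mrmr_rank(dm, labels, int(n_genes)).gene_ids
            want = [
                f"g{j}"
                for j in naive_mrmr(
                    [list(codes[:, j]) for j in range(n_genes)],
                    list(labels),
                    int(n_genes),
                )
            ]
            assert got == want

    def test_scores_beyond_rank_one_never_exceed_relevance(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(30, 12))
        labels = rng.integers(0, 2, size=30)
        dm = _dm(list(codes.T))
        rk = mrmr_rank(dm, labels, 12)
        for e in rk.entries[1:]:
            assert e.score <= relevance(dm.gene(e.gene_id), labels) + 1e-12

    def test_gene_order_permutation_only_matters_at_ties(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(40, 6))
        labels = rng.integers(0, 2, size=40)
        perm = rng.permutation(6)
        dm = _dm(list(codes.T))
        dm_p = _dm([codes[:, j] for j in perm], [f"g{j}" for j in perm])
        a = mrmr_rank(dm, labels, 6)
        b = mrmr_rank(dm_p, labels, 6)
        scores_a = [round(e.score, 9) for e in a.entries]
        scores_b = [round(e.score, 9) for e in b.entries]
        assert scores_a == scores_b
        for ga, gb, sa in zip(a.gene_ids, b.gene_ids, scores_a):
            if scores_a.count(sa) == 1:
                assert ga == gb

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_planted_signals_fill_the_top_of_the_ranking(self, seed):
        # every planted signal (parent or its redundant proxy) surfaces in the
        # top 10 of a 210-gene cohort; its twin is then heavily penalized
        em, truth = generate_cohort(
            SyntheticSpec(n_case=30, n_control=30, seed=seed)
        )
        em = quantile_normalize(em)
        dm = discretize_matrix(em)
        rk = mrmr_rank(dm, encode_labels(em.labels.to_numpy()), 10)
        covered = {
            truth.canonical(g) for g in rk.gene_ids if truth.role(g) != "null"
        }
        assert covered == truth.informative

    def test_tsv_writer_layout(self, tmp_path):
        labels = np.array([0, 0, 1, 1])
        dm = _dm([np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])])
        path = tmp_path / "rank.tsv"
        mrmr_rank(dm, labels, 2).to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("Rank\tName\t")
        assert lines[1].split("\t")[:2] == ["1", "g0"]
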