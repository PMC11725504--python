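import numpy as np
import pytest

from trajalign import (
    aggregate_alignment,
    alignment_similarity,
    binary_encode,
    build_state_machine,
    align_cost_matrix,
    cluster_alignments,
    distance_change_test,
    misclustering_rate,
    mml_null_significance,
    string_distance_matrix,
)


class TestAlignmentSimilarity:
    @pytest.mark.parametrize(
        "string,expected",
        [("MMVID", 60.0), ("MMMMM", 100.0), ("IDIDID", 0.0), ("WV", 100.0)],
    )
    def test_examples(self, string, expected):
        assert alignment_similarity(string) == pytest.approx(expected)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            alignment_similarity("")
        with pytest.raises(ValueError):
            alignment_similarity("MMX")


def _result_from_costs(cost):
    return align_cost_matrix(np.asarray(cost, dtype=float), build_state_machine())


class TestAggregateAlignment:
    def test_singleton_set_is_identity(self, rng):
        # on a gene-like alignment the landscape's modal-state traversal
        # reproduces the backtracked string exactly
        from trajalign import AlignmentConfig, align_arrays

        cfg = AlignmentConfig(n_interp_points=8, seed=0)
        t = np.linspace(0, 1, 200)
        ref = np.sin(3 * t) + 2 + rng.normal(0, 0.2, 200)
        query = np.where(t < 0.5, ref, 6.0 + rng.normal(0, 0.2, 200))
        res = align_arrays(ref, t, query, t, cfg, 8)
        assert aggregate_alignment([res]) == res.string

    def test_unanimous_set_is_identity(self):
        cost = -np.eye(5) * 2 + 1.0  # cheap diagonal: all-M alignment
        results = [_result_from_costs(cost) for _ in range(4)]
        assert aggregate_alignment(results) == results[0].string == "MMMMM"

    def test_majority_vote_wins(self):
        match_like = [_result_from_costs(-np.ones((3, 3))) for _ in range(3)]
        gap_like = [_result_from_costs(np.full((3, 3), 50.0))]
        agg = aggregate_alignment(match_like + gap_like)
        assert agg == "MMM"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            aggregate_alignment([])


class TestBinaryEncode:
    @pytest.mark.parametrize(
        "string,len_R,len_Q,expected",
        [
            ("MM", 2, 2, "1111"),
            ("ID", 1, 1, "00"),
            ("MID", 2, 2, "1010"),  # R: M,D -> 10 ; Q: M,I -> 10
            ("MIV", 1, 3, "1101"),  # R gets the M bit; Q: M,I,V -> 101
        ],
    )
    def test_walk_examples(self, string, len_R, len_Q, expected):
        assert binary_encode(string, len_R, len_Q) == expected

    def test_inconsistent_walk_rejected(self):
        with pytest.raises(ValueError, match="walk"):
            binary_encode("MM", 3, 2)


class TestStringDistances:
    def test_levenshtein_basics(self):
        d = string_distance_matrix(["MMM", "MMM", "III"])
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_levenshtein_normalized_by_longer(self):
        d = string_distance_matrix(["MMMM", "MMMMDD"])
        assert d[0, 1] == pytest.approx(2 / 6)

    def test_triangle_inequality_on_sampled_triples(self, rng):
        alphabet = np.array(list("MWVDI"))
        strings = [
            "".join(rng.choice(alphabet, size=rng.integers(4, 12))) for _ in range(40)
        ]
        d = string_distance_matrix(strings)
        idx = rng.integers(0, 40, size=(200, 3))
        for a, b, c in idx:
            assert d[a, c] <= d[a, b] + d[b, c] + 1e-12

    def test_hamming_on_binary_encodings(self):
        d = string_distance_matrix(["MM", "IIDD"], metric="hamming", len_R=2, len_Q=2)
        assert d[0, 1] == pytest.approx(1.0)
        assert np.all(d <= 1.0)


class TestClustering:
    def test_two_separated_groups(self):
        strings = ["MMMMM"] * 5 + ["IIDID"] * 5
        d = string_distance_matrix(strings)
        model = cluster_alignments(d, threshold=0.5)
        assert model.n_clusters == 2
        labels = model.labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_min_threshold_gives_unique_strings(self, rng):
        alphabet = np.array(list("MWVDI"))
        strings = ["".join(rng.choice(alphabet, size=6)) for _ in range(30)]
        d = string_distance_matrix(strings)
        model = cluster_alignments(d, threshold=1e-9)
        assert model.n_clusters == len(set(strings))

    def test_cluster_count_monotone_in_threshold(self, rng):
        alphabet = np.array(list("MWVDI"))
        strings = ["".join(rng.choice(alphabet, size=8)) for _ in range(25)]
        d = string_distance_matrix(strings)
        counts = [
            cluster_alignments(d, threshold=th).n_clusters for th in (0.05, 0.2, 0.5, 0.9)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_auto_mode_reports_curve(self):
        strings = ["MMMMM"] * 6 + ["IIDID"] * 6 + ["MMIID"] * 6
        d = string_distance_matrix(strings)
        model = cluster_alignments(d, threshold="auto")
        assert model.msc_curve is not None
        assert model.n_clusters >= 2

    def test_cluster_averages_from_results(self, rng):
        results = [_result_from_costs(-np.ones((3, 3))) for _ in range(4)]
        d = string_distance_matrix([r.string for r in results])
        model = cluster_alignments(d, threshold=0.5, results=results)
        assert list(model.cluster_averages.values()) == ["MMM"]


def test_misclustering_rate_counts_minority_members():
    labels = [0, 0, 0, 1, 1, 1]
    truth = ["a", "a", "b", "c", "c", "c"]
    assert misclustering_rate(np.array(labels), truth) == pytest.approx(100 / 6)


class TestNullSignificance:
    def test_shifted_gene_detected(self, rng):
        n_genes, n_cells = 30, 120
        a = rng.normal(2.0, 0.5, size=(n_cells, n_genes))
        b = rng.normal(2.0, 0.5, size=(n_cells, n_genes))
        b[:, 0] += 2.5  # 5 sigma shift on the first gene
        table = mml_null_significance(a, b, n_iter=20, subset_size=40, seed=5)
        assert table.loc[0, "p_adj"] < 0.05
        assert table["p_adj"].iloc[1:].median() > 0.2

    def test_p_monotone_in_shift(self, rng):
        n_cells = 120
        a = rng.normal(2.0, 0.5, size=(n_cells, 1))
        ps = []
        for shift in (0.0, 1.0, 2.0, 4.0):
            b = rng.normal(2.0 + shift, 0.5, size=(n_cells, 1))
            table = mml_null_significance(a, b, n_iter=20, subset_size=40, seed=3)
            ps.append(float(table["p"].iloc[0]))
        assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))

    def test_requires_enough_cells(self, rng):
        a = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="cells"):
            mml_null_significance(a, a, subset_size=50)


def test_distance_change_test_detects_location_shift(rng):
    res = distance_change_test(rng.normal(0, 1, 100), rng.normal(2, 1, 100))
    assert res.pvalue < 1e-6
    res_null = distance_change_test(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
    assert res_null.pvalue > 0.01
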