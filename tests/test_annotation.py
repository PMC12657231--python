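"""Annotation matrices, representations, RowDiff, count transforms."""

import numpy as np
import pytest

from annodbg.annotation import (
    AggregationSpec,
    aggregate_columns,
    annotate,
    convert_representation,
    decode_sample,
    matrix_from_columns,
    rowdiff_reconstruct,
    rowdiff_transform,
    set_bit_count,
    smooth_counts,
)
from annodbg.graph import build_graph

REPRESENTATIONS = ("column_sparse", "row_flat", "row_sparse", "brwt")


def random_matrix(rng, n, m, density=0.2, representation="column_sparse"):
    columns = [np.flatnonzero(rng.random(n) < density) for _ in range(m)]
    return matrix_from_columns(n, columns, [f"L{j}" for j in range(m)],
                               representation=representation)


class TestAnnotate:
    def test_two_sample_hand_example(self):
        g = build_graph(["ACGTT", "ACGAA"], 3)
        m = annotate(g, [("S1", ["ACGTT"]), ("S2", ["ACGAA"])])
        assert m.labels == ["S1", "S2"]
        assert list(m.get_row(g.node_index("ACG") - 1)) == [0, 1]
        assert list(m.get_row(g.node_index("GTT") - 1)) == [0]
        assert list(m.get_row(g.node_index("GAA") - 1)) == [1]

    def test_single_sample_column_is_all_ones(self):
        g = build_graph(["ACGTT"], 3)
        m = annotate(g, [("S", ["ACGTT"])])
        assert list(m.get_column(0)) == list(range(g.n))

    def test_absent_kmer_names_the_kmer(self):
        g = build_graph(["ACGTT"], 3)
        with pytest.raises(KeyError, match="AAA"):
            annotate(g, [("S", ["AAAT"])])

    def test_coordinates_payload(self):
        g = build_graph(["ACGTT"], 3)
        m = annotate(g, [("S", ["ACGTT"])], payload="coordinates")
        coords = m.coordinates[0]
        by_kmer = {
            kmer: coords[g.node_index(kmer) - 1] for kmer in ("ACG", "CGT", "GTT")
        }
        assert by_kmer == {"ACG": [(0, 0)], "CGT": [(0, 1)], "GTT": [(0, 2)]}

    def test_coordinates_are_lossless(self, random_dna_factory):
        seqs = [random_dna_factory(80), random_dna_factory(60)]
        g = build_graph(seqs, 9)
        m = annotate(g, [("S", seqs)], payload="coordinates")
        assert decode_sample(m, g, "S") == seqs

    def test_counts_payload_from_multiplicity(self):
        g = build_graph(["ACGACGA"], 3)
        m = annotate(g, [("S", ["ACGACGA"])], payload="counts")
        assert m.get_count(g.node_index("ACG") - 1, 0) == 2
        assert m.get_count(g.node_index("CGA") - 1, 0) == 2

    def test_primary_joint_graph_accepts_both_orientations(self, random_dna_factory):
        from annodbg.graph import primarize

        seq = random_dna_factory(300)
        canon = build_graph([seq], 9, mode="canonical")
        primary = primarize(canon)
        m = annotate(primary, [("S", [seq])])
        assert len(m.get_column(0)) == primary.n


class TestRepresentations:
    @pytest.mark.parametrize("target", REPRESENTATIONS)
    def test_equivalence_on_random_matrices(self, rng, target):
        for _ in range(5):
            base = random_matrix(rng, int(rng.integers(10, 80)), int(rng.integers(1, 12)))
            conv = convert_representation(base, target)
            for j in range(base.m):
                assert np.array_equal(conv.get_column(j), base.get_column(j))
            for i in range(base.n):
                assert np.array_equal(conv.get_row(i), base.get_row(i))

    def test_round_trip_conversion(self, rng):
        base = random_matrix(rng, 40, 6)
        back = convert_representation(
            convert_representation(base, "row_sparse"), "column_sparse"
        )
        assert np.array_equal(back.to_dense(), base.to_dense())

    def test_empty_matrix(self):
        m = matrix_from_columns(5, [np.empty(0, int)] * 3, ["a", "b", "c"], "brwt")
        assert all(len(m.get_column(j)) == 0 for j in range(3))
        assert all(len(m.get_row(i)) == 0 for i in range(5))

    def test_rowdiff_target_requires_graph(self, rng):
        base = random_matrix(rng, 10, 2)
        with pytest.raises(ValueError, match="graph"):
            convert_representation(base, "rowdiff<column_sparse>")


class TestRowDiff:
    def test_path_hand_example(self):
        # path ACG -> CGT -> GTA with rows [1,0], [1,0], [1,1]
        g = build_graph(["ACGTA"], 3)
        cols = [np.array([0, 1, 2]), np.array([g.node_index("GTA") - 1])]
        m = matrix_from_columns(3, cols, ["x", "y"])
        rd = rowdiff_transform(g, m)
        # non-anchor diffs: identical neighbour rows cancel
        for i in range(3):
            assert np.array_equal(rowdiff_reconstruct(rd, i), m.get_row(i))
        assert set_bit_count(rd) <= set_bit_count(m)

    def test_constant_matrix_diffs_are_empty_off_anchor(self, random_dna_factory):
        g = build_graph([random_dna_factory(100)], 7)
        cols = [np.arange(g.n), np.arange(g.n)]
        m = matrix_from_columns(g.n, cols, ["a", "b"])
        rd = rowdiff_transform(g, m)
        anchors = int(rd.rep.anchors.sum())
        assert set_bit_count(rd) == 2 * anchors

    def test_pure_cycle_gets_single_anchor(self):
        g = build_graph(["ACGACGACG"], 3)  # 3-node cycle
        m = matrix_from_columns(3, [np.array([0, 2])], ["a"])
        rd = rowdiff_transform(g, m)
        assert int(rd.rep.anchors.sum()) == 1
        for i in range(3):
            assert np.array_equal(rowdiff_reconstruct(rd, i), m.get_row(i))

    def test_anchor_row_stored_unchanged(self, rng, random_dna_factory):
        g = build_graph([random_dna_factory(120)], 7)
        m = random_matrix(rng, g.n, 4)
        rd = rowdiff_transform(g, m)
        anchors = np.flatnonzero(rd.rep.anchors)
        for i in anchors[:5]:
            assert np.array_equal(rd.rep.diff.get_row(int(i)), m.get_row(int(i)))

    def test_round_trip_on_random_graphs(self, rng, random_dna_factory):
        """Exact reconstruction over graphs with branches, cycles and
        multiple components."""
        for trial in range(30):
            seqs = [
                random_dna_factory(int(rng.integers(20, 150)))
                for _ in range(int(rng.integers(1, 4)))
            ]
            if trial % 3 == 0:
                seqs.append("ACGT" * 10)  # forced cycle component
            g = build_graph(seqs, 5)
            m = random_matrix(rng, g.n, int(rng.integers(1, 6)))
            rd = rowdiff_transform(g, m, anchor_spacing=int(rng.integers(2, 40)))
            for i in range(g.n):
                assert np.array_equal(rowdiff_reconstruct(rd, i), m.get_row(i))

    def test_sparsification_on_correlated_samples(self, random_dna_factory):
        # overlapping samples give near-identical neighbour rows
        base = random_dna_factory(400)
        samples = [("A", [base[:300]]), ("B", [base[100:]]), ("C", [base])]
        g = build_graph([base], 11)
        m = annotate(g, samples)
        rd = rowdiff_transform(g, m)
        assert set_bit_count(rd) <= set_bit_count(m)

    def test_anchor_spacing_bounds_chain_length(self, random_dna_factory):
        g = build_graph([random_dna_factory(500)], 7)
        m = matrix_from_columns(g.n, [np.arange(g.n)], ["x"])
        rd = rowdiff_transform(g, m, anchor_spacing=4)
        succ, anchors = rd.rep.successor, rd.rep.anchors
        for start in range(g.n):
            node, steps = start, 0
            while not anchors[node]:
                node = int(succ[node])
                steps += 1
                assert steps <= 4


class TestCountTransforms:
    def test_smooth_constant_unchanged(self):
        assert list(smooth_counts([7] * 9, 6)) == [7] * 9

    def test_smooth_removes_isolated_spike(self):
        assert list(smooth_counts([1, 100, 1, 1, 1], 2)) == [1, 1, 1, 1, 1]

    def test_smooth_window_zero_is_identity(self):
        assert list(smooth_counts([3, 1, 4, 1, 5], 0)) == [3, 1, 4, 1, 5]

    def test_smooth_rejects_bad_window(self):
        with pytest.raises(ValueError):
            smooth_counts([1, 2], -2)
        with pytest.raises(ValueError):
            smooth_counts([1, 2], 3)

    def test_aggregate_hand_example(self):
        # counts rows [[1,0],[2,3],[0,1]], v=[1,2], a=[1,2] -> all bits set
        counts = {
            0: (np.array([0, 1]), np.array([1, 2])),
            1: (np.array([1, 2]), np.array([3, 1])),
        }
        cols = [np.array([0, 1]), np.array([1, 2])]
        m = matrix_from_columns(3, cols, ["a", "b"], payload="counts", counts=counts)
        bits, sums = aggregate_columns(m, AggregationSpec(1, 2, 1, 2))
        assert list(bits) == [True, True, True]
        assert list(sums) == [1, 1, 1]

    def test_aggregate_vacuous_bounds_on_binary(self, rng):
        m = random_matrix(rng, 30, 5)
        bits, sums = aggregate_columns(m, AggregationSpec(1, 10**9, 0, 5))
        dense = m.to_dense()
        assert bits.all()
        assert np.array_equal(sums, dense.sum(axis=1))

    def test_aggregate_exact_row_requirement(self):
        cols = [np.array([1]), np.array([1])]
        m = matrix_from_columns(3, cols, ["a", "b"])
        bits, _ = aggregate_columns(m, AggregationSpec(1, 1, 2, 2))
        assert list(bits) == [False, True, False]

    def test_aggregate_invalid_bounds(self):
        with pytest.raises(ValueError):
            AggregationSpec(2, 1, 0, 1)

    def test_aggregate_matches_direct_formula_exhaustively(self):
        """Direct evaluation of the aggregation predicate on exhaustive
        small count matrices."""
        import itertools

        labels = ["a", "b"]
        for flat in itertools.product(range(3), repeat=4):  # 2x2 matrices
            counts_mat = np.array(flat).reshape(2, 2)
            cols, counts = [], {}
            for j in range(2):
                rows = np.flatnonzero(counts_mat[:, j])
                cols.append(rows)
                counts[j] = (rows, counts_mat[rows, j])
            m = matrix_from_columns(2, cols, labels, payload="counts", counts=counts)
            spec = AggregationSpec(1, 2, 1, 2)
            bits, sums = aggregate_columns(m, spec)
            for i in range(2):
                expected = sum(
                    1 for j in range(2) if spec.v_min <= counts_mat[i, j] <= spec.v_max
                )
                assert bits[i] == (spec.a_min <= expected <= spec.a_max)
                if bits[i]:
                    assert sums[i] == expected
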