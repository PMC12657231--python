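"""Annotation matrices: k-mer x label relations and their representations.

The annotation matrix A in {0,1}^(n x m) relates the n graph k-mers to m
labels (typically sample ids).  Several interchangeable representations are
provided — column-major sparse, flat row-major bitmasks, row-major sparse,
a fixed-arity binary tree over columns with OR-aggregate internal bit
vectors, and the RowDiff sparsification, which replaces each non-anchor row
with its XOR against the row of a designated successor node so that the
near-identical annotations of adjacent k-mers cancel.

Optional payloads attach k-mer counts (abundances) or coordinate tuples
(sequence index, 0-based offset) to the set bits; coordinates make the
encoding lossless with respect to the original sample sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph import DeBruijnGraph
from .kmers import reverse_complement

PAYLOADS = ("binary", "counts", "coordinates")


# ---------------------------------------------------------------------------
# representations: all expose n, m, get_row, get_column

class ColumnSparse:
    """Per-column sorted arrays of set row ids (column-major)."""

    name = "column_sparse"

    def __init__(self, n: int, columns: list[np.ndarray]):
        self.n = n
        self.columns = [np.asarray(c, dtype=np.int64) for c in columns]

    @property
    def m(self) -> int:
        return len(self.columns)

    def get_column(self, j: int) -> np.ndarray:
        return self.columns[j]

    def get_row(self, i: int) -> np.ndarray:
        return np.array(
            [j for j, col in enumerate(self.columns) if _sorted_contains(col, i)],
            dtype=np.int64,
        )


class RowFlat:
    """Per-row label bitmasks (row-major, flat)."""

    name = "row_flat"

    def __init__(self, n: int, m: int, masks: list[int]):
        self.n, self._m, self.masks = n, m, masks

    @property
    def m(self) -> int:
        return self._m

    def get_row(self, i: int) -> np.ndarray:
        mask = self.masks[i]
        return np.array([j for j in range(self._m) if mask >> j & 1], dtype=np.int64)

    def get_column(self, j: int) -> np.ndarray:
        bit = 1 << j
        return np.array([i for i in range(self.n) if self.masks[i] & bit], dtype=np.int64)


class RowSparse:
    """Per-row sorted arrays of set column ids (row-major, sparse)."""

    name = "row_sparse"

    def __init__(self, n: int, m: int, rows: list[np.ndarray]):
        self.n, self._m = n, m
        self.rows = [np.asarray(r, dtype=np.int64) for r in rows]

    @property
    def m(self) -> int:
        return self._m

    def get_row(self, i: int) -> np.ndarray:
        return self.rows[i]

    def get_column(self, j: int) -> np.ndarray:
        return np.array(
            [i for i, row in enumerate(self.rows) if _sorted_contains(row, j)],
            dtype=np.int64,
        )


class _BRWTNode:
    __slots__ = ("columns", "bits", "children")

    def __init__(self, columns: list[int], bits: np.ndarray, children: list):
        self.columns = columns  # global column ids under this node
        self.bits = bits  # over parent's set positions (root: all rows)
        self.children = children


class BRWT:
    """Arity-2 balanced tree over columns, labels in given order.

    Each internal node stores the OR-aggregate of its columns as a bit
    vector over the positions where the parent's aggregate is set; leaves
    store single columns the same way.
    """

    name = "brwt"

    def __init__(self, n: int, columns: list[np.ndarray]):
        self.n = n
        self._m = len(columns)
        dense = [np.zeros(n, dtype=bool) for _ in columns]
        for j, col in enumerate(columns):
            dense[j][np.asarray(col, dtype=np.int64)] = True
        self.root = self._build(list(range(self._m)), dense, np.ones(n, dtype=bool))

    def _build(self, cols: list[int], dense: list[np.ndarray], parent_set: np.ndarray):
        sub = [dense[j][parent_set] for j in cols]
        agg = np.zeros(int(parent_set.sum()), dtype=bool)
        for s in sub:
            agg |= s
        node = _BRWTNode(cols, agg, [])
        if len(cols) > 1:
            mid = (len(cols) + 1) // 2
            child_set = parent_set.copy()
            child_set[parent_set] = agg
            node.children = [
                self._build(cols[:mid], dense, child_set),
                self._build(cols[mid:], dense, child_set),
            ]
        return node

    @property
    def m(self) -> int:
        return self._m

    def get_column(self, j: int) -> np.ndarray:
        node, rows = self.root, np.flatnonzero(self.root.bits)
        while node.children:
            node = node.children[0] if j in node.children[0].columns else node.children[1]
            rows = rows[node.bits]
        return rows

    def get_row(self, i: int) -> np.ndarray:
        out: list[int] = []

        def descend(node: _BRWTNode, pos: int) -> None:
            if not node.bits[pos]:
                return
            if not node.children:
                out.extend(node.columns)
                return
            child_pos = int(np.count_nonzero(node.bits[:pos]))
            for child in node.children:
                descend(child, child_pos)

        descend(self.root, i)
        return np.array(sorted(out), dtype=np.int64)


def _sorted_contains(arr: np.ndarray, value: int) -> bool:
    pos = np.searchsorted(arr, value)
    return pos < len(arr) and arr[pos] == value


_REP_NAMES = ("column_sparse", "row_flat", "row_sparse", "brwt")


# ---------------------------------------------------------------------------
# the matrix facade

@dataclass
class AggregationSpec:
    v_min: float
    v_max: float
    a_min: float
    a_max: float

    def __post_init__(self) -> None:
        if self.v_min > self.v_max or self.a_min > self.a_max:
            raise ValueError("aggregation bounds must satisfy min <= max")


class AnnotationMatrix:
    """n x m binary relation with labels and an optional payload.

    ``rep`` is one of the representation objects above (or a
    :class:`RowDiffAnnotation`); row and column queries agree across all of
    them.  ``counts`` (when payload="counts") maps column -> (rows, values);
    ``coordinates`` (payload="coordinates") maps column -> {row: [(seq_idx,
    offset), ...]}.
    """

    def __init__(self, rep, labels: list[str], payload: str = "binary",
                 counts=None, coordinates=None):
        if payload not in PAYLOADS:
            raise ValueError(f"unknown payload {payload!r}")
        self.rep = rep
        self.labels = list(labels)
        self.payload = payload
        self.counts = counts
        self.coordinates = coordinates
        if rep.m != len(self.labels):
            raise ValueError("label count does not match matrix width")

    @property
    def n(self) -> int:
        return self.rep.n

    @property
    def m(self) -> int:
        return self.rep.m

    @property
    def representation(self) -> str:
        return self.rep.name

    def get_row(self, i: int) -> np.ndarray:
        return self.rep.get_row(i)

    def get_column(self, j: int) -> np.ndarray:
        return self.rep.get_column(j)

    def get_count(self, i: int, j: int) -> int:
        if self.payload != "counts":
            raise ValueError("matrix has no counts payload")
        rows, values = self.counts[j]
        pos = np.searchsorted(rows, i)
        if pos < len(rows) and rows[pos] == i:
            return int(values[pos])
        return 0

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n, self.m), dtype=bool)
        for j in range(self.m):
            out[self.get_column(j), j] = True
        return out

    def column_arrays(self) -> list[np.ndarray]:
        return [self.get_column(j) for j in range(self.m)]


def matrix_from_columns(n: int, columns: list[np.ndarray], labels: list[str],
                        representation: str = "column_sparse", **kw) -> AnnotationMatrix:
    rep = _make_rep(representation, n, len(labels), columns)
    return AnnotationMatrix(rep, labels, **kw)


def _make_rep(name: str, n: int, m: int, columns: list[np.ndarray]):
    if name == "column_sparse":
        return ColumnSparse(n, columns)
    if name == "brwt":
        return BRWT(n, columns)
    if name in ("row_flat", "row_sparse"):
        masks = [0] * n
        for j, col in enumerate(columns):
            bit = 1 << j
            for i in col:
                masks[int(i)] |= bit
        if name == "row_flat":
            return RowFlat(n, m, masks)
        rows = [
            np.array([j for j in range(m) if mask >> j & 1], dtype=np.int64)
            for mask in masks
        ]
        return RowSparse(n, m, rows)
    raise ValueError(f"unknown representation {name!r}")


# ---------------------------------------------------------------------------
# construction from samples

def annotate(
    joint_graph: DeBruijnGraph,
    samples: Sequence[tuple],
    payload: str = "binary",
    representation: str = "column_sparse",
) -> AnnotationMatrix:
    """Build the annotation matrix of a joint graph.

    ``samples`` is a list of ``(label, sequences)`` or ``(label, sequences,
    counts)`` tuples, where sequences are the (clean) contigs of the sample
    and counts, when given, are per-sequence arrays of per-k-mer abundances.
    Column j gets a set bit at every node whose k-mer occurs in sample j; a
    sample k-mer absent from the joint graph is an error (the joint graph
    must have been built from these contigs).
    """
    from .kmers import encode_sequence_dna

    k = joint_graph.k
    n = joint_graph.n
    labels = [s[0] for s in samples]
    columns: list[np.ndarray] = []
    counts_payload: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    coords_payload: dict[int, dict[int, list[tuple[int, int]]]] = {}

    for j, sample in enumerate(samples):
        label, sequences = sample[0], sample[1]
        given_counts = sample[2] if len(sample) > 2 else None
        row_hits: dict[int, int] = {}
        coords: dict[int, list[tuple[int, int]]] = {}
        for seq_idx, seq in enumerate(sequences):
            seq = seq if isinstance(seq, str) else seq.sequence
            rows = _map_sequence_rows(joint_graph, seq, label)
            weights = None
            if given_counts is not None:
                weights = np.asarray(given_counts[seq_idx])
                if len(weights) != len(rows):
                    raise ValueError(
                        f"sample {label!r}: counts length mismatch on sequence {seq_idx}"
                    )
            for offset, row in enumerate(rows):
                w = int(weights[offset]) if weights is not None else 1
                row_hits[row] = row_hits.get(row, 0) + w
                if payload == "coordinates":
                    coords.setdefault(row, []).append((seq_idx, offset))
        rows_sorted = np.array(sorted(row_hits), dtype=np.int64)
        columns.append(rows_sorted)
        if payload == "counts":
            counts_payload[j] = (
                rows_sorted,
                np.array([row_hits[r] for r in rows_sorted], dtype=np.int64),
            )
        elif payload == "coordinates":
            coords_payload[j] = coords

    rep = _make_rep(representation, n, len(labels), columns)
    return AnnotationMatrix(
        rep,
        labels,
        payload=payload,
        counts=counts_payload if payload == "counts" else None,
        coordinates=coords_payload if payload == "coordinates" else None,
    )


def _map_sequence_rows(graph: DeBruijnGraph, seq: str, label: str) -> np.ndarray:
    """0-based annotation rows of every k-mer of ``seq`` (mode-aware)."""
    from .kmers import encode_sequence_dna, revcomp_codes

    codes = encode_sequence_dna(seq, graph.k)
    if len(codes) < max(len(seq) - graph.k + 1, 0):
        # fall back to per-k-mer mapping to name the offending k-mer
        rows = []
        for off in range(len(seq) - graph.k + 1):
            kmer = seq[off : off + graph.k]
            idx, _ = graph.find(kmer)
            if idx == 0:
                raise KeyError(f"sample {label!r}: k-mer {kmer!r} absent from joint graph")
            rows.append(idx - 1)
        return np.array(rows, dtype=np.int64)
    pos = graph.code_positions(codes)
    if graph.mode == "primary":
        missing = pos < 0
        if missing.any():
            rc_pos = graph.code_positions(revcomp_codes(codes[missing], graph.k))
            pos[missing] = rc_pos
    if (pos < 0).any():
        off = int(np.flatnonzero(pos < 0)[0])
        raise KeyError(
            f"sample {label!r}: k-mer {seq[off:off + graph.k]!r} absent from joint graph"
        )
    return graph.position_to_index(pos) - 1


def decode_sample(matrix: AnnotationMatrix, graph: DeBruijnGraph, label: str) -> list[str]:
    """Reconstruct a sample's sequences from its coordinate annotations."""
    if matrix.payload != "coordinates":
        raise ValueError("decoding requires a coordinates payload")
    j = matrix.labels.index(label)
    indexes = graph.position_to_index(np.arange(graph.n))
    row_to_pos = np.empty(graph.n, dtype=np.int64)
    row_to_pos[indexes - 1] = np.arange(graph.n)
    placed: dict[int, dict[int, str]] = {}
    for row, occurrences in matrix.coordinates[j].items():
        kmer = graph.kmer_at_position(int(row_to_pos[row]))
        for seq_idx, offset in occurrences:
            placed.setdefault(seq_idx, {})[offset] = kmer
    out = []
    for seq_idx in sorted(placed):
        by_offset = placed[seq_idx]
        seq = by_offset[0]
        for offset in range(1, max(by_offset) + 1):
            seq += by_offset[offset][-1]
        out.append(seq)
    return out


# ---------------------------------------------------------------------------
# RowDiff

class RowDiffAnnotation:
    """RowDiff-transformed matrix: per-node successor pointers, anchor bits
    and sparsified diff rows (stored column-major)."""

    def __init__(self, n: int, m: int, successor: np.ndarray, anchors: np.ndarray,
                 diff: ColumnSparse):
        self.n, self._m = n, m
        self.successor = successor  # 0-based annotation row of successor, -1 none
        self.anchors = anchors  # bool over rows
        self.diff = diff
        self.name = f"rowdiff<{diff.name}>"

    @property
    def m(self) -> int:
        return self._m

    def get_row(self, i: int) -> np.ndarray:
        mask = 0
        node = i
        for _ in range(self.n + 1):
            for j in self.diff.get_row(node):
                mask ^= 1 << int(j)
            if self.anchors[node]:
                row = np.array([j for j in range(self._m) if mask >> j & 1], dtype=np.int64)
                return row
            node = int(self.successor[node])
            if node < 0:
                raise RuntimeError("successor chain ended before an anchor (corrupt rowdiff)")
        raise RuntimeError("successor chain exceeded matrix size (corrupt rowdiff)")

    def get_column(self, j: int) -> np.ndarray:
        return np.array([i for i in range(self.n) if _sorted_contains(self.get_row(i), j)],
                        dtype=np.int64)


def rowdiff_transform(
    graph: DeBruijnGraph,
    matrix: AnnotationMatrix,
    anchor_spacing: int = 32,
) -> AnnotationMatrix:
    """Apply the RowDiff transform to an annotation matrix.

    Every node with outgoing edges points at one successor (the edge with the
    smallest target node index); its row is replaced by the XOR with the
    successor's row.  Anchors — sink nodes, one node per successor cycle, and
    every ``anchor_spacing``-th node along successor chains — keep their
    original rows, so reconstruction always terminates.
    """
    if matrix.n != graph.n:
        raise ValueError("matrix rows are not aligned with graph nodes")
    n, m = matrix.n, matrix.m
    adj = graph._adjacency()
    succ_pos = adj["succ"]

    # annotation row of each node position
    pos_to_row = graph.position_to_index(np.arange(n)) - 1
    row_to_pos = np.empty(n, dtype=np.int64)
    row_to_pos[pos_to_row] = np.arange(n)

    successor = np.full(n, -1, dtype=np.int64)  # in row coordinates
    for pos in range(n):
        targets = succ_pos[pos][succ_pos[pos] >= 0]
        if len(targets):
            successor[pos_to_row[pos]] = pos_to_row[targets.min()]

    anchors = successor < 0  # sinks

    # break successor cycles: smallest row of each unresolved cycle
    color = np.zeros(n, dtype=np.int8)  # 0 new, 1 active, 2 done
    for start in range(n):
        if color[start]:
            continue
        chain = []
        node = start
        while True:
            if color[node] == 1:  # found a new cycle
                cycle_start = chain.index(node)
                cycle = chain[cycle_start:]
                anchors[min(cycle)] = True
                break
            if color[node] == 2 or anchors[node]:
                break
            color[node] = 1
            chain.append(node)
            nxt = int(successor[node])
            if nxt < 0:
                break
            node = nxt
        for v in chain:
            color[v] = 2

    # enforce anchor spacing along chains (distance-to-anchor <= spacing)
    dist = np.full(n, -1, dtype=np.int64)
    dist[anchors] = 0
    for start in range(n):
        if dist[start] >= 0:
            continue
        chain = []
        node = start
        while dist[node] < 0:
            chain.append(node)
            node = int(successor[node])
        d = int(dist[node])
        for v in reversed(chain):
            d += 1
            if d >= anchor_spacing and not anchors[v]:
                anchors[v] = True
                d = 0
            dist[v] = d

    # diff rows
    row_bits = _row_masks(matrix)
    diff_cols: list[list[int]] = [[] for _ in range(m)]
    for i in range(n):
        mask = row_bits[i]
        if not anchors[i]:
            mask ^= row_bits[successor[i]]
        for j in range(m):
            if mask >> j & 1:
                diff_cols[j].append(i)
    diff = ColumnSparse(n, [np.array(c, dtype=np.int64) for c in diff_cols])
    rep = RowDiffAnnotation(n, m, successor, anchors, diff)
    return AnnotationMatrix(rep, matrix.labels, payload="binary")


def rowdiff_reconstruct(matrix: AnnotationMatrix, node: int) -> np.ndarray:
    """Original row of a node from its RowDiff form (exact)."""
    if not isinstance(matrix.rep, RowDiffAnnotation):
        raise TypeError("matrix is not RowDiff-transformed")
    return matrix.rep.get_row(node)


def _row_masks(matrix: AnnotationMatrix) -> list[int]:
    masks = [0] * matrix.n
    for j in range(matrix.m):
        bit = 1 << j
        for i in matrix.get_column(j):
            masks[int(i)] |= bit
    return masks


def set_bit_count(matrix: AnnotationMatrix) -> int:
    if isinstance(matrix.rep, RowDiffAnnotation):
        return sum(len(c) for c in matrix.rep.diff.columns)
    return sum(len(matrix.get_column(j)) for j in range(matrix.m))


# ---------------------------------------------------------------------------
# conversions

def convert_representation(
    matrix: AnnotationMatrix,
    target: str,
    graph: DeBruijnGraph | None = None,
    anchor_spacing: int = 32,
) -> AnnotationMatrix:
    """Convert between representations; semantics are preserved exactly."""
    if target.startswith("rowdiff"):
        if graph is None:
            raise ValueError("rowdiff conversion requires a graph handle")
        inner = target[len("rowdiff"):].strip("<>") or "column_sparse"
        rd = rowdiff_transform(graph, matrix, anchor_spacing)
        if inner != "column_sparse":
            raise ValueError("rowdiff only supports a column_sparse inner form here")
        return rd
    columns = matrix.column_arrays()
    rep = _make_rep(target, matrix.n, matrix.m, columns)
    return AnnotationMatrix(
        rep, matrix.labels, payload=matrix.payload,
        counts=matrix.counts, coordinates=matrix.coordinates,
    )


# ---------------------------------------------------------------------------
# count transforms

def smooth_counts(unitig_counts: Sequence[int], window: int) -> np.ndarray:
    """Median-smooth per-unitig k-mer counts.

    Each position is replaced by the median of the counts at most
    ``window/2`` positions away within the same unitig (window truncated at
    the boundaries).  ``window`` must be even; 0 is the identity.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if window % 2:
        raise ValueError("window must be even")
    arr = np.asarray(unitig_counts)
    if window == 0 or len(arr) == 0:
        return arr.copy()
    half = window // 2
    out = np.empty_like(arr)
    for i in range(len(arr)):
        lo, hi = max(0, i - half), min(len(arr), i + half + 1)
        window_vals = np.sort(arr[lo:hi])
        out[i] = window_vals[(len(window_vals) - 1) // 2]  # lower median
    return out


def aggregate_columns(
    matrix: AnnotationMatrix, spec: AggregationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate the columns of a (counted) annotation matrix.

    Bit i of the result is set when a_min <= sum_j 1[v_min <= c_ij <= v_max]
    <= a_max, where c_ij is the count payload (1 at set bits for binary
    matrices); the returned count vector holds that sum where the bit is set.
    """
    n, m = matrix.n, matrix.m
    in_range_sum = np.zeros(n, dtype=np.int64)
    for j in range(m):
        if matrix.payload == "counts":
            rows, values = matrix.counts[j]
        else:
            rows = matrix.get_column(j)
            values = np.ones(len(rows), dtype=np.int64)
        hit = (values >= spec.v_min) & (values <= spec.v_max)
        in_range_sum[rows[hit]] += 1
    bits = (in_range_sum >= spec.a_min) & (in_range_sum <= spec.a_max)
    counts = np.where(bits, in_range_sum, 0)
    return bits, counts
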