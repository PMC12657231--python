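"""Exact k-mer search and label discovery (experiment discovery).

A query is matched k-mer by k-mer against the graph; for primary graphs a
k-mer matches when it or its reverse complement is stored, and an
orientation-switch heuristic (keep querying the orientation that hit last)
avoids most double lookups without changing any result.  Labels are
reported when the fraction of query k-mers carrying them reaches a cutoff.

The batched algorithm builds an intermediate batch graph from each query
batch, extracts its non-redundant contigs, maps those against the joint
graph once, materialises the annotated intersection as a small
hash-backend "query graph", and answers every query of the batch against
it — with results identical to per-query search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationMatrix, matrix_from_columns
from .graph import DeBruijnGraph, HashDBG, build_graph, extract_contigs
from .kmers import reverse_complement


@dataclass
class QueryConfig:
    min_kmers_fraction_label: float = 0.7
    min_kmers_fraction_graph: float = 0.0
    num_top_labels: int | None = None
    batch_size: int = 8_000_000  # query base pairs per batch

    def __post_init__(self) -> None:
        for f in (self.min_kmers_fraction_label, self.min_kmers_fraction_graph):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


@dataclass
class LabelHit:
    label: str
    fraction: float
    matched_kmers: int
    total_kmers: int
    count_sum: int | None = None
    kmer_counts: list[int] | None = None


@dataclass
class MatchProfile:
    query_id: str
    node_indices: np.ndarray  # per query k-mer, 0 = unmatched
    total_kmers: int
    labels: list[LabelHit] = field(default_factory=list)
    status: str = "ok"  # ok | too_short | below_graph_fraction

    @property
    def graph_fraction(self) -> float:
        if self.total_kmers == 0:
            return 0.0
        return float(np.count_nonzero(self.node_indices)) / self.total_kmers


@dataclass
class GraphIndex:
    """A joint de Bruijn graph with its annotation matrix."""

    graph: DeBruijnGraph
    annotation: AnnotationMatrix | None = None


def match_kmers(graph: DeBruijnGraph, query: str) -> np.ndarray:
    """Node index of every query k-mer (0 when unmatched).

    For primary graphs each k-mer matches if either orientation is stored.
    The orientation-switch heuristic only reorders the two lookups; results
    equal the naive both-orientation lookup by construction (a stored k-mer
    guarantees its reverse complement is absent from a primary graph).
    """
    k = graph.k
    total = len(query) - k + 1
    if total <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(total, dtype=np.int64)
    if graph.mode != "primary":
        for i in range(total):
            out[i] = graph.node_index(query[i : i + k])
        return out
    prefer_rc = False
    for i in range(total):
        kmer = query[i : i + k]
        first = reverse_complement(kmer) if prefer_rc else kmer
        idx = graph.node_index(first)
        if idx == 0:
            second = kmer if prefer_rc else reverse_complement(kmer)
            idx = graph.node_index(second)
            if idx:
                prefer_rc = not prefer_rc
        out[i] = idx
    return out


def query_labels(
    index: GraphIndex,
    query,
    config: QueryConfig | None = None,
) -> MatchProfile:
    """Label discovery for a single query sequence (or record)."""
    config = config or QueryConfig()
    query_id, seq = _query_parts(query)
    graph = index.graph
    if len(seq) < graph.k:
        return MatchProfile(query_id, np.empty(0, dtype=np.int64), 0, status="too_short")
    nodes = match_kmers(graph, seq)
    profile = MatchProfile(query_id, nodes, len(nodes))
    if profile.graph_fraction < config.min_kmers_fraction_graph:
        profile.status = "below_graph_fraction"
        return profile
    if index.annotation is None:
        return profile
    profile.labels = _label_hits(index.annotation, nodes, config)
    return profile


def _label_hits(annotation: AnnotationMatrix, nodes: np.ndarray,
                config: QueryConfig) -> list[LabelHit]:
    total = len(nodes)
    if total == 0:
        return []
    matched = nodes[nodes > 0] - 1  # annotation rows
    per_label = np.zeros(annotation.m, dtype=np.int64)
    # batch the row queries: count each distinct row once per occurrence
    rows, mult = np.unique(matched, return_counts=True)
    row_labels: dict[int, np.ndarray] = {}
    for row, times in zip(rows, mult):
        labs = annotation.get_row(int(row))
        row_labels[int(row)] = labs
        per_label[labs] += times
    hits = []
    for j in np.argsort(-per_label, kind="stable"):
        if per_label[j] == 0:
            continue
        fraction = per_label[j] / total
        if fraction < config.min_kmers_fraction_label:
            continue
        hit = LabelHit(annotation.labels[j], float(fraction), int(per_label[j]), total)
        if annotation.payload == "counts":
            counts = [annotation.get_count(int(r), int(j)) for r in matched
                      if _has_label(row_labels[int(r)], j)]
            hit.kmer_counts = counts
            hit.count_sum = int(sum(counts))
        hits.append(hit)
    if config.num_top_labels is not None:
        hits = hits[: config.num_top_labels]
    return hits


def _has_label(labs: np.ndarray, j: int) -> bool:
    pos = np.searchsorted(labs, j)
    return pos < len(labs) and labs[pos] == j


def _query_parts(query) -> tuple[str, str]:
    if isinstance(query, str):
        return "query", query
    return query.id, query.sequence


# ---------------------------------------------------------------------------
# batched search

def batch_query(
    index: GraphIndex,
    queries,
    config: QueryConfig | None = None,
) -> list[MatchProfile]:
    """Batched label discovery, equivalent to mapping :func:`query_labels`.

    Five steps per batch: (1) build the batch graph from the query
    sequences; (2) extract its non-redundant contigs; (3) map the contigs
    against the joint graph; (4) materialise the annotated intersection as a
    hash-backend query graph; (5) answer every query against it.
    """
    config = config or QueryConfig()
    results: list[MatchProfile] = []
    batch: list = []
    batch_bp = 0
    for query in queries:
        _, seq = _query_parts(query)
        batch.append(query)
        batch_bp += len(seq)
        if batch_bp >= config.batch_size:
            results.extend(_run_batch(index, batch, config))
            batch, batch_bp = [], 0
    if batch:
        results.extend(_run_batch(index, batch, config))
    return results


def _run_batch(index: GraphIndex, batch: list, config: QueryConfig) -> list[MatchProfile]:
    graph = index.graph
    k = graph.k
    seqs = [_query_parts(q)[1] for q in batch]
    usable = [s for s in seqs if len(s) >= k]
    if not usable:
        return [query_labels(index, q, config) for q in batch]

    # steps 1-2: batch graph and its non-redundant contigs
    batch_graph = build_graph(usable, k, mode="basic", backend="hash",
                              alphabet=graph.alphabet)
    contigs = extract_contigs(batch_graph, "contig")

    # step 3: map contigs onto the joint graph (mode-aware per-k-mer lookup)
    joint_index_of: dict[str, int] = {}
    annotation_rows: dict[int, np.ndarray] = {}
    kept_kmers: list[str] = []
    for contig in contigs.contigs:
        for off in range(len(contig) - k + 1):
            kmer = contig[off : off + k]
            idx, _ = graph.find(kmer)
            if idx == 0:
                continue
            joint_index_of[kmer] = idx
            kept_kmers.append(kmer)
            if index.annotation is not None and (idx - 1) not in annotation_rows:
                annotation_rows[idx - 1] = index.annotation.get_row(idx - 1)

    # step 4: the query graph — intersection of batch and joint k-mer sets
    query_index = _materialize_query_graph(
        index, kept_kmers, joint_index_of, annotation_rows, k, graph.alphabet
    )

    # step 5: per-query search against the query graph; node indices are
    # translated back to joint-graph indices for the reported profiles
    out = []
    for query in batch:
        profile = query_labels(query_index, query, config) if query_index else \
            query_labels(GraphIndex(graph, index.annotation), query, config)
        out.append(_translate_profile(profile, query_index, graph, index))
    return out


def _materialize_query_graph(index, kept_kmers, joint_index_of, annotation_rows,
                             k, alphabet) -> GraphIndex | None:
    if not kept_kmers:
        kept_kmers = []
    qgraph = build_graph(kept_kmers or ["A" * k], k, mode="basic", backend="hash",
                         alphabet=alphabet)
    if not kept_kmers:
        qgraph = HashDBG(np.empty(0, dtype=np.int64), k, "basic", alphabet)
    # joint index and annotation row per query-graph node
    joint_of_node = np.zeros(qgraph.n + 1, dtype=np.int64)
    for kmer, joint_idx in joint_index_of.items():
        joint_of_node[qgraph.node_index(kmer)] = joint_idx
    annotation = None
    if index.annotation is not None:
        m = index.annotation.m
        cols: list[list[int]] = [[] for _ in range(m)]
        counts = {j: ([], []) for j in range(m)} if index.annotation.payload == "counts" else None
        for node in range(1, qgraph.n + 1):
            row = joint_of_node[node] - 1
            for j in annotation_rows.get(int(row), ()):  # absent -> unannotated
                cols[int(j)].append(node - 1)
                if counts is not None:
                    counts[int(j)][0].append(node - 1)
                    counts[int(j)][1].append(index.annotation.get_count(int(row), int(j)))
        annotation = matrix_from_columns(
            qgraph.n,
            [np.array(c, dtype=np.int64) for c in cols],
            index.annotation.labels,
            payload=index.annotation.payload,
            counts={j: (np.array(r, dtype=np.int64), np.array(v, dtype=np.int64))
                    for j, (r, v) in counts.items()} if counts is not None else None,
        )
    qindex = GraphIndex(qgraph, annotation)
    qindex._joint_of_node = joint_of_node  # type: ignore[attr-defined]
    return qindex


def _translate_profile(profile: MatchProfile, query_index: GraphIndex | None,
                       graph, index) -> MatchProfile:
    if query_index is None or not hasattr(query_index, "_joint_of_node"):
        return profile
    mapping = query_index._joint_of_node
    profile.node_indices = mapping[profile.node_indices]
    return profile


# ---------------------------------------------------------------------------
# reporting

def profiles_to_tsv(profiles, path) -> None:
    """Query report: one row per (query, reported label)."""
    lines = ["query_id\tlabel\tmatched_fraction\tmatched_kmers\ttotal_kmers\tcount_sum"]
    for p in profiles:
        if not p.labels:
            lines.append(f"{p.query_id}\t-\t0\t0\t{p.total_kmers}\t-")
        for hit in p.labels:
            count = hit.count_sum if hit.count_sum is not None else "-"
            lines.append(
                f"{p.query_id}\t{hit.label}\t{hit.fraction:.6g}\t"
                f"{hit.matched_kmers}\t{hit.total_kmers}\t{count}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
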