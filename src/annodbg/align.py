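"""Seed-and-extend sequence-to-graph alignment.

Seeds are maximal runs of exact k-mer matches confined to a unitig
(Uni-MEMs); with a BOSS backend, seeds shorter than k can additionally be
found by matching query substrings to k-mer suffixes through contiguous
node ranges.  Each seed is extended forwards and backwards through the
graph with a generalisation of the Smith-Waterman-Gotoh affine-gap
algorithm: every node of the growing alignment tree carries score vectors
S (best), E (ending in insertion) and F (ending in deletion) over the
query, explored best-first by local score update.  The search space is
restricted by the X-drop rule (cells more than X below the running best
are discarded), by an aggregate score column per graph node (a tree node
that fails to improve it is dropped), and by a total node budget
proportional to the query length.

For primary graphs the extension traverses the implicit canonical graph:
children of a node are its stored children plus the parents of its reverse
complement, so alignments match those against the explicit canonical graph.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np

from .graph import DeBruijnGraph
from .kmers import reverse_complement
from .search import GraphIndex, QueryConfig, query_labels

NEG = -(10**9)


@dataclass
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: float = 27
    node_budget_factor: float = 20
    min_seed_length: int = 19
    min_exact_match: float = 0.0
    num_alignments: int = 1

    def __post_init__(self) -> None:
        if self.match < 0 or self.mismatch > 0:
            raise ValueError("match must be >= 0 and mismatch <= 0")
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError("need gap_open <= gap_extend <= 0")
        if self.xdrop < 0:
            raise ValueError("xdrop must be >= 0")

    def substitution(self, a: str, b: str) -> int:
        return self.match if a == b else self.mismatch


FAST_PROFILE = dict(min_exact_match=0.85, min_seed_length=27)
SENSITIVE_PROFILE = dict(min_exact_match=0.0, min_seed_length=27)


@dataclass
class Seed:
    query_start: int
    length: int  # matched characters
    kmers: list[str]  # oriented node strings along the seed path
    orientation: str = "+"
    node_offset: int = 0  # >0 for sub-k seeds: match starts inside the node

    @property
    def query_end(self) -> int:
        return self.query_start + self.length


@dataclass
class Alignment:
    query_id: str
    score: int
    identity: float  # exactly matching query nucleotides / query length
    spelled: str
    ops: str  # CIGAR-style: = X I D (I = query insertion)
    node_path: list[int]
    orientation: str = "+"
    query_start: int = 0
    query_end: int = 0


# ---------------------------------------------------------------------------
# seeding

def find_seeds(graph: DeBruijnGraph, query: str, scheme: ScoringScheme | None = None,
               orientation: str = "+") -> list[Seed]:
    """All Uni-MEM seeds of the query, longest first.

    Sub-k suffix seeds (min_seed_length < k) are generated through the BOSS
    range mechanism for query positions not already covered by a k-mer seed.
    """
    scheme = scheme or ScoringScheme()
    k = graph.k
    seeds: list[Seed] = []
    n_pos = len(query) - k + 1
    matched: list[str | None] = []
    for i in range(max(n_pos, 0)):
        kmer = query[i : i + k]
        idx, orient = graph.find(kmer)
        matched.append(kmer if idx else None)

    run_start = None
    for i in range(len(matched) + 1):
        here = matched[i] if i < len(matched) else None
        junction = False
        if here is not None and run_start is not None and i > run_start:
            # unitig boundary between consecutive matches splits the seed
            junction = (graph.out_degree(matched[i - 1]) > 1
                        or graph.in_degree(here) > 1)
        if here is None or junction:
            if run_start is not None:
                kmers = [m for m in matched[run_start:i]]
                seeds.append(Seed(run_start, (i - run_start) + k - 1, kmers, orientation))
                run_start = i if junction else None
        elif run_start is None:
            run_start = i

    min_len = scheme.min_seed_length
    seeds = [s for s in seeds if s.length >= max(min_len, k)]

    if min_len < k and graph.backend == "boss":
        covered = np.zeros(len(query), dtype=bool)
        for s in seeds:
            covered[s.query_start : s.query_end] = True
        seeds.extend(_subk_seeds(graph, query, min_len, covered, orientation))
    seeds.sort(key=lambda s: (-s.length, s.query_start))
    return seeds


def _subk_seeds(graph: DeBruijnGraph, query: str, kp: int, covered: np.ndarray,
                orientation: str, cap: int = 200) -> list[Seed]:
    """Sub-k seeds via the three-step BOSS suffix-range procedure: forward
    suffix ranges, reverse-complement ranges, and k-k' forward range steps."""
    k = graph.k
    out: list[Seed] = []
    for i in range(len(query) - kp + 1):
        if covered[i : i + kp].any():
            continue
        sub = query[i : i + kp]
        if any(c not in graph.alphabet.symbols for c in sub):
            continue
        hits: list[str] = []
        # step 1: forward matches — stored k-mers with suffix `sub`
        rng = graph.suffix_range(sub)
        for pos in rng.positions[:cap]:
            hits.append(_boss_kmer_string(graph, pos))
        # steps 2-3: matches stored in reverse complement: node ranges for
        # rc(sub), walked k-1-k' steps forward so rc(sub) becomes a prefix
        rc = reverse_complement(sub)
        digits = np.array([graph.alphabet.index(c) + 1 for c in rc], dtype=np.uint8)
        ranges = [graph.boss.node_range_for_suffix(digits)]
        for _ in range(k - 1 - kp):
            nxt = []
            for lo, hi in ranges:
                if lo >= hi:
                    continue
                for c in range(1, graph.alphabet.size + 1):
                    r2 = graph.boss.extend_node_range(lo, hi, c)
                    if r2[0] < r2[1]:
                        nxt.append(r2)
            ranges = nxt
        for lo, hi in ranges:
            start, stop = graph.boss.node_edge_span(lo, hi)
            for pos in range(start, stop):
                if graph.boss.real[pos]:
                    hits.append(reverse_complement(_boss_kmer_string(graph, pos)))
        for kmer in hits[:cap]:
            out.append(Seed(i, kp, [kmer], orientation, node_offset=k - kp))
    return out


def _boss_kmer_string(graph: DeBruijnGraph, pos: int) -> str:
    digits = graph.boss.kmer_at(int(pos))
    return "".join(graph.alphabet.symbols[d - 1] for d in digits)


# ---------------------------------------------------------------------------
# extension

class _State:
    __slots__ = ("sid", "parent", "char", "kmer", "chain", "S", "E", "F")

    def __init__(self, sid, parent, char, kmer, chain):
        self.sid = sid
        self.parent = parent
        self.char = char  # graph character this state consumes ('' at root)
        self.kmer = kmer  # oriented k-mer after this step (None in chains)
        self.chain = chain  # forced characters still to consume


class _Extension:
    """Best-first affine-gap DP over the alignment tree of one direction."""

    def __init__(self, graph: DeBruijnGraph, segment: str, init_chars: str,
                 start_kmer: str, scheme: ScoringScheme, backward: bool):
        self.graph = graph
        self.s = segment
        self.scheme = scheme
        self.backward = backward
        self.L = len(segment)
        self.best_score = 0
        self.best_cell: tuple[_State, int] | None = None
        self.aggregate: dict = {}
        self.states: list[_State] = []
        root = _State(0, None, "", None, (init_chars, start_kmer))
        root.S = np.full(self.L + 1, NEG, dtype=np.int64)
        root.E = np.full(self.L + 1, NEG, dtype=np.int64)
        root.F = np.full(self.L + 1, NEG, dtype=np.int64)
        root.S[0] = 0
        if self.L >= 1:
            # insertions opened right at the anchor
            gaps = scheme.gap_open + np.arange(self.L) * scheme.gap_extend
            root.E[1:] = gaps
            root.S[1:] = gaps
        self.states.append(root)

    def run(self) -> None:
        scheme = self.scheme
        budget = scheme.node_budget_factor * max(self.L, 1)
        counter = 0
        heap: list = []
        tie = 0

        def push_children(state: _State) -> None:
            nonlocal tie
            chain, kmer = state.chain
            if chain:
                children = [(chain[0], kmer, (chain[1:], kmer), None)]
            else:
                children = []
                if self.backward:
                    for pred in self.graph.predecessor_kmers(kmer):
                        children.append((pred[0], pred, ("", pred), pred))
                else:
                    for succ in self.graph.successor_kmers(kmer):
                        children.append((succ[-1], succ, ("", succ), succ))
            prio = -int(state.S.max())
            for char, node_kmer, chain_next, _ in children:
                child = _State(len(self.states), state, char, node_kmer, chain_next)
                self.states.append(child)
                heapq.heappush(heap, (prio, tie, child))
                tie += 1

        push_children(self.states[0])
        while heap:
            if counter >= budget:
                break
            _, _, state = heapq.heappop(heap)
            counter += 1
            self._compute(state)
            smax = int(state.S.max())
            if smax <= NEG // 2 and int(state.F.max()) <= NEG // 2:
                continue  # X-dropped everywhere
            if smax > self.best_score:
                self.best_score = smax
                self.best_cell = (state, int(state.S.argmax()))
            if not self._improves_aggregate(state):
                continue
            push_children(state)

    def _compute(self, state: _State) -> None:
        scheme, s = self.scheme, self.s
        p = state.parent
        L = self.L
        go, ge = scheme.gap_open, scheme.gap_extend
        F = np.maximum(p.S + go, p.F + ge)
        sub = np.array([scheme.substitution(state.char, c) for c in s], dtype=np.int64)
        diag = np.concatenate([[NEG], p.S[:-1] + sub])
        S_woE = np.maximum(diag, F)
        # E[i] = max_{j<i} S[j] + go + (i-1-j) ge, computed by accumulate
        t = S_woE - np.arange(L + 1) * ge + go
        acc = np.maximum.accumulate(t)
        E = np.full(L + 1, NEG, dtype=np.int64)
        if L >= 1:
            E[1:] = acc[:-1] + np.arange(L) * ge
        S = np.maximum(S_woE, E)
        cutoff = self.best_score - self.scheme.xdrop
        S[S < cutoff] = NEG
        F[F < cutoff] = NEG
        state.S, state.E, state.F = S, E, F

    def _improves_aggregate(self, state: _State) -> bool:
        if state.chain[0]:
            return True  # forced intra-node chain: the only route onward
        key = state.kmer
        prev = self.aggregate.get(key)
        if prev is None:
            self.aggregate[key] = state.S.copy()
            return True
        improved = bool((state.S > prev).any())
        if improved:
            np.maximum(prev, state.S, out=prev)
        return improved

    # -- traceback ------------------------------------------------------

    def traceback(self) -> tuple[list[str], list[str], int]:
        """(ops, graph chars, end position); ops ordered root -> best cell."""
        if self.best_cell is None:
            return [], [], 0
        state, i = self.best_cell
        ops: list[str] = []
        chars: list[str] = []
        layer = "S"
        while state.parent is not None or i > 0 or layer != "S":
            if layer == "S":
                if state.parent is None:
                    # only E cells are reachable at the root beyond position 0
                    layer = "E"
                    continue
                p = state.parent
                diag = p.S[i - 1] + self.scheme.substitution(state.char, self.s[i - 1]) \
                    if i >= 1 else NEG
                if i >= 1 and state.S[i] == diag and p.S[i - 1] > NEG // 2:
                    ops.append("=" if state.char == self.s[i - 1] else "X")
                    chars.append(state.char)
                    state, i = p, i - 1
                elif state.S[i] == state.F[i]:
                    layer = "F"
                elif state.S[i] == state.E[i]:
                    layer = "E"
                else:  # X-dropped intermediate; fall back to F then E
                    layer = "F" if state.F[i] > NEG // 2 else "E"
            elif layer == "F":
                p = state.parent
                ops.append("D")
                chars.append(state.char)
                if state.F[i] == p.F[i] + self.scheme.gap_extend:
                    state, layer = p, "F"
                else:
                    state, layer = p, "S"
            else:  # E: insertion consumes a query character in this state
                ops.append("I")
                if state.E[i] == state.E[i - 1] + self.scheme.gap_extend:
                    i -= 1
                else:
                    i -= 1
                    layer = "S"
        ops.reverse()
        chars.reverse()
        return ops, chars, self.best_cell[1]


def extend_seed(graph: DeBruijnGraph, seed: Seed, query: str,
                scheme: ScoringScheme | None = None,
                query_id: str = "query") -> list[Alignment]:
    """Extend one seed forwards and backwards into a full local alignment."""
    scheme = scheme or ScoringScheme()
    root = seed.kmers[0]
    offset = seed.node_offset

    fwd = _Extension(graph, query[seed.query_start :], root[offset:], root,
                     scheme, backward=False)
    fwd.run()
    bwd = _Extension(graph, query[: seed.query_start][::-1], root[:offset][::-1],
                     root, scheme, backward=True)
    bwd.run()

    if fwd.best_cell is None and bwd.best_cell is None:
        return []
    f_ops, f_chars, f_end = fwd.traceback()
    b_ops, b_chars, b_end = bwd.traceback()

    ops = b_ops[::-1] + f_ops
    spelled = "".join(b_chars[::-1]) + "".join(f_chars)
    score = fwd.best_score + bwd.best_score
    q_start = seed.query_start - b_end
    q_end = seed.query_start + f_end
    exact = sum(1 for o in ops if o == "=")
    identity = exact / len(query) if query else 0.0
    node_path = _path_nodes(graph, spelled)
    return [Alignment(query_id, int(score), identity, spelled, "".join(ops),
                      node_path, seed.orientation, q_start, q_end)]


def _path_nodes(graph: DeBruijnGraph, spelled: str) -> list[int]:
    k = graph.k
    out = []
    for i in range(len(spelled) - k + 1):
        idx, _ = graph.find(spelled[i : i + k])
        out.append(idx)
    return out


# ---------------------------------------------------------------------------
# full pipeline

def align(
    index: GraphIndex | DeBruijnGraph,
    query,
    profile: str | None = None,
    scheme: ScoringScheme | None = None,
    query_config: QueryConfig | None = None,
    max_seeds: int = 8,
    labels_from_all: bool = False,
) -> list[tuple[Alignment, list]]:
    """Align a query against an index; fetch labels for the aligned walk.

    ``profile`` "fast" sets (min_exact_match, min_seed_length) = (0.85, 27),
    "sensitive" sets (0.0, 27).  Labels are obtained by running the label
    query on the spelled sequence of the reported alignment in place of the
    raw query (of the best alignment only, unless ``labels_from_all``).
    """
    if isinstance(index, DeBruijnGraph):
        index = GraphIndex(index)
    graph = index.graph
    scheme = scheme or ScoringScheme()
    if profile is not None:
        presets = {"fast": FAST_PROFILE, "sensitive": SENSITIVE_PROFILE}
        if profile not in presets:
            raise ValueError(f"unknown alignment profile {profile!r}")
        scheme = replace(scheme, **presets[profile])

    if isinstance(query, str):
        query_id, seq = "query", query
    else:
        query_id, seq = query.id, query.sequence

    orientations = [("+", seq)]
    if graph.mode == "basic":
        orientations.append(("-", reverse_complement(seq)))

    candidates: list[Alignment] = []
    for orient, oriented_seq in orientations:
        seeds = find_seeds(graph, oriented_seq, scheme, orient)
        for seed in seeds[:max_seeds]:
            candidates.extend(
                extend_seed(graph, seed, oriented_seq, scheme, query_id)
            )
    candidates = [a for a in candidates if a.identity >= scheme.min_exact_match]
    candidates.sort(key=lambda a: (-a.score, a.spelled))
    deduped: list[Alignment] = []
    for a in candidates:
        if not any(a.spelled == b.spelled and a.query_start == b.query_start
                   for b in deduped):
            deduped.append(a)
    results = deduped[: scheme.num_alignments]

    out = []
    fetch = results if labels_from_all else results[:1]
    for alignment in results:
        labels = []
        if index.annotation is not None and alignment in fetch \
                and len(alignment.spelled) >= graph.k:
            profile_result = query_labels(index, alignment.spelled, query_config)
            labels = profile_result.labels
        out.append((alignment, labels))
    return out


def alignments_to_tsv(rows, path) -> None:
    """GAF-like TSV: query, orientation, span, path, score, identity, ops."""
    from pathlib import Path

    lines = ["query_id\torientation\tquery_start\tquery_end\tspelled_length"
             "\tscore\tidentity\tops\tnode_path\tlabels"]
    for alignment, labels in rows:
        labs = ",".join(h.label for h in labels) if labels else "-"
        path_str = ",".join(str(n) for n in alignment.node_path)
        lines.append(
            f"{alignment.query_id}\t{alignment.orientation}\t{alignment.query_start}"
            f"\t{alignment.query_end}\t{len(alignment.spelled)}\t{alignment.score}"
            f"\t{alignment.identity:.4f}\t{alignment.ops}\t{path_str}\t{labs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
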