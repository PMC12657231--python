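"""Edge-centric succinct k-mer dictionary (BOSS table).

Stored k-mers are treated as edges over (k-1)-mer nodes.  Edges are sorted
colexicographically by source-node label (with the sentinel ``$`` smallest),
ties broken by edge character.  The table keeps

* ``W``     — the edge-character array, with a *minus flag* on every edge
              whose (target node, character) pair repeats an earlier edge;
* ``last``  — a bit vector marking the final outgoing edge of each node;
* ``F``     — cumulative node counts per final node character.

Dummy edges pad the table so that every stored k-mer is reachable: a chain of
``$``-prefixed source k-mers for every node without an incoming edge, and a
``$``-labelled outgoing edge for every sink node.  Dummy edges are never
reported as stored k-mers.

Rank and select over ``W`` and ``last`` use full prefix-sum arrays (the
block-based scheme degenerated to block size one, adequate at desk scale),
and all navigation — membership, node ranges for label suffixes, sub-k
suffix ranges — is expressed through those rank/select primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SENTINEL = 0  # digit reserved for '$'


@dataclass
class SuffixRange:
    """Stored k-mers sharing a suffix.

    ``node_lo:node_hi`` is the contiguous BOSS node range whose labels end
    with the suffix minus its final character; ``char`` is that final
    character (-1 when the suffix is empty).  ``positions`` are the matching
    BOSS edge positions and ``node_indexes`` the graph indexes (1..n) of the
    corresponding stored k-mers.
    """

    node_lo: int
    node_hi: int
    char: int
    positions: np.ndarray
    node_indexes: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


class BossTable:
    """BOSS table over a sorted array of k-mer codes (alphabet size ``sigma``)."""

    def __init__(self, codes: np.ndarray, k: int, sigma: int = 4):
        self.k = k
        self.sigma = sigma
        codes = np.asarray(codes, dtype=np.int64)
        self._build(codes)

    # ------------------------------------------------------------------
    # construction

    def _digits(self, codes: np.ndarray, length: int) -> np.ndarray:
        """(len(codes), length) digit matrix, digits shifted by +1 so that 0
        remains free for the sentinel."""
        out = np.empty((len(codes), length), dtype=np.uint8)
        tmp = codes.copy()
        for col in range(length - 1, -1, -1):
            out[:, col] = (tmp % self.sigma) + 1
            tmp //= self.sigma
        return out

    def _build(self, codes: np.ndarray) -> None:
        k, sigma = self.k, self.sigma
        if len(codes) == 0:
            raise ValueError("cannot build a BOSS table from an empty k-mer set")
        digits = self._digits(codes, k)  # values 1..sigma
        sources = digits[:, : k - 1]
        targets = digits[:, 1:]
        chars = digits[:, k - 1].astype(np.uint8)

        # nodes needing dummy incoming chains: source labels absent from targets
        src_keys = _rows_to_keys(sources)
        tgt_keys = _rows_to_keys(targets)
        need_in = ~np.isin(src_keys, tgt_keys)

        dummy_sources: list[np.ndarray] = []
        dummy_chars: list[int] = []
        seen: set[bytes] = set()
        for row in sources[need_in]:
            # chain $^{k-1} -> $^{k-2} r0 -> ... -> r0..r_{k-2}
            label = np.zeros(k - 1, dtype=np.uint8)
            for j in range(k - 1):
                key = label.tobytes() + bytes([row[j]])
                if key not in seen:
                    seen.add(key)
                    dummy_sources.append(label.copy())
                    dummy_chars.append(int(row[j]))
                label = np.concatenate([label[1:], row[j : j + 1]])

        # sink nodes (targets with no outgoing edge) get a $ out-edge
        sink_rows = targets[~np.isin(tgt_keys, src_keys)]
        if len(sink_rows):
            sink_rows = np.unique(sink_rows, axis=0)
            for row in sink_rows:
                dummy_sources.append(row.astype(np.uint8))
                dummy_chars.append(SENTINEL)

        if dummy_sources:
            all_sources = np.vstack([sources, np.array(dummy_sources, dtype=np.uint8)])
            all_chars = np.concatenate([chars, np.array(dummy_chars, dtype=np.uint8)])
            real = np.concatenate(
                [np.ones(len(sources), bool), np.zeros(len(dummy_sources), bool)]
            )
        else:
            all_sources, all_chars, real = sources, chars, np.ones(len(sources), bool)

        # colex sort: last label column is the primary key, edge char breaks ties
        keys = [all_chars] + [all_sources[:, col] for col in range(k - 1)]
        order = np.lexsort(keys)
        self.sources = all_sources[order]
        self.W = all_chars[order]
        self.real = real[order]
        m = len(self.W)

        # last-edge-of-node bits
        boundary = np.empty(m, dtype=bool)
        boundary[:-1] = (self.sources[:-1] != self.sources[1:]).any(axis=1)
        boundary[-1] = True
        self.last = boundary
        self.n_nodes = int(self.last.sum())

        # minus flags: repeated (source-suffix, char) pairs share a target
        suffix_char = np.column_stack([self.sources[:, 1:], self.W])
        nonsentinel = self.W != SENTINEL
        flags = np.zeros(m, dtype=bool)
        if nonsentinel.any():
            rows = suffix_char[nonsentinel]
            _, inverse = np.unique(rows, axis=0, return_inverse=True)
            first = np.zeros(inverse.max() + 1, dtype=np.int64) - 1
            idx = np.flatnonzero(nonsentinel)
            for pos, group in zip(idx, inverse):
                if first[group] < 0:
                    first[group] = pos
                else:
                    flags[pos] = True
        self.flag = flags

        # rank structures (full prefix sums)
        self._last_cum = np.cumsum(self.last)
        self._last_pos = np.flatnonzero(self.last)
        self._real_cum = np.cumsum(self.real)
        self._unflagged_cum = np.zeros((sigma + 1, m), dtype=np.int64)
        for c in range(sigma + 1):
            self._unflagged_cum[c] = np.cumsum((self.W == c) & ~self.flag)

        # F: number of nodes whose label ends with a digit < c
        node_last_char = self.sources[self._last_pos, k - 2] if k >= 2 else None
        counts = np.bincount(node_last_char, minlength=sigma + 1)
        self.F = np.concatenate([[0], np.cumsum(counts)])  # F[c] = #nodes ending < c

        self.n = int(self.real.sum())  # stored (non-dummy) k-mers

    # ------------------------------------------------------------------
    # rank / select primitives

    def rank_last(self, pos: int) -> int:
        """Number of set ``last`` bits in positions [0, pos]."""
        return int(self._last_cum[pos]) if pos >= 0 else 0

    def select_last(self, i: int) -> int:
        """Position of the i-th (1-based) set ``last`` bit."""
        return int(self._last_pos[i - 1])

    def rank_W(self, char: int, pos: int, unflagged_only: bool = True) -> int:
        """Occurrences of ``char`` in W[0..pos] (unflagged by default)."""
        if pos < 0:
            return 0
        if unflagged_only:
            return int(self._unflagged_cum[char][pos])
        return int(np.count_nonzero(self.W[: pos + 1] == char))

    def node_edge_span(self, node_lo: int, node_hi: int) -> tuple[int, int]:
        """Edge positions [start, stop) of nodes node_lo..node_hi-1 (0-based)."""
        start = 0 if node_lo == 0 else self.select_last(node_lo) + 1
        stop = self.select_last(node_hi) + 1
        return start, stop

    # ------------------------------------------------------------------
    # navigation

    def extend_node_range(self, lo: int, hi: int, char: int) -> tuple[int, int]:
        """Nodes with suffix ``s + char`` given the node range [lo, hi) for
        suffix ``s``.  ``char`` is a digit 1..sigma."""
        if lo >= hi:
            return 0, 0
        start, stop = self.node_edge_span(lo, hi)
        before = self.rank_W(char, start - 1)
        inside = self.rank_W(char, stop - 1) - before
        base = int(self.F[char]) + before
        return base, base + inside

    def node_range_for_suffix(self, digits: np.ndarray) -> tuple[int, int]:
        """Contiguous node range whose labels end with the digit string."""
        lo, hi = 0, self.n_nodes
        for d in digits:
            lo, hi = self.extend_node_range(lo, hi, int(d))
            if lo >= hi:
                return 0, 0
        return lo, hi

    def edge_position(self, digits: np.ndarray) -> int:
        """BOSS position of the k-mer given as k digits (1..sigma), -1 if absent."""
        lo, hi = self.node_range_for_suffix(digits[: self.k - 1])
        if lo >= hi:
            return -1
        start, stop = self.node_edge_span(lo, hi)
        for pos in range(start, stop):
            if self.W[pos] == digits[self.k - 1]:
                return pos
        return -1

    def kmer_index(self, digits: np.ndarray) -> int:
        """Graph index (1..n) of a stored k-mer, 0 if absent or dummy."""
        pos = self.edge_position(digits)
        if pos < 0 or not self.real[pos]:
            return 0
        return int(self._real_cum[pos])

    def suffix_range(self, digits: np.ndarray) -> SuffixRange:
        """All stored k-mers whose length-``len(digits)`` suffix equals the
        given digit string (empty string matches every stored k-mer)."""
        if len(digits) == 0:
            positions = np.flatnonzero(self.real)
            return SuffixRange(0, self.n_nodes, -1, positions, self._real_cum[positions])
        lo, hi = self.node_range_for_suffix(digits[:-1])
        char = int(digits[-1])
        if lo >= hi:
            empty = np.empty(0, dtype=np.int64)
            return SuffixRange(0, 0, char, empty, empty.copy())
        start, stop = self.node_edge_span(lo, hi)
        span = np.arange(start, stop)
        hit = span[(self.W[start:stop] == char) & self.real[start:stop]]
        return SuffixRange(lo, hi, char, hit, self._real_cum[hit])

    # ------------------------------------------------------------------
    # introspection used by oracle tests

    def kmer_at(self, pos: int) -> np.ndarray:
        """Digit string (length k) of the edge at a BOSS position."""
        return np.concatenate([self.sources[pos], [self.W[pos]]])


def _rows_to_keys(rows: np.ndarray) -> np.ndarray:
    """Pack digit rows into fixed-width byte keys (safe for any k)."""
    rows = np.ascontiguousarray(rows, dtype=np.uint8)
    return np.frombuffer(rows.tobytes(), dtype=f"|S{rows.shape[1]}")
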