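"""De Bruijn graph abstraction with hash, bitmap and succinct (BOSS) backends.

Nodes are k-mers; edges are implicit: u -> v whenever the (k-1)-suffix of u
equals the (k-1)-prefix of v and both are stored.  Every backend maps stored
k-mers to unique indexes 1..n and absent k-mers to 0.

Modes:

* ``basic``     — k-mers stored exactly as they occur in the input;
* ``canonical`` — every input sequence is supplemented with its reverse
                  complement, so each k-mer is present in both orientations;
* ``primary``   — exactly one orientation of each reverse-complement pair is
                  stored (the one visited first by a traversal of the
                  canonical graph); the canonical graph can be simulated by
                  also looking up the reverse complement.

Assembly (contig/unitig extraction) is implemented once over the common
sorted-code view shared by all backends, so the extracted sequences are
backend independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .boss import BossTable
from .kmers import (
    DNA,
    Alphabet,
    AlphabetError,
    KmerSpectrum,
    build_spectrum,
    decode_kmer,
    encode_kmer,
    revcomp_codes,
    reverse_complement,
)

MODES = ("basic", "canonical", "primary")
BACKENDS = ("hash", "bitmap", "boss")


@dataclass
class ContigSet:
    """Disjoint node cover of a graph as spelled sequences."""

    contigs: list[str]
    mode: str  # contig | unitig
    primary: bool = False
    paths: list[np.ndarray] | None = None  # 0-based node positions, optional

    def __len__(self) -> int:
        return len(self.contigs)

    def total_kmers(self, k: int) -> int:
        return sum(len(c) - k + 1 for c in self.contigs)


class DeBruijnGraph:
    """Base class: k-mer dictionary plus implicit-edge navigation."""

    backend = "abstract"

    def __init__(self, codes: np.ndarray, k: int, mode: str, alphabet: Alphabet = DNA):
        if mode not in MODES:
            raise ValueError(f"unknown graph mode {mode!r}")
        if mode in ("canonical", "primary") and not alphabet.complementable:
            raise AlphabetError(f"{mode} mode requires a complementable alphabet")
        self.k = k
        self.mode = mode
        self.alphabet = alphabet
        self._codes = np.asarray(codes, dtype=np.int64)

    # -- storage contract ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self._codes)

    def codes(self) -> np.ndarray:
        """Sorted codes of all stored k-mers (shared assembly view)."""
        return self._codes

    def node_index(self, kmer: str) -> int:
        """Index in 1..n of a stored k-mer, 0 if absent."""
        raise NotImplementedError

    def _check_kmer(self, kmer: str) -> None:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership of an int64 code array."""
        if len(self._codes) == 0:
            return np.zeros(len(codes), dtype=bool)
        pos = np.minimum(np.searchsorted(self._codes, codes), len(self._codes) - 1)
        return self._codes[pos] == codes

    def code_positions(self, codes: np.ndarray) -> np.ndarray:
        """0-based positions into ``codes()`` (-1 for absent)."""
        if len(self._codes) == 0:
            return np.full(len(codes), -1, dtype=np.int64)
        pos = np.searchsorted(self._codes, codes)
        pos = np.minimum(pos, len(self._codes) - 1)
        out = np.where(self._codes[pos] == codes, pos, -1)
        return out.astype(np.int64)

    def position_to_index(self, positions: np.ndarray) -> np.ndarray:
        """Map 0-based sorted-code positions to node indexes (vectorised)."""
        raise NotImplementedError

    # -- mode-aware lookup ------------------------------------------------

    def find(self, kmer: str) -> tuple[int, int]:
        """(index, orientation) of a k-mer under the graph's mode semantics.

        Orientation is +1 when the k-mer itself is stored, -1 when (in primary
        mode) only its reverse complement is, and 0 when neither is found.
        """
        idx = self.node_index(kmer)
        if idx:
            return idx, 1
        if self.mode == "primary":
            idx = self.node_index(reverse_complement(kmer))
            if idx:
                return idx, -1
        return 0, 0

    # -- implicit edges ---------------------------------------------------

    def successor_kmers(self, kmer: str) -> list[str]:
        """Stored successors (suffix-prefix overlap k-1), as k-mer strings.

        In primary mode this navigates the implicit canonical graph: children
        of the node in stored orientation plus parents of its reverse
        complement.
        """
        suffix = kmer[1:]
        out = [suffix + c for c in self.alphabet.symbols if self.find(suffix + c)[0]]
        return out

    def predecessor_kmers(self, kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [c + prefix for c in self.alphabet.symbols if self.find(c + prefix)[0]]

    def out_degree(self, kmer: str) -> int:
        return len(self.successor_kmers(kmer))

    def in_degree(self, kmer: str) -> int:
        return len(self.predecessor_kmers(kmer))

    def kmer_at_position(self, position: int) -> str:
        return decode_kmer(int(self._codes[position]), self.k, self.alphabet)

    # -- adjacency over the sorted-code view (assembly fast path) ---------

    def _adjacency(self) -> dict[str, np.ndarray]:
        """Vectorised successor/predecessor position tables.

        ``succ``/``pred`` are (n, sigma) arrays of 0-based positions (-1
        absent); degrees are their row-wise valid counts.  Edges follow the
        *stored* k-mer set only (primary-mode implicit edges are handled at
        the string level where needed).
        """
        if getattr(self, "_adj", None) is not None:
            return self._adj
        sigma = self.alphabet.size
        n = self.n
        shift = sigma ** (self.k - 1)
        succ = np.empty((n, sigma), dtype=np.int64)
        pred = np.empty((n, sigma), dtype=np.int64)
        suffix = (self._codes % shift) * sigma
        prefix = self._codes // sigma
        for c in range(sigma):
            succ[:, c] = self.code_positions(suffix + c)
            pred[:, c] = self.code_positions(c * shift + prefix)
        self._adj = {
            "succ": succ,
            "pred": pred,
            "outdeg": (succ >= 0).sum(axis=1),
            "indeg": (pred >= 0).sum(axis=1),
        }
        return self._adj


class HashDBG(DeBruijnGraph):
    """Hash-table backend; also the oracle the other backends are tested
    against.  Indexes follow sorted code order."""

    backend = "hash"

    def __init__(self, codes, k, mode, alphabet=DNA):
        super().__init__(codes, k, mode, alphabet)
        self._table = {int(c): i + 1 for i, c in enumerate(self._codes)}

    def node_index(self, kmer: str) -> int:
        self._check_kmer(kmer)
        try:
            code = encode_kmer(kmer, self.alphabet)
        except AlphabetError:
            return 0
        return self._table.get(code.value, 0)

    def position_to_index(self, positions: np.ndarray) -> np.ndarray:
        return np.where(positions >= 0, positions + 1, 0)


class BitmapDBG(DeBruijnGraph):
    """Indicator-bitmap backend over the full |Σ|^k code space with
    byte-popcount rank for index queries."""

    backend = "bitmap"

    _POPCOUNT = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).sum(axis=1)

    def __init__(self, codes, k, mode, alphabet=DNA):
        super().__init__(codes, k, mode, alphabet)
        space = alphabet.size**k
        if space > 2**32:
            raise ValueError(
                f"bitmap backend needs |alphabet|^k <= 2^32 (k <= 16 for DNA); got k={k}"
            )
        n_bytes = (space + 7) // 8
        bitmap = np.zeros(n_bytes, dtype=np.uint8)
        np.bitwise_or.at(bitmap, self._codes // 8, (1 << (self._codes % 8)).astype(np.uint8))
        self._bitmap = bitmap
        self._byte_rank = np.concatenate([[0], np.cumsum(self._POPCOUNT[bitmap])])

    def _bit(self, code: int) -> bool:
        return bool((self._bitmap[code // 8] >> (code % 8)) & 1)

    def _rank(self, code: int) -> int:
        """Set bits in [0, code]."""
        byte, bit = divmod(code, 8)
        partial = int(self._bitmap[byte]) & ((1 << (bit + 1)) - 1)
        return int(self._byte_rank[byte]) + bin(partial).count("1")

    def node_index(self, kmer: str) -> int:
        self._check_kmer(kmer)
        try:
            code = encode_kmer(kmer, self.alphabet).value
        except AlphabetError:
            return 0
        if not self._bit(code):
            return 0
        return self._rank(code)

    def position_to_index(self, positions: np.ndarray) -> np.ndarray:
        # bitmap rank order coincides with sorted code order
        return np.where(positions >= 0, positions + 1, 0)


class SuccinctDBG(DeBruijnGraph):
    """BOSS-table backend.  Indexes follow BOSS edge order, which differs
    from sorted code order; dummy edges are never reported."""

    backend = "boss"

    def __init__(self, codes, k, mode, alphabet=DNA):
        super().__init__(codes, k, mode, alphabet)
        if self.n == 0:
            self.boss = None
            self._pos_to_index = np.empty(0, dtype=np.int64)
            return
        self.boss = BossTable(self._codes, k, alphabet.size)
        # vectorised map: sorted-code position -> BOSS graph index
        real_pos = np.flatnonzero(self.boss.real)
        rows = np.column_stack([self.boss.sources[real_pos], self.boss.W[real_pos]])
        codes_in_boss_order = np.zeros(len(rows), dtype=np.int64)
        for col in range(rows.shape[1]):
            codes_in_boss_order = codes_in_boss_order * alphabet.size + (
                rows[:, col].astype(np.int64) - 1
            )
        indexes = self.boss._real_cum[real_pos]
        order = np.argsort(codes_in_boss_order)
        assert np.array_equal(codes_in_boss_order[order], self._codes)
        self._pos_to_index = indexes[order]

    def _kmer_digits(self, kmer: str) -> np.ndarray | None:
        digits = np.empty(self.k, dtype=np.uint8)
        for i, ch in enumerate(kmer):
            idx = self.alphabet.symbols.find(ch)
            if idx < 0:
                return None
            digits[i] = idx + 1
        return digits

    def node_index(self, kmer: str) -> int:
        self._check_kmer(kmer)
        if self.boss is None:
            return 0
        digits = self._kmer_digits(kmer)
        if digits is None:
            return 0
        return self.boss.kmer_index(digits)

    def position_to_index(self, positions: np.ndarray) -> np.ndarray:
        return np.where(positions >= 0, self._pos_to_index[positions], 0)

    def suffix_range(self, s: str):
        """Stored k-mers having ``s`` as suffix (BOSS sub-k range query)."""
        if len(s) > self.k:
            raise ValueError("suffix longer than k")
        digits = np.array([self.alphabet.index(c) + 1 for c in s], dtype=np.uint8)
        return self.boss.suffix_range(digits)


def boss_suffix_range(graph: DeBruijnGraph, s: str):
    """Range of stored k-mers with suffix ``s``; BOSS backend only."""
    if graph.backend != "boss":
        raise TypeError("suffix-range queries require the BOSS backend")
    return graph.suffix_range(s)


_BACKEND_CLASSES = {"hash": HashDBG, "bitmap": BitmapDBG, "boss": SuccinctDBG}


def build_graph(
    source,
    k: int | None = None,
    mode: str = "basic",
    backend: str = "hash",
    alphabet: Alphabet = DNA,
) -> DeBruijnGraph:
    """Build a de Bruijn graph from a spectrum or from sequences.

    ``source`` may be a :class:`KmerSpectrum` or an iterable of sequences
    (strings or records).  In canonical mode the reverse complement of every
    k-mer is added alongside it.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")
    if isinstance(source, KmerSpectrum):
        spectrum = source
        if k is not None and k != spectrum.k:
            raise ValueError(f"k={k} does not match spectrum k={spectrum.k}")
        k = spectrum.k
        alphabet = spectrum.alphabet
        codes = spectrum.codes
    else:
        if k is None:
            raise ValueError("k is required when building from sequences")
        spectrum = build_spectrum(source, k, alphabet=alphabet)
        codes = spectrum.codes
    if mode == "canonical":
        if not alphabet.complementable:
            raise AlphabetError("canonical mode requires a complementable alphabet")
        codes = np.unique(np.concatenate([codes, revcomp_codes(codes, k)]))
    return _BACKEND_CLASSES[backend](codes, k, mode, alphabet)


# ---------------------------------------------------------------------------
# traversal / assembly

def _spell(graph: DeBruijnGraph, path: Sequence[int]) -> str:
    first = graph.kmer_at_position(path[0])
    tail = [graph.kmer_at_position(p)[-1] for p in path[1:]]
    return first + "".join(tail)


def extract_paths(
    graph: DeBruijnGraph,
    traversal_mode: str = "unitig",
    primary: bool = False,
    shuffle_seed: int | None = None,
) -> list[np.ndarray]:
    """Decompose the graph into a disjoint node cover of paths.

    Unitig mode breaks paths at every branch (an edge u->v is followed only
    when it is u's single outgoing and v's single incoming edge); contig mode
    extends until no untraversed outgoing edge remains.  With ``primary=True``
    (canonical graphs only) a node is never visited once its reverse
    complement has been, so exactly one orientation of each pair is emitted.
    """
    if traversal_mode not in ("unitig", "contig"):
        raise ValueError(f"unknown traversal mode {traversal_mode!r}")
    if primary and graph.mode != "canonical":
        raise ValueError("primary extraction requires a canonical-mode graph")
    n = graph.n
    if n == 0:
        return []
    adj = graph._adjacency()
    succ, pred = adj["succ"], adj["pred"]
    outdeg, indeg = adj["outdeg"], adj["indeg"]
    sigma = graph.alphabet.size

    rc_pos = None
    if primary:
        rc_pos = graph.code_positions(revcomp_codes(graph.codes(), graph.k))

    visited = np.zeros(n, dtype=bool)

    def blocked(p: int) -> bool:
        if visited[p]:
            return True
        return primary and rc_pos[p] >= 0 and visited[rc_pos[p]]

    if traversal_mode == "unitig":
        # u -> v followed iff outdeg(u)==1 and indeg(v)==1
        nxt = np.full(n, -1, dtype=np.int64)
        single_out = outdeg == 1
        targets = np.where(single_out, succ.max(axis=1), -1)
        ok = single_out & (targets >= 0)
        ok[ok] &= indeg[targets[ok]] == 1
        nxt[ok] = targets[ok]
        has_prev = np.zeros(n, dtype=bool)
        has_prev[nxt[nxt >= 0]] = True
        start_order = np.concatenate([np.flatnonzero(~has_prev), np.flatnonzero(has_prev)])
    else:
        start_order = np.concatenate(
            [np.flatnonzero(indeg == 0), np.flatnonzero(indeg > 0)]
        )

    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        start_order = rng.permutation(n)

    paths: list[np.ndarray] = []
    for start in start_order:
        start = int(start)
        if blocked(start):
            continue
        path = [start]
        visited[start] = True
        cur = start
        while True:
            if traversal_mode == "unitig":
                nxt_pos = int(nxt[cur])
                if nxt_pos < 0 or blocked(nxt_pos):
                    break
            else:
                nxt_pos = -1
                for c in range(sigma):
                    cand = int(succ[cur, c])
                    if cand >= 0 and not blocked(cand):
                        nxt_pos = cand
                        break
                if nxt_pos < 0:
                    break
            path.append(nxt_pos)
            visited[nxt_pos] = True
            cur = nxt_pos
        paths.append(np.asarray(path, dtype=np.int64))
    return paths


def extract_contigs(
    graph: DeBruijnGraph,
    traversal_mode: str = "unitig",
    primary: bool = False,
    shuffle_seed: int | None = None,
) -> ContigSet:
    paths = extract_paths(graph, traversal_mode, primary, shuffle_seed)
    contigs = [_spell(graph, p) for p in paths]
    return ContigSet(contigs, traversal_mode, primary, paths)


def primarize(
    canonical_graph: DeBruijnGraph,
    backend: str | None = None,
    shuffle_seed: int | None = None,
) -> DeBruijnGraph:
    """Collapse a canonical graph to a primary graph (one orientation per
    reverse-complement pair), via primary-contig extraction."""
    if canonical_graph.mode != "canonical":
        raise ValueError("primarize requires a canonical-mode graph")
    contigs = extract_contigs(canonical_graph, "contig", primary=True, shuffle_seed=shuffle_seed)
    return build_graph(
        contigs.contigs,
        canonical_graph.k,
        mode="primary",
        backend=backend or canonical_graph.backend,
        alphabet=canonical_graph.alphabet,
    )


# ---------------------------------------------------------------------------
# serialization: manifest + stored k-mer codes; backend structures are
# reconstructed deterministically on load

FORMAT_VERSION = 1


def save_graph(graph: DeBruijnGraph, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "backend": graph.backend,
        "k": graph.k,
        "mode": graph.mode,
        "n": graph.n,
        "alphabet": graph.alphabet.kind,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    np.savez_compressed(directory / "codes.npz", codes=graph.codes())


def load_graph(directory) -> DeBruijnGraph:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"index format version {manifest['format_version']} is not supported "
            f"(expected {FORMAT_VERSION})"
        )
    from .kmers import PROTEIN

    alphabet = DNA if manifest["alphabet"] == "dna" else PROTEIN
    codes = np.load(directory / "codes.npz")["codes"]
    return _BACKEND_CLASSES[manifest["backend"]](codes, manifest["k"], manifest["mode"], alphabet)
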