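"""k-mer alphabet model, integer encoding and spectrum construction.

A k-mer over an ordered alphabet of size ``s`` is encoded as a big-endian
base-``s`` integer, so that the integer order of codes coincides with the
lexicographic order of the strings.  Spectra (sorted unique k-mer codes with
multiplicities) are built with a buffered sort-dedupe scheme: incoming codes
accumulate in a bounded buffer which is sorted, de-duplicated and merged into
the running spectrum whenever it fills up, summing multiplicities so the exact
total count of every distinct k-mer is maintained.  The result is independent
of the buffer size.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

_DNA_SYMBOLS = "ACGT"
# amino acids, ascii order
_PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Invalid character or unsupported alphabet operation."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered character set with an optional complement operation.

    DNA uses A<C<G<T (so ``code(revcomp)`` is computable and lexicographic
    order matches integer order of codes); the protein alphabet has the 20
    standard residues in ascii order and no reverse complement.
    """

    kind: str
    symbols: str
    complementable: bool

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, char: str, position: int | None = None) -> int:
        idx = self.symbols.find(char)
        if idx < 0:
            where = "" if position is None else f" at position {position}"
            raise AlphabetError(f"invalid character {char!r}{where} for {self.kind} alphabet")
        return idx

    def max_k(self) -> int:
        """Largest k whose codes fit in a signed 64-bit integer."""
        k, space = 0, 1
        while space * self.size <= 2**63 - 1:
            space *= self.size
            k += 1
        return k


DNA = Alphabet("dna", _DNA_SYMBOLS, True)
PROTEIN = Alphabet("protein", _PROTEIN_SYMBOLS, False)

#: byte -> 0..3 lookup for vectorised DNA encoding; 255 marks invalid bytes
_DNA_BYTE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_DNA_SYMBOLS):
    _DNA_BYTE_CODES[ord(_c)] = _i
    _DNA_BYTE_CODES[ord(_c.lower())] = _i


@dataclass(frozen=True)
class KmerCode:
    """Integer code of a k-mer: a non-negative big-endian base-|Σ| number."""

    value: int
    k: int


def encode_kmer(s: str, alphabet: Alphabet = DNA) -> KmerCode:
    """Encode a k-mer string as its integer code.

    Raises :class:`AlphabetError` naming the offending position if a character
    is not in the alphabet.
    """
    value = 0
    for i, ch in enumerate(s):
        value = value * alphabet.size + alphabet.index(ch, i)
    return KmerCode(value, len(s))


def decode_kmer(code: KmerCode | int, k: int | None = None, alphabet: Alphabet = DNA) -> str:
    if isinstance(code, KmerCode):
        value, k = code.value, code.k
    else:
        if k is None:
            raise ValueError("k required when decoding a bare integer")
        value = int(code)
    out = []
    for _ in range(k):
        value, digit = divmod(value, alphabet.size)
        out.append(alphabet.symbols[digit])
    return "".join(reversed(out))


def reverse_complement(s: str) -> str:
    return s.translate(_DNA_COMPLEMENT)[::-1]


def canonical_kmer(s: str, alphabet: Alphabet = DNA) -> str:
    """Lexicographically smallest of a k-mer and its reverse complement."""
    if not alphabet.complementable:
        raise AlphabetError("canonical form is undefined for non-complementable alphabets")
    rc = reverse_complement(s)
    return s if s <= rc else rc


# ---------------------------------------------------------------------------
# vectorised code arithmetic (DNA fast path)

def encode_sequence_dna(seq: str, k: int) -> np.ndarray:
    """Codes of all k-mers of ``seq`` drawn from valid {A,C,G,T} segments.

    Characters outside the alphabet (N and friends) split the sequence into
    valid segments; segments shorter than k contribute no k-mers.
    """
    if k < 1:
        raise ValueError("k must be positive")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    digits = _DNA_BYTE_CODES[raw]
    if len(raw) < k:
        return np.empty(0, dtype=np.int64)
    bad = digits == 255
    if not bad.any():
        return _rolling_codes(digits.astype(np.int64), k)
    chunks = []
    start = 0
    for pos in np.flatnonzero(bad):
        if pos - start >= k:
            chunks.append(_rolling_codes(digits[start:pos].astype(np.int64), k))
        start = pos + 1
    if len(digits) - start >= k:
        chunks.append(_rolling_codes(digits[start:].astype(np.int64), k))
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def _rolling_codes(digits: np.ndarray, k: int) -> np.ndarray:
    """Codes of every k-window of a digit array (values 0..3)."""
    n = len(digits) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    # cumulative base-4 polynomial evaluation via prefix sums of shifted digits
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes + (digits[j : j + n] << (2 * (k - 1 - j)))
    return codes


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of DNA k-mer codes."""
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return out


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = revcomp_codes(codes, k)
    return np.minimum(codes, rc)


# ---------------------------------------------------------------------------
# spectrum

@dataclass
class KmerSpectrum:
    """Sorted unique k-mer codes with exact multiplicities."""

    k: int
    codes: np.ndarray
    counts: np.ndarray
    alphabet: Alphabet = field(default=DNA)
    mode: str = "basic"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.codes) != len(self.counts):
            raise ValueError("codes and counts must have equal length")
        if len(self.codes) > 1 and not (np.diff(self.codes) > 0).all():
            raise ValueError("codes must be strictly increasing")
        if len(self.counts) and (self.counts < 1).any():
            raise ValueError("counts must be positive")

    def __len__(self) -> int:
        return len(self.codes)

    def kmer_strings(self) -> Iterator[str]:
        for c in self.codes:
            yield decode_kmer(int(c), self.k, self.alphabet)

    def abundance_histogram(self) -> dict[int, int]:
        vals, freq = np.unique(self.counts, return_counts=True)
        return {int(v): int(f) for v, f in zip(vals, freq)}


class _SortedSetBuffer:
    """Bounded buffer that sorts/dedupes on overflow, merging counts."""

    def __init__(self, buffer_limit: int):
        if buffer_limit < 1:
            raise ValueError("buffer_limit must be >= 1")
        self.limit = buffer_limit
        self.chunks: list[np.ndarray] = []
        self.pending = 0
        self.codes = np.empty(0, dtype=np.int64)
        self.counts = np.empty(0, dtype=np.int64)

    def add(self, codes: np.ndarray) -> None:
        if len(codes) == 0:
            return
        self.chunks.append(codes)
        self.pending += len(codes)
        if self.pending >= self.limit:
            self.flush()

    def flush(self) -> None:
        if not self.chunks:
            return
        batch = np.concatenate(self.chunks)
        self.chunks, self.pending = [], 0
        ucodes, ucounts = np.unique(batch, return_counts=True)
        merged = np.concatenate([self.codes, ucodes])
        weights = np.concatenate([self.counts, ucounts])
        order = np.argsort(merged, kind="stable")
        merged, weights = merged[order], weights[order]
        if len(merged):
            boundary = np.empty(len(merged), dtype=bool)
            boundary[0] = True
            boundary[1:] = merged[1:] != merged[:-1]
            idx = np.flatnonzero(boundary)
            self.codes = merged[idx]
            self.counts = np.add.reduceat(weights, idx)


def build_spectrum(
    sequences: Iterable,
    k: int,
    buffer_limit: int = 2**22,
    mode: str = "basic",
    alphabet: Alphabet = DNA,
) -> KmerSpectrum:
    """Count all k-mers of the input sequences into a sorted spectrum.

    ``mode="canonical"`` counts each k-mer under its canonical form.  Strings
    and objects with a ``.sequence`` attribute are both accepted.  The result
    is independent of ``buffer_limit``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > alphabet.max_k():
        raise ValueError(f"k={k} exceeds representable code width for {alphabet.kind}")
    if mode not in ("basic", "canonical"):
        raise ValueError(f"unknown spectrum mode {mode!r}")
    if mode == "canonical" and not alphabet.complementable:
        raise AlphabetError("canonical mode requires a complementable alphabet")

    buf = _SortedSetBuffer(buffer_limit)
    for rec in sequences:
        seq = rec if isinstance(rec, str) else rec.sequence
        if alphabet.kind == "dna":
            codes = encode_sequence_dna(seq, k)
            if mode == "canonical":
                codes = canonical_codes(codes, k)
        else:
            codes = _encode_sequence_generic(seq, k, alphabet)
        buf.add(codes)
    buf.flush()
    return KmerSpectrum(k, buf.codes, buf.counts, alphabet=alphabet, mode=mode)


def _encode_sequence_generic(seq: str, k: int, alphabet: Alphabet) -> np.ndarray:
    codes: list[int] = []
    run: list[int] = []
    for ch in seq:
        idx = alphabet.symbols.find(ch)
        if idx < 0:
            run.clear()
            continue
        run.append(idx)
        if len(run) >= k:
            value = 0
            for d in run[-k:]:
                value = value * alphabet.size + d
            codes.append(value)
    return np.asarray(codes, dtype=np.int64)


# ---------------------------------------------------------------------------
# serialization: magic, version, k, element count, delta-coded codes, varints

_MAGIC = b"ANNODBGSPEC1"


def _write_varint(out: bytearray, value: int) -> None:
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    shift = value = 0
    while True:
        byte = data[pos]
        pos += 1
        value |= (byte & 0x7F) << shift
        if not byte & 0x80:
            return value, pos
        shift += 7


def save_spectrum(spectrum: KmerSpectrum, path) -> None:
    out = bytearray()
    out += _MAGIC
    out += struct.pack("<BQ", spectrum.k, len(spectrum))
    prev = 0
    for code in spectrum.codes:
        _write_varint(out, int(code) - prev)
        prev = int(code)
    for count in spectrum.counts:
        _write_varint(out, int(count))
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def load_spectrum(path) -> KmerSpectrum:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[: len(_MAGIC)] != _MAGIC:
        raise ValueError(f"{path}: not a spectrum file (bad magic)")
    k, n = struct.unpack_from("<BQ", data, len(_MAGIC))
    pos = len(_MAGIC) + struct.calcsize("<BQ")
    codes = np.empty(n, dtype=np.int64)
    prev = 0
    for i in range(n):
        delta, pos = _read_varint(data, pos)
        prev += delta
        codes[i] = prev
    counts = np.empty(n, dtype=np.int64)
    for i in range(n):
        counts[i], pos = _read_varint(data, pos)
    return KmerSpectrum(k, codes, counts)
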