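"""Sequence I/O and synthetic-data generation.

FASTA/FASTQ parsing and writing are delegated to Biopython's ``SeqIO``
(gzip-transparent).  The simulators generate the inputs every other module
needs without external data: random genomes, read sets with i.i.d. base
substitution errors at a chosen coverage, and mutated query reads with
substitutions plus single-base indels at one tenth of the substitution rate.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kmers import reverse_complement

_DNA = "ACGT"


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"record {self.id!r}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadSimSpec:
    """Conditions for simulating a read set from a random genome."""

    genome_length: int
    coverage: float
    read_length: int
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(frozen=True)
class MutationSpec:
    """Substitutions plus single-base indels, indels defaulting to 10% of
    the substitution probability."""

    substitution_rate: float
    indel_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.indel_rate is not None and not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")

    @property
    def effective_indel_rate(self) -> float:
        if self.indel_rate is None:
            return 0.1 * self.substitution_rate
        return self.indel_rate


# ---------------------------------------------------------------------------
# reading / writing

def _open_maybe_gzip(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _guess_format(path) -> str:
    name = Path(path).name.removesuffix(".gz")
    suffix = Path(name).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def read_sequences(path, format: str | None = None) -> list[SequenceRecord]:
    """Read all records of a FASTA/FASTQ file, in file order.

    RNA input is accepted: U is mapped to T on read.  An empty file yields an
    empty list; a malformed record raises ``ValueError``.
    """
    fmt = format or _guess_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    records = []
    with _open_maybe_gzip(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            seq = str(rec.seq).upper().replace("U", "T")
            quality = rec.letter_annotations.get("phred_quality")
            records.append(SequenceRecord(rec.id, seq, list(quality) if quality else None))
    return records


def write_sequences(records: Iterable[SequenceRecord], path, format: str | None = None) -> None:
    fmt = format or _guess_format(path)
    bio_records = []
    for rec in records:
        bio = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        if fmt == "fastq":
            bio.letter_annotations["phred_quality"] = rec.quality or [40] * len(rec.sequence)
        bio_records.append(bio)
    with _open_maybe_gzip(path, "wt") as fh:
        SeqIO.write(bio_records, fh, fmt)


# ---------------------------------------------------------------------------
# simulation

def random_genome(length: int, rng: np.random.Generator, record_id: str = "genome") -> SequenceRecord:
    bases = rng.integers(0, 4, size=length)
    return SequenceRecord(record_id, "".join(_DNA[b] for b in bases))


def _substitute(digits: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` to a uniform other base."""
    if rate <= 0:
        return digits
    hit = rng.random(len(digits)) < rate
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    out = digits.copy()
    out[hit] = (out[hit] + shifts) % 4
    return out


def simulate_sample(spec: ReadSimSpec) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """Simulate a genome and a read set drawn uniformly from both strands.

    The number of reads is ``round(coverage * genome_length / read_length)``;
    substitution errors are injected i.i.d. per base.  Deterministic given
    the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    genome = random_genome(spec.genome_length, rng)
    gdigits = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, c in enumerate(_DNA):
        lut[ord(c)] = i
    gdigits = lut[gdigits]

    n_reads = int(round(spec.coverage * spec.genome_length / spec.read_length))
    starts = rng.integers(0, spec.genome_length - spec.read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads = []
    for i, (start, strand) in enumerate(zip(starts, strands)):
        window = gdigits[start : start + spec.read_length]
        if strand:
            window = 3 - window[::-1]
        window = _substitute(window, spec.substitution_rate, rng)
        seq = "".join(_DNA[d] for d in window)
        reads.append(SequenceRecord(f"read_{i}|pos={start}|strand={'-' if strand else '+'}", seq))
    return genome, reads


def mutate_reads(reads: Sequence[SequenceRecord], spec: MutationSpec) -> list[SequenceRecord]:
    """Inject substitutions and single-base indels into each read.

    Each base is substituted with probability ``substitution_rate``; an indel
    event occurs per base with probability ``effective_indel_rate`` and is a
    single-base insertion or deletion with equal probability.  Read count is
    preserved; deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    indel_rate = spec.effective_indel_rate
    out = []
    for rec in reads:
        chars = list(rec.sequence)
        if spec.substitution_rate > 0:
            for i in range(len(chars)):
                if rng.random() < spec.substitution_rate:
                    choices = [c for c in _DNA if c != chars[i]]
                    chars[i] = choices[rng.integers(0, 3)]
        if indel_rate > 0:
            mutated: list[str] = []
            for ch in chars:
                if rng.random() < indel_rate:
                    if rng.random() < 0.5:  # deletion
                        continue
                    mutated.append(_DNA[rng.integers(0, 4)])  # insertion before base
                mutated.append(ch)
            chars = mutated or [rec.sequence[0]]  # never emit an empty read
        out.append(SequenceRecord(rec.id, "".join(chars)))
    return out


def write_manifest(path, spec) -> None:
    """Dump a simulation spec as a small key-value text file."""
    lines = [f"generator=numpy.random.default_rng"]
    for key, value in vars(spec).items():
        lines.append(f"{key}={value}")
    Path(path).write_text("\n".join(lines) + "\n")
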