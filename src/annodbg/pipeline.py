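"""The three-stage indexing workflow and index persistence.

Per sample: (1) build a sample graph from the raw reads and clean it
(abundance threshold from the k-mer spectrum, solid-unitig filter, tip
pruning); (2) build the joint graph from all clean contigs (canonical, then
optionally collapsed to primary); (3) annotate the joint graph with one
column per sample, mapping the clean contigs rather than the raw reads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationMatrix, annotate, matrix_from_columns
from .cleaning import CleaningConfig, clean_graph, spectrum_counts_for_graph
from .graph import build_graph, load_graph, primarize, save_graph
from .kmers import build_spectrum
from .search import GraphIndex

FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    k: int = 31
    mode: str = "canonical"  # basic | canonical | primary (via primarization)
    backend: str = "hash"
    clean: bool = True
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    representation: str = "column_sparse"
    payload: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def build_index(samples: list[tuple[str, list]], config: PipelineConfig) -> GraphIndex:
    """Run the full workflow over (label, sequences) samples.

    Sample sequences may be reads (cleaned per config) or pre-cleaned
    contigs (``config.clean=False`` skips the cleaning stage).
    """
    contig_sets = []
    for label, sequences in samples:
        if config.clean:
            spectrum = build_spectrum(sequences, config.k, mode="canonical")
            sample_graph = build_graph(spectrum, mode="canonical", backend="hash")
            counts = spectrum_counts_for_graph(sample_graph, spectrum)
            contigs = clean_graph(sample_graph, counts, config.cleaning).contigs
        else:
            contigs = [s if isinstance(s, str) else s.sequence for s in sequences]
        contig_sets.append((label, contigs))

    all_contigs = [c for _, contigs in contig_sets for c in contigs]
    if config.mode == "primary":
        canonical = build_graph(all_contigs, config.k, mode="canonical", backend="hash")
        joint = primarize(canonical, backend=config.backend)
    else:
        joint = build_graph(all_contigs, config.k, mode=config.mode,
                            backend=config.backend)
    annotation = annotate(joint, contig_sets, payload=config.payload,
                          representation=config.representation)
    return GraphIndex(joint, annotation)


# ---------------------------------------------------------------------------
# persistence

def save_index(index: GraphIndex, directory, config: PipelineConfig | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_graph(index.graph, directory / "graph")
    ann = index.annotation
    manifest = {
        "format_version": FORMAT_VERSION,
        "k": index.graph.k,
        "mode": index.graph.mode,
        "backend": index.graph.backend,
        "n_kmers": index.graph.n,
        "labels": ann.labels if ann else [],
        "payload": ann.payload if ann else None,
        "config": _config_dict(config) if config else None,
    }
    if ann is not None:
        arrays = {}
        for j in range(ann.m):
            arrays[f"col_{j}"] = ann.get_column(j)
            if ann.payload == "counts":
                rows, vals = ann.counts[j]
                arrays[f"cnt_rows_{j}"] = rows
                arrays[f"cnt_vals_{j}"] = vals
        np.savez_compressed(directory / "annotation.npz", **arrays)
    text = json.dumps(manifest, indent=2, sort_keys=True)
    (directory / "manifest.json").write_text(text)
    digest = hashlib.sha256(text.encode()).hexdigest()
    (directory / "manifest.sha256").write_text(digest + "\n")


def load_index(directory) -> GraphIndex:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"index format version {manifest['format_version']} is not supported"
        )
    graph = load_graph(directory / "graph")
    annotation = None
    ann_path = directory / "annotation.npz"
    if ann_path.exists() and manifest["labels"]:
        data = np.load(ann_path)
        labels = manifest["labels"]
        columns = [data[f"col_{j}"] for j in range(len(labels))]
        counts = None
        if manifest["payload"] == "counts":
            counts = {
                j: (data[f"cnt_rows_{j}"], data[f"cnt_vals_{j}"])
                for j in range(len(labels))
            }
        annotation = matrix_from_columns(
            graph.n, columns, labels, payload=manifest["payload"] or "binary",
            counts=counts,
        )
    return GraphIndex(graph, annotation)


def _config_dict(config: PipelineConfig) -> dict:
    out = dict(vars(config))
    out["cleaning"] = dict(vars(config.cleaning))
    return out
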