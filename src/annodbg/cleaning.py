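"""Per-sample graph cleaning.

Erroneous k-mers from sequencing noise sit at low abundance and form spurious
side paths.  Cleaning keeps a unitig when enough of its k-mers are solid
(abundance at or above a threshold), prunes short tips, and returns the
surviving unitigs as clean contigs from which a cleaned graph can be rebuilt.

The abundance threshold is estimated from the k-mer spectrum under the model
that erroneous k-mers (abundance at most 3) follow a negative binomial
distribution; the threshold is the 99.9th percentile of the fitted NB.  The
fit uses the closed-form identification of the truncated NB via adjacent pmf
ratios pmf(x+1)/pmf(x) = (x+r)(1-p)/(x+1) evaluated on the abundance-1/2/3
histogram bins.  (A moment fit on the truncated sample is useless here: the
variance of a sample restricted to {1,2,3} is essentially never above its
mean, so a mean/variance NB fit would always be degenerate.)  If the fit
fails, or the threshold would keep less than 20% of the total coverage, a
pre-defined fallback threshold (typically 2) is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graph import ContigSet, DeBruijnGraph, extract_paths, _spell


@dataclass
class CleaningConfig:
    threshold: int | str = "auto"
    fallback_threshold: int = 2
    tip_cutoff: int | None = None  # in k-mers; None -> 2k
    min_retained_coverage_fraction: float = 0.2
    solid_fraction: float = 0.5
    nb_percentile: float = 99.9

    def __post_init__(self) -> None:
        if not 0 < self.solid_fraction <= 1:
            raise ValueError("solid_fraction must be in (0, 1]")
        if not 0 < self.nb_percentile < 100:
            raise ValueError("nb_percentile must be in (0, 100)")
        if self.fallback_threshold < 1:
            raise ValueError("fallback_threshold must be positive")


def lenient_config() -> CleaningConfig:
    """Constant threshold 2, no tip pruning: keeps singleton-free unitigs
    while retaining as much signal as possible."""
    return CleaningConfig(threshold=2, tip_cutoff=0)


# ---------------------------------------------------------------------------
# threshold estimation

_ERROR_ABUNDANCE_MAX = 3  # k-mers at most this abundant are modelled as errors


def fit_error_nb(hist: dict[int, int]):
    """Fit the error distribution from an abundance histogram.

    Uses the bins at abundance 1..3 only.  The conditional NB distribution on
    {1, 2, 3} is identified exactly by the two adjacent-bin pmf ratios
    t_x = h_{x+1}/h_x = (x + r)(1 - p)/(x + 1): their ratio rho = t2/t1 pins
    r, then t1 pins p.  rho <= 2/3 is the r -> infinity boundary of the NB
    family (thinner-tailed than any proper NB), where the Poisson limit with
    lambda = 2 t1 is fitted instead — the common shape of real error spectra.
    Returns ("nb", r, p), ("poisson", lam), or None when the bins are empty
    or no member of the family matches (rho >= 4/3, heavier than the
    geometric boundary).
    """
    h1 = hist.get(1, 0)
    h2 = hist.get(2, 0)
    h3 = hist.get(3, 0)
    if min(h1, h2, h3) <= 0:
        return None
    t1 = h2 / h1  # (1+r)(1-p)/2
    t2 = h3 / h2  # (2+r)(1-p)/3
    rho = t2 / t1
    if rho >= 4 / 3:
        return None
    if rho <= 2 / 3:
        lam = 2 * t1
        return ("poisson", lam) if lam > 0 else None
    r = (4 - 3 * rho) / (3 * rho - 2)
    one_minus_p = 2 * t1 / (1 + r)
    if r <= 0 or not 0 < one_minus_p < 1:
        return None
    return "nb", r, 1 - one_minus_p


def estimate_threshold(
    hist: dict[int, int], config: CleaningConfig | None = None
) -> tuple[int, bool]:
    """Abundance threshold from a spectrum histogram.

    Returns ``(threshold, used_fallback)``.  The threshold is the ceiling of
    the configured percentile of the NB fitted to abundances <= 3; the
    fallback value is returned when the fit fails or when the threshold would
    retain less than ``min_retained_coverage_fraction`` of the total coverage
    (coverage counted in k-mer multiplicity).
    """
    config = config or CleaningConfig()
    if not hist:
        raise ValueError("empty abundance histogram")
    fit = fit_error_nb(hist)
    if fit is None:
        return config.fallback_threshold, True
    q = config.nb_percentile / 100.0
    if fit[0] == "poisson":
        threshold = int(np.ceil(stats.poisson.ppf(q, fit[1])))
    else:
        threshold = int(np.ceil(stats.nbinom.ppf(q, fit[1], fit[2])))
    # the fit only sees the abundance band <= _ERROR_ABUNDANCE_MAX, which the
    # model declares error-suspect a priori; a computed threshold inside that
    # band is not trusted (low-coverage samples are caught by the coverage
    # rule below and fall back instead)
    threshold = max(threshold, _ERROR_ABUNDANCE_MAX)
    total = sum(a * c for a, c in hist.items())
    kept = sum(a * c for a, c in hist.items() if a >= threshold)
    if total == 0 or kept / total < config.min_retained_coverage_fraction:
        return config.fallback_threshold, True
    return threshold, False


# ---------------------------------------------------------------------------
# cleaning

def clean_graph(
    graph: DeBruijnGraph,
    counts: np.ndarray,
    config: CleaningConfig | None = None,
) -> ContigSet:
    """Filter a sample graph down to its solid unitigs.

    ``counts`` holds per-node abundances aligned with ``graph.codes()``
    (position order).  A unitig is kept when at least ``solid_fraction`` of
    its k-mers have abundance >= threshold — for the default 0.5 this is the
    median criterion (lower median for even lengths).  Tips (unitigs whose
    last node has no outgoing edge) shorter than ``tip_cutoff`` k-mers are
    removed regardless of abundance.  The surviving unitigs are returned as
    clean contigs, suitable as input to ``build_graph``.
    """
    config = config or CleaningConfig()
    counts = np.asarray(counts)
    if len(counts) != graph.n:
        raise ValueError(f"counts length {len(counts)} != graph size {graph.n}")

    if config.threshold == "auto":
        vals, freq = np.unique(counts, return_counts=True)
        hist = {int(v): int(f) for v, f in zip(vals, freq)}
        threshold, _ = estimate_threshold(hist, config)
    else:
        threshold = int(config.threshold)
    tip_cutoff = config.tip_cutoff if config.tip_cutoff is not None else 2 * graph.k

    adj = graph._adjacency()
    outdeg = adj["outdeg"]

    paths = extract_paths(graph, "unitig")
    kept: list[np.ndarray] = []
    for path in paths:
        is_tip = outdeg[path[-1]] == 0
        if is_tip and len(path) < tip_cutoff:
            continue
        solid = np.count_nonzero(counts[path] >= threshold)
        if solid / len(path) >= config.solid_fraction:
            kept.append(path)
    contigs = [_spell(graph, p) for p in kept]
    return ContigSet(contigs, "unitig", False, kept)


def spectrum_counts_for_graph(graph: DeBruijnGraph, spectrum) -> np.ndarray:
    """Per-node abundances aligned to ``graph.codes()`` from a spectrum.

    For canonical-mode graphs built from a canonical spectrum, both
    orientations of a k-mer receive the canonical form's total count.
    """
    from .kmers import canonical_codes

    codes = graph.codes()
    lookup = codes
    if graph.mode == "canonical" and spectrum.mode == "canonical":
        lookup = canonical_codes(codes, graph.k)
    pos = np.searchsorted(spectrum.codes, lookup)
    pos = np.minimum(pos, max(len(spectrum.codes) - 1, 0))
    counts = np.zeros(len(codes), dtype=np.int64)
    if len(spectrum.codes):
        hit = spectrum.codes[pos] == lookup
        counts[hit] = spectrum.counts[pos[hit]]
    return counts
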