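# Methods

This note documents the models, algorithms and numerical choices behind
`annodbg`, and what the synthetic-data tests do and do not demonstrate.

## The index

A de Bruijn graph of order k is fully determined by its k-mer set: an edge
u→v exists exactly when the (k−1)-suffix of u equals the (k−1)-prefix of v
and both are stored, so only the node set is kept.  Every backend maps
stored k-mers to indexes 1..n (0 = absent):

* **HashDBG** — a dictionary keyed by the integer code; indexes follow
  sorted code order.  It is the reference implementation the others are
  tested against, and the backend used for throwaway graphs (batch query
  graphs, sample graphs).
* **BitmapDBG** — an indicator bitmap over the |Σ|^k code space with a
  byte-popcount prefix-sum for rank; the index of a stored k-mer is the
  rank of its bit.  Requires |Σ|^k ≤ 2^32 (k ≤ 16 for DNA).
* **SuccinctDBG** — an edge-centric BOSS table.  Stored k-mers are edges
  over (k−1)-mer nodes, sorted colexicographically by source label with the
  sentinel `$` smallest, ties broken by edge character.  Dummy `$`-padded
  source chains make every k-mer reachable and `$`-labelled out-edges
  terminate sinks; dummies are never reported.  A minus flag marks an edge
  whose (target, character) pair repeats an earlier edge, so counting
  unflagged characters maps edge ranges to node ranges.  Rank/select use
  full prefix-sum arrays — the block-rank scheme at block size one, which
  is the right trade-off at desk scale; the navigation contract (not the
  bit layout) is what the tests pin down.  Node ranges for label suffixes
  give membership in O(k) rank operations and support matching strings
  shorter than k (sub-k seeds).

Modes: *basic* stores k-mers as read; *canonical* supplements every input
sequence with its reverse complement; *primary* stores one orientation per
reverse-complement pair, produced by a canonical-graph traversal that never
visits a node whose reverse complement was visited.  The set of primary
sequences depends on traversal order but their k-mer count does not (each
pair contributes exactly one member; a final sweep over all nodes
guarantees the cover).  Looking up both orientations over a primary graph
simulates the canonical graph exactly.

Assembly is implemented once over the sorted-code view shared by all
backends.  Unitig mode follows an edge u→v only when it is u's single
out-edge and v's single in-edge; contig mode extends while any untraversed
out-edge remains.  Both produce a disjoint node cover (isolated cycles are
collected in a second pass).

## Graph cleaning

Erroneous k-mers sit at low abundance.  The unitig filter keeps a unitig
when at least `solid_fraction` (default 50%) of its k-mers have abundance
≥ threshold; tips (unitigs whose last node has no out-edge) shorter than
`tip_cutoff` (default 2k) k-mers are removed.  For odd unitig lengths the
50% rule is exactly "median ≥ threshold"; for even lengths it corresponds
to the upper median (the lower median, reported in contig headers, would
demand strictly more than half).

The automatic threshold models the abundance X of erroneous k-mers as
negative binomial and uses its 99.9th percentile.  Only the spectrum bins
at abundance 1–3 are attributed to errors.  Because a sample truncated to
{1,2,3} essentially always has variance below its mean, moment fits are
degenerate there; instead the truncated family is identified in closed form
from adjacent pmf ratios,

    pmf(x+1)/pmf(x) = (x + r)(1 − p) / (x + 1),

whose ratio across the two bin pairs pins r and then p.  The ratio
ρ = t₂/t₁ must lie in (2/3, 4/3) for a proper NB; ρ ≤ 2/3 is the r→∞
boundary, where the Poisson limit with λ = 2·h₂/h₁ is fitted instead (the
typical shape of real error spectra); ρ ≥ 4/3 (heavier than geometric)
fails the fit.  The returned threshold is
`max(ceil(ppf(0.999)), 3)` — the floor reflects that the model itself
declares the abundance band it was fitted on error-suspect, so no computed
threshold inside that band is trusted.  Estimation is deemed unsuccessful,
and the fallback (default 2) used, when the fit fails or when the threshold
would keep less than 20% of the total coverage (coverage counted in k-mer
multiplicity); the coverage rule is what protects genuinely low-coverage
samples from the floor.  On data simulated from NB(2, 0.5) with 2·10⁵
error k-mers per trial — the order of a small sequencing sample's error
spectrum — the estimator lands within ±1 of the true percentile in well
over 95 of 100 trials.

## Annotations

The matrix is built by mapping the *clean contigs* of each sample (not its
raw reads) against the joint graph — every contig k-mer must be present,
since the joint graph was built from those contigs.  Payloads: counts
(abundances) and coordinates, stored as (sequence index, 0-based offset of
the k-mer's first character); coordinates make the encoding lossless and a
decoder reconstructs the input sequences exactly.

Representations answer identical row/column queries: per-column sorted row
arrays; per-row bitmasks; per-row sorted column ids; and an arity-2 balanced
tree over columns in given order whose internal nodes store OR-aggregate bit
vectors over the parent's set positions (column topology optimisation by
similarity clustering is deliberately out of scope).

**RowDiff.**  Each node with out-edges designates the out-neighbour with
the smallest index as its successor; non-anchor rows are replaced by
row XOR successor-row.  Anchors — which keep their original rows and
terminate every reconstruction walk — are the sinks, the smallest-index
node of every successor cycle, and additional nodes inserted so that no
node is more than `anchor_spacing` (default 32, bounding worst-case
reconstruction work) steps from an anchor.  Reconstruction XORs diffs along
the successor chain and is exact by construction; a chain longer than n
steps indicates corruption and raises.  On annotations of overlapping
samples the transform empirically removes ~97% of set bits; on adversarial
(random) matrices it can inflate them — the gain comes entirely from
neighbour-row correlation.

Column aggregation sets bit i when a_min ≤ Σ_j 1[v_min ≤ c_ij ≤ v_max]
≤ a_max, with c_ij = 1 at set bits of binary columns, and always returns
the sum as a count vector.  Count smoothing replaces each position of a
unitig's count vector with the lower median of the window ±window/2
(default window 60: 30 before and 30 after), truncated at unitig ends.

## Search

A label is reported for a query when (matched k-mers carrying it)/(total
query k-mers) ≥ `min_kmers_fraction_label` (default 0.7); queries whose
overall graph-match fraction falls below `min_kmers_fraction_graph`
(default 0) are skipped.  Ties in the fraction ranking break by label
insertion order.  On primary graphs each k-mer is looked up in at most two
orientations; the switch heuristic keeps querying the orientation that hit
last and is a pure reordering — a found k-mer guarantees its reverse
complement is absent, so results equal the naive double lookup.

Batched search builds a basic hash graph from each batch (default 8 Mbp of
query sequence), extracts its contigs (a non-redundant superset of the
batch k-mers), maps them against the joint graph once, materialises the
intersection as an annotated hash "query graph", and answers each query
against it.  Because the query graph contains exactly the batch∩joint
k-mers in batch orientation with their joint annotation rows, reports are
identical to unbatched search — an equivalence the tests check literally.

## Alignment

Seeds are maximal runs of consecutive exact k-mer matches split at unitig
junctions (Uni-MEMs); with a BOSS backend and `min_seed_length` < k,
additional seeds match query substrings of length k′ to k-mer suffixes:
forward matches come from one suffix-range query, reverse-complement
matches from ranges for the reverse-complemented substring walked k−1−k′
steps forward so the matched characters become node prefixes.

Extension is anchored at the seed's first node and performed independently
forwards and backwards (the backward pass extends the reversed query prefix
over predecessor edges; for sub-k seeds the unmatched node prefix is
consumed as forced steps first).  Each alignment-tree node carries integer
vectors S/E/F over the query segment (best score / ending in insertion /
ending in deletion) with affine gaps; the root allows insertions opened at
the anchor (S[i] = gap_open + (i−1)·gap_extend), which is required for
gaps abutting the seed.  E is computed in closed form with a running
maximum, so each tree node costs O(ℓ) vector work.  The search is
best-first by the parent's best score; cells more than X (default 27)
below the running best are discarded; a tree node that fails to improve
the element-wise maximum score column of its graph node is dropped (forced
intra-node chains are exempt — they are the only route through the seed);
exploration stops after `node_budget_factor`·ℓ nodes (default 20ℓ).  With
X = ∞ and no budget, the two anchored passes recover classic local
affine-gap alignment scores exactly on simple paths: the optimal local
alignment passes through the first cell of one of its maximal exact runs
in match state, and the DP decomposes there.

Scoring defaults (match +2, mismatch −3, gap open −5, gap extend −2) are
package choices, config-overridable; the "fast" and "sensitive" profiles
set (min_exact_match, min_seed_length) to (0.85, 27) and (0.0, 27).
Sequence identity is the fraction of query nucleotides aligned as exact
matches; labels are fetched by running the label query on the spelled
sequence of the best alignment (optionally all reported alignments) in
place of the raw query.  Primary graphs are traversed as implicit canonical
graphs (children = stored children ∪ parents of the reverse complement), so
scores match the explicit canonical graph.  Equal-score alignments break
ties toward the lexicographically smallest spelled sequence.

## Random-match model and evaluation statistics

The expected number of samples a random query shares a k-mer with is
n·(1 − C(M−S, q)/C(M, q)) — sampling without replacement of the query's q
distinct k-mers from a space of M against a sample of S.  The ratio of
binomials is evaluated as a sum of log terms (q is small).  For canonical
DNA matching the class count (4^k + 4^(k/2))/2 (even k) or 4^k/2 (odd k)
is available alongside the plain 4^k space.  Recall at identity cutoff c is
the fraction of reads whose true source label is retrieved at identity ≥ c;
realignability is the trapezoidal area of that curve over [0,1].
Compression is decomposed exactly as chars/byte = (chars/relation) ×
(relations/byte).

## Synthetic data

The generator draws uniform random genomes, reads uniformly from both
strands with i.i.d. substitutions (read count = coverage·genome/read
length), and query mutations with single-base indels at one tenth of the
substitution rate (insertions and deletions equally likely).  It emulates
the *structure* of resequencing inputs — strand symmetry, error-induced
low-abundance k-mers, known read provenance — but not base-composition
bias, quality-correlated or platform-specific error profiles, repeats, or
contamination.  Passing tests therefore demonstrate algorithmic
correctness (set identities, exact equivalences, model recovery under the
assumed error law), not performance claims about real libraries; in
particular the cleaning thresholds are validated under the NB/Poisson
error model they assume.

## Problem sizes and defaults

Tests and the acceptance script run on genomes of 10–100 kb, k ∈ 4..31,
up to 20 samples and hundreds of queries — sizes chosen so the whole suite
re-runs in minutes on one CPU while still exercising every code path
(cycles, palindromic contexts, branching, batching boundaries).  Spectrum
buffer default 2^22 elements; anchor spacing 32; query batch 8·10⁶ bp;
label fraction 0.7.  Serialized graphs store the manifest plus the sorted
code array (compressed); backend structures are rebuilt deterministically
on load, which keeps the on-disk format backend-agnostic — a deliberate
trade of load time for simplicity at desk scale.  Index directories are
versioned and refused (not migrated) on version mismatch.

## Known limitations

* BOSS construction materialises Python-level dummy chains; fine to ~10⁶
  k-mers, not beyond.
* The bitmap backend allocates the full 4^k/8-byte bitmap: practical only
  for small k.
* RowDiff stores binary relations; counts/coordinates stay in their own
  payload and are not delta-coded.
* Protein graphs support basic mode only (no complement), match/mismatch
  scoring without substitution matrices.
* External-memory spectrum construction (disk spill) is not implemented;
  the buffer contract makes it a drop-in extension.
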