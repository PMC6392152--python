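# Methods

## The data model

A `SummarizedExperiment` binds a G × N assay matrix Q to a feature table
(G rows, unique non-empty string IDs), a sample table (N rows, likewise)
and optionally one genomic range per feature. The single container
invariant is positional alignment: after any subsetting, row i of the
realized assay, row i of the feature table and interval i of the ranges
describe the same feature, and likewise for samples. Subsetting accepts
identifier lists, 0-based positions, boolean masks or keep-all; selection
order is preserved and duplicated positions repeat, so `X[K, S]` behaves
like the matrix-subsetting idiom users of metadata-bound containers
expect. Exactly one assay per container; a feature selected by a metadata
column (the match-on-symbol idiom) resolves to the *first* match, with a
warning when the match is ambiguous.

Two deliberate departures from the loosest possible semantics: IDs must be
unique (duplicate row names make identifier selection ambiguous; they are
a constructor error here), and all library-level positions are 0-based
(the CLI accepts identifiers only, so the 0/1-base question never reaches
the shell).

## Delayed evaluation

The assay is a `DelayedMatrix`: an ordered row map and column map into a
storage *seed* plus a chain of pending elementwise transforms drawn from a
whitelist (`identity`, `log2p1`, `log10p1`). Subsetting composes index
maps; transform application appends to the chain; neither touches storage.
A whitelist rather than arbitrary callables keeps realization
deterministic and would permit server-side pushdown later; transforms are
nevertheless always applied client-side after fetch, which is what the
stratified-expression recipes do anyway.

Realization tiles the view into dense blocks of at most `block_cells`
values (default 2^20, a round 8 MiB of float64 — a declared constant, not
a claim about any service's optimum). Within a block the unique seed
indices are fetched and duplicates are filled by replication, never by
re-reading. Seeds without scattered-read support are read with one
`read_block` per maximal contiguous run pair, which guarantees no cell
outside the mapped rows × mapped columns is ever requested — the formal
version of the laziness claim, asserted in tests with an instrumented
seed. The peak temporary per block is bounded by `block_cells` values.

## The HDF-REST dialect and request planning

The client speaks a four-endpoint JSON dialect (service version, dataset
listing, dataset metadata, hyperslab value reads with 0-based half-open
bounds). The bundled mock service implements it exactly over fixture HDF5
files or in-memory arrays, single-threaded, with an append-only request
log; it logs each request *before* replying so a client can never observe
its own request as missing. Floats are serialized with round-trip decimal
text, making oracle comparisons exact rather than tolerance-based. Dataset
uuids are minted deterministically as `ds-<name>`, and the client resolves
a plain name through that convention after consulting the listing.
Identifier and metadata vectors are served as 1-D datasets under the same
endpoints (`select=[a:b]`, string type class), with nested HDF5 group
paths flattened to dotted names; `build_se_from_hsds` fetches those small
vectors eagerly — mirroring the SQL path, where annotation tables are read
eagerly — while the assay stays lazy.

Scattered selections are planned deterministically before any request:

1. per axis, consecutive indices coalesce into maximal runs;
2. adjacent runs merge greedily left-to-right while the merged span's
   wasted fraction (unneeded/fetched) stays ≤ `waste_ratio`
   (default 0.5);
3. slabs are the cross-product of row spans × column spans, split along
   the longer axis — snapping cuts to chunk boundaries when the budget
   allows — until each is ≤ `max_request_cells` (default 2^20).

The waste-ratio rule is this package's concrete, testable coalescing
policy; no external service documents one. It gives two bounds checked by
property tests: per axis, fetched extent ≤ needed/(1 − waste_ratio), and
the plan never fetches more than the naive bounding box. Chunk snapping
affects only where splits fall, never correctness. Transport policy: 3
attempts with exponential backoff from 0.25 s (transport errors and 5xx
only; 4xx never retried); a 413 oversized-selection response makes the
client halve the slab recursively. JSON value transfer only — adequate at
desk scale and the simplest bit-exact conformance surface.

## The SQL back end

The triple-store schema is one long-format assay table
`(feature_id, sample_id, value)` with unique pairs, plus feature and
sample annotation tables keyed by ID. Building an experiment reads the two
annotation tables eagerly, sorted by ID — result order is otherwise
engine-dependent, and a deterministic axis order is required for testing —
and exposes the assay as a lazy seed: each block read becomes one
canonical `SELECT ... WHERE feature_id IN (...) AND sample_id IN (...)
ORDER BY feature_id, sample_id` with sorted, quote-doubled IN-lists, so
identical selections produce byte-identical SQL. Only
SELECT/WHERE/IN/ORDER BY are emitted, keeping the text portable across
engines. Missing pairs pivot to NaN by default — absence of a record is
not evidence of zero expression — with an explicit fill constant available
for sparse count data. Duplicate pairs and stray keys are errors, not
silent overwrites. Warehouse-specific concerns (authentication, billing,
vendor reshaping layers, aliquot de-duplication) are out of scope; the
loader ingests a clean CSV bundle and neither detects nor resolves
replicate-sample multiplicity.

## Genomic ranges

Coordinates are 1-based closed intervals; two intervals overlap iff they
share a chromosome and `q.start ≤ s.end and s.start ≤ q.end`, so
boundary touches count. BED input (0-based half-open) is converted on
read. Strand is ignored by default (`*` semantics, the common
overlap-subsetting default); strand-aware matching is opt-in, with `*`
compatible with both strands. The implementation sorts subjects per
chromosome and scans with an early break — adequate at this scale and
trivially auditable against the all-pairs definition, which the tests do
on random instances. "Near"-window expansion of queries is not
implemented: no principled default width exists, so the operation is
limited to true overlap.

## The fixture generator

Fixtures are the study conditions for every test, so their defaults are
fixed and documented rather than tunable per-test: 500 features × 400
samples (large enough for multi-chunk request plans, small enough for
sub-second eager oracles), negative-binomial counts via a gamma–Poisson
mixture with dispersion 0.5 (variance = μ + 0.5 μ²), lognormal gene base
means (meanlog 1, sdlog 1, i.e. typical means of a few counts with a
heavy right tail), and a planted fold change of 4 for designated genes.
All draws come from one seeded generator in a fixed order — gene means,
sample covariate, then counts row by row — so a spec is a bit-reproducible
fixture across runs and back ends.

The single-cell scenario assigns each cell one of four capture-class
labels uniformly and gives each class one marker gene upregulated in that
class. The cohort scenario draws a continuous instability-like score from
a fixed 70/30 mixture (uniform on [0, 4) and on [4, 30]) so both strata
are always well populated at n = 400, and upregulates one designated gene
where the score ≥ 4, the conventional instability cutoff. Features tile
two chromosomes as consecutive non-overlapping 1 kb intervals.

What the generator does *not* emulate: library-size variation, dropout,
batch effects, correlated genes, realistic score distributions. Passing
tests therefore demonstrate the correctness of retrieval, planning,
subsetting and the recipe plumbing — elementwise equality with an eager
oracle is the reliability standard throughout — not robustness of any
statistical inference on real single-cell or cohort data.

At n = 400 with dispersion 0.5 the marker-gene group-mean ratio
concentrates well within [effect/2, 2·effect]; tests assert that band
rather than a tighter one to keep them meaningful across seeds.

## Numerical and degenerate-input choices

Realized values are float64 end to end. Empty selections are valid
everywhere (0-row/0-column views realize to empty arrays with zero
requests); an empty ID list is, however, rejected by the SQL translator,
whose callers handle empty selections without a query. Group labels for
threshold recipes are the predicate and its complement (`"<4"` /
`">=4"`); samples with a missing grouping value are dropped and counted.
`bind_sample_data` refuses column collisions and duplicate keys outright.
Ties in planning do not exist by construction: the greedy merge is
left-to-right and split points are arithmetic, so identical inputs give
identical plans.

## Problem sizes used by the test suite and acceptance script

Oracle-equality and cross-back-end checks run 200 and 50 random
selections (up to ~60 indices per axis) on the default 500 × 400 fixture;
planner properties use 500 random draws; overlap agreement uses 100
random instances of up to 100 × 500 intervals; view-algebra chains run
500 random sequences on a 24 × 18 base matrix. These sizes exercise
multi-chunk plans, run merging, 413 splitting and every selector form
while keeping the whole suite around a minute on one CPU.

## Known limitations

Matrices only (no higher-rank arrays, no delayed binary operations
between two delayed matrices); one assay per experiment; no write paths,
authentication or binary transfer on the REST dialect; no server-side
transform pushdown; no nearest/precede/follow range queries; fixture
realism limited as described above.
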