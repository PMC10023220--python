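# Methods

## Problem setting

`netquery` answers the question: *given a list of gene symbols, which
networks in a large, heterogeneous collection of pathways and
interaction networks best align with it?* Collections in this setting
are aggregates — curated pathway models, gene sets extracted from
published figures, term-derived regulation networks — so each member
network is reduced to its **gene set** (the set of normalized node
names) and all scoring is set-based. Network topology deliberately does
not enter any score; it is preserved for display, for subnetwork
extraction, and for round-tripping networks through the CX exchange
format.

## Scoring model

Let a collection contain `m` networks whose gene sets jointly cover a
universe `U` with `N = |U|` genes, and let `df(g)` be the number of
member sets containing gene `g` (its document frequency). A query is
first normalized (below) and intersected with `U`, yielding the
effective query `Q` with `n = |Q|`. For a candidate network with gene
set `D` (`K = |D|`, overlap `k = |Q ∩ D|`), three measures are
computed:

**Cosine similarity with binary TF and logarithmic IDF.** Each set is a
binary vector over `U` weighted by `idf(g) = ln(m / df(g))`:

    sim(Q, D) = Σ_{g ∈ Q∩D} idf(g)² / ( √Σ_{g∈Q} idf(g)² · √Σ_{g∈D} idf(g)² )

Gene sets carry no meaningful term counts, so term frequency is
presence/absence; the logarithmic IDF realizes the intended behavior
that rare shared genes dominate the score while a gene present in every
network (`df = m`) contributes nothing. A zero-norm vector (everything
ubiquitous, or nothing in the universe) yields similarity 0 by
convention. Whether a production system would use `ln`, `log2` or a
smoothed IDF is an internal choice; `ln(m/df)` is ours and is fixed.

**Hypergeometric upper tail.** The enrichment p-value is
`P(X ≥ k)` for `X ~ Hypergeometric(N, K, n)` — the classical urn in
which `n` query genes are drawn without replacement from `N` universe
genes of which `K` lie in the network. We compute it with
`scipy.stats.hypergeom.sf(k−1, N, K, n)`; when the double-precision
tail sum underflows to zero the implementation falls back to exact
integer arithmetic (`math.comb` + `fractions`) and, failing even that,
returns the smallest positive float, keeping `p_raw ∈ (0, 1]`. One
modeling point deserves emphasis: the sample size is the **effective
query size**, `n = |Q ∩ U|`. Descriptions of this family of tools
sometimes conflate `n` with the network size, but `K` already plays
that role; any reading with `n = K` makes the test independent of the
query, so the standard enrichment urn is used here.

**Benjamini–Hochberg adjustment with collection-wide multiplicity.**
Each raw p-value is multiplied by `m` — the number of networks
*queried*, i.e. the whole collection, not merely the candidates that
overlap the query — and divided by its ascending rank; a right-to-left
cumulative minimum (the step-up pass) restores monotonicity and values
are capped at 1. Using the full `m` is both the natural reading of
"number of networks queried" and the conservative choice: networks with
`k = 0` count toward the multiplicity although they are never returned
(a zero-overlap result is uninformative, and the inverted index never
produces one). Ties in raw p receive consecutive ranks after a stable
sort; the monotonicity pass then equalizes their adjusted values.

**Overlap** is simply `k`, reported together with the overlapping genes.

**Stable ranking.** Each sort key (`similarity` and `overlap`
descending, `pvalue` ascending on the adjusted value) is applied with a
stable sort, so chained sorts compose: sorting by p-value and then by
overlap produces an overlap-major list whose overlap-ties are ordered
by p-value. The default key is `similarity`.

## Symbol normalization

Queries are tokenized on whitespace/commas/semicolons, uppercased and
deduplicated (first occurrence wins), then partitioned against an
HGNC-style table into *matched* (already approved), *normalized*
(alias or previous symbol, mapped to its approved symbol) and
*invalid*. Lookup precedence is approved > alias > previous; an alias
claimed by several approved symbols is dropped at table load time and
therefore reports as invalid. Two inputs resolving to the same approved
symbol collapse to one effective gene (scoring is set-based) while both
remain visible in the partition. Queries beyond 400 symbols raise a
soft warning — a performance note, not a validity limit — and proceed.

## CX dialect

The CX reader/writer fixes a minimal dialect: a top-level JSON array of
single-key aspect objects; materialized aspects `nodes`, `edges`,
`nodeAttributes`, `edgeAttributes`, `networkAttributes`,
`cartesianLayout`, `metaData`; numeric node/edge identifiers; attribute
values typed by a declared `d` field defaulting to string. Any other
aspect is preserved opaquely, so read→write is lossless for content the
engine does not interpret. Node-to-gene mapping uses the node `name`
field (`represents` is carried but ignored). Edge direction is
recorded and ignored by scoring and traversal. Parsing is incremental —
one aspect element is decoded at a time on top of
`json.JSONDecoder.raw_decode` — so peak parse buffering is bounded by
the read chunk plus one element, not by document size; the tests assert
this on a 100 000-node document. The writer emits a regenerated
`metaData` aspect; `networkAttributes` carries the network name and, as
the reserved attribute `networkId`, the identifier, since this dialect
has no identifier aspect.

## Subnetwork queries

Interactomes are queried, not scored. *Direct* returns the induced
subgraph on the nodes whose normalized name is a query gene; *k-step
neighborhood* expands the matched seeds breadth-first to all nodes
within `depth` edges (default 1) before inducing. These two are the
minimal faithful set of query types. When a `max_nodes` cap is given,
seeds are always kept and neighbors are admitted in ascending
interactome-degree order — hubs reach everything and would otherwise
swamp the result, so low-degree (more query-specific) neighbors
survive. `annotate_query_nodes` adds a boolean `querynode` attribute to
every node so saved results retain the query marking.

## Synthetic study collections

The fixture generator emulates the one statistical property scoring
depends on: gene popularity skew. Gene `g` of popularity rank `r`
enters a background set with probability ∝ `r^(−s)`; the exponent
defaults to 1.0 (a Zipf-like law, the canonical model for such skews),
which makes the IDF weighting consequential — under `s = 0` similarity
degenerates toward normalized overlap. Default conditions: 500
background networks over a universe of 2 000 genes, set sizes uniform
on [6, 50] (typical curated-pathway sizes), plus one planted network
whose gene set equals the query — 8 genes drawn from the rarest decile,
mirroring a small experimental hit list. All outputs are pure functions
of the spec including its seed.

What the generator does **not** emulate: real pathway topology,
correlated co-membership of biologically related genes, OCR/curation
noise, or non-human symbols. Passing the planted-recovery benchmark
therefore shows the pipeline is wired correctly and the metrics behave
as designed, not that rankings on real collections are biologically
optimal.

## Numerical and design choices

- `min_set_size` filtering (default 1; 6 for figure-derived profiles)
  happens before df/universe computation, so `N` and `m` always refer
  to the retained sets.
- Candidate enumeration and all result orders are deterministic:
  candidates lexicographic by set id, overlapping genes sorted, ties
  broken by stable sort position.
- The index serializes to a single text file (header with `m` and `N`,
  then per-network sorted gene lists); the loader recomputes both
  counts and refuses a file whose header disagrees.
- Exact-rational enumeration of the hypergeometric tail is kept in the
  test suite as an independent oracle; the library route is scipy.
- Benchmark and test problem sizes (e.g. 100 planted-recovery seeds,
  200-collection scan agreement, universes of a few thousand genes)
  were chosen to exercise the contracts at realistic scale while
  keeping the full suite in the tens of seconds.

## Limitations

- Human gene symbols only; no cross-species orthology, no Entrez or
  UniProt identifiers.
- Scoring ignores topology by design; two networks with identical gene
  sets score identically.
- The BH adjustment controls FDR across networks within one
  collection, not across collections queried jointly.
- The CX dialect covers the analysis core plus opaque preservation; it
  is not a full CX/CX2 implementation and does not interpret visual
  style aspects.
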