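# netquery

Network gene set analysis over collections of pathway and interaction
networks. Given a list of gene symbols, `netquery` scores **every
network in an indexed collection** with three measures of alignment and
returns stably-ranked results; against a single large interactome it
extracts query-annotated subnetworks instead. It is aimed at
computational biologists who maintain or mine heterogeneous network
collections (curated pathways, figure-derived gene sets, term-derived
regulation networks, public interactomes) and want a reproducible,
scriptable scoring engine rather than a web service.

## The model

A collection of `m` networks is reduced to gene sets covering a
universe of `N` unique genes; `df(g)` counts the sets containing gene
`g`. A query, after symbol normalization and intersection with the
universe, is the effective set `Q` with `n = |Q|`. Each candidate
network `D` (`K = |D|` genes, overlap `k = |Q ∩ D|`) receives:

- **Similarity** — cosine of binary vectors weighted by
  `idf(g) = ln(m / df(g))`:
  `sim(Q,D) = Σ_{g∈Q∩D} idf(g)² / (‖Q‖·‖D‖)`.
  Rare shared genes dominate; a gene present in every network weighs
  zero.
- **P-value** — the hypergeometric upper tail
  `P(X ≥ k), X ~ Hypergeom(N, K, n)`, Benjamini–Hochberg adjusted with
  multiplicity `m` (the whole collection, including zero-overlap
  networks that are never returned): `p·m/rank`, step-up monotonicity,
  capped at 1.
- **Overlap** — `k`, with the overlapping genes listed.

Sorting by any key is stable, so chained sorts compose (p-value then
overlap ⇒ overlap-major, p-value-minor). Query symbols are partitioned
into *matched* / *normalized* (alias or previous symbol → approved) /
*invalid* against an HGNC-style table. Networks travel in a documented
subset of the CX exchange format (streamed, unknown aspects preserved)
or in GMT-style gene set text. See `docs/methods.md` for the full
account.

## Worked example

Everything below is generated — no downloads. The fixture generator
builds a collection of 500 background networks over a 2 000-gene
universe with Zipf-skewed gene popularity, plus one *planted* network
whose gene set equals an 8-gene query of rare genes:

```sh
$ printf 'n_networks = 500\nuniverse_size = 2000\nplanted_query_size = 8\nseed = 7\n' > spec.toml
$ netquery fixtures --spec spec.toml --out corpus
INFO netquery: wrote 501 sets under corpus
$ netquery index --collection corpus/collection.gmt --format gmt --out collection.idx
INFO netquery: indexed 501 networks, universe of 1748 genes -> collection.idx
$ cat corpus/query.txt
G01849 G01878 G01881 G01887 G01892 G01962 G01977 G01998
$ netquery query --index collection.idx --genes-file corpus/query.txt \
    --symbols corpus/symbols.tsv --sort pvalue --max-results 3 --out results.tsv
INFO netquery: 3 results (n=8, sort=pvalue) -> results.tsv
$ cat results.tsv
rank	set_id	name	k	K	similarity	p_raw	p_adj	overlapping_genes
1	planted	planted query network	8	8	1.0	4.700626341843093e-22	2.3550137972633895e-19	G01849,G01878,G01881,G01887,G01892,G01962,G01977,G01998
2	bg087	background network 87	1	47	0.07945063776186351	0.19626976680575942	1.0	G01892
3	bg191	background network 191	1	23	0.09358903789297134	0.10073364429046247	1.0	G01849
```

Reading the numbers: the planted network contains all 8 query genes
(`k = K = 8`), so its similarity is exactly 1 and its hypergeometric
tail is the chance of drawing all 8 successes in 8 draws from 1 748
genes — about 5×10⁻²², still decisive (2.4×10⁻¹⁹) after multiplying by
the 501 networks queried. The runners-up share a single gene each;
their adjusted p-values saturate at 1.0 and they tie, so their stable
(lexicographic) candidate order is preserved. The sidecar
`results.tsv.norm.json` reports the query partition (here all 8 symbols
matched as given, `"n": 8`).

Subnetwork extraction against the generated interactome:

```sh
$ netquery subnet --interactome corpus/interactome.cx \
    --genes "G00001 G00002 G00003" --mode neighborhood --depth 1 --out sub.cx
INFO netquery: subnetwork: 26 nodes, 28 edges -> sub.cx
```

The three seeds plus their one-hop neighbors are returned as an induced
subgraph in CX, every node carrying a boolean `querynode` annotation.

The same pipeline is available as a library: `generate_collection` /
`build_index` / `run_query` / `extract_subnetwork` in the `netquery`
package.

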