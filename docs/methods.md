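# Methods

## Scope and identity model

netpharm implements the desk-scale core of a network-pharmacology analysis:
everything downstream of the web-database exports. Gene identity is
uppercase-symbol string equality — symbols are trimmed and uppercased on
ingest and never alias-resolved, because the inputs this pipeline consumes
carry plain symbols and deterministic identity matters more here than HGNC
completeness. Live clients for prediction servers (SEA,
SwissTargetPrediction), PubChem, SwissADME or STRING are out of scope by
design; their exports arrive as files, and the synthetic generator stands in
for them when no files exist.

## Screening

The four Lipinski rules are applied with mixed boundary semantics: MW < 500
g/mol and HBA < 10 strict, HBD ≤ 5 and MLogP ≤ 4.15 inclusive. The mix is
deliberate — it is how screening tables report violation counts, and a
compound exactly on an inclusive bound passes. One violation is counted per
failed rule (0–4). TPSA < 140 Å² (strict) flags oral-permeability; the
threshold is configurable. Screening is annotative: the case study carried
all 32 compounds forward regardless of violations, so the pipeline reports
rather than filters, and callers wanting a hard filter apply one explicitly.
Descriptors come from the input table; recomputing them from SMILES is
possible with cheminformatics toolkits but is intentionally not part of the
tested path, since toolkits disagree with the published SwissADME values in
the third decimal.

## Two-stage overlap

Stage 1 intersects the target sets of the two prediction sources; stage 2
intersects that consensus with the disease set. Final membership is emitted
in lexicographic order so reports diff deterministically. The union
cardinality |A ∪ B| is also reported (the case study quotes 794 raw targets
for sources of 332 and 660 sharing 198).

## Enrichment

* **Rich factor** k/K is kept at full precision; display rounds to 4
  decimals. K is the annotation-wide pathway size from the GMT (optionally
  overridden by an explicit size table), never the query-restricted count.
* **Test form**: one-sided hypergeometric over-representation,
  p = P(X ≥ k), X ~ Hypergeom(N, K, n), computed by `scipy.stats.hypergeom.sf`.
  The case study names only the STRING enrichment service, whose default
  family this matches. An exact rational enumeration
  (`hypergeom_pvalue_exact`, integer binomials via `math.comb`) serves as
  the validation oracle; the two agree to 1e−12 for every (N ≤ 25, K, n, k).
* **FDR**: Benjamini–Hochberg step-up with monotonicity enforcement, capped
  at 1; cross-checked against `statsmodels.stats.multitest.multipletests`.
* **Background N** defaults to 20,000 (human protein-coding scale). The
  bundled case-study table prints no p-values, so N never enters the fixture
  checks.
* **Key pathway** = minimum rich factor; ties break by smaller FDR, then
  lexicographic pathway id.

The bundled seven-row enrichment table preserves its published quirks
verbatim (a gene-symbol typo, a duplicated gene, and one rich factor that is
not k/K for any integer K at the listed gene count). Background sizes are
therefore stored only for the four rows where the printed rich factor is
integer-recoverable, and recomputation tests cover exactly those rows.

## Networks and the double filter

The tripartite network restricts edges to pathway–target and target–drug
pairs; nodes are exactly the entities referenced by at least one pair, so
candidates whose links all dropped out upstream are excluded by
construction. Degree is the raw adjacency count (the case study quotes
integer degrees); per-layer maxima and pathway-side/drug-side breakdowns for
targets are reported separately.

Betweenness is shortest-path betweenness normalized by (n−1)(n−2)/2, so a
node on every shortest path between all other pairs scores exactly 1 — the
normalization implied by the published tables, where the hub's BC is printed
as 1. Pair dependencies split equally among tied shortest paths.

The **filter rule** at both stages: drop zero-metric nodes, rank the rest
descending, select the top ceil(f·n) where n is the *original* table size
(zeros included), and include every node tied with the boundary value.
This rule was chosen because it is the unique simple convention that
reproduces both published stages from the printed centrality tables —
13 targets → 5 on degree (cutoff 4 plus one boundary tie) and 5 → 1 on
betweenness — whereas plain top-30%-with-ties or plain ceil-count do not.
`keep_zeros` and `include_ties` expose the alternatives. Disconnected nodes
are retained in centrality tables with DC = BC = 0 (the published full-network
table lists four such targets); they can never be selected under the default
policy. Stage 2 always *recomputes* both centralities inside the induced
subnetwork before filtering on betweenness.

The published PPI network's own edge list is unrecoverable (its printed
node/edge counts are inconsistent with the printed degree sums), so
fixture-level checks inject the published centrality tables via
`hub_from_centrality_tables`; graph-level behavior is exercised on synthetic
planted-hub graphs.

## Docking triage

The package never invokes a docking engine. It writes a deterministic
Vina-style config (receptor, ligand, grid center/size, exhaustiveness 8,
10 modes, 4 kcal/mol energy range — the case study's settings, with the
40 Å cube centered at 128.688/128.088/133.365 for the GRIN2B structure) and
parses score tables. Activity is strict: energy < −6.0 kcal/mol; a record
on the boundary is inactive. Unicode minus signs are normalized before
parsing, since published tables print U+2212. Residue labels must match
`AaaNNN`; malformed labels are logged and skipped, not fatal.

## Synthetic generator

Each generator is a pure function of (config, seed); independent seed
streams per stage keep the outputs byte-identical across reruns. Defaults
are the case study's conditions: 32 drugs, sources of 332 and 660 targets
overlapping in 198, a 622-gene disease set overlapping the consensus in 15,
and seven pathways whose (K, hits) pairs — (21,2), (64,3), (48,2), (107,4),
(116,4), (229,3), (330,4) — reproduce the published rich-factor spread.
Docking energies are drawn in [−8, −4] kcal/mol with exactly 6 actives and
2 inactives; rounding to table precision is clamped so it can never push an
active onto the boundary.

The hub graph joins disjoint cliques (default two 5-cliques, plus 4
isolated nodes) through a single bridge node attached to *every* clique
member. That attachment pattern is a deliberate design choice: it gives the
bridge both the maximal degree (so it survives the degree stage) and all
inter-clique shortest paths (so it dominates betweenness in the
subnetwork). With equal clique sizes, boundary ties pull both cliques
through stage 1 and recovery is exact; with unequal cliques the degree
filter can strand a single complete clique (all betweenness zero) and lose
the hub — representable, but not the default.

What the generator does **not** emulate: realistic chemistry (descriptors
are uniform draws from drug-like ranges), true prediction-score or STRING
confidence distributions, correlated pathway membership, or PPI topology
beyond the planted clique-bridge motif. Passing tests on synthetic data
therefore demonstrate that each stage recovers planted combinatorial
structure exactly — not that the pipeline's biological conclusions transfer
to any particular real dataset.

## Numerical and degenerate-input choices

* Delimiters are auto-detected among tab/comma/semicolon, overridable.
* A missing PPI confidence column means confidence 1.0; scores above 1 are
  read as STRING's 0–1000 scale and divided by 1000.
* Duplicate undirected edges keep the maximum confidence; self-loops are
  dropped and counted.
* Empty prediction tables and queries hitting no pathway produce warnings
  and empty results, not errors; empty inputs to selectors
  (`key_pathway`, `best_binder`, `classify_binders`) are errors.
* An all-zero centrality table yields an empty selection with a warning, and
  the pipeline propagates an empty hub rather than failing.
* Pipeline runs with an empty final target set succeed with a warning and
  skip the downstream stages.

## Problem sizes

The test suite runs the exhaustive hypergeometric check at N ≤ 25, the
betweenness oracle over all connected graphs on ≤ 5 nodes plus sampled
6–7-node graphs, 500 hub-recovery replicates at the default graph shape, and
200 seeds of planted-cardinality recovery at a reduced study shape
(40/60-target sources, 12/5 overlaps) chosen so the full sweep stays
interactive; the study-scale shape (332/660/198, 622/15) is exercised once
per suite run and in the pipeline tests.
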