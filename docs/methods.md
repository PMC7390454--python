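# Methods

This note states precisely what `ppicore` computes. Symbols: the network
has N nodes; a study contributes a hit set H (|H| = K after restriction to
the network universe); a node v has degree n and k hit neighbors.

## 1. Network construction (`ppicore.string_network`)

Inputs are four tab-separated tables: interaction links
(`protein1`, `protein2`, `combined_score`, optional per-channel columns such
as `coexpression`), interaction actions (`item_id_a`, `item_id_b`, `mode`),
protein→symbol aliases, and an approved-symbol table. Directed duplicate
rows are symmetrized (unordered pair kept once; maximum score; union of
modes). An edge enters the network when:

- its mode matches the requested mode (default `binding`; six further
  action modes plus the `coexpression` score channel are supported),
- its confidence score is **≥** the cutoff (inclusive; default 700 for
  action modes, 1 for coexpression, i.e. any non-zero channel score),
- both endpoints map through the alias table to approved symbols, and the
  mapped endpoints differ (alias collisions that collapse an edge into a
  self-loop drop it).

Unmapped identifiers are reported, never silently dropped at parse time.
The node universe is edge-defined: a gene is in the universe iff it has at
least one qualifying edge. An empty result raises rather than returning an
empty graph.

## 2. Catalog QC (`ppicore.gwas_catalog`)

Association rows join ancestry (by study accession) and parent-term (by
trait name) tables, then pass a filter cascade:

1. keep, per publication, only rows from the genotyping platform with the
   most SNPs passing QC (ties keep all tied platforms);
2. drop rows with a non-empty p-value qualifier (e.g. sub-cohort text);
3. drop compound rsIDs (containing `x` or `;`, i.e. interactions or
   haplotypes);
4. drop loci annotated with more than 2 genes;
5. keep p ≤ 5 × 10⁻⁸ (genome-wide significance);
6. collapse a gene appearing at several loci to its minimum p;
7. keep studies whose broad ancestral category is one of five configured
   categories (European; African American or Afro-Caribbean; Hispanic or
   Latin American; South Asian; East Asian).

Steps 2–5 are row-local, so row order cannot change the result. Studies can
be merged by parent term (hit union, min-p per gene) for pooled analyses.

## 3. Degree-preserving null (`ppicore.randomization`)

One randomization replicate applies, in order:

- **Label stage** — for each degree class (nodes of equal degree), a
  uniform permutation of the labels within the class; the configured number
  of sweeps are composed into a single relabeling. Composition of uniform
  permutations is uniform on the same group, so the sweep count does not
  change the distribution, only mirrors the reference procedure.
- **Edge stage** — double edge swaps ((a,b),(c,d) → (a,d),(c,b), random
  orientation) restricted to edges with at least one endpoint of unique
  degree (label permutation alone cannot move those); proposals creating
  self-loops or parallel edges are rejected.

Both stages preserve every node's degree exactly and the total edge count;
simplicity (no self-loops, no multi-edges) is maintained by rejection.
Replicate r uses seed `base_seed + r`, so ensembles are reproducible and
embarrassingly parallel. Defaults mirror the reference analysis: 1,000
label sweeps, 100,000 edge swaps, 50,000 replicates.

## 4. Excess-PPI test (`ppicore.excess_ppi`)

For a study with hit set H, the statistic is the number of network edges
with both endpoints in H. The empirical p-value against B null replicates
with counts c₁…c_B and observed c is the add-one estimator

    p = (#{r : c_r ≥ c} + 1) / (B + 1),

never exactly zero. Studies with fewer than 2 in-network hits, or with no
internal edge, are *untestable* (reported with a reason, not a p-value).
`batch_excess` additionally reports a Benjamini–Hochberg column over the
testable studies; the headline `significant` flag uses the raw p < 0.05
threshold of the reference procedure. The funnel — total studies → ≥ 2 hits
→ ≥ 1 internal edge → excess → with detections — applies these gates in
order.

## 5. Detection screen (`ppicore.ppi_gene_detection`)

Every node with k ≥ 1 hit neighbors is tested (m such nodes). The raw
p-value is the inclusive hypergeometric upper tail

    p = P(X ≥ k),  X ~ Hypergeom(N, K, n),

computed exactly via the survival function (no approximations).
Benjamini–Hochberg runs over the m tested nodes. A sub-alpha node
(adjusted p < 0.05) is *detected* unless removed by:

- **MIN_SUPPORT** — fewer than 2 distinct supporting hit genes;
- **LOCUS_WINDOW** — all supporting hits on one chromosome within 1 Mb
  (inclusive span), i.e. compatible with a single GWAS locus. Applied only
  when coordinates are available; missing coordinates skip the filter with
  a warning rather than silently passing or failing the node.

Removed nodes stay in the output with their filter reason. Detected genes
are classified PPI-GWAS (also a hit), PPI-only (not a hit) or GWAS-only
(hit, not detected); with somatic seed sets the detected-and-seed class is
PPI-Somatically-Mutated.

## 6. Enrichment analyses (`ppicore.enrichment`)

Class-vs-class and class-vs-universe 2×2 comparisons against annotation
sets use one-sided Fisher tests *routed through the same hypergeometric
kernel as the screen* (P(X ≥ a) for the overlap cell), so the two modules
cannot drift apart numerically; tests cross-check this route against an
independent implementation. Annotation loaders: single-column gene lists;
ClinVar-style VCFs (genes with ≥ 1 variant whose clinical significance is
the single annotation `Pathogenic`; compound annotations are dropped and
counted); GMT pathway collections (BH-corrected per-pathway Fisher tests).
A degree-stratified variant repeats comparisons within degree bins
(default: degree quartiles) because both detectability and annotation
coverage increase with degree. The rank-fraction analysis ranks each
study's hits by ascending association p (average ranks on ties), assigns
rank/n fractions, and Fisher-tests whether PPI-GWAS genes concentrate in
the top 10% / 25%.

## 7. Second-closest-gene robustness (`ppicore.robustness`)

Gene intervals are 0-based half-open BED rows; SNP positions are 1-based.
Distance from a SNP to a gene is 0 inside the interval, else the gap to the
nearest edge; candidate ranking breaks ties by (distance, interval start,
symbol) for determinism. `replace_hits` substitutes the next-closest gene
(excluding the study's own genes, optionally restricted to the network
universe) for one uniformly chosen hit or for all hits, then the excess
test is re-run; a signal drop indicates the nearest-gene assignment carries
information.

## 8. Synthetic data (`ppicore.synthetic_data`)

Seeded generators produce every input format the pipeline consumes.
Backgrounds are Erdős–Rényi or configuration-model (Havel–Hakimi
realization + double edge swaps) graphs; signal is planted by targeted
double swaps so all degrees are preserved — a planted core node gains q hit
neighbors, and/or a clique is wired among hits. Synthetic association
p-values are log-uniform in [5 × 10⁻³⁰, 5 × 10⁻⁸]; synthetic coordinates
place successive genes on rotating chromosomes ≥ 3 Mb apart so the locus
filter is exercised but not triggered spuriously. Emitted files round-trip
exactly through the readers (p-values written with full precision).

## Defaults

| Quantity | Default |
| --- | --- |
| score cutoff (action modes) | ≥ 700 (inclusive) |
| genome-wide significance | p ≤ 5 × 10⁻⁸ |
| max genes per locus | 2 |
| null replicates B | 50,000 |
| label sweeps / edge swaps | 1,000 / 100,000 |
| screen alpha (BH-adjusted) | 0.05 |
| min supporting hits | 2 |
| locus window | 1 Mb |
| excess-PPI threshold (raw p) | 0.05 |
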