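"""Per-node hypergeometric screen for genes with excess seed-set neighbors.

Every network node with at least one neighbor in the seed set (GWAS hits or
somatically mutated genes) is tested: with N the network's node count, K the
seed-set size, n the node's degree and k its number of seed neighbors, the
raw p-value is the inclusive upper tail P(X >= k) of the hypergeometric
distribution — the chance that a random degree-n neighborhood would capture
at least k seeds.  Benjamini-Hochberg correction is applied over the m tested
nodes.  Detections (adjusted p below alpha) then pass two guards against
spurious signal: a minimum of two distinct supporting seed genes, and — when
genomic coordinates are available — removal of nodes whose supporting seeds
all lie within a 1 Mb window on one chromosome, i.e. likely one GWAS locus.

Detected genes ("PPI genes", candidate core genes) are classified by whether
they are themselves seeds: PPI-GWAS (detected and a hit), PPI-only (detected,
not a hit) and GWAS-only (hit, not detected); with somatic seeds the
detected-and-seed class is PPI-Somatically-Mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

# filter reason codes
MIN_SUPPORT = "MIN_SUPPORT"
LOCUS_WINDOW = "LOCUS_WINDOW"

PPI_ONLY = "PPI_ONLY"
PPI_GWAS = "PPI_GWAS"
GWAS_ONLY = "GWAS_ONLY"
PPI_SOMATIC = "PPI_SOMATIC"


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of one node's test: overlap k, degree n, seeds K, universe N."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError(f"k={self.k} outside [0, min(n={self.n}, K={self.K})]")
        if self.n > self.N:
            raise ValueError(f"degree n={self.n} exceeds universe N={self.N}")
        if self.K > self.N:
            raise ValueError(f"seed count K={self.K} exceeds universe N={self.N}")


@dataclass(frozen=True)
class DetectionConfig:
    alpha: float = 0.05
    min_support: int = 2
    locus_window: int = 1_000_000
    apply_locus_filter: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_support < 1 or self.locus_window < 0:
            raise ValueError("min_support >= 1 and locus_window >= 0 required")


@dataclass
class NodeEnrichmentResult:
    """One tested node's screen outcome."""

    gene: str
    degree: int
    overlap: int
    supporting_seeds: tuple
    raw_p: float
    adjusted_p: float = float("nan")
    detected: bool = False          # survives alpha + all filters
    filter_reason: str = ""          # why a sub-alpha node was removed
    gene_class: str = ""
    supporting_coords: dict = field(default_factory=dict)


def hypergeom_upper_tail(params: HypergeomParams) -> float:
    """Exact inclusive upper tail P(X >= k) for the node's parameters.

    Computed via the survival function of the hypergeometric distribution
    (evaluated in log space internally); no normal or Poisson approximation.
    """
    if params.k == 0:
        return 1.0
    return float(hypergeom.sf(params.k - 1, params.N, params.K, params.n))


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("raw p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _locus_confined(coords, window: int) -> bool:
    """True when all coordinates share a chromosome within ``window`` bp."""
    chroms = {c for c, _ in coords}
    if len(chroms) != 1:
        return False
    positions = [pos for _, pos in coords]
    return max(positions) - min(positions) <= window


def detect_ppi_genes(network, seed_set, config: DetectionConfig = DetectionConfig(),
                     coordinates: dict | None = None) -> list[NodeEnrichmentResult]:
    """Run the screen over every node with at least one seed neighbor.

    ``coordinates`` maps gene -> (chrom, position); when provided and
    ``config.apply_locus_filter`` is set, single-locus detections are removed.
    Returns a result per tested node (m results), with ``detected`` marking
    the survivors and ``filter_reason`` explaining removed sub-alpha nodes.
    """
    seeds = set(seed_set)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = seeds - set(network.nodes)
    if missing:
        raise ValueError(f"seed genes absent from network: {sorted(missing)}")

    N = network.number_of_nodes()
    K = len(seeds)
    results: list[NodeEnrichmentResult] = []
    for node in network.nodes:
        supporting = tuple(sorted(set(network.neighbors(node)) & seeds))
        k = len(supporting)
        if k == 0:
            continue
        n = network.degree(node)
        raw = hypergeom_upper_tail(HypergeomParams(k=k, n=n, K=K, N=N))
        results.append(
            NodeEnrichmentResult(
                gene=node, degree=n, overlap=k, supporting_seeds=supporting, raw_p=raw
            )
        )

    adjusted = bh_adjust([r.raw_p for r in results])
    for r, adj in zip(results, adjusted):
        r.adjusted_p = float(adj)
        if r.adjusted_p >= config.alpha:
            continue
        if r.overlap < config.min_support:
            r.filter_reason = MIN_SUPPORT
            continue
        if coordinates is not None and config.apply_locus_filter:
            coords = {g: coordinates[g] for g in r.supporting_seeds if g in coordinates}
            r.supporting_coords = coords
            if len(coords) < len(r.supporting_seeds):
                logging.getLogger(__name__).warning(
                    "locus filter skipped for %s: missing coordinates", r.gene
                )
            elif _locus_confined(coords.values(), config.locus_window):
                r.filter_reason = LOCUS_WINDOW
                continue
        r.detected = True
    return results


def detected_genes(results) -> set:
    return {r.gene for r in results if r.detected}


def classify_genes(results, seed_set, somatic: bool = False) -> dict:
    """Partition detected and seed genes into the three (disjoint) classes.

    Returns a dict with keys PPI_ONLY, GWAS_ONLY and PPI_GWAS (or PPI_SOMATIC
    when ``somatic``); also annotates each detected result's ``gene_class``.
    """
    seeds = set(seed_set)
    detected = detected_genes(results)
    both_key = PPI_SOMATIC if somatic else PPI_GWAS
    classes = {
        PPI_ONLY: detected - seeds,
        both_key: detected & seeds,
        GWAS_ONLY: seeds - detected,
    }
    for r in results:
        if r.detected:
            r.gene_class = both_key if r.gene in seeds else PPI_ONLY
    return classes
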