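"""Validation analytics for detected gene classes.

Detected candidate core genes are compared to external annotation gene sets
(ClinVar pathogenic-variant genes, COSMIC census genes, OncoKB / TTD drug
targets, pathway collections) with one-sided Fisher's exact tests in the
enrichment direction.  Because higher-degree nodes are both easier to detect
and better annotated, a degree-stratified variant repeats the comparison
within degree bins.  A rank-fraction analysis asks whether detected GWAS hits
(PPI-GWAS) carry more significant association p-values than undetected hits.

All 2x2 tests route through the same inclusive hypergeometric tail used by
the detection screen, so the two modules cannot drift apart numerically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EmptyInputError, FormatError
from .ppi_gene_detection import HypergeomParams, bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationGeneSet:
    """A named external gene list, restricted to the network universe."""

    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise EmptyInputError(f"annotation set {self.name!r} is empty")


def fisher_one_sided(a_in: int, a_out: int, b_in: int, b_out: int) -> float:
    """One-sided Fisher p for over-representation of 'in' among group A.

    Equivalent to the inclusive hypergeometric upper tail P(X >= a_in) when
    drawing |A| items from the pooled table — the same kernel the detection
    screen uses.
    """
    if min(a_in, a_out, b_in, b_out) < 0:
        raise ValueError("table counts must be non-negative")
    return hypergeom_upper_tail(
        HypergeomParams(k=a_in, n=a_in + a_out, K=a_in + b_in, N=a_in + a_out + b_in + b_out)
    )


def load_gene_list(path, universe) -> frozenset:
    """Single-column TSV of gene symbols, intersected with the universe."""
    symbols = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].dropna()
    uni = set(universe)
    kept = frozenset(s for s in symbols if s in uni)
    dropped = len(set(symbols)) - len(kept)
    if dropped:
        logger.info("%s: %d symbols outside the universe dropped", path, dropped)
    return kept


def load_clinvar_pathogenic(vcf_path, universe) -> frozenset:
    """Genes carrying at least one single-annotation Pathogenic variant.

    Variants whose clinical-significance field carries multiple annotations
    (comma- or slash-compounded, e.g. "Pathogenic/Likely_pathogenic") are
    dropped and counted; gene symbols come from the GENEINFO field
    ("SYMBOL:id|SYMBOL:id").
    """
    from cyvcf2 import VCF

    uni = set(universe)
    genes: set[str] = set()
    n_multi = 0
    for variant in VCF(str(vcf_path)):
        sig = variant.INFO.get("CLNSIG")
        if sig is None:
            continue
        if "," in sig or "/" in sig or "|" in sig:
            n_multi += 1
            continue
        if sig != "Pathogenic":
            continue
        geneinfo = variant.INFO.get("GENEINFO") or ""
        for part in geneinfo.split("|"):
            sym = part.split(":")[0].strip()
            if sym in uni:
                genes.add(sym)
    if n_multi:
        logger.info("dropped %d multi-annotation ClinVar variants", n_multi)
    if not genes:
        raise EmptyInputError("no pathogenic-variant genes survive within the universe")
    return frozenset(genes)


def load_annotation_sets(universe, clinvar_vcf=None, **gene_list_paths) -> dict:
    """Assemble named :class:`AnnotationGeneSet` objects from input files."""
    sets: dict[str, AnnotationGeneSet] = {}
    if clinvar_vcf is not None:
        sets["clinvar_pathogenic"] = AnnotationGeneSet(
            "clinvar_pathogenic", load_clinvar_pathogenic(clinvar_vcf, universe)
        )
    for name, path in gene_list_paths.items():
        sets[name] = AnnotationGeneSet(name, load_gene_list(path, universe))
    return sets


def overlap_row(class_a: str, genes_a, class_b: str, genes_b,
                annotation: AnnotationGeneSet) -> dict:
    """One enrichment comparison (A vs B) as a tidy row."""
    ga, gb = set(genes_a), set(genes_b)
    a_in = len(ga & annotation.genes)
    b_in = len(gb & annotation.genes)
    a_out, b_out = len(ga) - a_in, len(gb) - b_in
    if not ga or not gb:
        return {
            "class_a": class_a, "class_b": class_b, "annotation": annotation.name,
            "a_in": a_in, "a_out": a_out, "b_in": b_in, "b_out": b_out,
            "proportion_a": np.nan, "proportion_b": np.nan,
            "odds_ratio": np.nan, "fisher_p": np.nan, "empty_class": True,
        }
    num, den = a_in * b_out, a_out * b_in
    odds = np.nan if num == den == 0 else (np.inf if den == 0 else num / den)
    return {
        "class_a": class_a, "class_b": class_b, "annotation": annotation.name,
        "a_in": a_in, "a_out": a_out, "b_in": b_in, "b_out": b_out,
        "proportion_a": a_in / len(ga), "proportion_b": b_in / len(gb),
        "odds_ratio": odds,
        "fisher_p": fisher_one_sided(a_in, a_out, b_in, b_out),
        "empty_class": False,
    }


#: Comparisons run by default: each detected class against the undetected
#: hits, and each class against the whole universe.
DEFAULT_COMPARISONS = (
    ("PPI_ONLY", "GWAS_ONLY"),
    ("PPI_GWAS", "GWAS_ONLY"),
    ("PPI_SOMATIC", "GWAS_ONLY"),
    ("PPI_ONLY", "ALL"),
    ("PPI_GWAS", "ALL"),
    ("PPI_SOMATIC", "ALL"),
)


def class_overlap_enrichment(gene_classes: dict, annotation: AnnotationGeneSet,
                             universe, comparisons=None) -> pd.DataFrame:
    """Fisher enrichment rows for the configured class-vs-class comparisons.

    ``gene_classes`` maps class name -> gene set; the pseudo-class ``ALL``
    (the full universe) is always available as a comparator.
    """
    classes = dict(gene_classes)
    classes.setdefault("ALL", set(universe))
    if comparisons is None:
        comparisons = [
            (a, b) for a, b in DEFAULT_COMPARISONS if a in gene_classes and b in classes
        ]
    rows = [
        overlap_row(a, classes[a], b, classes[b], annotation) for a, b in comparisons
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DegreeBinSpec:
    """Degree bin edges; bin i is [edges[i], edges[i+1]) (last bin closed)."""

    edges: tuple

    @classmethod
    def quartiles(cls, degrees: dict) -> "DegreeBinSpec":
        vals = np.asarray(list(degrees.values()), dtype=float)
        qs = np.quantile(vals, [0, 0.25, 0.5, 0.75, 1.0])
        return cls(edges=tuple(np.unique(qs)))

    def assign(self, degree: float) -> int:
        idx = int(np.searchsorted(self.edges, degree, side="right")) - 1
        return min(max(idx, 0), len(self.edges) - 2)


def degree_stratified_enrichment(gene_classes: dict, annotation: AnnotationGeneSet,
                                 bins: DegreeBinSpec, degrees: dict,
                                 comparisons=None) -> pd.DataFrame:
    """Repeat the class enrichment independently inside each degree bin."""
    universe = set(degrees)
    frames = []
    for b in range(len(bins.edges) - 1):
        members = {g for g in universe if bins.assign(degrees[g]) == b}
        binned = {name: set(gs) & members for name, gs in gene_classes.items()}
        ann = AnnotationGeneSet(annotation.name, annotation.genes)
        df = class_overlap_enrichment(binned, ann, members, comparisons)
        df.insert(0, "degree_bin", b)
        df.insert(1, "bin_size", len(members))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def rank_fraction_analysis(studies_with_detections) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-fraction records plus top-decile/quartile Fisher tests.

    ``studies_with_detections`` is an iterable of (study, ppi_gwas_genes)
    pairs; only studies with at least one PPI-GWAS gene are included.  Within
    each study, hits are ranked by ascending p-value (ties get the average
    rank) and the rank fraction is rank / n_hits.  Fisher tests compare
    PPI-GWAS membership against membership in the top 10% / 25% fractions.
    """
    records = []
    for study, ppi_gwas in studies_with_detections:
        ppi_gwas = set(ppi_gwas)
        if not ppi_gwas or not study.hits:
            continue
        genes = sorted(study.hits)
        pvals = np.array([study.hits[g].p_value for g in genes])
        ranks = rankdata(pvals, method="average")
        n = len(genes)
        for g, p, r in zip(genes, pvals, ranks):
            records.append(
                {
                    "study_accession": study.study_accession,
                    "gene": g,
                    "gwas_p": p,
                    "rank": r,
                    "n_hits": n,
                    "rank_fraction": r / n,
                    "is_ppi_gwas": g in ppi_gwas,
                }
            )
    rec = pd.DataFrame(
        records,
        columns=["study_accession", "gene", "gwas_p", "rank",
                 "n_hits", "rank_fraction", "is_ppi_gwas"],
    )
    tests = []
    for label, cut in (("top_10pct", 0.10), ("top_25pct", 0.25)):
        if rec.empty:
            tests.append({"threshold": label, "fisher_p": np.nan,
                          "ppi_gwas_in_top": 0, "ppi_gwas_total": 0,
                          "others_in_top": 0, "others_total": 0})
            continue
        top = rec["rank_fraction"] <= cut
        is_pg = rec["is_ppi_gwas"]
        a_in = int((top & is_pg).sum())
        a_out = int((~top & is_pg).sum())
        b_in = int((top & ~is_pg).sum())
        b_out = int((~top & ~is_pg).sum())
        tests.append(
            {
                "threshold": label,
                "fisher_p": fisher_one_sided(a_in, a_out, b_in, b_out),
                "ppi_gwas_in_top": a_in,
                "ppi_gwas_total": a_in + a_out,
                "others_in_top": b_in,
                "others_total": b_in + b_out,
            }
        )
    return rec, pd.DataFrame(tests)


def read_gmt(path) -> dict:
    """Parse a GMT pathway file: name <tab> description <tab> genes...

    Duplicate pathway names are deduplicated (first occurrence wins).
    """
    collection: dict[str, frozenset] = {}
    n_dupes = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise FormatError(f"malformed GMT line in {path}: {line[:60]!r}")
                continue
            name, genes = parts[0], frozenset(g for g in parts[2:] if g)
            if name in collection:
                n_dupes += 1
                continue
            collection[name] = genes
    if n_dupes:
        logger.warning("%d duplicate pathway names in %s deduplicated", n_dupes, path)
    if not collection:
        raise EmptyInputError(f"GMT file {path} contains no pathways")
    return collection


def pathway_enrichment(gene_set, gmt_collection: dict, universe) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``gene_set`` per pathway, BH-corrected."""
    if not gmt_collection:
        raise EmptyInputError("pathway collection is empty")
    uni = set(universe)
    genes = set(gene_set) & uni
    rows = []
    for name, members in sorted(gmt_collection.items()):
        path_genes = set(members) & uni
        a_in = len(genes & path_genes)
        a_out = len(genes) - a_in
        b_in = len(path_genes) - a_in
        b_out = len(uni) - len(genes) - b_in
        rows.append(
            {
                "pathway": name,
                "pathway_size": len(path_genes),
                "overlap": a_in,
                "fisher_p": fisher_one_sided(a_in, a_out, b_in, b_out),
            }
        )
    df = pd.DataFrame(rows)
    df["bh_adjusted_p"] = bh_adjust(df["fisher_p"].to_numpy())
    return df.sort_values("fisher_p", kind="stable").reset_index(drop=True)
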