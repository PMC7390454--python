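"""Parse GWAS-catalog-format tables and derive QC'd per-study hit sets.

The GWAS catalog aggregates published associations; each row carries a study
accession, the lead SNP, its association p-value, and the gene(s) mapped or
reported for the locus.  The quality-control cascade applied here retains,
per publication, only the genotyping platform with the most SNPs passing QC;
drops rows whose p-value refers to a sample subset (non-empty free-text
qualifier); rejects compound rsIDs; caps loci at two annotated genes;
enforces genome-wide significance (p <= 5e-8); collapses a gene hit at
multiple loci to its most significant p-value; and restricts to a set of
broad ancestral categories.  Studies sharing a catalog "parent term" can be
merged into a pooled hit set for over-arching disease processes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8

#: Broad ancestral categories retained by default.
DEFAULT_ANCESTRIES = frozenset(
    {
        "European",
        "African American or Afro-Caribbean",
        "Hispanic or Latin American",
        "South Asian",
        "East Asian",
    }
)

ASSOC_COLUMNS = [
    "PUBMEDID",
    "STUDY ACCESSION",
    "DISEASE/TRAIT",
    "SNPS",
    "CHR_ID",
    "CHR_POS",
    "P-VALUE",
    "P-VALUE (TEXT)",
    "PLATFORM [SNPS PASSING QC]",
    "REPORTED GENE(S)",
    "MAPPED_GENE",
]


@dataclass(frozen=True)
class GwasAssociation:
    """One association row after joining ancestry and parent-term tables."""

    study_accession: str
    pubmed_id: str
    trait: str
    parent_term: str
    snp_id: str
    chrom: str
    position: int
    p_value: float
    p_value_text: str
    platform_snp_count: int
    mapped_genes: tuple
    reported_genes: tuple
    ancestry: str

    @property
    def genes(self) -> tuple:
        """Union of mapped and reported genes for the locus."""
        return tuple(dict.fromkeys(self.mapped_genes + self.reported_genes))


@dataclass(frozen=True)
class Hit:
    """A gene's best association within one study."""

    p_value: float
    chrom: str
    position: int
    snp_id: str


@dataclass
class GwasStudy:
    study_accession: str
    trait: str
    parent_term: str
    ancestry: str
    hits: dict = field(default_factory=dict)  # gene symbol -> Hit
    restricted_empty: bool = False  # no hits survived universe restriction

    @property
    def n_hits(self) -> int:
        return len(self.hits)


@dataclass
class ParentTermHitSet:
    parent_term: str
    study_accessions: tuple
    hits: dict  # gene -> Hit (per-gene minimum p over contributing studies)


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the catalog QC cascade."""

    p_threshold: float = GENOME_WIDE_P
    max_genes_per_locus: int = 2
    ancestries: frozenset = DEFAULT_ANCESTRIES
    rsid_reject: str = r"[x;]"


def _split_genes(cell) -> tuple:
    if not isinstance(cell, str) or not cell.strip():
        return ()
    parts = re.split(r"[,;]| - ", cell)
    return tuple(dict.fromkeys(p.strip() for p in parts if p.strip()))


def _platform_count(cell) -> int:
    """SNPs-passing-QC from a platform cell: bare integer or '[123456]'."""
    s = str(cell)
    m = re.search(r"\[([\d,]+)\]", s)
    if m:
        return int(m.group(1).replace(",", ""))
    return int(s.replace(",", ""))


def load_associations(assoc_path, ancestry_path, trait_map_path):
    """Read the association TSV and join ancestry + parent-term tables.

    The ancestry table needs columns ``STUDY ACCESSION`` and
    ``BROAD ANCESTRAL CATEGORY``; the trait map needs ``Disease trait`` and
    ``Parent term``.  Rows with unparseable p-values, positions, or platform
    counts are skipped and counted.
    """
    try:
        assoc = pd.read_csv(assoc_path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"association file {assoc_path} is empty") from None
    for col in ASSOC_COLUMNS:
        if col not in assoc.columns:
            raise FormatError(f"association file is missing required column {col!r}")
    if assoc.empty:
        raise EmptyInputError("association file has no data rows")

    anc = pd.read_csv(ancestry_path, sep="\t", dtype=str).fillna("")
    for col in ("STUDY ACCESSION", "BROAD ANCESTRAL CATEGORY"):
        if col not in anc.columns:
            raise FormatError(f"ancestry file is missing required column {col!r}")
    anc_map = dict(
        anc[["STUDY ACCESSION", "BROAD ANCESTRAL CATEGORY"]].itertuples(index=False, name=None)
    )

    tm = pd.read_csv(trait_map_path, sep="\t", dtype=str).fillna("")
    for col in ("Disease trait", "Parent term"):
        if col not in tm.columns:
            raise FormatError(f"trait-map file is missing required column {col!r}")
    term_map = dict(tm[["Disease trait", "Parent term"]].itertuples(index=False, name=None))

    out = []
    n_skipped = 0
    for row in assoc.itertuples(index=False):
        d = dict(zip(assoc.columns, row))
        try:
            p = float(d["P-VALUE"])
            pos = int(d["CHR_POS"])
            platform = _platform_count(d["PLATFORM [SNPS PASSING QC]"])
            if not (0 < p <= 1) or pos < 1:
                raise ValueError
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        out.append(
            GwasAssociation(
                study_accession=d["STUDY ACCESSION"],
                pubmed_id=d["PUBMEDID"],
                trait=d["DISEASE/TRAIT"],
                parent_term=term_map.get(d["DISEASE/TRAIT"], ""),
                snp_id=d["SNPS"],
                chrom=d["CHR_ID"],
                position=pos,
                p_value=p,
                p_value_text=d["P-VALUE (TEXT)"].strip(),
                platform_snp_count=platform,
                mapped_genes=_split_genes(d["MAPPED_GENE"]),
                reported_genes=_split_genes(d["REPORTED GENE(S)"]),
                ancestry=anc_map.get(d["STUDY ACCESSION"], ""),
            )
        )
    if n_skipped:
        logger.info("skipped %d unparseable association rows", n_skipped)
    if not out:
        raise EmptyInputError("no parseable association rows")
    return out


def qc_studies(associations, config: QcConfig = QcConfig()):
    """Apply the QC cascade and return one :class:`GwasStudy` per accession.

    Studies whose rows are entirely filtered away are returned with empty
    hit maps; callers decide how to treat them.
    """
    # (1) keep only the platform with the most SNPs passing QC per publication
    best: dict[str, int] = {}
    for a in associations:
        best[a.pubmed_id] = max(best.get(a.pubmed_id, -1), a.platform_snp_count)
    rows = [a for a in associations if a.platform_snp_count == best[a.pubmed_id]]

    reject_re = re.compile(config.rsid_reject)
    studies: dict[str, GwasStudy] = {}
    for a in associations:
        studies.setdefault(
            a.study_accession,
            GwasStudy(a.study_accession, a.trait, a.parent_term, a.ancestry),
        )

    for a in rows:
        # (2) whole-dataset p-values only; (3) compound rsIDs out;
        # (4) locus gene cap; (5) genome-wide significance; (7) ancestry
        if a.p_value_text:
            continue
        if reject_re.search(a.snp_id):
            continue
        genes = a.genes
        if len(genes) > config.max_genes_per_locus:
            continue
        if a.p_value > config.p_threshold:
            continue
        if a.ancestry not in config.ancestries:
            continue
        study = studies[a.study_accession]
        for g in genes:
            prev = study.hits.get(g)
            # (6) duplicate gene across loci -> keep the minimum p-value
            if prev is None or a.p_value < prev.p_value:
                study.hits[g] = Hit(a.p_value, a.chrom, a.position, a.snp_id)

    # studies whose every row fell to the ancestry filter are excluded entirely
    kept = {
        acc: s
        for acc, s in studies.items()
        if s.ancestry in config.ancestries
    }
    return list(kept.values())


def restrict_to_universe(studies, network):
    """Intersect each study's hits with the network's node set."""
    nodes = set(network.nodes)
    out = []
    for s in studies:
        hits = {g: h for g, h in s.hits.items() if g in nodes}
        out.append(
            replace_study(s, hits=hits, restricted_empty=(len(hits) == 0 and len(s.hits) > 0))
        )
    return out


def replace_study(study: GwasStudy, **kw) -> GwasStudy:
    d = dict(
        study_accession=study.study_accession,
        trait=study.trait,
        parent_term=study.parent_term,
        ancestry=study.ancestry,
        hits=dict(study.hits),
        restricted_empty=study.restricted_empty,
    )
    d.update(kw)
    return GwasStudy(**d)


def merge_parent_terms(studies, parent_term: str) -> ParentTermHitSet:
    """Pool hit sets of all studies annotated with ``parent_term``.

    Duplicate genes resolve to the minimum p-value across studies.
    """
    members = [s for s in studies if s.parent_term == parent_term]
    if not members:
        available = sorted({s.parent_term for s in studies if s.parent_term})
        raise ValueError(
            f"no studies carry parent term {parent_term!r}; available: {available}"
        )
    merged: dict[str, Hit] = {}
    for s in members:
        for g, h in s.hits.items():
            prev = merged.get(g)
            if prev is None or h.p_value < prev.p_value:
                merged[g] = h
    return ParentTermHitSet(
        parent_term=parent_term,
        study_accessions=tuple(s.study_accession for s in members),
        hits=merged,
    )


def studies_to_frame(studies) -> pd.DataFrame:
    """Tidy per-hit table (accession, trait, gene, p, chrom, pos, ancestry)."""
    rows = [
        (s.study_accession, s.trait, s.parent_term, s.ancestry, g,
         h.p_value, h.chrom, h.position, h.snp_id)
        for s in studies
        for g, h in sorted(s.hits.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["study_accession", "trait", "parent_term", "ancestry",
                 "gene", "p_value", "chrom", "position", "snp_id"],
    )


def frame_to_studies(df: pd.DataFrame):
    """Inverse of :func:`studies_to_frame`."""
    studies = []
    for acc, grp in df.groupby("study_accession", sort=False):
        first = grp.iloc[0]
        hits = {
            r.gene: Hit(float(r.p_value), str(r.chrom), int(r.position), str(r.snp_id))
            for r in grp.itertuples(index=False)
        }
        studies.append(
            GwasStudy(acc, first["trait"], first["parent_term"], first["ancestry"], hits)
        )
    return studies
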