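"""End-to-end orchestration: per-study, parent-term and custom-seed runs.

``run_full`` wires the stages together — network construction, catalog QC,
the excess-PPI permutation test, the per-node detection screen and gene
classification — and emits diff-able TSV tables plus a manifest recording
every seed and threshold, so identical configuration reproduces identical
outputs.  ``compare_interaction_types`` repeats the detection screen on
networks built from each interaction mode (and the coexpression channel)
restricted to a common node universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .excess_ppi import batch_excess
from .gwas_catalog import (
    GwasStudy,
    QcConfig,
    load_associations,
    merge_parent_terms,
    qc_studies,
    restrict_to_universe,
)
from .ppi_gene_detection import (
    DetectionConfig,
    classify_genes,
    detect_ppi_genes,
    detected_genes,
)
from .randomization import RandomizationConfig
from .string_network import build_network, read_string_tables, restrict_to_nodes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run (YAML-serializable)."""

    links: str
    actions: str
    aliases: str
    hgnc: str
    associations: str
    ancestry: str
    trait_map: str
    out_dir: str
    coordinates: str | None = None
    mode: str = "binding"
    score_min: int | None = None
    analysis: str = "per_study"  # per_study | parent_term | custom_seed_list
    parent_terms: list = field(default_factory=list)
    seed_list: list = field(default_factory=list)
    n_replicates: int = 50_000
    n_label_sweeps: int = 1000
    n_edge_swaps: int = 100_000
    base_seed: int = 0
    alpha: float = 0.05
    min_support: int = 2
    locus_window: int = 1_000_000
    excess_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def rand_config(self) -> RandomizationConfig:
        return RandomizationConfig(
            n_label_sweeps=self.n_label_sweeps,
            n_edge_swaps=self.n_edge_swaps,
            n_replicates=self.n_replicates,
            base_seed=self.base_seed,
        )

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(
            alpha=self.alpha,
            min_support=self.min_support,
            locus_window=self.locus_window,
        )


def results_to_frame(study_id, results) -> pd.DataFrame:
    rows = [
        {
            "study_accession": study_id,
            "gene": r.gene,
            "gene_class": r.gene_class,
            "degree": r.degree,
            "overlap_k": r.overlap,
            "raw_p": r.raw_p,
            "adjusted_p": r.adjusted_p,
            "detected": r.detected,
            "filter_reason": r.filter_reason,
            "supporting_hits": ",".join(r.supporting_seeds),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["study_accession", "gene", "gene_class", "degree", "overlap_k",
                 "raw_p", "adjusted_p", "detected", "filter_reason", "supporting_hits"],
    )


def run_full(config: RunConfig) -> dict:
    """Run the pipeline and write funnel/detections/classes tables + manifest.

    Returns the tables in-memory as a dict.  With ``n_replicates == 0`` the
    permutation stage is skipped (the detection screen does not need the
    ensemble); funnel columns that depend on it are then NA.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, mapper = read_string_tables(
        config.links, config.actions, config.aliases, config.hgnc
    )
    network = build_network(records, mapper, mode=config.mode, score_min=config.score_min)

    assoc = load_associations(config.associations, config.ancestry, config.trait_map)
    studies = restrict_to_universe(qc_studies(assoc, QcConfig()), network)

    if config.analysis == "parent_term":
        terms = config.parent_terms or sorted(
            {s.parent_term for s in studies if s.parent_term}
        )
        units = []
        for t in terms:
            merged = merge_parent_terms(studies, t)
            units.append(
                GwasStudy(study_accession=t, trait=t, parent_term=t, ancestry="",
                          hits=merged.hits)
            )
        studies = units

    coords = None
    if config.coordinates:
        from .robustness import GeneCoordinateTable

        table = GeneCoordinateTable.read_bed(config.coordinates)
        coords = table.snp_coordinates(studies)
        coords.update({g: c for g, c in table.midpoints().items() if g not in coords})

    # funnel gates, applied in order
    n_total = len(studies)
    ge2 = [s for s in studies if len(s.hits) >= 2]
    from .excess_ppi import count_edges_within

    ge1_edge = [s for s in ge2 if count_edges_within(network, set(s.hits)) >= 1]

    excess_df = None
    if config.n_replicates > 0:
        excess_df = batch_excess(network, ge1_edge, config.rand_config(),
                                 config.excess_threshold)
        excess_acc = set(excess_df.loc[excess_df["significant"], "study_accession"])
    else:
        excess_acc = None

    det_frames, class_rows = [], []
    detected_by_study = {}
    for s in studies:
        if not s.hits:
            continue
        results = detect_ppi_genes(network, set(s.hits), config.detection_config(), coords)
        classes = classify_genes(results, set(s.hits))
        detected_by_study[s.study_accession] = detected_genes(results)
        det_frames.append(results_to_frame(s.study_accession, results))
        for cls, genes in classes.items():
            for g in sorted(genes):
                class_rows.append(
                    {"study_accession": s.study_accession, "gene": g, "gene_class": cls}
                )

    detections = (
        pd.concat(det_frames, ignore_index=True) if det_frames
        else results_to_frame("", [])
    )
    classes_df = pd.DataFrame(class_rows, columns=["study_accession", "gene", "gene_class"])

    if excess_acc is None:
        n_excess, n_det_after_excess = pd.NA, pd.NA
    else:
        n_excess = len(excess_acc)
        n_det_after_excess = sum(
            1 for acc in excess_acc if detected_by_study.get(acc)
        )
    funnel = pd.DataFrame(
        [
            {
                "n_studies": n_total,
                "n_ge2_hits": len(ge2),
                "n_ge1_internal_edge": len(ge1_edge),
                "n_excess_ppi": n_excess,
                "n_excess_with_detections": n_det_after_excess,
                "n_with_detections": sum(1 for v in detected_by_study.values() if v),
            }
        ]
    )

    funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)
    detections.to_csv(out / "detections.tsv", sep="\t", index=False)
    classes_df.to_csv(out / "classes.tsv", sep="\t", index=False)
    if excess_df is not None:
        excess_df.to_csv(out / "excess.tsv", sep="\t", index=False)

    manifest = {
        "ppicore_version": __version__,
        "base_seed": config.base_seed,
        "n_replicates": config.n_replicates,
        "n_label_sweeps": config.n_label_sweeps,
        "n_edge_swaps": config.n_edge_swaps,
        "alpha": config.alpha,
        "min_support": config.min_support,
        "locus_window": config.locus_window,
        "excess_threshold": config.excess_threshold,
        "mode": config.mode,
        "score_min": config.score_min,
        "analysis": config.analysis,
        "n_network_nodes": network.number_of_nodes(),
        "n_network_edges": network.number_of_edges(),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return {
        "network": network,
        "studies": studies,
        "funnel": funnel,
        "detections": detections,
        "classes": classes_df,
        "excess": excess_df,
        "manifest": manifest,
    }


def compare_interaction_types(records, mapper, seed_set, modes,
                              universe_nodes=None,
                              annotation_sets=None,
                              marker_genes=(),
                              detection_config: DetectionConfig = DetectionConfig(),
                              coordinates=None) -> pd.DataFrame:
    """Detection-screen comparison across interaction-mode networks.

    Each mode's network is restricted to ``universe_nodes`` (typically the
    binding network's node set) before screening with ``seed_set``.  Reports
    per mode: node count, detection count, presence of each marker gene
    ("yes"/"no"/"not testable"), and an enrichment flag per annotation set
    (one-sided Fisher of detections vs the mode's universe, p < 0.05).
    """
    from .enrichment import overlap_row
    from .errors import EmptyNetworkError

    rows = []
    for mode in modes:
        row = {"mode": mode, "n_nodes": 0, "n_ppi_genes": 0}
        try:
            net = build_network(records, mapper, mode=mode)
            if universe_nodes is not None:
                net = restrict_to_nodes(net, universe_nodes)
        except EmptyNetworkError:
            for m in marker_genes:
                row[f"marker_{m}"] = "not testable"
            for name in (annotation_sets or {}):
                row[f"{name}_enriched"] = "not testable"
            row["empty_network"] = True
            rows.append(row)
            continue
        seeds = set(seed_set) & set(net.nodes)
        if seeds:
            results = detect_ppi_genes(net, seeds, detection_config, coordinates)
            detected = detected_genes(results)
        else:
            detected = set()
        row["n_nodes"] = net.number_of_nodes()
        row["n_ppi_genes"] = len(detected)
        for m in marker_genes:
            if m not in net.nodes:
                row[f"marker_{m}"] = "not testable"
            else:
                row[f"marker_{m}"] = "yes" if m in detected else "no"
        for name, ann in (annotation_sets or {}).items():
            rest = set(net.nodes) - detected
            if not detected:
                row[f"{name}_enriched"] = "not testable"
                continue
            r = overlap_row("detected", detected, "rest", rest, ann)
            row[f"{name}_enriched"] = (
                "enriched" if r["fisher_p"] < 0.05 and r["proportion_a"] > r["proportion_b"]
                else ""
            )
        row["empty_network"] = False
        rows.append(row)
    return pd.DataFrame(rows)
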