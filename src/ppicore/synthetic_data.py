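"""Seeded generators for every input the pipeline consumes.

Real runs require large third-party downloads (interaction tables, the GWAS
catalog, annotation databases).  This module fabricates structurally faithful
toy versions of all of them — interaction link/action/alias tables, an
approved-symbol table, catalog-format association/ancestry/trait-map TSVs,
gene coordinate BEDs, pathway GMTs — from explicit scenarios, so the full
pipeline runs and is validated offline.  Generators are pure functions of
(scenario, seed); planted signal (a core node rewired to touch q seed genes,
optionally a clique among seeds) is inserted with degree-preserving double
edge swaps so fixtures remain valid inputs for the randomization null.

Synthetic association p-values are drawn log-uniformly in [5e-30, 5e-8] so
every synthetic hit passes the genome-wide significance filter by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .gwas_catalog import ASSOC_COLUMNS, GwasStudy, Hit
from .robustness import GeneCoordinateTable

P_LOG_RANGE = (5e-30, 5e-8)

#: chromosome / spacing layout for synthetic gene coordinates
N_CHROMS = 22
GENE_LENGTH = 10_000
GENE_SPACING = 3_000_000  # distinct synthetic loci sit > 1 Mb apart


@dataclass(frozen=True)
class PlantedScenario:
    """A background network with optional planted excess-interaction signal.

    Either ``er_p`` (Erdős–Rényi edge probability) or ``degree_sequence``
    must be given.  ``n_seeds`` genes act as the seed (hit) set; one planted
    core node is rewired to have ``planted_overlap`` seed neighbors; a clique
    of ``clique_size`` seeds can additionally be wired together.
    """

    n_nodes: int
    er_p: float | None = None
    degree_sequence: tuple | None = None
    n_seeds: int = 15
    planted_overlap: int = 0
    clique_size: int = 0
    base_seed: int = 0

    def __post_init__(self):
        if (self.er_p is None) == (self.degree_sequence is None):
            raise ValueError("specify exactly one of er_p or degree_sequence")
        if self.planted_overlap > self.n_seeds:
            raise ValueError("planted_overlap cannot exceed n_seeds")


def gene_symbol(i: int) -> str:
    return f"G{i:04d}"


def generate_background(scenario: PlantedScenario) -> nx.Graph:
    """Simple background graph with symbol-named nodes, seeded."""
    if scenario.er_p is not None:
        g = nx.gnp_random_graph(scenario.n_nodes, scenario.er_p, seed=scenario.base_seed)
    else:
        seq = list(scenario.degree_sequence)
        if len(seq) != scenario.n_nodes:
            raise ValueError("degree_sequence length must equal n_nodes")
        if not nx.is_graphical(seq):
            raise ValueError(f"degree sequence {seq} is not graphical")
        g = nx.havel_hakimi_graph(seq)
        rng = np.random.default_rng(scenario.base_seed)
        nswap = 10 * max(g.number_of_edges(), 1)
        try:
            nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXError:
            pass  # tiny graphs can lack swappable edge pairs; realization stands
    # the universe is edge-defined (readers build networks from edge lists),
    # so isolated nodes would not round-trip and are dropped here
    g.remove_nodes_from(list(nx.isolates(g)))
    return nx.relabel_nodes(g, {i: gene_symbol(i) for i in g.nodes})


def _degree_preserving_add_edge(g: nx.Graph, u, v, rng, protected, max_tries=500) -> bool:
    """Add edge u-v without changing any degree, via one double swap.

    Removes u-x and v-y for suitable x, y and adds x-y; edges within
    ``protected`` (node set) are never removed.
    """
    if g.has_edge(u, v):
        return True
    xs = [x for x in g.neighbors(u) if x != v and x not in protected]
    ys = [y for y in g.neighbors(v) if y != u and y not in protected]
    rng.shuffle(xs)
    rng.shuffle(ys)
    tries = 0
    for x in xs:
        for y in ys:
            tries += 1
            if tries > max_tries:
                return False
            if x == y or g.has_edge(x, y):
                continue
            g.remove_edge(u, x)
            g.remove_edge(v, y)
            g.add_edge(u, v)
            g.add_edge(x, y)
            return True
    return False


def plant_signal(network: nx.Graph, scenario: PlantedScenario):
    """Insert the scenario's signal; returns (network copy, ground truth).

    Seeds are sampled uniformly; the planted node is a non-seed node of
    degree >= planted_overlap whose neighborhood is rewired (degree
    preserved everywhere) until it contains exactly ``planted_overlap``
    seeds.  Raises if rewiring cannot be completed in bounded attempts.
    """
    rng = np.random.default_rng(scenario.base_seed + 1)
    g = network.copy()
    nodes = sorted(g.nodes)
    seeds = set(rng.choice(nodes, size=scenario.n_seeds, replace=False))

    planted = None
    truth = {"seeds": seeds, "planted": None,
             "q": scenario.planted_overlap, "c": scenario.clique_size}
    if scenario.planted_overlap > 0:
        eligible = [v for v in nodes
                    if v not in seeds and g.degree(v) >= scenario.planted_overlap]
        if not eligible:
            raise ValueError("no non-seed node has degree >= planted_overlap")
        planted = eligible[int(rng.integers(len(eligible)))]
        protected = seeds | {planted}
        current = set(g.neighbors(planted)) & seeds
        targets = [s for s in sorted(seeds - current) if not g.has_edge(planted, s)]
        rng.shuffle(targets)
        attempts = 0
        for s in targets:
            if len(set(g.neighbors(planted)) & seeds) >= scenario.planted_overlap:
                break
            attempts += 1
            if not _degree_preserving_add_edge(g, planted, s, rng, protected):
                continue
        k = len(set(g.neighbors(planted)) & seeds)
        if k < scenario.planted_overlap:
            raise RuntimeError(
                f"planting failed after {attempts} attempts: overlap {k} < "
                f"{scenario.planted_overlap}"
            )
        truth["planted"] = planted

    if scenario.clique_size >= 2:
        members = sorted(seeds)[: scenario.clique_size]
        protected = seeds | ({planted} if planted else set())
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                _degree_preserving_add_edge(g, u, v, rng, protected)

    return g, truth


def coordinate_table(genes) -> GeneCoordinateTable:
    """Deterministic gene intervals: successive genes on rotating chromosomes,
    spaced so that genes sharing a chromosome sit several Mb apart."""
    rows = []
    for i, g in enumerate(sorted(genes)):
        chrom = str(i % N_CHROMS + 1)
        start = (i // N_CHROMS + 1) * GENE_SPACING
        rows.append((chrom, start, start + GENE_LENGTH, g))
    return GeneCoordinateTable(pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"]))


def synthetic_study(accession: str, genes, coords: GeneCoordinateTable, rng,
                    trait: str = "synthetic trait", parent_term: str = "Synthetic",
                    ancestry: str = "European", favored=()) -> GwasStudy:
    """A study whose hits are ``genes`` with log-uniform significant p-values.

    Genes in ``favored`` get their p-value shifted downward (multiplied by
    1e-6), for fixtures where detected hits should rank better.
    """
    lo, hi = np.log10(P_LOG_RANGE[0]), np.log10(P_LOG_RANGE[1])
    mid = coords.midpoints()
    hits = {}
    for g in sorted(genes):
        p = 10 ** rng.uniform(lo, hi)
        if g in favored:
            p *= 1e-6
        chrom, pos = mid[g]
        hits[g] = Hit(p_value=float(p), chrom=chrom, position=pos,
                      snp_id=f"rs{abs(hash(g)) % 10**7}")
    return GwasStudy(accession, trait, parent_term, ancestry, hits)


def _pid(symbol: str) -> str:
    return f"9606.ENSP_{symbol}"


def emit_fixture_files(network: nx.Graph, studies, out_dir, seed: int = 0,
                       extra_low_score_edges: int = 0,
                       extra_modes: dict | None = None) -> dict:
    """Write the full file set the pipeline readers consume.

    Produces STRING-style links/actions/aliases, an HGNC-style symbol table,
    catalog-style association/ancestry/trait-map TSVs and a BED coordinate
    file; returns a dict of paths.  Edges of ``network`` are emitted as mode
    "binding" with scores >= 700 (plus a coexpression score), so building the
    binding network at the default threshold round-trips exactly.  Optional
    decoy edges below threshold and extra mode layers can be added.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes)

    link_rows, action_rows = [], []
    for u, v in sorted(tuple(sorted(e)) for e in network.edges()):
        score = int(rng.integers(700, 1000))
        coexp = int(rng.integers(0, 1000))
        link_rows.append((_pid(u), _pid(v), score, coexp))
        action_rows.append((_pid(u), _pid(v), "binding"))

    non_edges = None
    if extra_low_score_edges:
        non_edges = [e for e in nx.non_edges(network)]
        idx = rng.choice(len(non_edges), size=min(extra_low_score_edges, len(non_edges)),
                         replace=False)
        for i in idx:
            u, v = sorted(non_edges[i])
            link_rows.append((_pid(u), _pid(v), int(rng.integers(150, 700)),
                              int(rng.integers(0, 1000))))
            action_rows.append((_pid(u), _pid(v), "binding"))

    if extra_modes:
        for mode, edges in extra_modes.items():
            for u, v in edges:
                u, v = sorted((u, v))
                link_rows.append((_pid(u), _pid(v), int(rng.integers(700, 1000)),
                                  int(rng.integers(0, 1000))))
                action_rows.append((_pid(u), _pid(v), mode))

    paths = {
        "links": out / "links.tsv",
        "actions": out / "actions.tsv",
        "aliases": out / "aliases.tsv",
        "hgnc": out / "hgnc.tsv",
        "associations": out / "associations.tsv",
        "ancestry": out / "ancestry.tsv",
        "trait_map": out / "trait_map.tsv",
        "bed": out / "genes.bed",
    }
    pd.DataFrame(link_rows, columns=["protein1", "protein2", "combined_score",
                                     "coexpression"]).to_csv(
        paths["links"], sep="\t", index=False)
    pd.DataFrame(action_rows, columns=["item_id_a", "item_id_b", "mode"]).to_csv(
        paths["actions"], sep="\t", index=False)
    pd.DataFrame({"protein_id": [_pid(g) for g in genes], "alias": genes}).to_csv(
        paths["aliases"], sep="\t", index=False)
    pd.DataFrame({"symbol": genes}).to_csv(paths["hgnc"], sep="\t", index=False)

    assoc_rows, anc_rows, tm_rows = [], {}, {}
    for j, s in enumerate(studies):
        anc_rows[s.study_accession] = s.ancestry
        tm_rows[s.trait] = s.parent_term
        for g, h in sorted(s.hits.items()):
            assoc_rows.append(
                {
                    "PUBMEDID": f"{90000000 + j}",
                    "STUDY ACCESSION": s.study_accession,
                    "DISEASE/TRAIT": s.trait,
                    "SNPS": h.snp_id,
                    "CHR_ID": h.chrom,
                    "CHR_POS": h.position,
                    "P-VALUE": repr(h.p_value),
                    "P-VALUE (TEXT)": "",
                    "PLATFORM [SNPS PASSING QC]": "ToyChip [500000]",
                    "REPORTED GENE(S)": g,
                    "MAPPED_GENE": g,
                }
            )
    pd.DataFrame(assoc_rows, columns=ASSOC_COLUMNS).to_csv(
        paths["associations"], sep="\t", index=False)
    pd.DataFrame(
        {"STUDY ACCESSION": list(anc_rows), "BROAD ANCESTRAL CATEGORY": list(anc_rows.values())}
    ).to_csv(paths["ancestry"], sep="\t", index=False)
    pd.DataFrame(
        {"Disease trait": list(tm_rows), "Parent term": list(tm_rows.values())}
    ).to_csv(paths["trait_map"], sep="\t", index=False)

    coordinate_table(genes).write_bed(paths["bed"])
    return paths


def violation_catalog(coords: GeneCoordinateTable | None = None):
    """Catalog tables with exactly one row violating each QC rule.

    Returns ``(assoc_df, ancestry_df, trait_map_df, expected)`` where
    ``expected`` maps study accession -> the hit genes that must survive QC.
    Clean rows use distinct genes G0000..; each violation is labelled by the
    gene it would (wrongly) contribute.
    """
    def row(pubmed, acc, gene, snp="rs1", p="1e-12", ptext="", platform="Chip [500000]",
            mapped=None, reported=None, chrom="1", pos=1000):
        return {
            "PUBMEDID": pubmed, "STUDY ACCESSION": acc, "DISEASE/TRAIT": "trait A",
            "SNPS": snp, "CHR_ID": chrom, "CHR_POS": pos, "P-VALUE": p,
            "P-VALUE (TEXT)": ptext, "PLATFORM [SNPS PASSING QC]": platform,
            "REPORTED GENE(S)": reported if reported is not None else gene,
            "MAPPED_GENE": mapped if mapped is not None else gene,
        }

    rows = [
        # clean hits that must survive
        row("p1", "GCST_A", "G0001", snp="rs10"),
        row("p1", "GCST_A", "G0002", snp="rs11"),
        # platform with fewer SNPs passing QC -> dropped
        row("p1", "GCST_A", "G0003", snp="rs12", platform="OldChip [100]"),
        # non-empty p-value qualifier -> dropped
        row("p1", "GCST_A", "G0004", snp="rs13", ptext="women"),
        # compound rsID -> dropped
        row("p1", "GCST_A", "G0005", snp="rs14x rs15"),
        # locus annotated with 3 genes -> dropped
        row("p1", "GCST_A", "G0006", snp="rs16", mapped="G0006, G0007, G0008"),
        # above genome-wide significance -> dropped
        row("p1", "GCST_A", "G0009", snp="rs17", p="6e-8"),
        # duplicate gene at two loci -> collapses to the smaller p
        row("p1", "GCST_A", "G0002", snp="rs18", p="1e-20", pos=5000),
        # disallowed ancestry -> whole study dropped
        row("p2", "GCST_B", "G0010", snp="rs19"),
    ]
    assoc = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    ancestry = pd.DataFrame(
        {
            "STUDY ACCESSION": ["GCST_A", "GCST_B"],
            "BROAD ANCESTRAL CATEGORY": ["European", "Founder or isolated population"],
        }
    )
    trait_map = pd.DataFrame({"Disease trait": ["trait A"], "Parent term": ["Synthetic"]})
    expected = {"GCST_A": {"G0001": 1e-12, "G0002": 1e-20}}
    return assoc, ancestry, trait_map, expected
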