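"""Build filtered protein-protein interaction networks from STRING-format tables.

The STRING database distributes scored protein links, an "actions" table
labelling each link with interaction modes (binding, reaction, catalysis,
activation, inhibition, ptmod, expression), and an alias table mapping its
internal protein identifiers to gene symbols.  This module parses those
tables, maps identifiers onto approved HGNC gene symbols, and constructs
undirected simple graphs restricted to one interaction mode at a high
confidence threshold (combined score >= 700 by convention), or alternatively
from the coexpression score column with no score filter.

Networks are plain :class:`networkx.Graph` objects over gene symbols; the
node set defines the universe ``N`` for all downstream enrichment tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import EmptyInputError, EmptyNetworkError, FormatError

logger = logging.getLogger(__name__)

#: Interaction mode labels carried by the STRING actions table.
MODE_LABELS = frozenset(
    {"binding", "reaction", "catalysis", "activation", "inhibition", "ptmod", "expression"}
)

#: Conventional high-confidence combined-score cutoff.
DEFAULT_SCORE_MIN = 700


@dataclass(frozen=True)
class InteractionRecord:
    """One symmetrized protein pair with its score(s) and interaction modes.

    ``protein_a``/``protein_b`` are raw STRING identifiers in sorted order;
    ``combined_score`` is STRING's integer confidence (0-999, the maximum
    over duplicate rows for the pair); ``coexpression`` is the coexpression
    channel score (0 when the links file has no such column).
    """

    protein_a: str
    protein_b: str
    combined_score: int
    modes: frozenset = field(default_factory=frozenset)
    coexpression: int = 0

    def __post_init__(self):
        if not 0 <= self.combined_score <= 999:
            raise ValueError(f"combined_score {self.combined_score} outside [0, 999]")


@dataclass
class GeneIdMapper:
    """Many-to-one map from raw STRING protein identifiers to approved symbols.

    Assembled from a STRING alias table joined against an HGNC approved-symbol
    list: a protein identifier maps to the first of its aliases that is an
    approved symbol.  Identifiers with no approved alias are reported via
    :attr:`unmapped`, never silently retained.
    """

    alias_to_symbol: dict
    unmapped: set = field(default_factory=set)

    def map(self, raw_id: str):
        """Return the approved symbol for ``raw_id``, or None if unmappable."""
        sym = self.alias_to_symbol.get(raw_id)
        if sym is None:
            self.unmapped.add(raw_id)
        return sym


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    degree_table: pd.DataFrame
    mean_clustering: float


def _read_tsv(path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{label} file {path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{label} file {path} has no data rows")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{label} file {path} is missing required column {col!r}")
    return df


def read_string_tables(links_path, actions_path, aliases_path, hgnc_path):
    """Parse STRING links/actions/aliases plus an HGNC table.

    Returns ``(records, mapper)`` where ``records`` is a list of symmetrized
    :class:`InteractionRecord` (unordered pairs deduplicated, max score and
    mode-set union over duplicate rows) and ``mapper`` a :class:`GeneIdMapper`.

    Expected layouts (tab-separated, headered): links with ``protein1``,
    ``protein2``, ``combined_score`` and optionally ``coexpression``; actions
    with ``item_id_a``, ``item_id_b``, ``mode``; aliases with ``protein_id``,
    ``alias``; HGNC with ``symbol``.
    """
    links = _read_tsv(links_path, ["protein1", "protein2", "combined_score"], "links")
    actions = _read_tsv(actions_path, ["item_id_a", "item_id_b", "mode"], "actions")
    aliases = _read_tsv(aliases_path, ["protein_id", "alias"], "aliases")
    hgnc = _read_tsv(hgnc_path, ["symbol"], "HGNC")

    approved = set(hgnc["symbol"].dropna())
    alias_to_symbol: dict[str, str] = {}
    unmapped: set[str] = set()
    for pid, grp in aliases.groupby("protein_id", sort=False):
        hits = [a for a in grp["alias"] if a in approved]
        if hits:
            alias_to_symbol[pid] = hits[0]
        else:
            unmapped.add(pid)
    mapper = GeneIdMapper(alias_to_symbol=alias_to_symbol, unmapped=unmapped)

    # mode sets per unordered raw-id pair
    modes: dict[tuple, set] = {}
    bad_modes = 0
    for a, b, m in actions[["item_id_a", "item_id_b", "mode"]].itertuples(index=False):
        if m not in MODE_LABELS:
            bad_modes += 1
            continue
        modes.setdefault(tuple(sorted((a, b))), set()).add(m)

    has_coexp = "coexpression" in links.columns
    merged: dict[tuple, list] = {}  # pair -> [score, coexpression]
    n_dupes = 0
    for row in links.itertuples(index=False):
        pair = tuple(sorted((row.protein1, row.protein2)))
        score = int(row.combined_score)
        coexp = int(row.coexpression) if has_coexp else 0
        if pair in merged:
            n_dupes += 1
            merged[pair][0] = max(merged[pair][0], score)
            merged[pair][1] = max(merged[pair][1], coexp)
        else:
            merged[pair] = [score, coexp]

    records = [
        InteractionRecord(
            protein_a=a,
            protein_b=b,
            combined_score=sc,
            modes=frozenset(modes.get((a, b), set())),
            coexpression=cx,
        )
        for (a, b), (sc, cx) in merged.items()
    ]
    logger.info(
        "parsed %d link rows -> %d unique pairs (%d duplicates merged, "
        "%d action rows with unknown mode dropped, %d protein ids unmappable)",
        len(links), len(records), n_dupes, bad_modes, len(unmapped),
    )
    return records, mapper


def build_network(records, mapper, mode="binding", score_min=None) -> nx.Graph:
    """Build the undirected symbol-level network for one interaction mode.

    Keeps records whose mode set contains ``mode`` and whose combined score is
    at least ``score_min`` (inclusive; defaults to 700).  For
    ``mode="coexpression"`` the score is read from the coexpression column
    instead and ``score_min`` defaults to 1, i.e. any nonzero coexpression
    evidence qualifies.  Identifiers that cannot be mapped to an approved
    symbol are dropped (counted); pairs whose two identifiers collapse onto
    one symbol are dropped as self-loops.
    """
    if mode != "coexpression" and mode not in MODE_LABELS:
        raise ValueError(f"unknown interaction mode {mode!r}")
    if score_min is None:
        score_min = 1 if mode == "coexpression" else DEFAULT_SCORE_MIN
    if not 0 <= score_min <= 999:
        raise ValueError(f"score_min {score_min} outside [0, 999]")

    g = nx.Graph()
    n_unmapped = n_selfloop = 0
    for rec in records:
        score = rec.coexpression if mode == "coexpression" else rec.combined_score
        if score < score_min:
            continue
        if mode != "coexpression" and mode not in rec.modes:
            continue
        a = mapper.map(rec.protein_a)
        b = mapper.map(rec.protein_b)
        if a is None or b is None:
            n_unmapped += 1
            continue
        if a == b:
            n_selfloop += 1
            continue
        g.add_edge(a, b)
    if n_unmapped:
        logger.warning("%d surviving records dropped for unmappable identifiers", n_unmapped)
    if n_selfloop:
        logger.warning("%d records collapsed to self-loops and were dropped", n_selfloop)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no edges survive mode={mode!r} at score_min={score_min}"
        )
    logger.info(
        "built %s network: %d nodes, %d edges", mode, g.number_of_nodes(), g.number_of_edges()
    )
    return g


def restrict_to_nodes(network: nx.Graph, node_list) -> nx.Graph:
    """Induced subgraph on ``node_list`` (intersection with the network)."""
    nodes = set(node_list)
    if not nodes:
        raise ValueError("node_list is empty")
    keep = nodes & set(network.nodes)
    if not keep:
        raise EmptyNetworkError("no requested nodes are present in the network")
    return nx.Graph(network.subgraph(keep))


def network_summary(network: nx.Graph) -> NetworkSummary:
    """Node/edge counts, per-node degrees, and mean local clustering.

    The clustering coefficient is the mean over all nodes of the local
    clustering coefficient, with nodes of degree < 2 contributing 0.
    """
    if network.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot summarize an empty network")
    degree_table = pd.DataFrame(
        sorted(network.degree()), columns=["gene", "degree"]
    )
    return NetworkSummary(
        n_nodes=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        degree_table=degree_table,
        mean_clustering=nx.average_clustering(network),
    )


def write_edge_list(network: nx.Graph, path) -> None:
    """Write the network as a two-column TSV of sorted symbol pairs."""
    rows = sorted(tuple(sorted(e)) for e in network.edges())
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> nx.Graph:
    """Read a two-column edge TSV produced by :func:`write_edge_list`."""
    df = _read_tsv(path, ["gene_a", "gene_b"], "edge list")
    g = nx.Graph()
    g.add_edges_from(df[["gene_a", "gene_b"]].itertuples(index=False, name=None))
    return g
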