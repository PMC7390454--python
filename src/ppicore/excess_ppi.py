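"""Test a gene set for excess internal PPI edges against the randomized null.

The observed number of edges with both endpoints in the set (GWAS hits of one
study, merged parent-term hits, or somatically mutated genes) is compared to
its distribution across degree-preserving randomized networks.  The empirical
p-value uses the add-one convention p = (r + 1) / (B + 1), where r is the
number of replicates with at least the observed count, so p is never zero and
the minimum attainable value is 1 / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ppi_gene_detection import bh_adjust
from .randomization import RandomizationConfig, null_edge_counts

DEFAULT_THRESHOLD = 0.05


@dataclass
class EmpiricalNullResult:
    """Outcome of one excess-PPI permutation test."""

    observed_count: int
    null_counts: np.ndarray
    empirical_p: float
    n_replicates: int
    significant: bool
    testable: bool = True
    reason: str = ""

    @classmethod
    def untestable(cls, observed: int, reason: str) -> "EmpiricalNullResult":
        return cls(
            observed_count=observed,
            null_counts=np.empty(0, dtype=np.int64),
            empirical_p=float("nan"),
            n_replicates=0,
            significant=False,
            testable=False,
            reason=reason,
        )


def count_edges_within(network, gene_set) -> int:
    """Number of network edges with both endpoints in ``gene_set``."""
    genes = set(gene_set) & set(network.nodes)
    if len(genes) < len(set(gene_set)):
        logging.getLogger(__name__).warning(
            "%d gene_set members absent from network were ignored",
            len(set(gene_set)) - len(genes),
        )
    return sum(1 for u, v in network.edges() if u in genes and v in genes)


def excess_ppi_test(
    network,
    gene_set,
    rand_config: RandomizationConfig,
    threshold: float = DEFAULT_THRESHOLD,
) -> EmpiricalNullResult:
    """Permutation test for excess edges within ``gene_set``.

    Sets with fewer than 2 members, or with zero observed internal edges, are
    returned with an untestable status (they carry no signal the null could
    be compared against) rather than raising, so batch runs can tabulate the
    tested/untestable funnel.
    """
    genes = set(gene_set) & set(network.nodes)
    observed = count_edges_within(network, genes)
    if len(genes) < 2:
        return EmpiricalNullResult.untestable(observed, "fewer than 2 genes in network")
    if observed < 1:
        return EmpiricalNullResult.untestable(observed, "no internal edges observed")
    null = null_edge_counts(network, genes, rand_config)
    r = int(np.sum(null >= observed))
    p = (r + 1) / (len(null) + 1)
    return EmpiricalNullResult(
        observed_count=observed,
        null_counts=null,
        empirical_p=p,
        n_replicates=len(null),
        significant=p < threshold,
    )


def batch_excess(
    network,
    studies,
    rand_config: RandomizationConfig,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Run :func:`excess_ppi_test` over many studies.

    One row per study: hit count, observed internal edges, empirical p,
    testable and significant flags, plus a BH-adjusted column across the
    testable studies.
    """
    rows = []
    for s in studies:
        res = excess_ppi_test(network, set(s.hits), rand_config, threshold)
        rows.append(
            {
                "study_accession": s.study_accession,
                "n_hits": len(set(s.hits) & set(network.nodes)),
                "observed_edges": res.observed_count,
                "empirical_p": res.empirical_p,
                "testable": res.testable,
                "significant": res.significant,
                "reason": res.reason,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "study_accession", "n_hits", "observed_edges",
            "empirical_p", "testable", "significant", "reason",
        ],
    )
    df["bh_adjusted_p"] = np.nan
    if len(df) and df["testable"].any():
        mask = df["testable"].to_numpy()
        df.loc[mask, "bh_adjusted_p"] = bh_adjust(df.loc[mask, "empirical_p"].to_numpy())
    return df
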