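"""Hypergeometric over-representation analysis of gene sets.

For a query of ``n`` genes drawn from a measured background of ``N`` genes,
``K`` of which carry a term, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution — the chance of seeing at
least the observed overlap ``k`` by random sampling. The background is the
set of genes on the array (the measured universe), and significance is
declared on the raw p-value below alpha by default, with an optional
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSet, PipelineConfig
from .detest import fdr_adjust

logger = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "term_id",
    "term_name",
    "N",
    "K",
    "n",
    "k",
    "p_value",
    "adjusted_p",
    "enriched",
)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed in log space (scipy survival function), stable for N up to
    at least 1e5. Bounds: K <= N, n <= N, k <= min(K, n).
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N (N={N}, K={K}, n={n})")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_sets(
    query: set[str] | frozenset[str],
    gene_sets: dict[str, GeneSet],
    background: set[str] | frozenset[str],
    config: PipelineConfig,
    allow_empty_query: bool = True,
) -> pd.DataFrame:
    """One hypergeometric record per term, sorted by p-value.

    Every term is intersected with the background before testing; terms
    with no background gene are dropped (with a log line). Query genes
    must be a subset of the background.
    """
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query genes absent from background: {stray[:10]}")
    if not query:
        if allow_empty_query:
            return pd.DataFrame(columns=list(RECORD_COLUMNS))
        raise ValueError("empty query")

    N, n = len(background), len(query)
    rows = []
    for term_id in gene_sets:
        gs = gene_sets[term_id]
        term_genes = set(gs.genes) & background
        K = len(term_genes)
        if K == 0:
            logger.info("term %s has no background genes; dropped", term_id)
            continue
        k = len(term_genes & query)
        p = hypergeometric_tail(N, K, n, k)
        rows.append(
            {
                "term_id": term_id,
                "term_name": gs.description,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows, columns=list(RECORD_COLUMNS[:-2]))
    if len(table):
        table["adjusted_p"] = fdr_adjust(table["p_value"].to_numpy())
        basis = table["adjusted_p"] if config.enrichment_adjust else table["p_value"]
        table["enriched"] = basis < config.enrichment_alpha
        table = table.sort_values(
            ["p_value", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["adjusted_p"] = np.array([], dtype=float)
        table["enriched"] = np.array([], dtype=bool)
    return table
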