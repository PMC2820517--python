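"""Genome-wide Granger causal network construction.

All ordered gene pairs of a re-referenced panel are tested, p-values are
corrected for multiple testing (Bonferroni by default, Benjamini-Hochberg
optionally; BH q-values are always reported alongside as the FDR
estimate), and the thresholded network is pruned so every gene keeps at
most its single most significant incoming link — a bivariate-model scan
tends to infer indirect links, and keeping the strongest incoming edge
per target removes most of them. Regulators are ranked by out-degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .granger import InsufficientDataError, granger_test
from .preprocess import ExpressionPanel, stack_lagged_rows

logger = logging.getLogger(__name__)

__all__ = ["CausalNetwork", "scan_all_pairs", "adjust_and_threshold",
           "prune_incoming", "rank_regulators", "out_degree_distribution"]

EDGE_COLUMNS = ["source", "target", "n_rows", "f_stat", "df2", "p_raw", "status"]


@dataclass
class CausalNetwork:
    """Directed edge table with multiplicity-corrected significance.

    ``edges`` carries (source, target, p_raw, p_adjusted, q_value) plus
    bootstrap ``confidence`` once computed; after pruning every target
    has in-degree <= 1.
    """

    edges: pd.DataFrame
    genes: list[str]
    alpha: float
    correction: str
    pruned: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def scan_all_pairs(panel: ExpressionPanel) -> pd.DataFrame:
    """Granger-test every ordered gene pair of a re-referenced panel.

    Returns a table with one row per ordered pair (p*(p-1) rows for p
    genes). Pairs that cannot be tested are kept as rows with a reason
    code in ``status`` and p_raw = NaN.
    """
    if panel.n_genes < 2:
        raise ValueError("need at least 2 genes to scan")
    rows = []
    for src in panel.gene_ids:
        for tgt in panel.gene_ids:
            if src == tgt:
                continue
            design = stack_lagged_rows(panel, src, tgt)
            try:
                res = granger_test(design)
            except InsufficientDataError:
                rows.append((src, tgt, design.n_rows, np.nan, np.nan,
                             np.nan, "insufficient-data"))
                continue
            status = "ok"
            if res.collinear:
                status = "collinear"
            elif res.degenerate:
                status = "degenerate"
            rows.append((src, tgt, res.n_rows, res.f_stat, res.df2,
                         res.p_value, status))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def adjust_and_threshold(edge_table: pd.DataFrame,
                         method: str = "bonferroni",
                         alpha: float = 0.01) -> CausalNetwork:
    """Correct scan p-values and keep edges with adjusted p below alpha.

    ``method`` is ``bonferroni`` or ``bh``; BH q-values are reported for
    every tested pair regardless of the thresholding method.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction method: {method!r}")
    genes = sorted(set(edge_table["source"]) | set(edge_table["target"])) \
        if len(edge_table) else []
    tested = edge_table[edge_table["p_raw"].notna()].copy()
    if len(tested) == 0:
        empty = tested.assign(p_adjusted=np.nan, q_value=np.nan)
        return CausalNetwork(edges=empty, genes=genes, alpha=alpha,
                             correction=method)
    p = tested["p_raw"].to_numpy()
    bonf = np.minimum(p * len(p), 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    tested["p_adjusted"] = bonf if method == "bonferroni" else q
    tested["q_value"] = q
    kept = tested[tested["p_adjusted"] < alpha].reset_index(drop=True)
    return CausalNetwork(edges=kept, genes=genes, alpha=alpha,
                         correction=method,
                         metadata={"n_tested": int(len(tested))})


def prune_incoming(network: CausalNetwork) -> CausalNetwork:
    """Keep, per target gene, only the most significant incoming edge.

    The edge with the smallest raw p wins; exact ties break by
    lexicographic source id (logged).
    """
    edges = network.edges
    if len(edges) == 0:
        return CausalNetwork(edges=edges.copy(), genes=network.genes,
                             alpha=network.alpha, correction=network.correction,
                             pruned=True, metadata=dict(network.metadata))
    ordered = edges.sort_values(["target", "p_raw", "source"],
                                kind="mergesort")
    ties = ordered.duplicated(subset=["target", "p_raw"], keep=False)
    if ties.any():
        logger.info("p-value ties at %d target(s); broken by source id",
                    ordered.loc[ties, "target"].nunique())
    pruned = ordered.drop_duplicates(subset="target", keep="first")
    pruned = pruned.sort_index().reset_index(drop=True)
    return CausalNetwork(edges=pruned, genes=network.genes,
                         alpha=network.alpha, correction=network.correction,
                         pruned=True, metadata=dict(network.metadata))


def rank_regulators(network: CausalNetwork) -> pd.DataFrame:
    """Rank causal regulators by the number of genes they drive.

    Returns (gene, out_degree) sorted by descending out-degree, ties by
    gene id; genes with zero out-degree are excluded.
    """
    counts = network.edges.groupby("source").size()
    table = (counts.rename("out_degree").reset_index()
             .rename(columns={"source": "gene"}))
    table = table.sort_values(["out_degree", "gene"],
                              ascending=[False, True], kind="mergesort")
    return table.reset_index(drop=True)


def out_degree_distribution(network: CausalNetwork) -> pd.DataFrame:
    """Histogram of out-degrees over the whole gene universe.

    Zero-degree genes are counted, so histogram counts sum to the number
    of genes.
    """
    counts = network.edges.groupby("source").size()
    degrees = pd.Series(0, index=pd.Index(network.genes, name="gene"))
    degrees.loc[counts.index] = counts
    hist = degrees.value_counts().sort_index()
    return (hist.rename_axis("out_degree").rename("n_genes").reset_index())
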