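"""TSV readers and writers for panels, sample sheets and edge lists.

On-disk formats:

* expression matrix — TSV, genes as rows (index column ``gene_id``),
  samples as columns;
* sample sheet — TSV with columns sample_id, individual_id, timepoint,
  arm; every (individual, timepoint) cell must be present exactly once;
* edge lists — TSV with a header; SIF export uses the interaction type
  ``granger``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dbn import TwoSliceNetwork
from .netscan import CausalNetwork
from .preprocess import ExpressionPanel
from .simulate import GroundTruthPanel

logger = logging.getLogger(__name__)

__all__ = ["write_panel", "read_panel", "write_edges", "write_sif",
           "read_intra_edges", "write_truth", "write_consensus"]


def write_panel(panel: ExpressionPanel, matrix_path, samples_path) -> None:
    """Write a panel as an expression matrix plus its sample sheet."""
    sample_ids, rows = [], []
    for i, ind in enumerate(panel.individual_ids):
        for t_pos, t in enumerate(panel.timepoints):
            sid = f"{ind}_t{int(t)}"
            sample_ids.append((sid, i, t_pos))
            rows.append((sid, ind, int(t), panel.arm))
    mat = pd.DataFrame(
        {sid: panel.values[:, i, t_pos] for sid, i, t_pos in sample_ids},
        index=pd.Index(panel.gene_ids, name="gene_id"),
    )
    mat.to_csv(matrix_path, sep="\t")
    pd.DataFrame(rows, columns=["sample_id", "individual_id",
                                "timepoint", "arm"]
                 ).to_csv(samples_path, sep="\t", index=False)


def read_panel(matrix_path, samples_path,
               log2_transform: bool = False) -> ExpressionPanel:
    """Load an expression matrix plus sample sheet into a panel.

    Input is assumed already log-scale; ``log2_transform`` applies log2
    on load for linear-scale matrices. Individuals with an incomplete
    timepoint grid are dropped with a warning; an individual missing
    timepoint 0 is an error since baseline referencing needs it.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    required = {"sample_id", "individual_id", "timepoint", "arm"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing_cols)}")
    unknown = set(sheet["sample_id"]) - set(mat.columns)
    if unknown:
        raise ValueError(f"sample ids missing from matrix: {sorted(unknown)[:5]}")
    dup = sheet.duplicated(subset=["individual_id", "timepoint"])
    if dup.any():
        bad = sheet.loc[dup, ["individual_id", "timepoint"]].iloc[0]
        raise ValueError("duplicate (individual, timepoint): "
                         f"{tuple(bad)}")

    timepoints = np.array(sorted(sheet["timepoint"].unique()), dtype=int)
    individuals = []
    for ind, grp in sheet.groupby("individual_id", sort=True):
        have = set(grp["timepoint"])
        if 0 not in have and 0 in timepoints:
            raise ValueError(f"individual {ind!r} lacks timepoint 0 "
                             "(required for baseline referencing)")
        if have != set(timepoints.tolist()):
            logger.warning("dropping individual %r: observed timepoints %s "
                           "do not cover %s", ind, sorted(have),
                           timepoints.tolist())
            continue
        individuals.append(ind)
    if not individuals:
        raise ValueError("no individual has a complete timepoint grid")

    arms = sheet[sheet["individual_id"].isin(individuals)]["arm"].unique()
    arm = arms[0] if len(arms) == 1 else "mixed"
    lookup = sheet.set_index(["individual_id", "timepoint"])["sample_id"]
    values = np.empty((mat.shape[0], len(individuals), len(timepoints)))
    for i, ind in enumerate(individuals):
        for k, t in enumerate(timepoints):
            col = lookup.loc[(ind, t)]
            values[:, i, k] = mat[col].to_numpy()
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    if log2_transform:
        values = np.log2(values)
    return ExpressionPanel(values=values, gene_ids=list(mat.index),
                           individual_ids=list(individuals),
                           timepoints=timepoints, arm=str(arm))


def write_edges(network: CausalNetwork, path) -> None:
    cols = ["source", "target", "p_raw", "p_adjusted", "q_value"]
    if "confidence" in network.edges.columns:
        cols.append("confidence")
    network.edges[cols].to_csv(path, sep="\t", index=False)


def write_sif(network: CausalNetwork, path) -> None:
    with open(path, "w") as fh:
        for row in network.edges.itertuples():
            fh.write(f"{row.source}\tgranger\t{row.target}\n")


def read_intra_edges(path, genes: list[str]) -> TwoSliceNetwork:
    """Load an intra-slice network from a (parent, child) TSV edge list."""
    table = pd.read_csv(path, sep="\t")
    if not {"parent", "child"} <= set(table.columns):
        raise ValueError("intra-slice edge list needs columns parent, child")
    edges = frozenset(zip(table["parent"], table["child"]))
    return TwoSliceNetwork(genes=genes, intra_edges=edges)


def write_truth(truth: GroundTruthPanel, path) -> None:
    rows = [(p, c, "intra", truth.coefficients[(p, c)])
            for p, c in sorted(truth.true_intra_edges)]
    rows += [(p, c, "inter", truth.coefficients[(p, c)])
             for p, c in sorted(truth.true_inter_edges)]
    pd.DataFrame(rows, columns=["parent", "child", "slice", "coefficient"]
                 ).to_csv(path, sep="\t", index=False)


def write_consensus(net: TwoSliceNetwork, path) -> None:
    freqs = net.frequencies or {}
    rows = [(p, c, "intra", "") for p, c in sorted(net.intra_edges)]
    rows += [(p, c, "inter", f"{freqs.get((p, c), 1.0):.6g}")
             for p, c in sorted(net.inter_edges)]
    pd.DataFrame(rows, columns=["parent", "child", "slice", "frequency"]
                 ).to_csv(path, sep="\t", index=False)
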