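"""Per-link confidence by bootstrapping individuals.

The sampling unit is the individual: each replicate draws N individuals
with replacement (a duplicated individual contributes its full series,
hence duplicate pooled rows), re-runs the all-pairs scan and multiple-
testing threshold, and a link scores a success when its adjusted p passes
the corrected cutoff in that replicate. Confidence = successes / B.

The confidence is the fraction of replicates in which a link is
*significant* — its corrected p-value falls below the threshold. This is
the only reading consistent with high confidence marking well-supported
links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netscan import CausalNetwork, adjust_and_threshold, scan_all_pairs
from .preprocess import ExpressionPanel

__all__ = ["BootstrapReport", "bootstrap_confidence", "resample_individuals"]


@dataclass
class BootstrapReport:
    """Per-edge bootstrap support for a point-estimate network."""

    B: int
    confidence: pd.DataFrame        # (source, target, confidence)
    replicate_seeds: list[int]
    point_network: CausalNetwork

    def network_with_confidence(self) -> CausalNetwork:
        """The point-estimate network with a ``confidence`` column merged in."""
        edges = self.point_network.edges.merge(
            self.confidence, on=["source", "target"], how="left")
        return CausalNetwork(
            edges=edges, genes=self.point_network.genes,
            alpha=self.point_network.alpha,
            correction=self.point_network.correction,
            pruned=self.point_network.pruned,
            metadata=dict(self.point_network.metadata),
        )


def resample_individuals(panel: ExpressionPanel,
                         rng: np.random.Generator) -> ExpressionPanel:
    """Draw N individuals with replacement, keeping full series together."""
    n = panel.n_individuals
    idx = rng.integers(0, n, size=n)
    return ExpressionPanel(
        values=panel.values[:, idx, :],
        gene_ids=list(panel.gene_ids),
        individual_ids=[f"bs{k:03d}" for k in range(n)],
        timepoints=panel.timepoints.copy(),
        arm=panel.arm,
    )


def bootstrap_confidence(panel: ExpressionPanel, B: int = 100,
                         alpha: float = 0.01, seed: int = 0,
                         correction: str = "bonferroni") -> BootstrapReport:
    """Bootstrap link confidence over B individual-resampling replicates.

    ``panel`` must already be baseline re-referenced. Confidence is
    defined for every edge of the point-estimate (thresholded, unpruned)
    network; significance is scored before pruning within each replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if panel.n_individuals < 2:
        raise ValueError("need at least 2 individuals to resample")
    point = adjust_and_threshold(scan_all_pairs(panel),
                                 method=correction, alpha=alpha)
    edge_keys = list(zip(point.edges["source"], point.edges["target"]))
    successes = {k: 0 for k in edge_keys}

    ss = np.random.SeedSequence(seed)
    replicate_seeds = [int(s) % (2**31 - 1)
                       for s in ss.generate_state(B).tolist()]
    for b in range(B):
        rng = np.random.default_rng(replicate_seeds[b])
        rep_panel = resample_individuals(panel, rng)
        rep_net = adjust_and_threshold(scan_all_pairs(rep_panel),
                                       method=correction, alpha=alpha)
        rep_edges = set(zip(rep_net.edges["source"], rep_net.edges["target"]))
        for k in edge_keys:
            if k in rep_edges:
                successes[k] += 1

    confidence = pd.DataFrame(
        [(s, t, successes[(s, t)] / B) for (s, t) in edge_keys],
        columns=["source", "target", "confidence"],
    )
    return BootstrapReport(B=B, confidence=confidence,
                           replicate_seeds=replicate_seeds,
                           point_network=point)
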