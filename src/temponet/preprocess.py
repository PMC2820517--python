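"""Expression-panel container, baseline re-referencing and lagged stacking.

A panel holds log-scale expression values indexed by (gene, individual,
timepoint). Individual-specific scale differences are removed by
referencing each individual's profile to its own time-0 profile
(subtraction on the log scale); the pooled Granger test then stacks
lagged regression rows across individuals so that many short series act
as one virtual long series under shared coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ExpressionPanel", "LaggedDesign",
           "reference_to_baseline", "stack_lagged_rows"]


@dataclass
class ExpressionPanel:
    """Log-scale expression tensor with gene/individual/timepoint labels.

    ``values`` has shape (n_genes, n_individuals, n_timepoints);
    timepoints are strictly increasing integer indices. Missing values are
    not permitted: loaders must reject incomplete individuals explicitly.
    """

    values: np.ndarray
    gene_ids: list[str]
    individual_ids: list[str]
    timepoints: np.ndarray
    arm: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=int)
        ng, ni, nt = self.values.shape
        if ng != len(self.gene_ids) or ni != len(self.individual_ids) \
                or nt != len(self.timepoints):
            raise ValueError("values shape does not match labels")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("duplicate gene ids")
        if len(set(self.individual_ids)) != ni:
            raise ValueError("duplicate individual ids")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("panel contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None


@dataclass
class LaggedDesign:
    """Stacked lag-1 regression rows (y_t, y_{t-1}, x_{t-1}).

    Rows never span two individuals; for N individuals observed at L
    timepoints each, the design has N*(L-1) rows. ``individual_idx`` and
    ``t_index`` record each row's provenance.
    """

    y: np.ndarray
    y_lag: np.ndarray
    x_lag: np.ndarray
    individual_idx: np.ndarray
    t_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.y)
        for arr in (self.y_lag, self.x_lag, self.individual_idx, self.t_index):
            if len(arr) != n:
                raise ValueError("all row arrays must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.y)


def reference_to_baseline(panel: ExpressionPanel) -> ExpressionPanel:
    """Subtract each individual's time-0 profile and drop time 0.

    value(g, i, t) becomes value(g, i, t) - value(g, i, 0) for t >= 1, so
    an L-timepoint panel becomes an (L-1)-timepoint panel of deviations
    from the individual's own baseline.
    """
    if panel.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints to re-reference")
    referenced = panel.values[:, :, 1:] - panel.values[:, :, :1]
    return ExpressionPanel(
        values=referenced,
        gene_ids=list(panel.gene_ids),
        individual_ids=list(panel.individual_ids),
        timepoints=panel.timepoints[1:],
        arm=panel.arm,
    )


def stack_lagged_rows(panel: ExpressionPanel, source_gene: str,
                      target_gene: str) -> LaggedDesign:
    """Pool lag-1 rows for an ordered (source -> target) gene pair.

    For every individual and every consecutive timepoint pair (t-1, t)
    the row (target_t, target_{t-1}, source_{t-1}) is emitted. Rows are
    grouped by individual, so no row mixes two individuals' series.
    """
    if panel.n_timepoints < 2:
        raise ValueError("every individual needs at least 2 timepoints")
    si = panel.gene_index(source_gene)
    ti = panel.gene_index(target_gene)
    tgt = panel.values[ti]   # (N, L)
    src = panel.values[si]
    y = tgt[:, 1:].ravel()
    y_lag = tgt[:, :-1].ravel()
    x_lag = src[:, :-1].ravel()
    n, l1 = tgt.shape[0], tgt.shape[1] - 1
    individual_idx = np.repeat(np.arange(n), l1)
    t_index = np.tile(np.arange(1, l1 + 1), n)
    return LaggedDesign(y=y, y_lag=y_lag, x_lag=x_lag,
                        individual_idx=individual_idx, t_index=t_index)


def pair_series_design(x: np.ndarray, y: np.ndarray) -> LaggedDesign:
    """Lag-1 design for a single (X, Y) series pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("series must have equal length >= 2")
    n = len(y) - 1
    return LaggedDesign(
        y=y[1:], y_lag=y[:-1], x_lag=x[:-1],
        individual_idx=np.zeros(n, dtype=int),
        t_index=np.arange(1, n + 1),
    )


def pooled_pairs_design(pairs) -> LaggedDesign:
    """Stack lag-1 rows of many (X, Y) series pairs into one design.

    Each pair contributes len-1 rows; this is the pooled "virtual long
    series" used to combine short per-individual series.
    """
    ys, ylags, xlags, idx, ts = [], [], [], [], []
    for i, p in enumerate(pairs):
        ys.append(p.y[1:])
        ylags.append(p.y[:-1])
        xlags.append(p.x[:-1])
        n = len(p.y) - 1
        idx.append(np.full(n, i))
        ts.append(np.arange(1, n + 1))
    return LaggedDesign(
        y=np.concatenate(ys), y_lag=np.concatenate(ylags),
        x_lag=np.concatenate(xlags),
        individual_idx=np.concatenate(idx), t_index=np.concatenate(ts),
    )
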