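"""Two-slice dynamic Bayesian network learning with a fixed intra-slice.

The network spans two time slices: variables at t-1 and at t. A supplied
intra-slice directed acyclic network (edges acting within slice t) is
held fixed — its coefficients are re-estimated per candidate model but
its edges are never added or removed. Only inter-slice links
(parent at t-1 -> child at t, self links allowed) are learned, by greedy
hill-climbing on the Gaussian BIC score from random restarts; edges
appearing in at least a threshold fraction (default 30%) of the restart
structures form the consensus network.

Because inter-slice parents point backward in time and the intra-slice
structure is fixed, the BIC of the whole network decomposes into
independent per-child scores, so each child's parent set is searched
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .preprocess import ExpressionPanel

__all__ = ["TwoSliceNetwork", "TransitionData", "transition_rows",
           "node_bic_score", "lagged_correlation_candidates",
           "learn_inter_slice", "consensus_network", "self_link_fraction"]

Edge = tuple[str, str]


@dataclass
class TwoSliceNetwork:
    """Fixed intra-slice edges plus (learned) inter-slice edges.

    ``frequencies`` is populated only on consensus networks and maps each
    union inter-slice edge to the fraction of restart structures that
    contained it.
    """

    genes: list[str]
    intra_edges: frozenset = frozenset()
    inter_edges: frozenset = frozenset()
    frequencies: dict[Edge, float] | None = None
    node_bic: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.intra_edges = frozenset(self.intra_edges)
        self.inter_edges = frozenset(self.inter_edges)
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.intra_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("intra-slice edges must form a DAG")

    @property
    def total_bic(self) -> float:
        if self.node_bic is None:
            raise ValueError("network carries no node scores")
        return sum(self.node_bic.values())


@dataclass
class TransitionData:
    """Pooled consecutive-slice value pairs.

    ``prev`` and ``curr`` are (n_rows, n_genes) matrices: row r holds all
    gene values at t-1 and at t for one (individual, timepoint) pair.
    Pairs never cross individuals.
    """

    genes: list[str]
    prev: np.ndarray
    curr: np.ndarray
    individual_idx: np.ndarray
    t_index: np.ndarray
    _gene_pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.prev.shape != self.curr.shape:
            raise ValueError("prev and curr must have identical shape")
        if self.prev.shape[1] != len(self.genes):
            raise ValueError("column count must match gene list")
        self._gene_pos = {g: k for k, g in enumerate(self.genes)}

    @property
    def n_rows(self) -> int:
        return self.prev.shape[0]

    def col(self, gene: str) -> int:
        try:
            return self._gene_pos[gene]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene!r}") from None


def transition_rows(panel: ExpressionPanel) -> TransitionData:
    """Extract all (t-1, t) paired gene vectors, pooled across individuals.

    The panel should already be baseline re-referenced. N individuals at
    L timepoints yield N*(L-1) transition rows.
    """
    if panel.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints per individual")
    vals = panel.values  # (G, N, L)
    g, n, l = vals.shape
    prev = vals[:, :, :-1].reshape(g, n * (l - 1)).T
    curr = vals[:, :, 1:].reshape(g, n * (l - 1)).T
    # reshape flattens (N, L-1) row-major: rows grouped by individual
    individual_idx = np.repeat(np.arange(n), l - 1)
    t_index = np.tile(np.arange(1, l), n)
    return TransitionData(genes=list(panel.gene_ids), prev=prev, curr=curr,
                          individual_idx=individual_idx, t_index=t_index)


def node_bic_score(child: str, intra_parents: set[str] | frozenset,
                   inter_parents: set[str] | frozenset,
                   data: TransitionData) -> float:
    """Gaussian BIC of one child's local regression; lower is better.

    The child at time t is regressed on an intercept, its intra-slice
    parents at t, and its inter-slice parents at t-1. The score is the
    profile-likelihood form

        BIC = n * ln(RSS / n) + k * ln(n)

    with k = number of regression coefficients + 1 (the noise variance).
    An exactly-fitting model (RSS = 0) scores -inf and dominates.
    """
    n = data.n_rows
    n_parents = len(intra_parents) + len(inter_parents)
    if n <= n_parents + 2:
        raise ValueError(
            f"{n} rows cannot support {n_parents} parents for {child!r}")
    cols = [np.ones(n)]
    for p in sorted(intra_parents):
        cols.append(data.curr[:, data.col(p)])
    for p in sorted(inter_parents):
        cols.append(data.prev[:, data.col(p)])
    design = np.column_stack(cols)
    y = data.curr[:, data.col(child)]
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    k = design.shape[1] + 1
    tss = float(((y - y.mean())**2).sum())
    if rss <= 1e-12 * max(tss, 1.0):  # numerically exact fit dominates
        return -math.inf
    return n * math.log(rss / n) + k * math.log(n)


def lagged_correlation_candidates(data: TransitionData, alpha: float = 0.05,
                                  top_k: int | None = None
                                  ) -> dict[str, list[str]]:
    """Screen candidate inter-slice parents by marginal lagged correlation.

    A gene qualifies as a candidate parent of a child when the
    correlation between the gene at t-1 and the child at t is significant
    at ``alpha`` after Bonferroni correction over all G*G ordered pairs
    (sure-independence screening with multiplicity control). ``top_k``
    optionally caps each child's list at the strongest correlates, which
    bounds search cost on large panels.

    The BIC penalty alone admits chance parents at roughly two standard
    errors of a null partial correlation whatever the sample size, so on
    an all-genes candidate set a scan over many null pairs accumulates
    spurious parents; requiring marginal significance first keeps the
    genome-wide false-parent count near zero while strong true parents
    pass easily.
    """
    n, g = data.prev.shape
    if n < 4:
        raise ValueError("need at least 4 transition rows to screen")
    prev = data.prev - data.prev.mean(axis=0)
    curr = data.curr - data.curr.mean(axis=0)
    prev_n = prev / np.maximum(np.linalg.norm(prev, axis=0), 1e-300)
    curr_n = curr / np.maximum(np.linalg.norm(curr, axis=0), 1e-300)
    r = prev_n.T @ curr_n  # r[parent, child]
    t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(t, n - 2)
    keep = p * (g * g) < alpha
    candidates: dict[str, list[str]] = {}
    for ci, child in enumerate(data.genes):
        idx = np.where(keep[:, ci])[0]
        idx = idx[np.argsort(-np.abs(r[idx, ci]), kind="stable")]
        if top_k is not None:
            idx = idx[:top_k]
        candidates[child] = [data.genes[i] for i in idx]
    return candidates


def _intra_parent_map(genes, intra_edges) -> dict[str, frozenset]:
    parents: dict[str, set[str]] = {g: set() for g in genes}
    for p, c in intra_edges:
        parents[c].add(p)
    return {g: frozenset(ps) for g, ps in parents.items()}


def _greedy_child_search(child: str, intra_parents: frozenset,
                         candidates: list[str], data: TransitionData,
                         rng: np.random.Generator,
                         max_parents: int) -> tuple[frozenset, float]:
    """First-improvement hill-climbing over add/remove toggles.

    Starts from a seeded random parent subset and repeatedly sweeps the
    candidates in a freshly shuffled order, toggling any membership change
    that strictly lowers the BIC, until a full sweep makes no move.
    """
    cand = list(candidates)
    current = {c for c in cand if rng.random() < 0.5}
    while len(current) > max_parents:
        current.discard(cand[int(rng.integers(len(cand)))])
    score = node_bic_score(child, intra_parents, current, data)
    tol = 1e-9
    improved = True
    while improved:
        improved = False
        order = list(rng.permutation(len(cand)))
        for ci in order:
            g = cand[ci]
            trial = set(current)
            if g in trial:
                trial.discard(g)
            else:
                if len(trial) >= max_parents:
                    continue
                trial.add(g)
            trial_score = node_bic_score(child, intra_parents, trial, data)
            if trial_score < score - tol:
                current, score = trial, trial_score
                improved = True
    return frozenset(current), score


def learn_inter_slice(data: TransitionData, intra: TwoSliceNetwork,
                      candidates: dict[str, list[str]] | None = None,
                      restarts: int = 1000, seed: int = 0,
                      max_parents: int | None = None) -> list[TwoSliceNetwork]:
    """Learn inter-slice parent sets per child; one network per restart.

    ``candidates`` maps each child to its admissible inter-slice parents
    (default: every gene, self included). ``max_parents`` caps the parent
    set so the local regression stays identifiable (default: enough rows
    must remain for the intercept, intra parents and noise variance).
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    genes = list(data.genes)
    if candidates is None:
        candidates = {g: list(genes) for g in genes}
    intra_parents = _intra_parent_map(genes, intra.intra_edges)
    networks = []
    ss = np.random.SeedSequence(seed)
    child_states = ss.spawn(restarts)
    for r in range(restarts):
        rng = np.random.default_rng(child_states[r])
        inter: set[Edge] = set()
        node_bic: dict[str, float] = {}
        for child in genes:
            cap = data.n_rows - len(intra_parents[child]) - 3
            cap = min(cap, len(candidates.get(child, [])))
            if max_parents is not None:
                cap = min(cap, max_parents)
            parents, score = _greedy_child_search(
                child, intra_parents[child], candidates.get(child, []),
                data, rng, max_parents=max(cap, 0))
            inter.update((p, child) for p in parents)
            node_bic[child] = score
        networks.append(TwoSliceNetwork(
            genes=genes, intra_edges=intra.intra_edges,
            inter_edges=frozenset(inter), node_bic=node_bic))
    return networks


def consensus_network(structures: list[TwoSliceNetwork],
                      freq_threshold: float = 0.3) -> TwoSliceNetwork:
    """Keep inter-slice edges present in >= threshold fraction of restarts.

    The threshold is inclusive; frequencies are recorded for every edge
    in the union of restart structures.
    """
    if not structures:
        raise ValueError("need at least one structure")
    if not 0 < freq_threshold <= 1:
        raise ValueError("freq_threshold must be in (0, 1]")
    counts: dict[Edge, int] = {}
    for net in structures:
        for e in net.inter_edges:
            counts[e] = counts.get(e, 0) + 1
    b = len(structures)
    freqs = {e: n / b for e, n in counts.items()}
    kept = frozenset(e for e, f in freqs.items() if f >= freq_threshold)
    return TwoSliceNetwork(
        genes=structures[0].genes, intra_edges=structures[0].intra_edges,
        inter_edges=kept, frequencies=freqs)


def self_link_fraction(network: TwoSliceNetwork) -> float | None:
    """Fraction of inter-slice edges whose parent equals the child.

    Returns ``None`` for a network with no inter-slice edges.
    """
    if not network.inter_edges:
        return None
    n_self = sum(1 for p, c in network.inter_edges if p == c)
    return n_self / len(network.inter_edges)
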