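"""Synthetic data generators for causality-test benchmarking.

Two families of generators are provided:

* first-order bivariate autoregressive (BVAR) pairs, the workhorse of the
  simulation study: a driver series X and a response series Y whose next
  value depends on its own past and on the driver's past;
* multi-gene cohort panels governed by a linear-Gaussian two-slice model
  (within-slice directed acyclic structure plus between-slice lagged
  edges), with per-individual baseline offsets, emulating short expression
  time courses collected from many individuals.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .preprocess import ExpressionPanel

__all__ = [
    "BVARParams",
    "RealizedCoefficients",
    "PairSeries",
    "CohortSpec",
    "GroundTruthPanel",
    "simulate_bvar_pair",
    "simulate_pair_population",
    "permute_pair_assignment",
    "thin_series",
    "simulate_cohort_panel",
]


@dataclass(frozen=True)
class BVARParams:
    """Generative parameters of the first-order stationary BVAR model.

    The model is

        X_t = a * X_{t-1} + eps_x,t
        Y_t = b * Y_{t-1} + c * X_{t-1} + eps_y,t

    where the coefficients (a, b, c) are drawn once per series from normal
    distributions with the means/SDs below, the noises are i.i.d. normal,
    and initial values are uniform on [-init_halfwidth, +init_halfwidth].
    ``c`` is the causal coefficient from the driver's past onto the
    response; setting ``c_mean = c_sd = 0`` yields two independent AR(1)
    processes.

    Defaults are mid-strength stationary dynamics: coefficient means 0.5,
    coefficient SDs 0.1, unit noise, unit initial half-width.
    """

    a_mean: float = 0.5
    a_sd: float = 0.1
    b_mean: float = 0.5
    b_sd: float = 0.1
    c_mean: float = 0.5
    c_sd: float = 0.1
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    init_halfwidth: float = 1.0

    def __post_init__(self) -> None:
        vals = [
            self.a_mean, self.a_sd, self.b_mean, self.b_sd, self.c_mean,
            self.c_sd, self.noise_sd_x, self.noise_sd_y, self.init_halfwidth,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("BVARParams fields must be finite")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.a_sd < 0 or self.b_sd < 0 or self.c_sd < 0:
            raise ValueError("coefficient SDs must be non-negative")
        if self.init_halfwidth < 0:
            raise ValueError("init_halfwidth must be non-negative")


@dataclass(frozen=True)
class RealizedCoefficients:
    """The (a, b, c) coefficients actually drawn for one series."""

    a: float
    b: float
    c: float


@dataclass
class PairSeries:
    """One (X, Y) series pair of common length T.

    ``coef`` holds the realized per-series coefficients; it is ``None``
    for null pairs produced by permuting the series assignment, where no
    X -> Y causal coefficient exists by construction.
    """

    x: np.ndarray
    y: np.ndarray
    series_id: str
    coef: RealizedCoefficients | None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D vectors of equal length")
        if len(self.x) < 2:
            raise ValueError("series must have at least 2 time points")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("series contain non-finite values")

    def __len__(self) -> int:
        return len(self.x)


def _draw_coefs(params: BVARParams, rng: np.random.Generator, n: int):
    a = rng.normal(params.a_mean, params.a_sd, size=n)
    b = rng.normal(params.b_mean, params.b_sd, size=n)
    c = rng.normal(params.c_mean, params.c_sd, size=n)
    return a, b, c


def _evolve(params: BVARParams, a, b, c, length: int,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized recursion over ``n`` series simultaneously."""
    n = len(a)
    x = np.empty((n, length))
    y = np.empty((n, length))
    h = params.init_halfwidth
    x[:, 0] = rng.uniform(-h, h, size=n)
    y[:, 0] = rng.uniform(-h, h, size=n)
    ex = rng.normal(0.0, params.noise_sd_x, size=(n, length - 1))
    ey = rng.normal(0.0, params.noise_sd_y, size=(n, length - 1))
    for t in range(1, length):
        x[:, t] = a * x[:, t - 1] + ex[:, t - 1]
        y[:, t] = b * y[:, t - 1] + c * x[:, t - 1] + ey[:, t - 1]
    return x, y


def simulate_bvar_pair(params: BVARParams, length: int, seed: int) -> PairSeries:
    """Simulate one BVAR pair of the given length.

    The seed fixes the coefficient draws, the initial values, and every
    noise term, so identical calls return identical series.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    a, b, c = _draw_coefs(params, rng, 1)
    x, y = _evolve(params, a, b, c, length, rng)
    return PairSeries(
        x=x[0], y=y[0], series_id="pair-0",
        coef=RealizedCoefficients(float(a[0]), float(b[0]), float(c[0])),
    )


def simulate_pair_population(params: BVARParams, n_series: int, length: int,
                             seed: int) -> list[PairSeries]:
    """Simulate ``n_series`` independent BVAR pairs.

    Per-series coefficients are independently drawn; output is
    deterministic given the seed.
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    a, b, c = _draw_coefs(params, rng, n_series)
    x, y = _evolve(params, a, b, c, length, rng)
    return [
        PairSeries(
            x=x[i], y=y[i], series_id=f"pair-{i}",
            coef=RealizedCoefficients(float(a[i]), float(b[i]), float(c[i])),
        )
        for i in range(n_series)
    ]


def permute_pair_assignment(population: list[PairSeries],
                            seed: int) -> list[PairSeries]:
    """Re-pair every Y_i with the X of a different series.

    A seeded cyclic shift by a uniformly drawn nonzero offset guarantees a
    derangement (no Y keeps its own X), so the re-paired X carries no
    information about Y beyond chance while each marginal series remains a
    genuine AR process. The returned pairs carry ``coef=None`` to mark the
    absent causal coefficient.
    """
    n = len(population)
    if n < 2:
        raise ValueError("need at least 2 series to re-pair")
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(1, n))
    out = []
    for i, pair in enumerate(population):
        j = (i + offset) % n
        out.append(PairSeries(
            x=population[j].x.copy(), y=pair.y.copy(),
            series_id=f"{pair.series_id}|x-from-{population[j].series_id}",
            coef=None,
        ))
    return out


def thin_series(series: PairSeries, interval: int) -> PairSeries:
    """Keep every ``interval``-th point starting at index 0.

    The output length is ceil(T / interval). Thinning a first-order
    process widens the effective sampling interval, which attenuates the
    observable lag-1 dependence.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if interval == 1:
        return series
    return replace(series,
                   x=series.x[::interval].copy(),
                   y=series.y[::interval].copy())


@dataclass
class CohortSpec:
    """Ground-truth description of a multi-gene two-slice cohort generator.

    ``intra_edges`` act within a time slice (parent and child at the same
    t) and must form a DAG; ``inter_edges`` act across consecutive slices
    (parent at t-1, child at t) and may include self edges (g, g), the
    autoregressive links. Coefficients map each edge to its linear weight.
    ``baseline_sd`` is the SD of the per-individual, per-gene constant
    offset that baseline re-referencing is meant to remove.
    """

    genes: list[str]
    intra_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    inter_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for (p, c) in list(self.intra_edges) + list(self.inter_edges):
            if p not in gene_set or c not in gene_set:
                raise ValueError(f"edge endpoint not in gene list: ({p}, {c})")
        for (p, c) in self.intra_edges:
            if p == c:
                raise ValueError("self edges are only allowed inter-slice")
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.intra_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("intra-slice edges must form a DAG")


@dataclass
class GroundTruthPanel:
    """A simulated panel together with the structure that generated it."""

    panel: ExpressionPanel
    true_intra_edges: set[tuple[str, str]]
    true_inter_edges: set[tuple[str, str]]
    coefficients: dict[tuple[str, str], float]


def simulate_cohort_panel(spec: CohortSpec, n_individuals: int,
                          n_timepoints: int, seed: int) -> GroundTruthPanel:
    """Simulate a cohort expression panel from a known two-slice structure.

    For each individual a per-gene baseline offset is drawn; the deviation
    from baseline starts at zero at time 0 and then evolves under the
    linear-Gaussian two-slice system: each gene at time t is the weighted
    sum of its intra-slice parents at t and its inter-slice parents at
    t-1, plus Gaussian noise. Emitted values are baseline + deviation on
    the log scale, so baseline re-referencing recovers the deviations
    exactly.
    """
    if n_individuals < 1 or n_timepoints < 2:
        raise ValueError("need >= 1 individual and >= 2 timepoints")
    genes = list(spec.genes)
    gi = {g: k for k, g in enumerate(genes)}
    g_intra = nx.DiGraph()
    g_intra.add_nodes_from(genes)
    g_intra.add_edges_from(spec.intra_edges)
    topo = list(nx.topological_sort(g_intra))

    rng = np.random.default_rng(seed)
    G, N, T = len(genes), n_individuals, n_timepoints
    baseline = rng.normal(0.0, spec.baseline_sd, size=(G, N))
    z = np.zeros((G, N, T))
    noise = rng.normal(0.0, spec.noise_sd, size=(G, N, T - 1))
    intra_by_child: dict[str, list[tuple[int, float]]] = {g: [] for g in genes}
    inter_by_child: dict[str, list[tuple[int, float]]] = {g: [] for g in genes}
    for (p, c), w in spec.intra_edges.items():
        intra_by_child[c].append((gi[p], w))
    for (p, c), w in spec.inter_edges.items():
        inter_by_child[c].append((gi[p], w))

    for t in range(1, T):
        for g in topo:  # topo order so intra parents at t are already set
            k = gi[g]
            val = noise[k, :, t - 1].copy()
            for pk, w in inter_by_child[g]:
                val += w * z[pk, :, t - 1]
            for pk, w in intra_by_child[g]:
                val += w * z[pk, :, t]
            z[k, :, t] = val

    values = baseline[:, :, None] + z
    panel = ExpressionPanel(
        values=values,
        gene_ids=genes,
        individual_ids=[f"ind{i:03d}" for i in range(N)],
        timepoints=np.arange(T),
        arm="synthetic",
    )
    coefficients = dict(spec.intra_edges)
    coefficients.update(spec.inter_edges)
    return GroundTruthPanel(
        panel=panel,
        true_intra_edges=set(spec.intra_edges),
        true_inter_edges=set(spec.inter_edges),
        coefficients=coefficients,
    )
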