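"""Simulation study: causality-test power versus design choices.

Reproduces, at configurable scale, the benchmark experiments behind the
pooled short-series causality test: detection power (recall) as a
function of series length, of sampling interval at fixed point count,
and of pooling many short series versus one long series; plus empirical
false-positive rates on permutation nulls. Recall is reported both at
the raw alpha and at a Bonferroni-corrected threshold over the
replicate population.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._seeds import substream_seed
from .granger import granger_test
from .preprocess import pair_series_design, pooled_pairs_design
from .simulate import (BVARParams, permute_pair_assignment,
                       simulate_pair_population, thin_series)

__all__ = ["power_vs_length", "power_vs_interval", "pooled_vs_long",
           "empirical_fpr"]

POWER_COLUMNS = ["condition", "n_replicates", "recall", "recall_corrected",
                 "fpr", "alpha", "seed"]


def _pair_pvalues(pairs) -> np.ndarray:
    return np.array([granger_test(pair_series_design(p.x, p.y)).p_value
                     for p in pairs])


def power_vs_length(params: BVARParams, lengths: list[int], reps: int = 200,
                    alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Recall of the per-series test as the series length varies.

    One population of ``reps`` full-length causal pairs is simulated;
    each shorter condition tests the leading ``length`` points of the
    same series (common random numbers, as when partial time points of a
    simulated series are used). Recall is the fraction with p below
    alpha (raw) or below alpha / reps (Bonferroni-corrected over the
    replicate set). Lengths too short for the F-test's degrees of
    freedom are skipped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    usable = [l for l in lengths if l - 1 >= 4]
    pairs = []
    if usable:
        pairs = simulate_pair_population(
            params, reps, max(usable), substream_seed(seed, "series-population"))
    rows = []
    for length in lengths:
        if length - 1 < 4:  # lag-1 rows < k_full + 1
            rows.append((f"length={length} (skipped: too short)", reps,
                         np.nan, np.nan, np.nan, alpha, seed))
            continue
        prefixes = [replace(p, x=p.x[:length], y=p.y[:length]) for p in pairs]
        p = _pair_pvalues(prefixes)
        rows.append((f"length={length}", reps,
                     float(np.mean(p < alpha)),
                     float(np.mean(p < alpha / reps)),
                     np.nan, alpha, seed))
    return pd.DataFrame(rows, columns=POWER_COLUMNS)


def power_vs_interval(params: BVARParams, intervals: list[int],
                      fixed_point_count: int = 60, reps: int = 200,
                      alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Recall at different sampling intervals, holding point count fixed.

    One population of full-length causal pairs is simulated (length =
    max interval * fixed_point_count); for each interval, the leading
    interval * fixed_point_count points of the same series are thinned
    to every interval-th point, so every condition tests the same number
    of points from the same realizations while the effective spacing
    grows. Wider spacing attenuates the lag-1 signal, so recall should
    not increase with the interval.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(i < 1 for i in intervals):
        raise ValueError("intervals must be >= 1")
    full_len = max(intervals) * fixed_point_count
    pairs = simulate_pair_population(
        params, reps, full_len, substream_seed(seed, "series-population"))
    rows = []
    for interval in intervals:
        span = interval * fixed_point_count
        thinned = [thin_series(replace(p, x=p.x[:span], y=p.y[:span]),
                               interval) for p in pairs]
        p = _pair_pvalues(thinned)
        rows.append((f"interval={interval}", reps,
                     float(np.mean(p < alpha)),
                     float(np.mean(p < alpha / reps)),
                     np.nan, alpha, seed))
    return pd.DataFrame(rows, columns=POWER_COLUMNS)


def pooled_vs_long(params: BVARParams, n_series: int = 40, short_len: int = 6,
                   long_len: int = 240, reps: int = 200, alpha: float = 1e-5,
                   seed: int = 0) -> pd.DataFrame:
    """Pooled many-short-series test versus one long-series test.

    Each replicate simulates ``n_series`` short pairs sharing the same
    coefficient distribution, stacks their lagged rows into one pooled
    design, and tests it; separately a single ``long_len``-point pair is
    tested at the same alpha. Comparable information requires
    n_series * (short_len - 1) to be of the order of long_len.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pooled_hits = 0
    long_hits = 0
    for r in range(reps):
        rep_seed = substream_seed(seed, "pooled-vs-long", r)
        short = simulate_pair_population(params, n_series, short_len, rep_seed)
        res = granger_test(pooled_pairs_design(short))
        pooled_hits += res.p_value < alpha
        long_pair = simulate_pair_population(params, 1, long_len, rep_seed)[0]
        res_long = granger_test(pair_series_design(long_pair.x, long_pair.y))
        long_hits += res_long.p_value < alpha
    rows = [
        (f"pooled {n_series}x{short_len}", reps, pooled_hits / reps,
         np.nan, np.nan, alpha, seed),
        (f"single long {long_len}", reps, long_hits / reps,
         np.nan, np.nan, alpha, seed),
    ]
    return pd.DataFrame(rows, columns=POWER_COLUMNS)


def empirical_fpr(params: BVARParams, reps: int = 1000,
                  alphas: tuple[float, ...] = (0.01, 0.05),
                  length: int = 240, seed: int = 0) -> pd.DataFrame:
    """False-positive rate on permuted (null) pairs across an alpha grid.

    ``reps`` causal pairs are simulated, then the series assignment is
    permuted (every Y re-paired with another series' X) so that no X -> Y
    dependence remains while each marginal stays autoregressive. FPR at
    each alpha is the fraction of permuted pairs with p below alpha.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2 to permute the assignment")
    pairs = simulate_pair_population(
        params, reps, length, substream_seed(seed, "fpr-sim"))
    nulls = permute_pair_assignment(pairs, substream_seed(seed, "fpr-perm"))
    p = _pair_pvalues(nulls)
    rows = [(f"alpha={a:g}", reps, np.nan, np.nan, float(np.mean(p < a)),
             a, seed) for a in alphas]
    return pd.DataFrame(rows, columns=POWER_COLUMNS)
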