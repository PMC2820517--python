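# temponet

Causal network inference from **many short gene-expression time series**.

Longitudinal molecular studies in humans rarely yield the long time
courses that classical time-series causality methods need; instead they
yield many *short* series — e.g. a cohort of 40 individuals sampled at 7
time points over a day. temponet implements the analysis stack for this
regime:

* a **pooled Granger causality test** that combines each individual's
  short series into one "virtual long series" after removing
  individual-specific baselines;
* **network construction**: all-ordered-pairs testing, multiple-testing
  control (Bonferroni or Benjamini–Hochberg, with BH q-values reported
  as the FDR), pruning of indirect links so every gene keeps only its
  single most significant incoming edge, and regulator ranking by
  out-degree;
* **bootstrap link confidence** by resampling individuals with
  replacement;
* a **two-slice dynamic Bayesian network (DBN)** learner that holds a
  supplied intra-slice network fixed and learns only the inter-slice
  (t−1 → t) links by BIC-scored greedy search with random restarts,
  followed by a consensus over restarts;
* a ground-truthed **simulator** (bivariate AR pairs and multi-gene
  linear-Gaussian two-slice cohorts) for power studies and validation.

## The model

Dynamics are first-order, stationary and bivariate. A driver X and a
response Y evolve as

    X_t = a · X_{t−1} + ε_x,t
    Y_t = b · Y_{t−1} + c · X_{t−1} + ε_y,t

X Granger-causes Y when c ≠ 0, tested by comparing the full regression
of y_t on (1, y_{t−1}, x_{t−1}) against the reduced autoregression on
(1, y_{t−1}):

    F = (RSS_r − RSS_f) / (RSS_f / (n − 3)) ~ F(1, n − 3)

For a cohort, each individual's log-expression profile is first
referenced to its own time-0 profile (removing individual scale
effects), then the lagged rows of all individuals are stacked into one
design under shared coefficients: N individuals at L effective time
points contribute n = N·(L−1) rows, so 40×6 short series are tested with
the power of a ~200-point series. Single 6-point series are essentially
powerless; the pooled test is not.

The two-slice DBN scores each child gene's local model — child at t
regressed on an intercept, its fixed intra-slice parents at t, and
candidate inter-slice parents at t−1 — with the Gaussian BIC
`n·ln(RSS/n) + k·ln(n)`. Because inter-slice parents point backward in
time, the score decomposes per child and each child is searched
independently. Self links (a gene at t−1 driving itself at t) are
allowed and, in autocorrelated expression data, dominate.

## Worked example

Simulate a 5-gene cohort (40 individuals × 7 time points; every gene
has a self link with coefficient 0.5 plus one cross edge g0→g1 with
coefficient 0.8), then scan it:

```sh
temponet simulate --individuals 40 --timepoints 7 --seed 11 --out-dir demo-sim
temponet scan --panel demo-sim/panel.tsv --samples demo-sim/samples.tsv \
              --alpha 0.01 --bootstrap 100 --seed 11 --out-dir demo-scan
temponet dbn  --panel demo-sim/panel.tsv --samples demo-sim/samples.tsv \
              --restarts 50 --consensus 0.3 --seed 11 --out-dir demo-dbn
```

`demo-scan/edges.tsv` (the pruned Granger network):

```
source  target  p_raw                   p_adjusted              q_value                 confidence
g0      g1      1.9497210179422673e-25  3.8994420358845346e-24  3.8994420358845346e-24  1.0
```

The one planted cross edge g0→g1 is recovered at p ≈ 2·10⁻²⁵ (Bonferroni
over the 20 ordered pairs), with bootstrap confidence 1.0 over 100
individual-resampling replicates; `regulators.tsv` ranks g0 as the only
causal regulator (out-degree 1). `demo-dbn/consensus.tsv` contains
exactly the six true inter-slice links (five self links plus g0→g1), all
at consensus frequency 1.0, i.e. a self-link fraction of 5/6 ≈ 0.83:

```
parent  child   slice   frequency
g0      g0      inter   1
g0      g1      inter   1
g1      g1      inter   1
...
```

The same operations are available as a library (`temponet.granger`,
`temponet.netscan`, `temponet.bootstrap`, `temponet.dbn`,
`temponet.simulate`, `temponet.experiments`).

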