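# Methods

## Generative model for a pair of series

The simulator's bivariate autoregressive (BVAR) model is first-order and
stationary: per series, coefficients (a, b, c) are drawn once from
normal distributions and held fixed over time; noises are i.i.d.
Gaussian; initial values are uniform on [−h, +h]. Defaults (all
overridable on `BVARParams`):

| parameter | default | meaning |
|---|---|---|
| a_mean, a_sd | 0.5, 0.1 | own-lag coefficient of the driver X |
| b_mean, b_sd | 0.5, 0.1 | own-lag coefficient of the response Y |
| c_mean, c_sd | 0.5, 0.1 | causal coefficient X_{t−1} → Y_t |
| noise_sd_x, noise_sd_y | 1.0 | innovation SDs |
| init_halfwidth | 1.0 | support half-width of the uniform initial values |

These are mid-strength stationary dynamics (|a|, |b| < 1), chosen so
that the benchmark regime behaves like the motivating study design:
single 6-point series never reach a corrected significance threshold,
while 40 pooled 6-point series detect the causal link with recall
comparable to a single 240-point series. No intercept is simulated;
individual baselines are a panel-level offset removed by re-referencing.

Null (permuted) pairs are built by re-pairing every response with the
driver of a different series via a seeded cyclic shift with a nonzero
offset — a simple derangement, so no pair keeps its own driver, while
each marginal series remains a genuine AR(1) realization (the
autoregressive part of the null model stays valid).

## Cohort generator

`simulate_cohort_panel` generalizes the pair model to G genes under a
linear-Gaussian two-slice structure: intra-slice edges (within time t,
a DAG, evaluated in topological order) and inter-slice edges (t−1 → t,
self edges allowed). Each individual receives a per-gene baseline
offset (SD 1 by default); the deviation from baseline is exactly zero
at time 0 and then evolves with Gaussian innovations (SD 1 by default).
Emitted values are baseline + deviation on the log scale, so
re-referencing each individual to its time-0 profile recovers the
deviations exactly.

What the generator emulates: short per-individual series with shared
dynamics, individual scale offsets, known causal structure, and
pervasive autoregression (self links). What it does not emulate:
measurement error of microarrays, non-Gaussian or heavy-tailed
expression noise, non-stationary (e.g. meal-response) coefficients,
contemporaneous confounding beyond the modelled intra-slice edges, and
the ~10⁴-gene scale of a genome-wide panel. Passing recovery tests on
this generator therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not performance on real
expression data.

Benchmark panels used by the test-suite and the acceptance script: 20
genes, 40 individuals, 7 time points (6 effective after
re-referencing → 200 transition rows); every gene carries a self link
(coefficient 0.6) plus strong cross edges (coefficient 0.9, six edges)
for the recovery study, or sparse cross edges (coefficient 0.5, four
edges) for the self-link study. Universal self links mirror the
empirical dominance of autoregression in expression dynamics; the
cohort geometry matches a realistic one-day sampling design.

## Pooled Granger test

* Baseline referencing is subtraction on the log scale; time 0 is
  dropped (an all-zero time point carries no regression information),
  leaving L−1 effective points per individual.
* Lagged rows never span two individuals; N individuals at L effective
  points give n = N·(L−1) rows and denominator df = n − 3.
* An intercept is included in both nested models (a config flag removes
  it, changing k_full to 2): after referencing, series need not be
  mean-zero at every lag.
* One shared coefficient set is fitted across individuals — the pooling
  assumption is that response slopes are similar across individuals;
  no per-individual slopes or mixed effects.
* Degenerate cases: an exactly collinear response (RSS_full below
  1e−12 of RSS_reduced) reports p = 0 with a `degenerate` flag; a
  constant driver column reports p = 1 with a `collinear` flag rather
  than a singular fit.
* Only lag 1 is supported by design; with ≤ 6 effective points per
  individual, higher lag orders are not identifiable and are excluded
  from the model space.

## Network construction

All p·(p−1) ordered pairs are tested. The 0.01 significance cutoff is
applied to Bonferroni-adjusted p-values by default (conservative;
Benjamini–Hochberg available by flag), and BH q-values are always
reported alongside as the FDR estimate. Thresholding happens before
pruning; pruning then keeps, per target, the single incoming edge with
the smallest raw p (ties broken lexicographically by source id and
logged). The rationale for pruning is that a bivariate test cannot
separate direct from indirect drivers; the strongest incoming link is
retained as the best-supported direct explanation. Regulators are
ranked by out-degree in the pruned network; the out-degree histogram is
exported with zero-degree genes included (no power-law fit is
performed).

## Bootstrap confidence

The resampling unit is the individual: each replicate draws N
individuals with replacement, keeping each individual's full series
intact (duplicated individuals contribute duplicated rows). The scan
and threshold are re-run per replicate, and a link's confidence is the
fraction of replicates in which it is significant — i.e. its corrected
p-value falls *below* the threshold; significance is scored before
pruning. Default B = 100.

## Two-slice DBN learning

* Score: Gaussian profile-likelihood BIC, `n·ln(RSS/n) + k·ln(n)` with
  k = number of regression coefficients + 1 (noise variance); lower is
  better; an (numerically) exact fit scores −∞. This fixed variant keeps
  scores comparable across runs.
* The intra-slice network is a required input and is never modified;
  intra-slice parents enter each child's regression at time t with
  freely re-estimated coefficients.
* Search: per child (the score decomposes because inter-slice parents
  point backward in time), first-improvement hill-climbing over
  add/remove toggles of candidate parents, starting from a seeded
  random subset and sweeping candidates in a freshly shuffled order
  until a full sweep yields no improving move. BIC is strictly
  decreasing along accepted moves, so the search terminates.
* Restarts and consensus: one structure per restart (default 1000;
  tests and the acceptance script use 50 to keep runtimes in seconds);
  the consensus keeps inter-slice edges present in ≥ 30% of structures
  (inclusive threshold), recording frequencies on all union edges.
* Candidate screening: by default every gene (self included) is a
  candidate parent of every child. The BIC penalty alone accepts a null
  parent whose partial correlation exceeds ≈ √(ln n / n) — about two
  null standard errors *regardless of n* — so an unrestricted scan over
  G·(G−1) null candidates accumulates a handful of spurious parents
  that every restart reproduces (consensus cannot remove them).
  `lagged_correlation_candidates` therefore screens candidates by
  marginal lagged correlation, keeping a parent only if its t−1 → t
  correlation with the child is significant at α = 0.05 after
  Bonferroni correction over all G² ordered pairs (optionally capped at
  the top-K correlates to bound cost on large panels). Strong true
  parents pass this screen easily; genome-wide chance correlates
  essentially never do. Residual false positives are the
  reverse-direction shadows of true edges (indirect lagged
  correlations), an inherent limitation of marginal screening plus
  per-child scoring.

## Simulation experiments

`power_vs_length` and `power_vs_interval` reuse one simulated
population across conditions (each shorter or thinned condition takes
the leading points of the same full-length series), so condition
comparisons are paired rather than independent — the low-variance way
to measure how power decays with fewer points or wider spacing.
`pooled_vs_long` shares the per-replicate seed between the pooled and
the long arm. `empirical_fpr` permutes the simulated population and
reports false-positive rates across an alpha grid. Default replicate
count is 200 (the `--full` CLI flag restores 1000); recall is reported
at the raw alpha and at the Bonferroni-corrected alpha over the
replicate set.

## Numerical conventions

* OLS is solved by `numpy.linalg.lstsq`; rank-deficient designs fall
  back to the minimum-norm solution with a logged warning.
* All stochastic stages derive their seeds from a master seed plus a
  stage name through `SeedSequence` (seeds stay below 2³¹), making every
  pipeline byte-reproducible.
* Re-running any CLI subcommand with the same options reproduces
  identical artifacts; manifests record versions, seeds and row counts.

## Known limitations

* Bivariate testing infers indirect links by design; pruning to one
  incoming edge is a heuristic, not a structural identification.
* The pooled test assumes homogeneous dynamics across individuals; true
  inter-individual coefficient heterogeneity beyond the simulated SD
  (0.1) inflates residual variance and is not modelled as random
  effects.
* The DBN learner assumes linear-Gaussian local models and a fixed,
  correct intra-slice network; errors in the supplied intra-slice
  structure propagate to the inter-slice estimates.
* Thinned (wide-interval) sampling of a first-order process is still
  tested with a lag-1 model; power loss with interval is therefore a
  property of the observed, not the latent, process.
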