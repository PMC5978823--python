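# Methods

## Model and assumptions

The estimand is a person-specific lag-1 network: the matrix *W* of
standardized coefficients in node-wise regressions of every item at day *t*
on all items at day *t − 1*. The implied generative model is a stationary
first-order vector autoregression around a smooth mean trend, with
approximately Gaussian innovations and a one-day causal resolution.
Implicit assumptions worth keeping in mind:

- **Stationarity after detrending.** Dynamics (the coefficients) are
  constant over the diary; only the mean may drift. Regime changes,
  treatment effects, or weekend cycles faster than the polynomial can track
  violate this.
- **One-day lag.** Effects operating within a day (contemporaneous) or over
  several days are not modeled; a skipped day removes information rather
  than stretching the lag (see pairing policy).
- **Whole-day missingness at random.** A diary is completed or skipped as a
  unit; skipping is unrelated to symptom level. Days with any missing item
  are treated as fully missing for estimation (configurable in principle via
  the mask, but the shipped pipeline uses complete days only).

## Detrending

Each item is regressed on polynomials in *week-time* (days since the first
span day, divided by 7) of orders 0–10, fitted on an orthonormalized
(QR) basis so that order 10 is numerically safe on ~90 points. The default
order cap of 10 is enough for linear and curvilinear drift plus monthly
cyclicity over a ~4-month diary; it is reduced to n − 2 for short series.

**Criterion choice (open design point).** Order is chosen by information
criterion; the default is BIC, with AICc (n·ln(RSS/n) + 2k +
2k(k + 1)/(n − k − 1), k = order + 1 coefficients including the intercept)
available via `criterion="aicc"`. The choice matters: an AIC-type penalty
(~2 per parameter) lets pure noise at n = 90 acquire a spurious trend order
in roughly a quarter of series, while BIC's ln(n) penalty keeps the
false-trend rate under 5% (measured at 200 seeded replicates) and still
recovers a noiseless quadratic exactly. Because an invented trend removes
real day-to-day variance before network estimation, we treat
over-detrending as the costlier error and default to BIC. Order selection
is argmin over the criterion table; ties resolve to the lower order.

Residuals are exactly mean-zero over observed days and keep the item's
scale; z-scaling happens in the network stage. Lag-1 residual
autocorrelation (over calendar-consecutive observed pairs, t-test at
α = 0.05) is reported as a diagnostic only — the network's self-loops model
autocorrelation explicitly, so removing it here would remove it twice.

## Lag pairs and estimation

Under the default `calendar` policy, a pair (t − 1, t) enters only when
both days are fully observed; `sequential` (consecutive observations
regardless of gap) is provided for sensitivity analysis. Predictor and
outcome columns are z-standardized (population SD) over the pair set;
constant columns are zeroed with a warning and their coefficients forced
to 0.

Each node's LASSO path minimizes ‖y − Xβ‖²/(2n) + λ‖β‖₁ on a 100-point
log grid from λ_max = max|Xᵀy|/n (the smallest all-zero penalty) down to
10⁻³·λ_max, solved by coordinate descent at tolerance 1e-12 so that results
are exactly invariant to item order. AICc is evaluated at every grid point
with k = the number of nonzero coefficients (the standard LASSO df
estimate) and RSS from the penalized fit; the chosen index is the argmin,
ties to the larger penalty. Intercepts are unnecessary (mean-zero inputs),
and there is no post-selection re-fitting: reported weights are the
penalized estimates.

**Known behavior of AICc tuning.** With many observations per candidate
parameter (e.g. 200 pairs, 6 items) AICc behaves like AIC and retains
weakly supported edges: in the shipped Monte-Carlo experiment it recovers
every planted 0.4 effect (sensitivity 1.0, sign accuracy 1.0) but keeps
small spurious coefficients, giving off-diagonal support specificity around
0.6–0.7. In the data-poor regime the method is designed for (p = 22,
~89 pairs) the small-sample correction term dominates and the same tuning
is conservative: the measured false-edge rate on pure noise is ≈ 9%. Users
wanting hard sparsity guarantees at large n should treat retained small
edges with caution (the bivariate cross-check table helps).

## Network bookkeeping

Edge counts are reported on the full pre-pruning node set: a p-item diary
has p² possible lag-1 relations, self-loops included. Nodes whose
off-diagonal row and column are entirely zero are pruned (a self-loop alone
does not rescue a node — it relates the symptom to nothing else); pruning
iterates to a fixed point. For every retained edge the plain lag-1 Pearson
correlation over the same pair set is tabulated, because a near-zero
partial weight can coexist with a substantial bivariate relation when
predictors share variance.

## Centrality

Conventions, chosen to match standard weighted-network practice:

- Out-strength / in-strength: Σ|W| over the row / column, diagonal
  excluded.
- Betweenness: directed, weighted, edge traversal cost 1/|w|, shortest
  paths by Dijkstra, fractional (Brandes) credit over co-minimal paths,
  endpoints excluded, self-loops ignored.
- Signs are dropped throughout (a strong negative edge transmits as much
  "information" as a positive one); the self-loop is reported separately as
  persistence (default threshold |w| ≥ 0.3, configurable).
- z-scores use the sample SD (n − 1) across the retained nodes; a constant
  column yields z = 0 with a warning.

These conventions are cross-checked in the test suite against brute-force
path enumeration and against python-igraph.

## Community detection

Direction is collapsed by symmetrizing (W + Wᵀ)/2 — community structure is
conventionally defined for undirected graphs — and the diagonal is
ignored. The signed spin-glass objective rewards within-community positive
weight above its configuration-model expectation and penalizes
within-community negative weight, with separate resolution parameters γ⁺,
γ⁻ (both default 1). Minimization is simulated annealing: geometric
cooling 1.0 → 0.01 with factor 0.99, 50·p single-node Metropolis moves per
temperature, 20 restarts by default keeping the lowest-energy assignment;
every random draw derives from the user seed, so results are
bit-reproducible. Disconnected graphs are partitioned per weakly connected
component (null terms computed within each component, which keeps the
reported Hamiltonian equal to its recomputation from the membership), and
community ids are relabeled contiguously from 0.

Partitions are scored by signed directed modularity Q = Q⁺ − Q⁻, each
class normalized by its own total weight; Q ∈ [−1, 1], an empty class
contributes 0. Note that some community-detection software prints an
*unnormalized* objective on an arbitrary scale, so modularity magnitudes
are not comparable across implementations — only the sign and relative
ordering are. We report both the normalized Q and the raw Hamiltonian.

## Synthetic generator

`simulate` draws y_t = trend(t) + Aᵀ·(y_{t−1} − trend(t−1)) + ε_t with
Gaussian innovations, a 100-step burn-in, and whole days masked i.i.d.
(optionally in blocks) with a given probability; the spectral radius of A
must be < 1. Because the trend enters the mean only, the ground-truth A is
unaffected, letting detrending and estimation be validated jointly. The
diary-shaped preset uses p = 22, a 122-day span, missingness 0.26
(expected ≈ 90 observed days), five items with quadratic week-time trends,
24 planted cross-effects of |a| = 0.35 with ~30% negative, and
self-loops of 0.3.

What it does **not** emulate: bounded ordinal response scales (values are
Gaussian), floor effects, reactive measurement, weekday cycles,
missingness correlated with symptom severity, and time-varying dynamics.
Passing recovery tests on this generator therefore show the estimator
works when its assumptions hold, not that those assumptions hold in any
given diary.

## Problem sizes and numerical choices

- Monte-Carlo experiments: support recovery at p = 6, 8 planted effects,
  200 pairs, 100 replicates; null sparsity at p = 22, 89 pairs,
  50 replicates; detrend selectivity at n = 90, 200 replicates. These sizes
  mirror the data regime the method targets while keeping a full run of the
  suite and the acceptance script in the tens of seconds.
- Exact-fit guard: ln(RSS) is floored at 1e-300; criteria with
  non-positive small-sample denominators are +∞.
- The annealing inner loop is JIT-compiled with numba when available, with
  an identical pure-Python fallback (results are bit-identical either way
  since all random draws are pre-generated).
- Plot assertions use exported layout/edge metadata (positions, colors,
  widths), not rendered pixels; layouts are Fruchterman–Reingold with |w|
  attraction and a fixed seed.

## Known limitations

- Standard errors / confidence intervals for edges are not provided;
  regularized estimates have no straightforward sampling distribution and
  bootstrapping a single short series is out of scope.
- The AICc-tuned LASSO is liberal at large n (see above).
- No contemporaneous (lag-0) network, no multi-day lags, no imputation of
  missing days, and no population-level (multilevel) pooling.
- Community detection on a sparse ~20-node network is low-powered; the
  spin-glass result should be read qualitatively (cohesive structure or
  not), not as a precise partition.
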