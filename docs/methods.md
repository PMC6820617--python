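# Methods

## The assay and its data

A Random Impact Test (RIT) shakes a batch of dry, unopened pods (protocol: 20
pods, in triplicate per genotype) together with steel balls in fixed-length
intervals of 8 s. After each interval the operator counts the pods that have
not yet released any seed. The record for one assay is therefore a
non-increasing, right-continuous step series of intact counts on the grid
t = 0, 8, 16, … s. Pods still intact when the operator stops leave a
right-truncated series; the reader accepts these with a warning since the fit
does not require a terminal zero.

## Model

The intact count is modelled as an exponential decay,

    count(t) = A · exp(−b · t),

with intercept `A` (in pod-count units; expected near the starting number N₀)
and decay rate `b` (1/s). Both parameters are estimated by unweighted
nonlinear least squares on the counts, including the time-zero anchor
(0, N₀): the intercept is estimated, not fixed, so a drift of `A` away from
N₀ is visible as a diagnostic. `b ≥ 0` is enforced by a bounded trust-region
solver (a negative decay rate is physically meaningless here); fits are
initialized from an ordinary least-squares line through the log-counts
(zero counts excluded there, retained in the nonlinear fit) and restarted
from jittered starting values only if the optimizer fails.

The resistance summary is the RIT₅₀ half-life: the time at which half the
*initial* pods have shattered on the fitted curve,

    RIT₅₀ = ln(2A / N₀) / b,

which reduces to ln 2 / b when A = N₀. The `fitted` variant (half of A rather
than of N₀, i.e. exactly ln 2 / b) is exposed as an option for sensitivity
analysis; the two differ only when the fitted intercept drifts from N₀.

## Error propagation

The RIT₅₀ standard error is first-order error propagation (delta method)
through the parameter covariance: with gradient
g = (∂t₅₀/∂A, ∂t₅₀/∂b) = (1/(Ab), −t₅₀/b), se² = gᵀ Σ_θ g, and a
normal-quantile interval truncated below at 0 (default level 0.95).

The choice of Σ_θ matters more than it may look. The textbook nonlinear-LS
covariance — residual variance times the inverse Gauss–Newton normal matrix —
assumes independent errors. RIT counts at successive inspections are the
*same* pods re-counted, so the errors are strongly serially correlated, and
the iid formula understates the RIT₅₀ variance several-fold at protocol size
(20 pods): in simulation its 95% intervals cover the truth barely a quarter
of the time. The default covariance is therefore the sandwich

    Σ_θ = (JᵀJ)⁻¹ Jᵀ Σ_y J (JᵀJ)⁻¹,

where Σ_y is the covariance of an empirical survival count of N₀ independent
pods evaluated on the fitted curve: for inspection times s ≤ t with survival
fractions S(s) ≥ S(t), cov = N₀ · S(t)(1 − S(s)), with
S(t) = min(1, (A/N₀)e^(−bt)) and zero variance at the deterministic time-zero
anchor. This is the honest propagation of errors for the assay's observation
process; the iid formula remains available as `FitOptions(cov_method="iid")`
for comparison. A parametric bootstrap (simulate from the fitted curve with
the same per-pod observation model, refit, take the SD and percentile
interval of the bootstrap RIT₅₀ distribution) serves as an independent check;
in simulation the median delta-to-bootstrap SE ratio is ≈ 1.0.

## Genotype comparison

Replicate RIT₅₀ values (typically 3 per genotype) are summarized as mean ±
standard error of the mean. Mutants are compared to the wild-type reference
by a two-sided Welch unequal-variance t-test on the replicate half-lives
(default), with significance stars at strict thresholds *** p < 0.001,
** p < 0.01, * p < 0.05. Fold change is the ratio of genotype mean to
reference mean. Because Welch at triplicate level has roughly 2 degrees of
freedom, its power is intrinsically limited; a z-test combining the
delta-method SEs of the individual fits is provided as the alternative
(`method="ztest"`) and is the better-powered choice when replication is
minimal but each fit is precise. No multiple-testing correction is applied to
the starred p-values (matching the per-genotype annotation convention), but a
Holm-adjusted column is always emitted alongside in the ranked report.

## Simulator

The simulator draws an independent break-time per pod — exponential with rate
`b` by default, so the fitted decay law is the exact mean curve and recovery
experiments are well-specified — and observes the counts pathwise on the
protocol grid (default 20 pods, 8-s intervals, 15 intervals, triplicates).
Pathwise generation (not independent binomials per timepoint) reproduces the
serial correlation of a real assay, which is exactly the feature that makes
the iid covariance fail. All randomness flows from a single integer seed;
per-replicate streams are derived deterministically from
(seed, genotype, replicate) so datasets are byte-identical across runs. A
Weibull shape parameter probes misspecification: shape > 1 creates a lag
phase before breakage begins.

What the simulator does not emulate: operator miscounts, humidity drift
between intervals, batch effects across replicate days, or any lag phase by
default. Passing recovery tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to those field effects.

## Numerical choices and problem sizes

- Optimizer tolerances 1e-12 (xtol/ftol/gtol), up to 3 jittered restarts on
  failure; degenerate inputs (no decay, < 3 points, < 2 distinct positive
  times) raise explicit errors rather than returning silent garbage.
- The brute-force validation oracle is a zooming dense grid search over
  A ∈ [1, 40], b ∈ [0.001, 1], 201 A-points × 801 b-points per stage,
  5 stages; b is sampled 4× more densely because the RSS valley runs along
  A*(b).
- Validation experiment sizes: 1000 simulations for bias/RMSE/coverage,
  100 assays × 500 resamples for the bootstrap cross-check, 200 repetitions
  for the two-genotype fold-change pipeline. These sizes give Monte-Carlo
  error comfortably below the quantities being checked.
- Confidence level defaults to 0.95 throughout.

## Known limitations

- The least-squares fit is not the interval-censored maximum-likelihood
  estimator; for 20 pods the efficiency loss is modest (RMSE within ~15% of
  the ln2/b · n^(−1/2) information bound in simulation) but an MLE would be
  the natural extension.
- Delta-method intervals are symmetric on the time scale and can truncate at
  0 for fast-shattering genotypes; the bootstrap percentile interval is the
  fallback there.
- Welch at n = 3 replicates is conservative; see the z-test alternative
  above.
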