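"""Exponential-decay fitting and RIT50 half-life estimation for one assay.

The intact-pod count during a Random Impact Test is modelled as

    count(t) = A * exp(-b * t)

where ``A`` is the intercept (expected to sit near the starting number of pods)
and ``b`` is the decay rate in 1/s. The RIT50 half-life is the time at which
half the *initial* pods have shattered, read off the fitted curve:

    rit50 = ln(2 A / N0) / b        (N0 = initial pod count)

which reduces to the familiar ln(2)/b when the fitted intercept equals N0.
Standard errors on the half-life come from first-order error propagation (the
delta method) through the parameter covariance of the least-squares fit; a
parametric bootstrap is provided as an independent check on those intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .errors import (
    BootstrapUnstableError,
    DegenerateFitError,
    HalfLifeUndefinedError,
    InitializationError,
)
from .io import RITAssay, RITObservation

_B_FLOOR = 1e-9  # smallest admissible decay rate for initialization


@dataclass(frozen=True)
class FitOptions:
    """Tunables for the nonlinear least-squares fit.

    ``half_life_definition`` selects what "half" refers to: ``"initial_count"``
    (default; half of the protocol's starting pod number N0) or ``"fitted"``
    (half of the fitted intercept A, the pure ln2/b variant, useful for
    sensitivity analysis when A drifts from N0).
    """

    tol: float = 1e-12
    max_iter: int = 200
    n_restarts: int = 3
    half_life_definition: str = "initial_count"
    level: float = 0.95
    cov_method: str = "binomial"  # "binomial" (sandwich) or "iid"


@dataclass(frozen=True)
class DecayFit:
    """Least-squares estimates of (A, b) with their large-sample covariance."""

    A_hat: float
    b_hat: float
    cov: np.ndarray  # 2x2, order (A, b)
    rss: float
    n_obs: int
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.A_hat * np.exp(-self.b_hat * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class HalfLifeEstimate:
    """RIT50 point estimate with delta-method SE and confidence interval."""

    rit50_s: float
    se_s: float
    ci_low_s: float
    ci_high_s: float
    level: float
    genotype: str = ""
    replicate_id: str = ""


def loglinear_init(assay: RITAssay) -> tuple[float, float]:
    """Starting values from OLS of log-counts on time, over positive counts only.

    Zero counts are excluded (log undefined); the slope is floored so the
    returned rate is strictly positive.
    """
    t, y = assay.times, assay.counts
    mask = y > 0
    if mask.sum() < 2:
        raise InitializationError(
            f"need at least 2 positive counts for initialization, got {int(mask.sum())}"
        )
    slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
    return float(np.exp(intercept)), float(max(-slope, _B_FLOOR))


def _check_fit_preconditions(assay: RITAssay) -> tuple[np.ndarray, np.ndarray]:
    t, y = assay.times, assay.counts
    if len(t) < 3:
        raise DegenerateFitError(f"need >= 3 observations, got {len(t)}")
    if len(np.unique(t[t > 0])) < 2:
        raise DegenerateFitError("need at least 2 distinct positive times")
    if np.all(y >= assay.initial_count):
        raise DegenerateFitError("rate not identifiable: no decay observed")
    if not np.any((y > 0) & (y < assay.initial_count)):
        raise DegenerateFitError(
            "rate poorly identifiable: no count strictly between 0 and initial_count"
        )
    return t, y


def _inv(m: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(m)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(m)


def _covariance(
    t: np.ndarray,
    residuals: np.ndarray,
    A: float,
    b: float,
    n0: int,
    method: str,
) -> np.ndarray:
    """Large-sample covariance of (A_hat, b_hat) at the optimum.

    ``method="iid"`` is the textbook nonlinear-LS formula: residual variance
    times the inverse Gauss-Newton normal matrix. It assumes independent
    homoscedastic errors — but RIT counts at successive inspections are the
    *same* pods re-counted, so their errors are strongly positively
    correlated and the iid formula understates the parameter variance
    severalfold.

    ``method="binomial"`` (default) is the sandwich estimator
    ``(J'J)^-1 J' S J (J'J)^-1`` with S the covariance of an empirical
    survival count of n0 pods evaluated on the fitted curve:
    ``S[s,t] = n0 * S(max) * (1 - S(min))`` for survival fraction
    ``S(t) = min(1, (A/n0) exp(-b t))``. The time-zero anchor is
    deterministic (all pods intact by protocol) and gets zero variance.
    """
    e = np.exp(-b * t)
    J = np.column_stack([e, -A * t * e])  # d model / d(A, b)
    n, p = len(t), 2
    bread = _inv(J.T @ J)
    if method == "iid":
        rss = float(residuals @ residuals)
        sigma2 = rss / (n - p) if n > p else np.inf
        cov = sigma2 * bread
    elif method == "binomial":
        surv = np.minimum(1.0, (A / n0) * e)
        s_min = np.minimum.outer(surv, surv)  # S at the later time (S decreasing)
        s_max = np.maximum.outer(surv, surv)  # S at the earlier time
        meat_obs = n0 * s_min * (1.0 - s_max)
        zero = t == 0
        meat_obs[zero, :] = 0.0
        meat_obs[:, zero] = 0.0
        cov = bread @ (J.T @ meat_obs @ J) @ bread
    else:
        raise ValueError(f"unknown cov_method {method!r}")
    return 0.5 * (cov + cov.T)


def fit_decay(assay: RITAssay, options: FitOptions | None = None) -> DecayFit:
    """Fit count = A exp(-b t) by unweighted nonlinear least squares.

    The optimizer is a bounded trust-region least-squares solver keeping both
    parameters non-negative; it is initialized from :func:`loglinear_init` and
    restarted from jittered starts on failure. Zero counts are retained (they
    are informative about the tail). The parameter covariance follows
    ``options.cov_method`` — see :func:`_covariance`; the default accounts for
    the serial correlation of re-counting the same pods.
    """
    opts = options or FitOptions()
    t, y = _check_fit_preconditions(assay)

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-p[1] * t) - y

    def jac(p: np.ndarray) -> np.ndarray:
        e = np.exp(-p[1] * t)
        return np.column_stack([e, -p[0] * t * e])

    try:
        A0, b0 = loglinear_init(assay)
    except InitializationError:
        A0, b0 = float(assay.initial_count), math.log(2) / max(t.max() / 2, 1.0)
    A0 = min(max(A0, 1e-6), 10 * assay.initial_count)

    rng = np.random.default_rng(0)  # jitter only; fit itself is deterministic
    best = None
    for attempt in range(opts.n_restarts + 1):
        if attempt == 0:
            p0 = np.array([A0, b0])
        else:
            p0 = np.array([A0, b0]) * np.exp(rng.normal(0, 0.5, size=2))
        p0 = np.maximum(p0, [1e-6, _B_FLOOR])
        try:
            sol = optimize.least_squares(
                resid,
                p0,
                jac=jac,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                xtol=opts.tol,
                ftol=opts.tol,
                gtol=opts.tol,
                max_nfev=opts.max_iter * 10,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[1]:
            best = (sol, rss)
        break  # restarts are for optimizer failure only
    if best is None:
        return DecayFit(np.nan, np.nan, np.full((2, 2), np.nan), np.nan, len(t), False)
    sol, rss = best
    A_hat, b_hat = float(sol.x[0]), float(sol.x[1])
    cov = _covariance(t, sol.fun, A_hat, b_hat, assay.initial_count, opts.cov_method)
    return DecayFit(A_hat, b_hat, cov, rss, len(t), True)


def half_life(
    fit: DecayFit,
    initial_count: int,
    *,
    level: float = 0.95,
    definition: str = "initial_count",
    genotype: str = "",
    replicate_id: str = "",
) -> HalfLifeEstimate:
    """Half-life of the fitted decay with a delta-method confidence interval.

    With ``definition="initial_count"`` the estimate solves
    ``A exp(-b t) = N0/2``; the delta-method gradient is
    ``(dt/dA, dt/db) = (1/(A b), -t/b)``. With ``definition="fitted"`` the
    target is ``A/2`` so the estimate is ``ln 2 / b`` and ``dt/dA = 0``.
    The normal-quantile interval is truncated below at 0.
    """
    if not fit.converged or not np.isfinite(fit.b_hat):
        raise HalfLifeUndefinedError("fit did not converge")
    if fit.b_hat <= 0:
        raise HalfLifeUndefinedError("decay rate is zero: half-life undefined")
    A, b = fit.A_hat, fit.b_hat
    if definition == "fitted":
        t50 = math.log(2) / b
        g = np.array([0.0, -t50 / b])
    elif definition == "initial_count":
        ratio = 2.0 * A / initial_count
        if ratio <= 1.0:
            raise HalfLifeUndefinedError(
                f"fitted curve (A={A:.4g}) never reaches initial_count/2 = {initial_count / 2}"
            )
        t50 = math.log(ratio) / b
        g = np.array([1.0 / (A * b), -t50 / b])
    else:
        raise ValueError(f"unknown half-life definition {definition!r}")
    var = float(g @ fit.cov @ g)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return HalfLifeEstimate(
        rit50_s=t50,
        se_s=se,
        ci_low_s=max(t50 - z * se, 0.0),
        ci_high_s=t50 + z * se,
        level=level,
        genotype=genotype,
        replicate_id=replicate_id,
    )


def estimate_assay(
    assay: RITAssay, options: FitOptions | None = None
) -> tuple[DecayFit, HalfLifeEstimate]:
    """Convenience: fit an assay and derive its half-life in one call."""
    opts = options or FitOptions()
    fit = fit_decay(assay, opts)
    est = half_life(
        fit,
        assay.initial_count,
        level=opts.level,
        definition=opts.half_life_definition,
        genotype=assay.genotype,
        replicate_id=assay.replicate_id,
    )
    return fit, est


def _simulate_from_fit(
    assay: RITAssay, fit: DecayFit, rng: np.random.Generator
) -> RITAssay:
    """One parametric-bootstrap assay: per-pod break-times drawn so the intact
    count has survival curve min(1, (A/N0) exp(-b t)), observed on the assay's
    positive grid times with the (0, N0) anchor."""
    n0 = assay.initial_count
    u = rng.uniform(size=n0)
    # Invert S(t) = (A/N0) exp(-b t): break-time = ln(A/(N0 u))/b, clipped at 0.
    with np.errstate(divide="ignore"):
        break_times = np.log(fit.A_hat / (n0 * u)) / fit.b_hat
    break_times = np.maximum(break_times, 0.0)
    times = assay.times
    obs = [RITObservation(0.0, n0)]
    for t in times[times > 0]:
        obs.append(RITObservation(float(t), int(np.sum(break_times > t))))
    return RITAssay(
        genotype=assay.genotype,
        replicate_id=assay.replicate_id,
        observations=obs,
        initial_count=n0,
        interval_s=assay.interval_s,
    )


def bootstrap_half_life(
    assay: RITAssay,
    fit: DecayFit,
    *,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
    definition: str = "initial_count",
    options: FitOptions | None = None,
) -> tuple[float, float, float]:
    """Parametric-bootstrap SE and percentile CI for the half-life.

    Simulates ``n_boot`` assays from the fitted curve with the binomial
    observation model on the assay's own grid, refits each, and summarizes the
    bootstrap half-life distribution. Raises
    :class:`~ritfit.errors.BootstrapUnstableError` when more than 20% of refits
    fail. Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    if not fit.converged:
        raise HalfLifeUndefinedError("cannot bootstrap a non-converged fit")
    opts = options or FitOptions()
    rng = np.random.default_rng(seed)
    draws = []
    failed = 0
    for _ in range(n_boot):
        sim = _simulate_from_fit(assay, fit, rng)
        try:
            bfit = fit_decay(sim, opts)
            est = half_life(bfit, sim.initial_count, level=level, definition=definition)
        except Exception:
            failed += 1
            continue
        draws.append(est.rit50_s)
    if failed > 0.2 * n_boot:
        raise BootstrapUnstableError(
            f"{failed}/{n_boot} bootstrap refits failed to converge"
        )
    draws_arr = np.array(draws)
    se = float(np.std(draws_arr, ddof=1))
    alpha = 1.0 - level
    lo, hi = np.quantile(draws_arr, [alpha / 2, 1 - alpha / 2])
    return se, float(lo), float(hi)


class GridFitResult(NamedTuple):
    """Result of the brute-force grid search: best lattice point and final steps."""

    A_hat: float
    b_hat: float
    rss: float
    A_step: float
    b_step: float


def grid_search_fit(
    assay: RITAssay,
    *,
    A_range: tuple[float, float] = (1.0, 40.0),
    b_range: tuple[float, float] = (0.001, 1.0),
    n_grid: int = 201,
    n_refine: int = 5,
) -> GridFitResult:
    """Brute-force dense grid-search least squares, as an independent oracle.

    Evaluates the exact RSS surface on a lattice and zooms ``n_refine`` times
    around the minimum. Deliberately avoids any gradient machinery so it
    cross-checks the trust-region fit. The b axis is sampled 4x more densely
    than A: the RSS valley runs along A*(b), which moves by many A-steps per
    b-step, so a square lattice would let the argmin drift sideways.
    """
    t, y = assay.times, assay.counts
    (a_lo, a_hi), (b_lo, b_hi) = A_range, b_range
    n_grid_b = 4 * (n_grid - 1) + 1
    best = (np.nan, np.nan, np.inf)
    a_step = b_step = np.nan
    for _ in range(n_refine):
        A = np.linspace(a_lo, a_hi, n_grid)
        b = np.linspace(b_lo, b_hi, n_grid_b)
        # rss[i, j] for (A[i], b[j]) via broadcasting
        curves = np.exp(-b[:, None] * t[None, :])  # (n_grid, n_t)
        # residual: A[i] * curves[j] - y  -> compute as quadratic in A
        s_cc = (curves * curves).sum(axis=1)  # (n_grid,)
        s_cy = (curves * y).sum(axis=1)
        s_yy = float(y @ y)
        rss = A[:, None] ** 2 * s_cc[None, :] - 2 * A[:, None] * s_cy[None, :] + s_yy
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        if rss[i, j] < best[2]:
            best = (float(A[i]), float(b[j]), float(rss[i, j]))
        # zoom: shrink each axis around the minimum to a quarter of its width
        a_step = (a_hi - a_lo) / (n_grid - 1)
        b_step = (b_hi - b_lo) / (n_grid_b - 1)
        half_a = max((a_hi - a_lo) / 8, 2 * a_step)
        half_b = max((b_hi - b_lo) / 8, 2 * b_step)
        a_lo, a_hi = best[0] - half_a, best[0] + half_a
        b_lo, b_hi = max(best[1] - half_b, 1e-12), best[1] + half_b
    return GridFitResult(best[0], best[1], best[2], a_step, b_step)
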