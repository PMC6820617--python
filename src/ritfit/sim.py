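"""Stochastic Random Impact Test simulator.

Each pod draws an independent break-time; the assay observes, on a regular
interval grid, how many pods have not yet broken. With exponential break-times
(the default) the expected intact count is exactly ``n_pods * exp(-b t)``, so
the fitted decay law is the true mean curve and parameter-recovery experiments
are well-specified. Counts are generated pathwise per pod — the same pods are
re-inspected after every interval — so counts are monotone non-increasing
within an assay, as in a real bench sheet. The marginal count at time t is
Binomial(n_pods, exp(-b t)).

A Weibull break-time hook (``shape != 1``) probes model misspecification:
shape > 1 produces a lag phase (little breakage in early intervals), shape < 1
front-loads breakage.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .decay import FitOptions, estimate_assay
from .errors import UsageError
from .io import RITAssay, RITDataset, RITObservation

PROTOCOL_N_PODS = 20
PROTOCOL_INTERVAL_S = 8.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one genotype's synthetic assays.

    ``true_b`` is the per-pod hazard in 1/s; the true half-life of the intact
    fraction is ln(2)/true_b. ``n_intervals`` is the number of shaking
    intervals, so the observation grid is 0, interval_s, ..., n_intervals *
    interval_s (n_intervals + 1 inspections including the time-zero count).
    Pods still intact at the last inspection stay as a right-truncated tail.
    """

    true_b: float
    genotype: str = "simulated"
    n_pods: int = PROTOCOL_N_PODS
    interval_s: float = PROTOCOL_INTERVAL_S
    n_intervals: int = 15
    n_reps: int = 3
    seed: int = 0
    weibull_shape: float = 1.0  # 1 = exponential break-times

    def __post_init__(self):
        if self.n_pods < 1:
            raise ValueError(f"n_pods must be >= 1, got {self.n_pods}")
        if not self.true_b > 0:
            raise ValueError(f"true_b must be positive, got {self.true_b}")
        if not self.interval_s > 0:
            raise ValueError(f"interval_s must be positive, got {self.interval_s}")
        if self.n_intervals < 2:
            raise ValueError(f"n_intervals must be >= 2, got {self.n_intervals}")
        if not self.weibull_shape > 0:
            raise ValueError(f"weibull_shape must be positive, got {self.weibull_shape}")

    @property
    def true_half_life_s(self) -> float:
        return math.log(2) / self.true_b

    @classmethod
    def from_half_life(cls, true_half_life_s: float, **kwargs) -> "SimConfig":
        """Build a config from the target half-life instead of the rate."""
        return cls(true_b=math.log(2) / true_half_life_s, **kwargs)

    @property
    def grid(self) -> np.ndarray:
        return self.interval_s * np.arange(self.n_intervals + 1, dtype=float)


def _sub_seed(seed: int, *labels: str) -> np.random.SeedSequence:
    """Deterministic per-(genotype, replicate) seed stream, stable across runs."""
    return np.random.SeedSequence([seed] + [zlib.crc32(s.encode("utf-8")) for s in labels])


def _draw_break_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.weibull_shape == 1.0:
        return rng.exponential(1.0 / config.true_b, size=config.n_pods)
    # S(t) = exp(-(true_b * t)^shape): same half-life scaling family
    return rng.weibull(config.weibull_shape, size=config.n_pods) / config.true_b


def simulate_assay(config: SimConfig, replicate_id: str = "r1") -> RITAssay:
    """Generate one assay: per-pod break-times observed as intact counts on the grid.

    Deterministic given ``(config.seed, config.genotype, replicate_id)``.
    """
    rng = np.random.default_rng(_sub_seed(config.seed, config.genotype, replicate_id))
    break_times = _draw_break_times(config, rng)
    obs = [
        RITObservation(float(t), int(np.sum(break_times > t))) for t in config.grid
    ]
    return RITAssay(
        genotype=config.genotype,
        replicate_id=replicate_id,
        observations=obs,
        initial_count=config.n_pods,
        interval_s=config.interval_s,
    )


def simulate_dataset(configs: list[SimConfig], reference: str | None = None) -> RITDataset:
    """Simulate ``n_reps`` assays per config into one dataset (replicates r1..rn)."""
    labels = [c.genotype for c in configs]
    if len(set(labels)) != len(labels):
        raise UsageError(f"duplicate genotype labels in configs: {labels}")
    if reference is not None and reference not in labels:
        raise UsageError(f"reference {reference!r} not among genotypes {labels}")
    assays = [
        simulate_assay(c, f"r{i + 1}") for c in configs for i in range(c.n_reps)
    ]
    return RITDataset(assays, reference_genotype=reference)


@dataclass(frozen=True)
class RecoveryReport:
    """Bias/RMSE/coverage of the half-life estimator under a known truth."""

    true_half_life_s: float
    n_sims: int
    n_converged: int
    bias_s: float
    rmse_s: float
    coverage: float
    level: float
    mean_rit50_s: float
    frac_nonconverged: float
    estimates: np.ndarray = field(repr=False, compare=False, default=None)


def recovery_experiment(
    config: SimConfig,
    n_sims: int = 1000,
    level: float = 0.95,
    *,
    fit_options: FitOptions | None = None,
) -> RecoveryReport:
    """Repeat simulate -> fit -> half-life ``n_sims`` times against the known truth.

    Reports bias and RMSE of the RIT50 estimate relative to ln(2)/true_b, the
    empirical coverage of the delta-method CI at ``level`` (among converged
    fits), and the fraction of simulations where the fit or half-life failed.
    """
    if n_sims < 100:
        raise ValueError(f"n_sims must be >= 100, got {n_sims}")
    opts = fit_options or FitOptions(level=level)
    truth = config.true_half_life_s
    estimates, covered = [], 0
    failed = 0
    for i in range(n_sims):
        assay = simulate_assay(replace(config, seed=config.seed), f"sim{i}")
        try:
            _, est = estimate_assay(assay, opts)
        except Exception:
            failed += 1
            continue
        estimates.append(est.rit50_s)
        if est.ci_low_s <= truth <= est.ci_high_s:
            covered += 1
    est_arr = np.array(estimates)
    n_ok = len(est_arr)
    return RecoveryReport(
        true_half_life_s=truth,
        n_sims=n_sims,
        n_converged=n_ok,
        bias_s=float(est_arr.mean() - truth) if n_ok else np.nan,
        rmse_s=float(np.sqrt(np.mean((est_arr - truth) ** 2))) if n_ok else np.nan,
        coverage=covered / n_ok if n_ok else np.nan,
        level=level,
        mean_rit50_s=float(est_arr.mean()) if n_ok else np.nan,
        frac_nonconverged=failed / n_sims,
        estimates=est_arr,
    )
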