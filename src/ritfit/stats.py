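"""Replicate aggregation and genotype-vs-wild-type comparison of RIT50 values.

Replicate half-lives (typically triplicates, i.e. 60 pods per genotype) are
summarized as mean +/- standard error. Mutant genotypes are compared to the
wild-type reference with a two-sided Welch unequal-variance t-test on the
replicate half-lives; fold change is the ratio of genotype mean to reference
mean. Significance stars follow the usual convention with strict thresholds:
*** p < 0.001, ** p < 0.01, * p < 0.05. No multiple-testing correction is
applied to the starred p-values, but a Holm-adjusted column is reported
alongside in the ranked table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decay import HalfLifeEstimate
from .errors import InsufficientReplicationError, UsageError


@dataclass(frozen=True)
class GenotypeSummary:
    """Per-genotype mean RIT50, standard error of the mean, replicate count."""

    genotype: str
    mean_rit50_s: float
    se_s: float
    n_reps: int
    single_replicate: bool = False  # se_s = 0 by convention; flagged


@dataclass(frozen=True)
class ComparisonResult:
    """One genotype tested against the wild-type reference."""

    genotype: str
    reference: str
    diff_s: float
    fold_change: float
    p_value: float
    stars: str
    t_stat: float = math.nan
    df: float = math.nan


def significance_stars(p: float) -> str:
    """Map a p-value to the star annotation (strict thresholds)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_genotype(estimates: list[HalfLifeEstimate]) -> GenotypeSummary:
    """Mean and SE of replicate half-lives for one genotype.

    A single replicate yields se_s = 0 with the ``single_replicate`` flag set
    and a warning, since no dispersion can be estimated.
    """
    if not estimates:
        raise UsageError("no estimates to summarize")
    genotypes = {e.genotype for e in estimates}
    if len(genotypes) > 1:
        raise UsageError(f"mixed genotypes in summary: {sorted(genotypes)}")
    values = np.array([e.rit50_s for e in estimates])
    n = len(values)
    if n == 1:
        warnings.warn(
            f"genotype {estimates[0].genotype!r} has a single replicate; se set to 0",
            stacklevel=2,
        )
        return GenotypeSummary(estimates[0].genotype, float(values[0]), 0.0, 1, True)
    return GenotypeSummary(
        genotype=estimates[0].genotype,
        mean_rit50_s=float(values.mean()),
        se_s=float(values.std(ddof=1) / math.sqrt(n)),
        n_reps=n,
    )


def _welch(test: np.ndarray, reference: np.ndarray) -> tuple[float, float, float]:
    res = sps.ttest_ind(test, reference, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def _ztest_delta(
    test_ses: list[float], ref_ses: list[float], diff: float
) -> tuple[float, float, float]:
    """z-test using delta-method SEs of the individual replicate estimates.

    The SE of each group mean is sqrt(sum se_i^2)/n; the test statistic is
    diff over the combined SE, referred to a standard normal.
    """
    se_t = math.sqrt(sum(s**2 for s in test_ses)) / len(test_ses)
    se_r = math.sqrt(sum(s**2 for s in ref_ses)) / len(ref_ses)
    se = math.hypot(se_t, se_r)
    z = diff / se if se > 0 else math.inf * np.sign(diff) if diff else 0.0
    p = 2 * sps.norm.sf(abs(z))
    return z, float(p), math.inf


def compare_genotypes(
    test_values: list[float],
    reference_values: list[float],
    *,
    test_label: str,
    reference_label: str,
    method: str = "welch",
    test_ses: list[float] | None = None,
    reference_ses: list[float] | None = None,
) -> ComparisonResult:
    """Two-sided comparison of replicate RIT50 values against the reference.

    ``method="welch"`` (default) is the unequal-variance t-test on replicate
    half-lives. ``method="ztest"`` instead combines the delta-method SEs of
    the per-replicate estimates (pass ``test_ses``/``reference_ses``) into a
    normal test — useful when replication is minimal but each fit is precise.
    """
    t_arr = np.asarray(test_values, dtype=float)
    r_arr = np.asarray(reference_values, dtype=float)
    if len(t_arr) < 2 or len(r_arr) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 replicates per group, got {len(t_arr)} vs {len(r_arr)}"
        )
    diff = float(t_arr.mean() - r_arr.mean())
    fold = float(t_arr.mean() / r_arr.mean())
    if np.array_equal(t_arr, r_arr) or (t_arr.std() == 0 and r_arr.std() == 0 and diff == 0):
        stat, p, df = 0.0, 1.0, float(len(t_arr) + len(r_arr) - 2)
    elif method == "welch":
        stat, p, df = _welch(t_arr, r_arr)
    elif method == "ztest":
        if test_ses is None or reference_ses is None:
            raise UsageError("method='ztest' needs test_ses and reference_ses")
        stat, p, df = _ztest_delta(test_ses, reference_ses, diff)
    else:
        raise UsageError(f"unknown comparison method {method!r}")
    return ComparisonResult(
        genotype=test_label,
        reference=reference_label,
        diff_s=diff,
        fold_change=fold,
        p_value=p,
        stars=significance_stars(p),
        t_stat=stat,
        df=df,
    )


def rank_genotypes(
    summaries: list[GenotypeSummary],
    replicate_values: dict[str, list[float]],
    reference: str,
    *,
    method: str = "welch",
    replicate_ses: dict[str, list[float]] | None = None,
) -> pd.DataFrame:
    """Ranked comparison report: genotypes sorted by mean RIT50, most resistant first.

    Each row carries fold change vs the reference, the raw Welch p-value with
    its stars, and a Holm-adjusted p-value across the non-reference genotypes.
    Ties in the mean are broken by genotype label for a stable order. The
    reference row is flagged and carries no p-value.
    """
    labels = [s.genotype for s in summaries]
    if reference not in labels:
        raise UsageError(
            f"reference {reference!r} not among genotypes: {sorted(labels)}"
        )
    ref_summary = next(s for s in summaries if s.genotype == reference)
    ref_vals = replicate_values[reference]
    rows = []
    for s in sorted(summaries, key=lambda s: (-s.mean_rit50_s, s.genotype)):
        row = {
            "genotype": s.genotype,
            "n_reps": s.n_reps,
            "mean_rit50_s": s.mean_rit50_s,
            "se_s": s.se_s,
            "fold_change": s.mean_rit50_s / ref_summary.mean_rit50_s,
            "p_value": np.nan,
            "stars": "",
            "is_reference": s.genotype == reference,
        }
        if s.genotype != reference:
            try:
                cmp = compare_genotypes(
                    replicate_values[s.genotype],
                    ref_vals,
                    test_label=s.genotype,
                    reference_label=reference,
                    method=method,
                    test_ses=(replicate_ses or {}).get(s.genotype),
                    reference_ses=(replicate_ses or {}).get(reference),
                )
                row["p_value"] = cmp.p_value
                row["stars"] = cmp.stars
            except InsufficientReplicationError:
                pass  # summary still reported, no p-value
        rows.append(row)
    df = pd.DataFrame(rows)
    mask = df["p_value"].notna() & ~df["is_reference"]
    df["p_holm"] = np.nan
    if mask.any():
        df.loc[mask, "p_holm"] = multipletests(df.loc[mask, "p_value"], method="holm")[1]
    return df[
        ["genotype", "n_reps", "mean_rit50_s", "se_s", "fold_change",
         "p_value", "p_holm", "stars", "is_reference"]
    ]
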