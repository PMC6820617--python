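"""End-to-end helpers chaining fit -> summarize -> compare over a dataset."""

from __future__ import annotations

import pandas as pd

from .decay import DecayFit, FitOptions, HalfLifeEstimate, estimate_assay
from .errors import RitfitError
from .io import RITDataset
from .stats import GenotypeSummary, rank_genotypes, summarize_genotype


def fit_dataset(
    dataset: RITDataset, options: FitOptions | None = None
) -> tuple[list[HalfLifeEstimate], dict[tuple[str, str], DecayFit], dict[tuple[str, str], str]]:
    """Fit every assay; return half-life estimates, fits, and per-assay failures."""
    opts = options or FitOptions()
    estimates: list[HalfLifeEstimate] = []
    fits: dict[tuple[str, str], DecayFit] = {}
    failures: dict[tuple[str, str], str] = {}
    for assay in dataset.assays:
        key = (assay.genotype, assay.replicate_id)
        try:
            fit, est = estimate_assay(assay, opts)
        except RitfitError as exc:
            failures[key] = str(exc)
            continue
        fits[key] = fit
        estimates.append(est)
    return estimates, fits, failures


def summarize_dataset(estimates: list[HalfLifeEstimate]) -> list[GenotypeSummary]:
    """Group half-life estimates by genotype and summarize each group."""
    order: list[str] = []
    groups: dict[str, list[HalfLifeEstimate]] = {}
    for e in estimates:
        groups.setdefault(e.genotype, []).append(e)
        if e.genotype not in order:
            order.append(e.genotype)
    return [summarize_genotype(groups[g]) for g in order]


def compare_dataset(
    estimates: list[HalfLifeEstimate], reference: str, *, method: str = "welch"
) -> pd.DataFrame:
    """Full comparison report (ranked table with fold changes, p-values, stars)."""
    summaries = summarize_dataset(estimates)
    values = {
        s.genotype: [e.rit50_s for e in estimates if e.genotype == s.genotype]
        for s in summaries
    }
    ses = {
        s.genotype: [e.se_s for e in estimates if e.genotype == s.genotype]
        for s in summaries
    }
    return rank_genotypes(summaries, values, reference, method=method, replicate_ses=ses)
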