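"""Data model, validation, and tabular readers/writers for Random Impact Test assays.

An RIT assay shakes a fixed number of dry pods (protocol default 20) in fixed-length
intervals (protocol default 8 s) and records, after each interval, how many pods are
still intact (have released no seed). The on-disk exchange format is a tidy long
table with one row per inspection::

    genotype,replicate,time_s,intact_count
    Cabriolet,r1,0,20
    Cabriolet,r1,8,13
    ...

Optional columns ``initial_count`` and ``interval_s`` override the protocol defaults
per assay. Comma is the default delimiter; tab is accepted.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, UsageError, ValidationError

REQUIRED_COLUMNS = ("genotype", "replicate", "time_s", "intact_count")

DEFAULT_INITIAL_COUNT = 20
DEFAULT_INTERVAL_S = 8.0


@dataclass(frozen=True)
class RITObservation:
    """A single inspection: cumulative shaking time and the intact-pod count."""

    time_s: float
    intact_count: int


@dataclass
class RITAssay:
    """One assay's intact-count time series with genotype/replicate metadata.

    ``time_zero_synthesized`` is set when the input sheet carried no explicit
    time-zero row and ``(0, initial_count)`` was inserted, which the protocol
    guarantees (all pods are intact before shaking starts).
    """

    genotype: str
    replicate_id: str
    observations: list[RITObservation]
    initial_count: int = DEFAULT_INITIAL_COUNT
    interval_s: float = DEFAULT_INTERVAL_S
    time_zero_synthesized: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_s for o in self.observations], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([o.intact_count for o in self.observations], dtype=float)

    @property
    def right_truncated(self) -> bool:
        """True when the series ends while some pods remain intact."""
        return bool(self.observations) and self.observations[-1].intact_count > 0


@dataclass
class RITDataset:
    """A collection of assays, optionally naming the wild-type reference genotype."""

    assays: list[RITAssay]
    reference_genotype: str | None = None
    validation_findings: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def genotypes(self) -> list[str]:
        seen: list[str] = []
        for a in self.assays:
            if a.genotype not in seen:
                seen.append(a.genotype)
        return seen

    def by_genotype(self, genotype: str) -> list[RITAssay]:
        return [a for a in self.assays if a.genotype == genotype]


def validate_assay(assay: RITAssay) -> list[str]:
    """Check an assay against the data invariants; return findings, never raise.

    The rules: times strictly increasing, counts non-increasing (pods cannot
    un-break), every count within [0, initial_count], and a time-zero count,
    if recorded, equal to the initial count.
    """
    v: list[str] = []
    if assay.initial_count <= 0:
        v.append(f"initial_count must be positive, got {assay.initial_count}")
    if assay.interval_s <= 0:
        v.append(f"interval_s must be positive, got {assay.interval_s}")
    if not assay.observations:
        v.append("assay has no observations")
        return v
    obs = assay.observations
    for o in obs:
        if o.time_s < 0:
            v.append(f"negative time_s {o.time_s}")
        if o.intact_count < 0:
            v.append(f"negative intact_count {o.intact_count} at time {o.time_s}")
        if o.intact_count > assay.initial_count:
            v.append(
                f"intact_count {o.intact_count} at time {o.time_s} exceeds "
                f"initial_count {assay.initial_count}"
            )
    for a, b in zip(obs, obs[1:]):
        if b.time_s == a.time_s:
            v.append(f"duplicate time_s {a.time_s} (counts {a.intact_count}, {b.intact_count})")
        elif b.time_s < a.time_s:
            v.append(f"time_s not increasing: {a.time_s} followed by {b.time_s}")
        if b.intact_count > a.intact_count:
            v.append(
                "non-monotone intact_count: "
                f"{a.intact_count} at time {a.time_s} then {b.intact_count} at time {b.time_s}"
            )
    if obs[0].time_s == 0 and obs[0].intact_count != assay.initial_count:
        v.append(
            f"count at time 0 is {obs[0].intact_count} but initial_count is "
            f"{assay.initial_count}"
        )
    return v


def _ensure_time_zero(assay: RITAssay) -> RITAssay:
    if assay.observations and assay.observations[0].time_s == 0:
        return assay
    assay.observations.insert(0, RITObservation(0.0, assay.initial_count))
    assay.time_zero_synthesized = True
    return assay


def read_rit_table(
    path: str | Path,
    *,
    delimiter: str | None = None,
    reference_genotype: str | None = None,
    on_invalid: str = "raise",
) -> RITDataset:
    """Read a long-format RIT table into a validated :class:`RITDataset`.

    Rows are grouped into assays by ``(genotype, replicate)`` and sorted by time.
    A missing time-zero row is synthesized as ``(0, initial_count)``. Assays whose
    last count is positive (right-truncated) are accepted with a warning.

    Parameters
    ----------
    delimiter:
        ``None`` sniffs comma vs tab from the header line.
    on_invalid:
        ``"raise"`` raises :class:`ValidationError` on the first invalid assay;
        ``"skip"`` drops invalid assays, recording findings on the dataset;
        ``"keep"`` keeps them (findings still recorded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        header = path.read_text(encoding="utf-8").splitlines()
        delimiter = "\t" if header and "\t" in header[0] else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return RITDataset([], reference_genotype)

    def _num(col: str, row: int, value, caster, what: str):
        try:
            out = caster(value)
        except (TypeError, ValueError):
            raise ParseError(f"column {col!r}: cannot parse {value!r} as {what}", row=row + 2)
        return out

    records = []
    for i, row in df.iterrows():
        time_s = _num("time_s", i, row["time_s"], float, "a number")
        count_f = _num("intact_count", i, row["intact_count"], float, "an integer")
        if not float(count_f).is_integer():
            raise ParseError(
                f"column 'intact_count': {row['intact_count']!r} is not an integer", row=i + 2
            )
        rec = {
            "genotype": str(row["genotype"]).strip(),
            "replicate": str(row["replicate"]).strip(),
            "time_s": time_s,
            "intact_count": int(count_f),
        }
        if "initial_count" in df.columns and pd.notna(row.get("initial_count")):
            rec["initial_count"] = int(_num("initial_count", i, row["initial_count"], float, "an integer"))
        if "interval_s" in df.columns and pd.notna(row.get("interval_s")):
            rec["interval_s"] = _num("interval_s", i, row["interval_s"], float, "a number")
        records.append(rec)

    assays: list[RITAssay] = []
    findings: dict[tuple[str, str], list[str]] = {}
    seen: set[tuple[str, str]] = set()
    long = pd.DataFrame(records)
    for (genotype, replicate), grp in long.groupby(["genotype", "replicate"], sort=False):
        key = (genotype, replicate)
        if key in seen:  # groupby merges duplicates; kept for clarity
            raise ValidationError(f"duplicate assay key {key}")
        seen.add(key)
        grp = grp.sort_values("time_s", kind="stable")
        assay = RITAssay(
            genotype=genotype,
            replicate_id=replicate,
            observations=[
                RITObservation(t, c) for t, c in zip(grp["time_s"], grp["intact_count"])
            ],
            initial_count=int(grp["initial_count"].iloc[0]) if "initial_count" in grp else DEFAULT_INITIAL_COUNT,
            interval_s=float(grp["interval_s"].iloc[0]) if "interval_s" in grp else DEFAULT_INTERVAL_S,
        )
        _ensure_time_zero(assay)
        v = validate_assay(assay)
        if v:
            findings[key] = v
            if on_invalid == "raise":
                raise ValidationError(
                    f"assay {genotype}/{replicate}: " + "; ".join(v)
                )
            if on_invalid == "skip":
                continue
        if assay.right_truncated:
            warnings.warn(
                f"assay {genotype}/{replicate} is right-truncated "
                f"(last count {assay.observations[-1].intact_count} > 0)",
                stacklevel=2,
            )
        assays.append(assay)
    ds = RITDataset(assays, reference_genotype)
    ds.validation_findings = findings
    return ds


def dataset_to_frame(dataset: RITDataset) -> pd.DataFrame:
    """Flatten a dataset back to the long table format consumed by the reader."""
    rows = []
    for a in dataset.assays:
        for o in a.observations:
            rows.append(
                {
                    "genotype": a.genotype,
                    "replicate": a.replicate_id,
                    "time_s": o.time_s,
                    "intact_count": o.intact_count,
                    "initial_count": a.initial_count,
                    "interval_s": a.interval_s,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genotype", "replicate", "time_s", "intact_count", "initial_count", "interval_s"],
    )


def write_rit_table(dataset: RITDataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a dataset as a long-format delimited table (UTF-8, header row)."""
    dataset_to_frame(dataset).to_csv(path, sep=delimiter, index=False)


def wide_to_long(df: pd.DataFrame, *, time_columns: list[str] | None = None) -> pd.DataFrame:
    """Convert a bench-sheet-style wide table (one column per timepoint) to long format.

    Wide sheets carry ``genotype`` and ``replicate`` columns plus one numeric-named
    column per cumulative shaking time, e.g. ``0, 8, 16, ...``. Any other columns
    (``initial_count``, ``interval_s``) are carried through.
    """
    df = df.copy()
    df.columns = [str(c).strip() for c in df.columns]
    if time_columns is None:
        time_columns = []
        for c in df.columns:
            try:
                float(c)
            except ValueError:
                continue
            time_columns.append(c)
    if not time_columns:
        raise FormatError("no timepoint columns found in wide table")
    id_cols = [c for c in df.columns if c not in time_columns]
    if "genotype" not in id_cols or "replicate" not in id_cols:
        raise FormatError("wide table needs 'genotype' and 'replicate' columns")
    long = df.melt(id_vars=id_cols, value_vars=time_columns, var_name="time_s", value_name="intact_count")
    long["time_s"] = long["time_s"].astype(float)
    long = long.dropna(subset=["intact_count"])
    long["intact_count"] = long["intact_count"].astype(int)
    front = ["genotype", "replicate", "time_s", "intact_count"]
    return long[front + [c for c in long.columns if c not in front]].sort_values(
        ["genotype", "replicate", "time_s"], kind="stable"
    ).reset_index(drop=True)


# Stable column orders for the result tables; field names map 1:1 onto columns
# except replicate_id -> replicate.
HALF_LIFE_COLUMNS = ["genotype", "replicate", "rit50_s", "se_s", "ci_low_s", "ci_high_s", "level"]
SUMMARY_COLUMNS = ["genotype", "mean_rit50_s", "se_s", "n_reps"]


def _record_row(record) -> dict:
    d = dataclasses.asdict(record)
    if "replicate_id" in d:
        d["replicate"] = d.pop("replicate_id")
    return d


def write_results_table(records: list, path: str | Path, *, kind: str = "half_life") -> None:
    """Write half-life estimates or genotype summaries as a delimited table.

    The record list must be homogeneous. ``kind`` selects the header for an empty
    list ("half_life" or "summary"); for a non-empty list it is inferred.
    """
    if records:
        types = {type(r).__name__ for r in records}
        if len(types) > 1:
            raise UsageError(f"mixed record types: {sorted(types)}")
        cols = HALF_LIFE_COLUMNS if hasattr(records[0], "rit50_s") else SUMMARY_COLUMNS
        df = pd.DataFrame([_record_row(r) for r in records])[cols]
    else:
        cols = HALF_LIFE_COLUMNS if kind == "half_life" else SUMMARY_COLUMNS
        df = pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(path)
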