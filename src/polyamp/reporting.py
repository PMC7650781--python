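"""Validation summaries, genotype concordance and the amplicon-run cost model.

Percentages are always recomputed from counts, never copied from a source
table: published summary cells are occasionally inconsistent with their own
counts, and counts are the primary data.

Display convention for validation percentages: one-decimal cells are
truncated (floor) at the first decimal, integer cells rounded half-up —
matching how such tables are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core_model import DataError


@dataclass(frozen=True)
class MethodValidation:
    """Validation counts for one SNP-selection method (or pooled column)."""

    method: str
    total: int
    missing: int
    validated: int

    def __post_init__(self) -> None:
        if self.missing > self.total:
            raise DataError(f"{self.method}: missing {self.missing} > total {self.total}")
        if self.validated > self.assayed:
            raise DataError(
                f"{self.method}: validated {self.validated} > assayed {self.assayed}"
            )

    @property
    def assayed(self) -> int:
        return self.total - self.missing

    @property
    def pct_of_assayed(self) -> Optional[float]:
        if self.assayed == 0:
            return None
        return 100.0 * self.validated / self.assayed

    @property
    def pct_of_targets(self) -> Optional[float]:
        if self.total == 0:
            return None
        return 100.0 * self.validated / self.total


def display_percent(value: Optional[float], decimals: int = 1) -> str:
    """Format a percentage: truncate at one decimal, round half-up at zero
    decimals; missing values render as '.'."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "."
    if decimals == 0:
        return str(int(Decimal(repr(value)).quantize(0, rounding=ROUND_HALF_UP)))
    factor = 10**decimals
    return f"{math.floor(value * factor) / factor:.{decimals}f}"


def validation_summary(
    records: pd.DataFrame, subset_methods: Optional[Sequence[str]] = None
) -> dict[str, MethodValidation]:
    """Per-method validation counts plus pooled columns.

    ``records`` needs columns target_id, method, status ("assayed" or
    "missing") and validated (bool). Returns one MethodValidation per method
    in first-appearance order, a "Sum" column pooling all methods, and — when
    ``subset_methods`` is given — a pooled column named by joining the subset
    with " + ". A record marked both missing and validated is a data error.
    """
    required = {"target_id", "method", "status", "validated"}
    if not required <= set(records.columns):
        raise DataError(f"records table needs columns {sorted(required)}")
    bad = records[(records["status"] == "missing") & records["validated"].astype(bool)]
    if len(bad):
        raise DataError(
            f"targets marked missing but validated: {bad['target_id'].tolist()}"
        )

    def pool(name: str, df: pd.DataFrame) -> MethodValidation:
        return MethodValidation(
            method=name,
            total=len(df),
            missing=int((df["status"] == "missing").sum()),
            validated=int(df["validated"].astype(bool).sum()),
        )

    out: dict[str, MethodValidation] = {}
    for method in records["method"].drop_duplicates():
        out[method] = pool(method, records[records["method"] == method])
    out["Sum"] = pool("Sum", records)
    if subset_methods is not None:
        name = " + ".join(subset_methods)
        out[name] = pool(name, records[records["method"].isin(subset_methods)])
    return out


def validation_table(summary: Mapping[str, MethodValidation]) -> pd.DataFrame:
    """Render a summary as the conventional rows-by-method table."""
    rows = ["Total no. of targets", "No. of missing targets", "No. of targets assayed",
            "No. of targets validated", "% Validation (of assayed)",
            "% Validation (of targets)"]
    data = {}
    for name, v in summary.items():
        data[name] = [
            v.total, v.missing, v.assayed, v.validated,
            display_percent(v.pct_of_assayed),
            display_percent(v.pct_of_targets),
        ]
    return pd.DataFrame(data, index=rows)


def counts_to_records(
    counts: Sequence[tuple[str, int, int, int]]
) -> pd.DataFrame:
    """Expand (method, total, missing, validated) count tuples into the
    per-target records table validation_summary consumes. Validated targets
    are taken from the assayed ones (missing targets cannot validate)."""
    rows = []
    for method, total, missing, validated in counts:
        if missing > total or validated > total - missing:
            raise DataError(f"{method}: inconsistent counts")
        for i in range(total):
            status = "missing" if i < missing else "assayed"
            rows.append(
                {
                    "target_id": f"{method}_{i + 1:02d}",
                    "method": method,
                    "status": status,
                    "validated": status == "assayed" and i - missing < validated,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConcordanceResult:
    percent: Optional[float]  # None when the first vector is monomorphic
    n_compared: int
    n_matching: int
    monomorphic: bool


def concordance(
    calls_a: Mapping[str, object], calls_b: Mapping[str, object]
) -> ConcordanceResult:
    """Percent of genotype calls matching between two assays over their
    shared, mutually non-missing accessions.

    ``calls_a`` is the reference assay (e.g. KASP clusters); if it shows a
    single cluster the comparison is flagged monomorphic and no percentage is
    reported. Missing calls are None values. Raises DataError when no
    accession overlaps.
    """
    shared = [
        k for k in calls_a
        if k in calls_b and calls_a[k] is not None and calls_b[k] is not None
    ]
    if not shared:
        raise DataError("no shared called accessions between assays")
    clusters = {v for v in calls_a.values() if v is not None}
    if len(clusters) < 2:
        return ConcordanceResult(None, len(shared), 0, True)
    n_match = sum(calls_a[k] == calls_b[k] for k in shared)
    return ConcordanceResult(100.0 * n_match / len(shared), len(shared), n_match, False)


@dataclass(frozen=True)
class CostSheet:
    """Itemised reagent/consumable costs for one amplicon-sequencing run."""

    items: tuple[tuple[str, float], ...]
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise DataError("n_samples must be >= 1")
        for label, amount in self.items:
            if amount < 0:
                raise DataError(f"negative cost for {label!r}")


def cost_model(sheet: CostSheet) -> tuple[float, float]:
    """Total run cost and per-sample cost (two decimals, half-up)."""
    total = sum(amount for _, amount in sheet.items)
    per_sample = float(
        Decimal(repr(total / sheet.n_samples)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return total, per_sample
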