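"""Mn(II)-oxidizing activity from LBB colorimetry.

The leucoberbelin-blue (LBB) assay reads oxidized manganese as absorbance at
620 nm against a KMnO4 standard curve.  The oxidized-Mn content of a culture
is expressed as the equivalent MnO2 concentration (µM), using the assay
stoichiometry that 1 µM MnO2 corresponds to 0.4 µM KMnO4, and categorized
into four activity classes:

    high    >= 50 µM MnO2
    medium  [10, 50) µM
    low     [1, 10)  µM
    none    < 1 µM

Interval boundaries are half-open, closed on the left, matching the explicit
``>= 50`` convention at the top class.  The module also builds the horizon x
category contingency table used to summarize a stratified-soil isolate survey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KMNO4_PER_MNO2",
    "CATEGORIES",
    "HORIZONS",
    "CalibrationCurve",
    "ActivityRecord",
    "ActivityTable",
    "fit_calibration",
    "kmno4_to_mno2",
    "mno2_to_kmno4",
    "categorize",
    "tabulate",
    "read_activity_csv",
]

#: µM KMnO4 equivalent to 1 µM of formed MnO2 in the LBB assay.
KMNO4_PER_MNO2 = 0.4

#: Activity categories in decreasing order of activity.
CATEGORIES = ("high", "medium", "low", "none")

#: Soil horizons, surface to substratum.
HORIZONS = ("A", "B", "C")

# (lower bound, category) pairs; intervals are [lower, next lower).
_CATEGORY_BOUNDS = ((50.0, "high"), (10.0, "medium"), (1.0, "low"), (0.0, "none"))


class CalibrationError(ValueError):
    """Raised when a standard series cannot support a calibration fit."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line absorbance = slope * kmno4_uM + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise CalibrationError(f"r_squared outside [0, 1]: {self.r_squared}")

    def absorbance_to_kmno4(self, absorbance: float) -> float:
        """Invert the standard curve: absorbance at 620 nm -> µM KMnO4."""
        return (absorbance - self.intercept) / self.slope

    def absorbance_to_mno2(self, absorbance: float) -> float:
        """Absorbance at 620 nm -> equivalent µM MnO2 (clipped at 0)."""
        return kmno4_to_mno2(max(self.absorbance_to_kmno4(absorbance), 0.0))


def fit_calibration(
    standards: Sequence[tuple[float, float]], *, through_origin: bool = False
) -> CalibrationCurve:
    """Fit the KMnO4 standard curve (absorbance at 620 nm vs concentration).

    Parameters
    ----------
    standards
        ``(kmno4_uM, absorbance_620nm)`` pairs; at least two distinct
        concentrations are required.
    through_origin
        Force a zero intercept (Beer-Lambert behavior implies one); default
        is ordinary least squares with intercept.
    """
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standard points")
    x = np.asarray([s[0] for s in standards], dtype=float)
    y = np.asarray([s[1] for s in standards], dtype=float)
    if np.any(x < 0) or np.any(y < 0) or not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise CalibrationError("standards must be finite and non-negative")
    if np.ptp(x) == 0:
        raise CalibrationError("standard concentrations have zero variance")

    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        fitted = slope * x
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
        fitted = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationCurve(slope=slope, intercept=intercept, r_squared=min(r_squared, 1.0))


def kmno4_to_mno2(kmno4_uM: float) -> float:
    """Convert µM KMnO4 to the equivalent µM MnO2 (1 µM MnO2 = 0.4 µM KMnO4)."""
    if not math.isfinite(kmno4_uM) or kmno4_uM < 0:
        raise ValueError(f"KMnO4 concentration must be finite and >= 0, got {kmno4_uM}")
    return kmno4_uM / KMNO4_PER_MNO2


def mno2_to_kmno4(mno2_uM: float) -> float:
    """Inverse of :func:`kmno4_to_mno2`: µM MnO2 -> equivalent µM KMnO4."""
    if not math.isfinite(mno2_uM) or mno2_uM < 0:
        raise ValueError(f"MnO2 concentration must be finite and >= 0, got {mno2_uM}")
    return mno2_uM * KMNO4_PER_MNO2


def categorize(mno2_uM: float) -> str:
    """Assign an activity category to an equivalent MnO2 concentration (µM)."""
    if not math.isfinite(mno2_uM):
        raise ValueError(f"MnO2 concentration must be finite, got {mno2_uM}")
    if mno2_uM < 0:
        raise ValueError(f"MnO2 concentration must be >= 0, got {mno2_uM}")
    for lower, cat in _CATEGORY_BOUNDS:
        if mno2_uM >= lower:
            return cat
    return "none"  # pragma: no cover - bounds end at 0


@dataclass(frozen=True)
class ActivityRecord:
    """One isolate's Mn(II)-oxidizing activity measurement."""

    isolate_id: str
    horizon: str
    mno2_uM: float
    category: str = field(default="")

    def __post_init__(self) -> None:
        if self.horizon not in HORIZONS:
            raise ValueError(f"unknown horizon {self.horizon!r}; expected one of {HORIZONS}")
        expected = categorize(self.mno2_uM)
        if self.category == "":
            object.__setattr__(self, "category", expected)
        elif self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with {self.mno2_uM} µM "
                f"(expected {expected!r})"
            )


@dataclass(frozen=True)
class ActivityTable:
    """Horizon x category contingency table for an isolate survey.

    ``counts`` is indexed by horizon with one column per activity category.
    ``column_percentages`` gives each category's compiled count as % of the
    grand total; ``within_category_percentages`` gives, per category, the %
    contributed by each horizon.  Percentages are raw ratios; round for
    presentation.
    """

    counts: pd.DataFrame

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        """The compiled per-category row."""
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def column_percentages(self) -> pd.Series:
        return 100.0 * self.column_totals / self.grand_total

    @property
    def within_category_percentages(self) -> pd.DataFrame:
        totals = self.column_totals.replace(0, np.nan)
        return 100.0 * self.counts / totals

    @property
    def active_fraction_percent(self) -> float:
        """Percent of isolates in any active category (high + medium + low)."""
        active = sum(self.column_totals[c] for c in CATEGORIES if c != "none")
        return 100.0 * active / self.grand_total

    def to_frame(self) -> pd.DataFrame:
        """Counts with a compiled row and a row-total column, survey style."""
        out = self.counts.copy()
        out["total"] = self.row_totals
        out.loc["compiled"] = out.sum(axis=0)
        return out


def tabulate(records: Iterable[ActivityRecord]) -> ActivityTable:
    """Cross-tabulate isolate records into a horizon x category table."""
    records = list(records)
    if not records:
        raise ValueError("no activity records to tabulate")
    counts = pd.DataFrame(0, index=list(HORIZONS), columns=list(CATEGORIES), dtype=int)
    for rec in records:
        counts.loc[rec.horizon, rec.category] += 1
    return ActivityTable(counts=counts)


def read_activity_csv(path, calibration: CalibrationCurve | None = None) -> list[ActivityRecord]:
    """Read isolate measurements from CSV.

    Expects columns ``isolate_id,horizon,mno2_uM`` or, with ``calibration``
    supplied, ``isolate_id,horizon,absorbance_620nm``.
    """
    df = pd.read_csv(path)
    if "mno2_uM" in df.columns:
        values = df["mno2_uM"].astype(float)
    elif "absorbance_620nm" in df.columns:
        if calibration is None:
            raise ValueError("absorbance input requires a calibration curve")
        values = df["absorbance_620nm"].astype(float).map(calibration.absorbance_to_mno2)
    else:
        raise ValueError("CSV must have a mno2_uM or absorbance_620nm column")
    return [
        ActivityRecord(isolate_id=str(r.isolate_id), horizon=str(r.horizon), mno2_uM=float(v))
        for r, v in zip(df.itertuples(index=False), values)
    ]
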