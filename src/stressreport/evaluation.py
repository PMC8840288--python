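"""Quantitative evaluation suite for the explainable stress report.

Four instruments:

* **RPD robustness** — the relative percentage difference between the
  reference-interval midpoints derived from two data subsets,
  RPD = 100 * |mu_A - mu_B| / (2 |mu_B|), aggregated over features; small
  totals mean the intervals are robust to resampling.
* **Flag consistency** — the percentage of report rows whose star flag
  (outside reference interval) and circle flag (positive impact) agree.
* **Chi-squared concordance** — Pearson's test (no continuity correction)
  on the 2x2 contingency of impact sign vs. interval membership; a small
  p rejects independence, i.e. the IMPACT and the interval point at the
  same observations.
* **F1-binary** — precision/recall harmonic mean on the stress class.

A literature ground-truth table of stress-indicating physiology (heart
rate and HRV ranges under stress vs. no stress, plus direction-only
entries for trapezius EMG amplitude and respiration rate) ships as a
packaged CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

from .intervals import IntervalPair
from .registry import StressReportError
from .report import StressReport


@dataclass
class GroundTruthEntry:
    """One literature finding: stress vs no-stress range (mean ± sd, when
    reported) or a direction-only effect."""

    feature: str
    direction: str
    unit: str
    no_stress_range: tuple[float, float] | None = None  # (mean, sd)
    stress_range: tuple[float, float] | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 < self.p_value < 1.0:
            raise StressReportError(f"p_value {self.p_value} outside (0, 1)")


def ground_truth_table() -> list[GroundTruthEntry]:
    """Published stress-effect table: five heart-derived features with
    numeric ranges, plus direction-only entries for EMG and respiration."""
    path = resources.files("stressreport").joinpath(
        "data/ground_truth_stress_indicators.csv"
    )
    entries = []
    with path.open() as fh:
        for row in csv.DictReader(fh):
            has_ranges = row["no_stress_mean"] != ""
            entries.append(
                GroundTruthEntry(
                    feature=row["feature"],
                    direction=row["direction"],
                    unit=row["unit"],
                    no_stress_range=(float(row["no_stress_mean"]), float(row["no_stress_sd"]))
                    if has_ranges
                    else None,
                    stress_range=(float(row["stress_mean"]), float(row["stress_sd"]))
                    if has_ranges
                    else None,
                    p_value=float(row["p_value"]) if row["p_value"] != "" else None,
                )
            )
    return entries


def rpd(interval_a: IntervalPair, interval_b: IntervalPair) -> float | None:
    """Relative percentage difference between reference-interval midpoints,
    100 * |mu_A - mu_B| / (2 |mu_B|); None when undefined (unavailable
    interval, feature mismatch is an error, zero denominator)."""
    if interval_a.feature != interval_b.feature:
        raise StressReportError(
            f"feature mismatch: {interval_a.feature!r} vs {interval_b.feature!r}"
        )
    if not (interval_a.available and interval_b.available):
        return None
    mu_a = interval_a.reference_midpoint
    mu_b = interval_b.reference_midpoint
    if mu_b == 0:
        return None
    return 100.0 * abs(mu_a - mu_b) / (2.0 * abs(mu_b))


def total_rpd(per_feature_rpds, mode: str = "mean") -> float:
    """Aggregate per-feature RPDs (mean by default; ``mode="sum"`` gives
    the summed variant).  Undefined (None/NaN) entries are dropped."""
    values = [v for v in per_feature_rpds if v is not None and np.isfinite(v)]
    if not values:
        raise StressReportError("no defined RPD values to aggregate")
    if mode == "mean":
        return float(np.mean(values))
    if mode == "sum":
        return float(np.sum(values))
    raise StressReportError(f"unknown RPD aggregation mode {mode!r}")


def flag_consistency(
    reports: list[StressReport],
) -> tuple[float, dict[str, float]]:
    """Pooled percentage of rows whose star and circle flags agree, plus
    the per-feature breakdown.  Rows without a star flag (unavailable
    interval) are not counted."""
    agree: dict[str, int] = {}
    total: dict[str, int] = {}
    for report in reports:
        for row in report.rows:
            if row.star_flag is None:
                continue
            total[row.test] = total.get(row.test, 0) + 1
            if row.star_flag == row.circle_flag:
                agree[row.test] = agree.get(row.test, 0) + 1
    n = sum(total.values())
    if n == 0:
        raise StressReportError("no flagged rows to evaluate")
    overall = 100.0 * sum(agree.values()) / n
    per_feature = {f: 100.0 * agree.get(f, 0) / total[f] for f in total}
    return overall, per_feature


def chi2_concordance(impact_signs, in_reference) -> tuple[float | None, float | None]:
    """Pearson chi-squared (no Yates correction) on the 2x2 contingency of
    {impact > 0, impact < 0} x {outside, inside reference interval}.

    Observations with zero impact are excluded.  Degenerate margins yield
    ``(None, None)`` rather than an error.
    """
    signs = np.asarray(impact_signs, dtype=float)
    inside = np.asarray(in_reference, dtype=bool)
    if signs.shape != inside.shape:
        raise StressReportError("impact_signs and in_reference must align")
    keep = signs != 0
    signs, inside = signs[keep], inside[keep]
    table = np.array(
        [
            [np.sum((signs > 0) & ~inside), np.sum((signs > 0) & inside)],
            [np.sum((signs < 0) & ~inside), np.sum((signs < 0) & inside)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None, None
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def f1_binary(y_true, y_pred) -> float:
    """Harmonic mean of precision and recall on the stress class; 0 when
    precision + recall is 0.  Requires at least one true positive label."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.sum() == 0:
        raise StressReportError("y_true contains no stress labels")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0
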