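"""Nonparametric stress and reference intervals per feature.

Training observations are partitioned, feature by feature, on the sign of
their Shapley contribution: positive phi -> Stress Group, negative phi ->
No-Stress Group (zero contributions are excluded).  A two-sided Welch
t-test validates that the two groups separate, and the central 95% range
(2.5th to 97.5th percentile, linear-interpolation quantiles) of the
No-Stress Group becomes the clinical-style REFERENCE INTERVAL; the
analogue over the Stress Group is the stress interval.  Intervals are
published only when both groups reach a minimum size (default 20) so the
tail percentiles are stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .model import StressModel
from .registry import StressReportError

DEFAULT_GROUP_FLOOR = 20


@dataclass
class IntervalPair:
    """Stress and reference interval for one feature, with the Welch-test
    p-value and the direction of the stress effect."""

    feature: str
    available: bool
    reference_interval: tuple[float, float] | None = None
    stress_interval: tuple[float, float] | None = None
    direction: str | None = None  # increases_with_stress / decreases_with_stress
    t_pvalue: float | None = None
    n_stress: int = 0
    n_nostress: int = 0

    @property
    def reference_midpoint(self) -> float | None:
        if self.reference_interval is None:
            return None
        lo, hi = self.reference_interval
        return 0.5 * (lo + hi)

    @property
    def stress_midpoint(self) -> float | None:
        if self.stress_interval is None:
            return None
        lo, hi = self.stress_interval
        return 0.5 * (lo + hi)


def partition_by_impact(
    values: np.ndarray, phis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Route observations by the sign of their Shapley contribution:
    phi > 0 -> stress group, phi < 0 -> no-stress group, phi == 0 excluded."""
    values = np.asarray(values, dtype=float)
    phis = np.asarray(phis, dtype=float)
    if values.shape != phis.shape:
        raise StressReportError("values and phis must be aligned")
    return values[phis > 0], values[phis < 0]


def welch_t_test(a, b) -> float:
    """Two-sided unequal-variance t-test p-value.

    Two identical constant samples are maximally compatible with the
    null: p = 1.0 is returned with a degenerate-variance warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StressReportError("each sample needs >= 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("both samples have zero variance", RuntimeWarning, stacklevel=2)
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    _, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p)


def derive_intervals(
    stress_group,
    nostress_group,
    feature: str = "",
    group_floor: int = DEFAULT_GROUP_FLOOR,
) -> IntervalPair:
    """2.5/97.5-percentile intervals for both groups; below-floor groups
    yield an unavailable marker instead of an error."""
    stress_group = np.asarray(stress_group, dtype=float)
    nostress_group = np.asarray(nostress_group, dtype=float)
    if len(stress_group) < group_floor or len(nostress_group) < group_floor:
        return IntervalPair(
            feature=feature,
            available=False,
            n_stress=len(stress_group),
            n_nostress=len(nostress_group),
        )
    ref = tuple(np.percentile(nostress_group, [2.5, 97.5]))
    stress = tuple(np.percentile(stress_group, [2.5, 97.5]))
    direction = (
        "increases_with_stress"
        if np.mean(stress_group) >= np.mean(nostress_group)
        else "decreases_with_stress"
    )
    return IntervalPair(
        feature=feature,
        available=True,
        reference_interval=(float(ref[0]), float(ref[1])),
        stress_interval=(float(stress[0]), float(stress[1])),
        direction=direction,
        t_pvalue=welch_t_test(stress_group, nostress_group),
        n_stress=len(stress_group),
        n_nostress=len(nostress_group),
    )


def interval_table(
    model: StressModel,
    fm: FeatureMatrix,
    Phi: np.ndarray,
    group_floor: int = DEFAULT_GROUP_FLOOR,
) -> list[IntervalPair]:
    """One IntervalPair per model feature from the whole training matrix.

    ``Phi`` must hold one Shapley vector per row of ``fm`` (see
    :func:`stressreport.shapley.explain_matrix`).
    """
    Phi = np.asarray(Phi, dtype=float)
    if Phi.shape != (len(fm), model.n_features):
        raise StressReportError(
            f"Phi shape {Phi.shape} does not cover all rows x features "
            f"({len(fm)}, {model.n_features})"
        )
    X = fm.X
    pairs = []
    for j, feature in enumerate(model.feature_names):
        stress_vals, nostress_vals = partition_by_impact(X[:, j], Phi[:, j])
        pairs.append(
            derive_intervals(stress_vals, nostress_vals, feature, group_floor)
        )
    return pairs


def split_by_direction(
    pairs: list[IntervalPair],
) -> tuple[list[IntervalPair], list[IntervalPair]]:
    """(features that increase with stress, features that decrease)."""
    inc = [p for p in pairs if p.available and p.direction == "increases_with_stress"]
    dec = [p for p in pairs if p.available and p.direction == "decreases_with_stress"]
    return inc, dec


def intervals_to_frame(pairs: list[IntervalPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "feature": p.feature,
                "available": p.available,
                "ref_lo": p.reference_interval[0] if p.available else np.nan,
                "ref_hi": p.reference_interval[1] if p.available else np.nan,
                "stress_lo": p.stress_interval[0] if p.available else np.nan,
                "stress_hi": p.stress_interval[1] if p.available else np.nan,
                "direction": p.direction if p.available else "",
                "p_value": p.t_pvalue if p.available else np.nan,
                "n_stress": p.n_stress,
                "n_nostress": p.n_nostress,
            }
        )
    return pd.DataFrame(rows)


def intervals_from_frame(frame: pd.DataFrame) -> list[IntervalPair]:
    pairs = []
    for _, row in frame.iterrows():
        if bool(row["available"]):
            pairs.append(
                IntervalPair(
                    feature=row["feature"],
                    available=True,
                    reference_interval=(float(row["ref_lo"]), float(row["ref_hi"])),
                    stress_interval=(float(row["stress_lo"]), float(row["stress_hi"])),
                    direction=str(row["direction"]),
                    t_pvalue=float(row["p_value"]),
                    n_stress=int(row["n_stress"]),
                    n_nostress=int(row["n_nostress"]),
                )
            )
        else:
            pairs.append(
                IntervalPair(
                    feature=row["feature"],
                    available=False,
                    n_stress=int(row["n_stress"]),
                    n_nostress=int(row["n_nostress"]),
                )
            )
    return pairs
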