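"""Blood-test-style stress report: header, rows, dual flags, rendering.

Each report row mirrors a laboratory test line: TEST name, measured
RESULT with UNIT, the REFERENCE INTERVAL (rendered as centre ± half-width),
the signed IMPACT percentage, and two flags — a star flag that is red when
the result falls outside the closed reference interval, and a circle flag
that is red when the feature's IMPACT is positive (i.e. the feature pushed
the prediction toward stress).  The header carries USER STRESS LEVEL
(rounded percent of the model's vote fraction) and SYSTEM CONFIDENCE LEVEL
(the model's historic cross-validated F1, as a percent).
"""

from __future__ import annotations

import html as html_mod
import json
from dataclasses import dataclass, field

from .intervals import IntervalPair
from .model import StressModel, predict_stress_probability
from .registry import SIMPLE_AGGREGATE_FEATURES, UNIT_OF, StressReportError
from .shapley import ShapleyExplanation

AGGREGATION_LEVELS = ("full", "simple", "custom")


@dataclass
class ReportRow:
    test: str
    result: float
    unit: str
    reference_interval: tuple[float, float] | None
    impact_pct: float
    star_flag: str | None  # "red" / "green"; None when no interval available
    circle_flag: str


@dataclass
class StressReport:
    user_stress_level: int  # percent 0-100
    system_confidence_level: float  # percent
    rows: list[ReportRow]
    aggregation_level: str = "full"
    subject_id: str = ""
    custom_features: list[str] = field(default_factory=list)


def assign_flags(
    result: float,
    interval: tuple[float, float],
    impact_pct: float,
    directional: bool = False,
    direction: str | None = None,
) -> tuple[str, str]:
    """Star flag: red iff the result lies outside the closed interval
    [lo, hi] (with ``directional=True``, only on the interval's stress
    side).  Circle flag: red iff the impact is strictly positive; a zero
    impact is rendered green (no evidence toward stress)."""
    lo, hi = interval
    if directional and direction is not None:
        if direction == "increases_with_stress":
            outside = result > hi
        else:
            outside = result < lo
    else:
        outside = result < lo or result > hi
    star = "red" if outside else "green"
    circle = "red" if impact_pct > 0 else "green"
    return star, circle


def build_report(
    model: StressModel,
    x,
    expl: ShapleyExplanation,
    intervals: list[IntervalPair],
    confidence: float,
    directional_flags: bool = False,
    subject_id: str = "",
) -> StressReport:
    """Assemble the full report for one observation.

    ``x`` is a mapping feature -> value (or vector in model order);
    ``intervals`` must cover the model's features — features whose
    interval is marked unavailable are rendered without a star flag.
    """
    if isinstance(x, dict):
        vec = [float(x[f]) for f in model.feature_names if f in x]
        if len(vec) != model.n_features:
            missing = [f for f in model.feature_names if f not in x]
            raise StressReportError(f"observation missing features: {missing}")
    else:
        vec = [float(v) for v in x]
        if len(vec) != model.n_features:
            raise StressReportError(
                f"expected {model.n_features} feature values, got {len(vec)}"
            )
    by_feature = {p.feature: p for p in intervals}
    missing = [f for f in model.feature_names if f not in by_feature]
    if missing:
        raise StressReportError(f"intervals missing for features: {missing}")
    p_x = predict_stress_probability(model, dict(zip(model.feature_names, vec)))
    rows = []
    for j, feature in enumerate(model.feature_names):
        pair = by_feature[feature]
        ipct = float(expl.impact_pct[j])
        if pair.available:
            star, circle = assign_flags(
                vec[j],
                pair.reference_interval,
                ipct,
                directional=directional_flags,
                direction=pair.direction,
            )
            ref = pair.reference_interval
        else:
            star, circle = None, "red" if ipct > 0 else "green"
            ref = None
        rows.append(
            ReportRow(
                test=feature,
                result=vec[j],
                unit=UNIT_OF.get(feature, ""),
                reference_interval=ref,
                impact_pct=ipct,
                star_flag=star,
                circle_flag=circle,
            )
        )
    return StressReport(
        user_stress_level=int(round(100.0 * p_x)),
        system_confidence_level=float(confidence),
        rows=rows,
        aggregation_level="full",
        subject_id=subject_id,
    )


def aggregate_olap(
    report: StressReport, level: str, custom: list[str] | None = None
) -> StressReport:
    """OLAP-style roll-up: ``full`` is the identity; ``simple`` keeps only
    heart-rate, respiration-rate and temperature tests; ``custom`` keeps a
    caller-supplied subset.  Header values are never altered."""
    if level not in AGGREGATION_LEVELS:
        raise StressReportError(f"unknown aggregation level {level!r}")
    if level == "full":
        keep = None
    elif level == "simple":
        keep = set(SIMPLE_AGGREGATE_FEATURES)
    else:
        if not custom:
            raise StressReportError("custom aggregation needs a non-empty feature list")
        known = {row.test for row in report.rows}
        unknown = [f for f in custom if f not in known]
        if unknown:
            raise StressReportError(f"unknown features in custom subset: {unknown}")
        keep = set(custom)
    rows = report.rows if keep is None else [r for r in report.rows if r.test in keep]
    return StressReport(
        user_stress_level=report.user_stress_level,
        system_confidence_level=report.system_confidence_level,
        rows=list(rows),
        aggregation_level=level,
        subject_id=report.subject_id,
        custom_features=list(custom) if level == "custom" else [],
    )


# ---------------------------------------------------------------------------
# Rendering


def _interval_text(ref: tuple[float, float] | None) -> str:
    if ref is None:
        return "n/a"
    center = 0.5 * (ref[0] + ref[1])
    half = 0.5 * (ref[1] - ref[0])
    return f"{center:.4g} ± {half:.4g}"


def report_to_dict(report: StressReport) -> dict:
    return {
        "user_stress_level": report.user_stress_level,
        "system_confidence_level": report.system_confidence_level,
        "aggregation_level": report.aggregation_level,
        "subject_id": report.subject_id,
        "custom_features": report.custom_features,
        "rows": [
            {
                "test": r.test,
                "result": r.result,
                "unit": r.unit,
                "reference_interval": list(r.reference_interval)
                if r.reference_interval is not None
                else None,
                "impact_pct": r.impact_pct,
                "star_flag": r.star_flag,
                "circle_flag": r.circle_flag,
            }
            for r in report.rows
        ],
    }


def report_from_dict(doc: dict) -> StressReport:
    rows = [
        ReportRow(
            test=r["test"],
            result=r["result"],
            unit=r["unit"],
            reference_interval=tuple(r["reference_interval"])
            if r["reference_interval"] is not None
            else None,
            impact_pct=r["impact_pct"],
            star_flag=r["star_flag"],
            circle_flag=r["circle_flag"],
        )
        for r in doc["rows"]
    ]
    return StressReport(
        user_stress_level=doc["user_stress_level"],
        system_confidence_level=doc["system_confidence_level"],
        rows=rows,
        aggregation_level=doc.get("aggregation_level", "full"),
        subject_id=doc.get("subject_id", ""),
        custom_features=list(doc.get("custom_features", [])),
    )


_TEXT_HEADER = (
    "{:<16} {:>12} {:<12} {:>18} {:>9} {:>6} {:>7}".format(
        "TESTS", "RESULT", "UNIT", "REFERENCE INTERVAL", "IMPACT", "STAR", "CIRCLE"
    )
)


def render(report: StressReport, format: str = "text") -> str:
    """Serialize the report.  ``json`` round-trips losslessly through
    :func:`report_from_dict`; ``text`` and ``html`` mirror the printed
    column order TESTS / RESULT / UNIT / REFERENCE INTERVAL / IMPACT /
    FLAGS."""
    if format == "json":
        return json.dumps(report_to_dict(report), sort_keys=True, indent=1)
    if format == "text":
        lines = [
            "STRESS PREDICTION REPORT"
            + (f"  (subject {report.subject_id})" if report.subject_id else ""),
            f"USER STRESS LEVEL:       {report.user_stress_level}%",
            f"SYSTEM CONFIDENCE LEVEL: {report.system_confidence_level:.1f}%",
            f"AGGREGATION LEVEL:       {report.aggregation_level}",
            "",
            _TEXT_HEADER,
            "-" * len(_TEXT_HEADER),
        ]
        for r in report.rows:
            lines.append(
                "{:<16} {:>12.5g} {:<12} {:>18} {:>+8.2f}% {:>6} {:>7}".format(
                    r.test,
                    r.result,
                    r.unit,
                    _interval_text(r.reference_interval),
                    r.impact_pct,
                    r.star_flag if r.star_flag is not None else "-",
                    r.circle_flag,
                )
            )
        return "\n".join(lines) + "\n"
    if format == "html":
        def flag_dot(color: str | None, shape: str) -> str:
            if color is None:
                return "&mdash;"
            glyph = "&#9733;" if shape == "star" else "&#9679;"
            return f'<span style="color:{color}">{glyph}</span>'

        body_rows = "\n".join(
            "<tr><td>{}</td><td>{:.5g}</td><td>{}</td><td>{}</td>"
            "<td>{:+.2f}%</td><td>{} {}</td></tr>".format(
                html_mod.escape(r.test),
                r.result,
                html_mod.escape(r.unit),
                html_mod.escape(_interval_text(r.reference_interval)),
                r.impact_pct,
                flag_dot(r.star_flag, "star"),
                flag_dot(r.circle_flag, "circle"),
            )
            for r in report.rows
        )
        return (
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>Stress prediction report</title>"
            "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
            "padding:4px 8px;font-family:sans-serif;font-size:13px}</style>"
            "</head><body>"
            f"<h2>STRESS PREDICTION REPORT</h2>"
            f"<p>USER STRESS LEVEL: <b>{report.user_stress_level}%</b><br>"
            f"SYSTEM CONFIDENCE LEVEL: <b>{report.system_confidence_level:.1f}%</b></p>"
            "<table><tr><th>TESTS</th><th>RESULT</th><th>UNIT</th>"
            "<th>REFERENCE INTERVAL</th><th>IMPACT</th><th>FLAGS</th></tr>"
            f"{body_rows}</table></body></html>"
        )
    raise StressReportError(f"unknown report format {format!r}")
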