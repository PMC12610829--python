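"""Serialization of separation reports to CSV, JSON and Markdown.

JSON keeps full floating-point precision and round-trips losslessly;
Markdown mirrors the layout of clinical descriptive tables with every
numeric cell rounded to 2 decimals (half away from zero); CSV is a flat
long format (section, group, variable, field, value). All three are
byte-deterministic for a given report.
"""

from __future__ import annotations

import json

import numpy as np

from .stats import (
    GROUP_PAIRS,
    GroupDescriptives,
    SeparationReport,
    round_half_away,
)

FORMATS = ("csv", "json", "markdown")

_DESC_FIELDS = ("mean", "sd", "minimum", "maximum", "cv",
                "ci_low", "ci_high", "skewness", "kurtosis", "normality_p")


def _fmt(x) -> str:
    if x is None:
        return "-"
    if isinstance(x, float):
        return f"{round_half_away(x, 2):.2f}"
    return str(x)


def _jsonify(obj):
    """Replace non-finite floats by null so output is strict JSON."""
    if isinstance(obj, float):
        return obj if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def report_to_json(report: SeparationReport) -> str:
    return json.dumps(_jsonify(report.to_dict()), indent=2, sort_keys=True,
                      allow_nan=False)


def report_from_json(text: str) -> SeparationReport:
    d = json.loads(text)
    d["mahalanobis"] = np.asarray(d["mahalanobis"], dtype=float)
    d["variables"] = tuple(d["variables"])
    d["group_names"] = tuple(d["group_names"])
    d["group_sizes"] = tuple(d["group_sizes"])
    d["manova_df"] = tuple(d["manova_df"])
    d["anova"] = {
        k: tuple(float("nan") if x is None else x for x in v)
        for k, v in d["anova"].items()
    }
    d["markers"] = {k: tuple(v) for k, v in d["markers"].items()}
    d["homogeneity"] = [tuple(h) for h in d["homogeneity"]]
    d["descriptives"] = {
        g: {v: GroupDescriptives(**cells) for v, cells in vars_.items()}
        for g, vars_ in d["descriptives"].items()
    }
    return SeparationReport(**d)


def report_to_markdown(report: SeparationReport) -> str:
    lines = [f"# Separation report: {report.scheme} ({report.index_kind})", ""]
    for gname in report.group_names:
        n = report.group_sizes[report.group_names.index(gname)]
        lines.append(f"## Descriptives: {gname} (n = {n})")
        lines.append("")
        header = ["Variable", "Mean", "SD", "Min", "Max", "CV", "CI",
                  "Skewness", "Kurtosis", "p-Value"]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for var in report.variables:
            d = report.descriptives[gname][var]
            ci = f"{_fmt(d.ci_low)}-{_fmt(d.ci_high)}"
            lines.append(
                "| " + " | ".join([
                    var, _fmt(d.mean), _fmt(d.sd), _fmt(d.minimum),
                    _fmt(d.maximum), _fmt(d.cv), ci,
                    _fmt(d.skewness), _fmt(d.kurtosis), _fmt(d.normality_p),
                ]) + " |"
            )
        lines.append("")
    lines.append("## MANOVA")
    lines.append("")
    lines.append(
        f"Wilks' lambda = {_fmt(report.wilks_lambda)}, "
        f"F({_fmt(report.manova_df[0])}, {_fmt(report.manova_df[1])}) = "
        f"{_fmt(report.manova_f)}, p = {report.manova_p:.3g}"
    )
    lines.append("")
    lines.append("## Discriminant analysis, ANOVA and pairwise markers")
    lines.append("")
    header = ["Variable", *report.group_names, "Contribution %", "ANOVA F", "ANOVA p"]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for var in report.variables:
        marks = report.markers.get(var, ("",) * len(report.group_names))
        F, p = report.anova[var]
        cells = [var, *[m or "-" for m in marks],
                 _fmt(report.contributions[var]), _fmt(F), f"{p:.3g}"]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    nm = " | ".join(f"{c}/{t}" for c, t, _ in report.homogeneity)
    pct = " | ".join(f"{p:.2f}" for _, _, p in report.homogeneity)
    lines.append(f"| n/m | {nm} | | | |")
    lines.append(f"| Homogeneity % | {pct} | | | |")
    lines.append("")
    kind = "D^2" if report.squared_distances else "D"
    lines.append(f"## Mahalanobis distances ({kind})")
    lines.append("")
    lines.append("| | " + " | ".join(report.group_names) + " |")
    lines.append("|" + "---|" * (len(report.group_names) + 1))
    M = np.asarray(report.mahalanobis)
    for i, gname in enumerate(report.group_names):
        row = " | ".join(_fmt(float(M[i, j])) for j in range(M.shape[1]))
        lines.append(f"| {gname} | {row} |")
    lines.append("")
    return "\n".join(lines)


def report_to_csv(report: SeparationReport) -> str:
    rows = [("section", "group", "variable", "field", "value")]
    for gname in report.group_names:
        for var in report.variables:
            d = report.descriptives[gname][var]
            rows.append(("descriptives", gname, var, "n", repr(d.n)))
            for f in _DESC_FIELDS:
                v = getattr(d, f)
                rows.append(("descriptives", gname, var, f,
                             "" if v is None else repr(v)))
    rows.append(("manova", "", "", "wilks_lambda", repr(report.wilks_lambda)))
    rows.append(("manova", "", "", "F", repr(report.manova_f)))
    rows.append(("manova", "", "", "p", repr(report.manova_p)))
    for var in report.variables:
        F, p = report.anova[var]
        rows.append(("anova", "", var, "F", repr(F)))
        rows.append(("anova", "", var, "p", repr(p)))
        for gname, m in zip(report.group_names, report.markers[var]):
            rows.append(("markers", gname, var, "marker", m))
        rows.append(("contributions", "", var, "percent",
                     repr(report.contributions[var])))
    for gname, (c, t, p) in zip(report.group_names, report.homogeneity):
        rows.append(("homogeneity", gname, "", "n_correct", repr(c)))
        rows.append(("homogeneity", gname, "", "n_total", repr(t)))
        rows.append(("homogeneity", gname, "", "percent", repr(p)))
    M = np.asarray(report.mahalanobis)
    g = len(report.group_names)
    pairs = GROUP_PAIRS if g == 3 else [(a, b) for a in range(g) for b in range(a + 1, g)]
    for a, b in pairs:
        rows.append(("mahalanobis", f"{report.group_names[a]}|{report.group_names[b]}",
                     "", "distance", repr(float(M[a, b]))))
    return "\n".join(",".join(r) for r in rows) + "\n"


def write_report_tables(report: SeparationReport, path, format: str = "markdown") -> None:
    """Serialize a report deterministically in the requested format."""
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    if format == "json":
        text = report_to_json(report)
    elif format == "markdown":
        text = report_to_markdown(report)
    else:
        text = report_to_csv(report)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
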