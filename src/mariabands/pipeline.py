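"""End-to-end orchestration: simulate/read -> score -> classify -> report.

One :class:`RunConfig` drives the whole comparison of literature-based
and cluster-derived severity bands for each requested index kind. All
randomness flows from the single config seed; identical configs produce
byte-identical outputs, recorded (with file hashes) in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import cluster_index, severity_labels
from .cohort import CohortTable, filter_pathological, read_cohort, write_cohort
from .indices import DEFAULT_COEFFICIENTS, IndexCoefficients, index_cohort
from .reporting import write_report_tables
from .simulate import generate_cohort, preset_configs
from .stats import (ANALYSIS_VARIABLES, build_separation_report,
                    compare_schemes, round_half_away)
from .thresholds import LITERATURE_THRESHOLDS, ThresholdSpec, classify_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one analysis run."""

    outdir: str
    preset: str | None = "maria_clusters"
    input_path: str | None = None
    dialect: str = "csv"
    index_kinds: tuple = ("maria", "dwi_maria")
    k: int = 3
    seed: int = 0
    thresholds: dict = field(default_factory=dict)  # index kind -> (low, high)
    coefficients: dict = field(default_factory=dict)
    normality_test: str = "shapiro"
    welch: bool = False
    squared_distances: bool = False
    report_format: str = "markdown"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True), encoding="utf-8")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the output manifest.

    Stages: obtain cohort (preset simulation or file), score indices,
    filter to pathological segments, literature-threshold classify,
    gap-cluster at k, build one separation report per scheme, and
    compare the schemes pairwise. Every intermediate table and report
    lands under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coeffs = (IndexCoefficients.from_dict(config.coefficients)
              if config.coefficients else DEFAULT_COEFFICIENTS)

    if config.input_path is not None:
        log.info("reading cohort from %s", config.input_path)
        cohort = read_cohort(config.input_path, config.dialect)
        truth = None
    elif config.preset is not None:
        log.info("simulating preset %r with seed %d", config.preset, config.seed)
        cohort, truth = generate_cohort(preset_configs(config.preset, config.seed))
    else:
        raise ValueError("config needs either a preset or an input path")
    write_cohort(cohort, outdir / "cohort.csv")

    # Score every computable index: the five analysis variables include
    # both composite indices even when only one drives classification.
    compute_kinds = (("maria", "dwi_maria") if cohort.has_contrast
                     else ("dwi_maria",))
    missing_kinds = set(config.index_kinds) - set(compute_kinds)
    if missing_kinds:
        raise ValueError(
            f"cohort lacks contrast fields needed for {sorted(missing_kinds)}")
    indexed = index_cohort(cohort, coeffs, compute_kinds)
    variables = tuple(v for v in ANALYSIS_VARIABLES if v in indexed.columns)
    indexed.to_csv(outdir / "indexed.csv", index=False)
    path_mask = indexed["pathological"] == 1
    analysis = indexed[path_mask].reset_index(drop=True)
    if len(analysis) == 0:
        raise ValueError("stage filter_pathological: no pathological segments")
    log.info("%d of %d segments pathological", len(analysis), len(indexed))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "provenance": cohort.provenance,
        "n_segments": len(indexed),
        "n_pathological": len(analysis),
        "results": {},
        "files": {},
    }

    for kind in config.index_kinds:
        scores = analysis[kind].to_numpy(dtype=float)
        if kind in config.thresholds:
            low, high = config.thresholds[kind]
            spec = ThresholdSpec(float(low), float(high), kind)
        else:
            spec = LITERATURE_THRESHOLDS[kind]
        th_labels, th_counts = classify_cohort(scores, spec)
        clustering = cluster_index(scores, k=config.k)
        cl_labels = (severity_labels(clustering) if config.k == 3
                     else clustering.labels)

        np.savetxt(outdir / f"labels_threshold_{kind}.csv", th_labels, fmt="%d")
        np.savetxt(outdir / f"labels_cluster_{kind}.csv", cl_labels, fmt="%d")
        _write_json(outdir / f"clustering_{kind}.json", {
            "k": clustering.k,
            "cluster_sizes": clustering.cluster_sizes,
            "cluster_ranges": clustering.cluster_ranges,
            "boundaries": clustering.boundaries,
            "schedule_tail": [
                dataclasses.asdict(s) for s in clustering.schedule[-10:]
            ],
        })

        kw = dict(
            variables=variables,
            normality_test=config.normality_test,
            welch=config.welch,
            squared_distances=config.squared_distances,
        )
        rep_th = build_separation_report(
            analysis, th_labels, scheme="threshold", index_kind=kind, **kw)
        rep_cl = build_separation_report(
            analysis, cl_labels, scheme="cluster", index_kind=kind, **kw)
        for rep, scheme in ((rep_th, "threshold"), (rep_cl, "cluster")):
            for fmt, ext in (("json", "json"), (config.report_format, "md")):
                suffix = "json" if fmt == "json" else (
                    "md" if fmt == "markdown" else "csv")
                write_report_tables(
                    rep, outdir / f"report_{scheme}_{kind}.{suffix}", fmt)
        manifest["results"][kind] = {
            "threshold_counts": {c.label: n for c, n in th_counts.items()},
            "cluster_sizes": clustering.cluster_sizes,
            "cluster_boundaries": (
                [round_half_away(b, 4) for b in clustering.boundaries]
                if clustering.boundaries else None),
        }
        if config.k == 3:
            # The threshold scheme always has 3 bands, so the head-to-head
            # comparison is only defined at the clinical k.
            comparison = compare_schemes(rep_th, rep_cl)
            _write_json(outdir / f"comparison_{kind}.json", comparison)
            manifest["results"][kind]["cluster_larger_in_all_pairs"] = (
                comparison["b_larger_in_all_pairs"])

    if truth is not None:
        np.savetxt(outdir / "truth_labels.csv",
                   truth[path_mask.to_numpy()], fmt="%d")

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    _write_json(outdir / "manifest.json", manifest)
    return manifest
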