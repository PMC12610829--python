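"""Segment-level cohort data model and tabular I/O.

A cohort is a table of bowel-segment measurements taken from magnetic
resonance enterography (MRE): one row per (patient, anatomical segment).
The seven segments follow the fixed anatomical map used in segmental MRE
reading (I jejunum, II proximal/middle ileum, III distal/terminal ileum,
IV right colon, V transverse colon, VI left colon, VII sigmoid/rectum).

The table carries exactly the raw quantities that the activity-index
formulas consume: wall thickness (mm), the T2 signal-intensity ratio of
wall to psoas muscle, qualitative edema and ulceration flags, pre/post
contrast wall signal intensities with their noise standard deviations,
the ordinal high-b DWI signal score, the apparent diffusion coefficient
(ADC, stored in units of 1e-3 mm^2/s so typical bowel values are
0.9-2.1), and a binary flag marking pathological involvement.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortValidationError, EmptyGroupError

log = logging.getLogger(__name__)

SEGMENTS = ("I", "II", "III", "IV", "V", "VI", "VII")

#: Continuous columns that must be finite and strictly positive.
CONTINUOUS_FIELDS = (
    "wall_thickness",
    "t2_ratio",
    "wsi_pre",
    "wsi_post",
    "sd_noise_pre",
    "sd_noise_post",
    "adc",
)

#: Binary {0,1} flag columns.
FLAG_FIELDS = ("edema", "ulceration", "pathological")

#: Contrast-dependent columns; may be absent when only DWI MaRIA is needed.
CONTRAST_FIELDS = ("wsi_pre", "wsi_post", "sd_noise_pre", "sd_noise_post")

#: Full schema in canonical column order.
COLUMNS = (
    "patient_id",
    "segment",
    "wall_thickness",
    "t2_ratio",
    "edema",
    "ulceration",
    "wsi_pre",
    "wsi_post",
    "sd_noise_pre",
    "sd_noise_post",
    "dwi_signal",
    "adc",
    "pathological",
)

REQUIRED_COLUMNS = tuple(c for c in COLUMNS if c not in CONTRAST_FIELDS)


@dataclass(frozen=True)
class SegmentMeasurement:
    """One bowel segment's raw MRE-derived measurements."""

    patient_id: str
    segment: str
    wall_thickness: float
    t2_ratio: float
    edema: int
    ulceration: int
    dwi_signal: int
    adc: float
    pathological: int
    wsi_pre: float | None = None
    wsi_post: float | None = None
    sd_noise_pre: float | None = None
    sd_noise_post: float | None = None


@dataclass
class CohortTable:
    """A validated collection of segment measurements.

    ``frame`` holds one row per segment in the canonical column order;
    ``provenance`` records where the rows came from (a source file or a
    generator seed) for inclusion in run manifests.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_contrast(self) -> bool:
        return all(c in self.frame.columns for c in CONTRAST_FIELDS)

    @property
    def records(self) -> list[SegmentMeasurement]:
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            out.append(
                SegmentMeasurement(
                    patient_id=str(d["patient_id"]),
                    segment=str(d["segment"]),
                    wall_thickness=float(d["wall_thickness"]),
                    t2_ratio=float(d["t2_ratio"]),
                    edema=int(d["edema"]),
                    ulceration=int(d["ulceration"]),
                    dwi_signal=int(d["dwi_signal"]),
                    adc=float(d["adc"]),
                    pathological=int(d["pathological"]),
                    wsi_pre=float(d["wsi_pre"]) if "wsi_pre" in d else None,
                    wsi_post=float(d["wsi_post"]) if "wsi_post" in d else None,
                    sd_noise_pre=float(d["sd_noise_pre"]) if "sd_noise_pre" in d else None,
                    sd_noise_post=float(d["sd_noise_post"]) if "sd_noise_post" in d else None,
                )
            )
        return out


def validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw dataframe against the segment schema.

    Returns a copy restricted to schema columns in canonical order.
    Raises :class:`CohortValidationError` naming the first offending row
    and field. Extra columns are dropped with a logged warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    has_contrast = all(c in frame.columns for c in CONTRAST_FIELDS)
    partial = [c for c in CONTRAST_FIELDS if c in frame.columns]
    if partial and not has_contrast:
        absent = [c for c in CONTRAST_FIELDS if c not in frame.columns]
        raise CohortValidationError(
            f"contrast columns must be given together; present {partial}, missing {absent}"
        )
    keep = [c for c in COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in keep]
    if extra:
        log.warning("ignoring extra column(s): %s", extra)
    out = frame[keep].copy()
    if len(out) == 0:
        raise CohortValidationError("cohort is empty")

    numeric = [c for c in CONTINUOUS_FIELDS if c in out.columns]
    for col in numeric + ["dwi_signal", *FLAG_FIELDS]:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError("non-numeric or missing value", row=row, field=col)
        out[col] = coerced
    for col in numeric:
        vals = out[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"must be finite and > 0, got {vals[bad][0]!r}", row=row, field=col
            )
    for col in FLAG_FIELDS:
        vals = out[col].to_numpy(dtype=float)
        bad = ~np.isin(vals, (0.0, 1.0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"flag must be 0 or 1, got {vals[bad][0]!r}", row=row, field=col
            )
        out[col] = out[col].astype(int)
    dwi = out["dwi_signal"].to_numpy(dtype=float)
    bad = ~np.isfinite(dwi) | (dwi < 0) | (dwi != np.round(dwi))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise CohortValidationError(
            "DWI signal must be a non-negative integer score", row=row, field="dwi_signal"
        )
    out["dwi_signal"] = out["dwi_signal"].astype(int)

    out["patient_id"] = out["patient_id"].astype(str)
    out["segment"] = out["segment"].astype(str)
    bad = ~out["segment"].isin(SEGMENTS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError(
            f"segment must be one of {SEGMENTS}", row=row, field="segment"
        )
    dup = out.duplicated(subset=["patient_id", "segment"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortValidationError(
            "duplicate (patient_id, segment) pair", row=row, field="segment"
        )
    return out.reset_index(drop=True)


def read_cohort(path, dialect: str = "csv") -> CohortTable:
    """Read and validate a segment-level cohort from CSV or TSV."""
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return CohortTable(frame=validate_frame(frame), provenance=str(path))


def write_cohort(cohort: CohortTable, path, dialect: str = "csv") -> None:
    """Write a cohort back to disk in the canonical column order."""
    sep = "," if dialect == "csv" else "\t"
    cohort.frame.to_csv(path, sep=sep, index=False)


def filter_pathological(cohort: CohortTable) -> CohortTable:
    """Keep only segments flagged as pathological, preserving order.

    Only these segments enter the comparative threshold/cluster analyses;
    morphologically normal segments are never scored.
    """
    mask = cohort.frame["pathological"] == 1
    if not mask.any():
        raise EmptyGroupError("no pathological segments in cohort")
    return CohortTable(
        frame=cohort.frame[mask].reset_index(drop=True),
        provenance=cohort.provenance,
    )
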