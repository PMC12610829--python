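"""MRE activity-index formulas: RCE, MaRIA and DWI MaRIA.

The two segmental activity scores are linear combinations of raw MRE
measurements:

    MaRIA     = 1.5 * wall thickness (mm) + 0.02 * RCE
                + 5 * edema + 10 * ulceration

    DWI MaRIA = 1.5 * wall thickness (mm) + 3.5 * DWI signal
                + 1.75 * T2 SI ratio - 1.321 * ADC

with relative contrast enhancement (RCE, percent) defined from pre/post
gadolinium wall signal intensities (WSI) and the image noise SDs:

    RCE = (WSI_post - WSI_pre) / WSI_pre * 100 * (SD_pre / SD_post)

ADC enters in units of 1e-3 mm^2/s (typical bowel-wall values 0.9-2.1),
so the diffusion term is on the order of -1.3 to -2.8 index units; this
is the only reading that keeps DWI MaRIA on its conventional scale.
All coefficients live in one :class:`IndexCoefficients` object so a
site can recalibrate without touching formula code.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import MissingFieldError

INDEX_KINDS = ("maria", "dwi_maria")


@dataclass(frozen=True)
class IndexCoefficients:
    """Coefficients of the two activity-index formulas (published defaults)."""

    maria_wt: float = 1.5      # per mm wall thickness
    maria_rce: float = 0.02    # per percent RCE
    maria_edema: float = 5.0   # edema flag
    maria_ulcer: float = 10.0  # ulceration flag
    dwim_wt: float = 1.5       # per mm wall thickness
    dwim_dwi: float = 3.5      # per DWI signal score unit
    dwim_t2: float = 1.75      # per T2 SI ratio unit
    dwim_adc: float = 1.321    # per 1e-3 mm^2/s ADC (subtracted)

    @classmethod
    def from_dict(cls, d: dict) -> "IndexCoefficients":
        known = {k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown coefficient name(s): {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_COEFFICIENTS = IndexCoefficients()


def compute_rce(wsi_pre, wsi_post, sd_noise_pre, sd_noise_post):
    """Relative contrast enhancement in percent; may be negative."""
    wsi_pre = np.asarray(wsi_pre, dtype=float)
    wsi_post = np.asarray(wsi_post, dtype=float)
    sd_noise_pre = np.asarray(sd_noise_pre, dtype=float)
    sd_noise_post = np.asarray(sd_noise_post, dtype=float)
    if np.any(wsi_pre <= 0) or np.any(sd_noise_post <= 0):
        raise ValueError("wsi_pre and sd_noise_post must be strictly positive")
    out = (wsi_post - wsi_pre) / wsi_pre * 100.0 * (sd_noise_pre / sd_noise_post)
    return out if out.ndim else float(out)


def compute_maria(wall_thickness, rce, edema, ulceration,
                  coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS):
    """Contrast-enhanced MaRIA score for one segment (vectorized)."""
    edema = np.asarray(edema, dtype=float)
    ulceration = np.asarray(ulceration, dtype=float)
    if np.any(~np.isin(edema, (0.0, 1.0))) or np.any(~np.isin(ulceration, (0.0, 1.0))):
        raise ValueError("edema and ulceration flags must be 0 or 1")
    out = (
        coeffs.maria_wt * np.asarray(wall_thickness, dtype=float)
        + coeffs.maria_rce * np.asarray(rce, dtype=float)
        + coeffs.maria_edema * edema
        + coeffs.maria_ulcer * ulceration
    )
    return out if out.ndim else float(out)


def compute_dwi_maria(wall_thickness, dwi_signal, t2_ratio, adc,
                      coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS):
    """Non-contrast DWI MaRIA score for one segment (vectorized).

    ``adc`` is expected in 1e-3 mm^2/s; negative values are rejected.
    """
    adc = np.asarray(adc, dtype=float)
    if np.any(adc < 0):
        raise ValueError("ADC must be non-negative")
    out = (
        coeffs.dwim_wt * np.asarray(wall_thickness, dtype=float)
        + coeffs.dwim_dwi * np.asarray(dwi_signal, dtype=float)
        + coeffs.dwim_t2 * np.asarray(t2_ratio, dtype=float)
        - coeffs.dwim_adc * adc
    )
    return out if out.ndim else float(out)


def index_cohort(cohort: CohortTable,
                 coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS,
                 indices=INDEX_KINDS) -> pd.DataFrame:
    """Score every segment, returning the cohort frame plus index columns.

    Adds ``rce`` and ``maria`` when the contrast-enhanced index is
    requested, and ``dwi_maria`` for the diffusion variant. Row order is
    preserved. Requesting MaRIA on a cohort without contrast columns
    raises :class:`~mariabands.errors.MissingFieldError`.
    """
    unknown = set(indices) - set(INDEX_KINDS)
    if unknown:
        raise ValueError(f"unknown index kind(s): {sorted(unknown)}")
    frame = cohort.frame.copy()
    if "maria" in indices:
        if not cohort.has_contrast:
            raise MissingFieldError(
                "MaRIA requires contrast fields (wsi_pre/wsi_post/sd_noise_pre/"
                "sd_noise_post); only DWI MaRIA is computable on this cohort"
            )
        frame["rce"] = compute_rce(
            frame["wsi_pre"], frame["wsi_post"],
            frame["sd_noise_pre"], frame["sd_noise_post"],
        )
        frame["maria"] = compute_maria(
            frame["wall_thickness"], frame["rce"],
            frame["edema"], frame["ulceration"], coeffs,
        )
    if "dwi_maria" in indices:
        frame["dwi_maria"] = compute_dwi_maria(
            frame["wall_thickness"], frame["dwi_signal"],
            frame["t2_ratio"], frame["adc"], coeffs,
        )
    return frame
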