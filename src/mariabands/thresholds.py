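"""Literature-based threshold classification into severity bands.

Published cut-offs stratify each scored segment into inactive, active or
severe disease: for MaRIA, <=7 inactive, (7, 11] active, >11 severe; for
DWI MaRIA, <=8 inactive, (8, 12.5] active, >12.5 severe. Boundary values
belong to the lower band (plain floating-point comparison, no epsilon).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np


class ActivityClass(IntEnum):
    """Ordered disease-activity bands: inactive < active < severe."""

    INACTIVE = 0
    ACTIVE = 1
    SEVERE = 2

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class ThresholdSpec:
    """Two cut-offs defining the three bands for one index kind."""

    low_cut: float
    high_cut: float
    index_kind: str

    def __post_init__(self):
        if not self.low_cut < self.high_cut:
            raise ValueError(
                f"low_cut must be < high_cut, got ({self.low_cut}, {self.high_cut})"
            )


#: Published literature cut-offs per index kind.
LITERATURE_THRESHOLDS = {
    "maria": ThresholdSpec(7.0, 11.0, "maria"),
    "dwi_maria": ThresholdSpec(8.0, 12.5, "dwi_maria"),
}


def classify(score: float, spec: ThresholdSpec) -> ActivityClass:
    """Assign one score to its severity band (boundaries inclusive below)."""
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    if score <= spec.low_cut:
        return ActivityClass.INACTIVE
    if score <= spec.high_cut:
        return ActivityClass.ACTIVE
    return ActivityClass.SEVERE


def classify_cohort(scores, spec: ThresholdSpec):
    """Classify a vector of scores.

    Returns ``(labels, counts)``: an integer array of
    :class:`ActivityClass` values aligned with the input, and a dict of
    per-class counts that always sums to the input size.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size and not np.all(np.isfinite(scores)):
        bad = int(np.flatnonzero(~np.isfinite(scores))[0])
        raise ValueError(f"non-finite score at position {bad}")
    labels = np.where(
        scores <= spec.low_cut,
        ActivityClass.INACTIVE,
        np.where(scores <= spec.high_cut, ActivityClass.ACTIVE, ActivityClass.SEVERE),
    ).astype(int)
    counts = {cls: int(np.sum(labels == cls)) for cls in ActivityClass}
    return labels, counts
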