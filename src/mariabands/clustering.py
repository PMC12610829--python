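"""Data-driven severity bands from 1-D single-linkage clustering.

Segments are clustered on one composite activity index (MaRIA or DWI
MaRIA) after z-standardization, using Euclidean distances and
agglomerative single-link (nearest-neighbour) linkage, starting from
singletons and stopping at a prespecified number of clusters (k = 3 for
the clinical inactive/active/severe bands).

On the line, single linkage has a clean closed form: the k-cluster
solution is obtained by cutting the k-1 largest adjacent gaps of the
sorted values, so every cluster is a contiguous interval and the full
agglomeration schedule is simply the adjacent gaps in ascending order.
The implementation below runs the explicit agglomeration (recording the
schedule, as one would inspect for chaining on a dendrogram) and is
tested against both the largest-gap closed form and brute-force
enumeration of contiguous partitions.

Tie-break: when several merges (equivalently cuts) share the same
distance, cuts prefer the smallest left member index in sorted order;
tied merges are therefore processed right-to-left. Duplicate values
merge at height zero before any positive-height merge.

The per-cluster minima and maxima in original index units define
data-driven severity cut-offs for the cohort; the midpoint of each
inter-cluster gap is reported as a single usable boundary value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError
from .thresholds import ActivityClass


def zstandardize(values) -> np.ndarray:
    """Center and scale to sample SD 1 (n-1 denominator).

    Raises :class:`DegenerateInputError` for n < 2 or constant input.
    The resulting partition is invariant to this affine transform; the
    agglomeration-schedule heights are in z-units.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D array of index values")
    if values.size < 2:
        raise DegenerateInputError(f"need at least 2 values, got {values.size}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant input has no z-scores")
    return (values - values.mean()) / sd


@dataclass(frozen=True)
class AgglomerationStep:
    """One merge of the schedule: the two boundary members and the gap height."""

    step_number: int
    merge_height: float
    left_member_index: int   # index into the sorted value sequence
    right_member_index: int  # always left_member_index + 1 on the line


@dataclass
class ClusteringResult:
    """Partition of 1-D values plus the evidence used to derive cut-offs.

    ``labels`` are cluster ids in the original input order, numbered
    0..k-1 left to right along the sorted axis (so ids already ascend
    with cluster mean). ``schedule`` holds all n-1 merges.
    ``severity_map``, ``cluster_ranges`` and ``boundaries`` are filled by
    :func:`assign_severity` and :func:`derive_cutoffs`.
    """

    labels: np.ndarray
    schedule: list[AgglomerationStep]
    k: int
    severity_map: dict[int, ActivityClass] | None = None
    cluster_ranges: list[tuple[float, float]] | None = None
    boundaries: list[float] | None = None

    @property
    def cluster_sizes(self) -> list[int]:
        return [int(np.sum(self.labels == c)) for c in range(self.k)]


def single_link_cluster_1d(values, k: int) -> ClusteringResult:
    """Agglomerative single-link clustering of 1-D values into k clusters.

    Records the full agglomeration schedule (heights non-decreasing) and
    returns labels in the original input order; the result is invariant
    to input order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D array of values")
    n = values.size
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    order = np.argsort(values, kind="stable")
    srt = values[order]
    gaps = np.diff(srt)  # gap i separates sorted members i and i+1

    # Single link on the line: merge adjacent gaps in ascending order.
    # Tied gaps are processed right-to-left so that the surviving (cut)
    # gaps are the leftmost among ties.
    merge_order = sorted(range(n - 1), key=lambda i: (gaps[i], -i))
    schedule = [
        AgglomerationStep(
            step_number=s + 1,
            merge_height=float(gaps[i]),
            left_member_index=int(i),
            right_member_index=int(i + 1),
        )
        for s, i in enumerate(merge_order)
    ]
    cut_gaps = sorted(merge_order[n - k:])  # the k-1 never-performed merges
    labels_sorted = np.zeros(n, dtype=int)
    for c in cut_gaps:
        labels_sorted[c + 1:] += 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return ClusteringResult(labels=labels, schedule=schedule, k=k)


def assign_severity(result: ClusteringResult, original_values) -> ClusteringResult:
    """Map the three clusters to severity bands by ascending cluster mean."""
    if result.k != 3:
        raise ValueError(f"severity labelling needs exactly 3 clusters, got k={result.k}")
    original_values = np.asarray(original_values, dtype=float)
    means = [original_values[result.labels == c].mean() for c in range(result.k)]
    order = np.argsort(means, kind="stable")
    severity_map = {int(cid): ActivityClass(rank) for rank, cid in enumerate(order)}
    return replace(result, severity_map=severity_map)


def derive_cutoffs(result: ClusteringResult, original_values) -> ClusteringResult:
    """Per-cluster (min, max) ranges and mid-gap boundary values.

    The ranges are the cohort-specific data-driven thresholds; the
    boundaries are the midpoints of the gaps between adjacent cluster
    ranges (a single usable cut-off per gap). For touching clusters the
    boundary equals the shared value.
    """
    if result.k < 2:
        raise ValueError("cut-offs need at least 2 clusters")
    original_values = np.asarray(original_values, dtype=float)
    stats = []
    for c in range(result.k):
        members = original_values[result.labels == c]
        stats.append((float(members.min()), float(members.max())))
    stats.sort()
    for (lo_a, hi_a), (lo_b, _) in zip(stats, stats[1:]):
        assert hi_a <= lo_b, "1-D single-link clusters must be disjoint intervals"
    boundaries = [(hi_a + lo_b) / 2.0 for (_, hi_a), (lo_b, _) in zip(stats, stats[1:])]
    return replace(result, cluster_ranges=stats, boundaries=boundaries)


def cluster_index(values, k: int = 3, standardize: bool = True) -> ClusteringResult:
    """Full data-driven banding of one index: z-standardize, cluster,
    label severities (for k = 3) and derive cut-offs in original units."""
    values = np.asarray(values, dtype=float)
    z = zstandardize(values) if standardize else values
    result = single_link_cluster_1d(z, k)
    if k == 3:
        result = assign_severity(result, values)
    if k >= 2:
        result = derive_cutoffs(result, values)
    return result


def severity_labels(result: ClusteringResult) -> np.ndarray:
    """Labels as ActivityClass integer values (requires assign_severity)."""
    if result.severity_map is None:
        raise ValueError("severity_map not assigned; call assign_severity first")
    lut = np.array([int(result.severity_map[c]) for c in range(result.k)])
    return lut[result.labels]
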