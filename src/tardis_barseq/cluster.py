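"""Abundance-greedy Levenshtein clustering of barcode counts.

Sequencing and PCR errors scatter each true barcode into a cloud of
low-count neighbors within small edit distance.  The corrector sorts
sequences by count (descending, ties lexicographic) and lets each one join
the nearest existing centroid that is (a) within edit distance ``radius``
and (b) at least ``merge_ratio`` times more abundant; otherwise it founds a
new centroid.  This is the sphere-clustering scheme popularized by
starcode-style barcode denoisers.  After clustering, centroids whose
length differs from ``required_length`` are dropped with their mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import edlib


@dataclass
class ClusterParams:
    radius: int = 2
    merge_ratio: float = 5.0
    required_length: int | None = 15

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.merge_ratio < 1:
            raise ValueError("merge_ratio must be >= 1")


@dataclass
class ClusterResult:
    """Error-corrected counts plus the member → centroid assignment map."""

    centroids: dict[str, int]
    assignments: dict[str, str]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.centroids.values()) + sum(self.dropped.values())


def edit_distance(a: str, b: str, cap: int | None = None) -> int:
    """Levenshtein distance between two sequences.

    With ``cap`` set, distances above the cap short-circuit (banded
    alignment) and ``cap + 1`` is returned.  Symmetric; zero iff equal.
    """
    k = -1 if cap is None else cap
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    if d == -1:
        return cap + 1
    return d


def cluster_barcodes(
    raw_counts: Mapping[str, int], params: ClusterParams | None = None
) -> ClusterResult:
    """Greedy error correction of a barcode → count table.

    Processing order is count-descending with lexicographic tie-break, so
    the result is deterministic.  A sequence joins the candidate centroid
    minimizing (edit distance, -current centroid count, centroid sequence)
    among those within ``radius`` whose current aggregated count is at
    least ``merge_ratio`` times the sequence's own count.  Total mass is
    conserved: centroid counts + dropped counts == raw counts.
    """
    params = params or ClusterParams()
    if any(c <= 0 for c in raw_counts.values()):
        raise ValueError("raw counts must be positive")

    order = sorted(raw_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    centroid_counts: dict[str, int] = {}
    assignments: dict[str, str] = {}
    for seq, count in order:
        best: tuple[int, int, str] | None = None
        for centroid, ccount in centroid_counts.items():
            if ccount < params.merge_ratio * count:
                continue
            d = edit_distance(seq, centroid, cap=params.radius)
            if d > params.radius:
                continue
            key = (d, -ccount, centroid)
            if best is None or key < best:
                best = key
        if best is None:
            centroid_counts[seq] = count
            assignments[seq] = seq
        else:
            centroid = best[2]
            centroid_counts[centroid] += count
            assignments[seq] = centroid

    dropped: dict[str, int] = {}
    if params.required_length is not None:
        for centroid in [c for c in centroid_counts if len(c) != params.required_length]:
            dropped[centroid] = centroid_counts.pop(centroid)
    return ClusterResult(centroid_counts, assignments, dropped)
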