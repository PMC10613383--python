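"""TAD boundary comparison and rearrangement classification.

Two TAD call sets (pre- and post-perturbation, same contact-matrix bin
size) are compared boundary-by-boundary: a boundary is *concordant* if the
complementary set has a boundary within one bin width (inclusive), else
*discordant*. Regions between consecutive concordant anchors that contain
at least one discordant boundary are candidate rearrangements; candidates
touching a centromere are discarded. Each candidate is classified from the
number of pre-TADs (``m``) and post-TADs (``k``) intersecting it:

========================  =================
condition                 category
========================  =================
``m > 1, k == 1``         simple_merge
``m == 1, k > 1``         simple_split
``m > k >= 2``            complex_merge
``2 <= m < k``            complex_split
``m == k >= 2``           balanced_shift
========================  =================

``m == k == 1`` (only possible with gapped TAD inputs, when a gap edge
moves) is treated as a degenerate balanced shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GenomicInterval, overlap_bp

CATEGORIES = (
    "simple_merge",
    "simple_split",
    "complex_merge",
    "complex_split",
    "balanced_shift",
)


@dataclass
class TADSet:
    """Ordered, non-overlapping TAD intervals per chromosome plus the
    contact-matrix bin size used to call them."""

    tads: dict[str, np.ndarray]  # chrom -> (k, 2) int array of [start, end)
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, arr in self.tads.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"empty/inverted TAD on {chrom}")
            order = np.argsort(arr[:, 0])
            arr = arr[order]
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"overlapping TADs on {chrom}")
            self.tads[chrom] = arr

    @classmethod
    def from_intervals(
        cls, intervals: list[GenomicInterval] | pd.DataFrame, bin_size: int
    ) -> "TADSet":
        tads: dict[str, list[list[int]]] = {}
        if isinstance(intervals, pd.DataFrame):
            rows = intervals[["chrom", "start", "end"]].itertuples(index=False)
        else:
            rows = ((iv.chrom, iv.start, iv.end) for iv in intervals)
        for chrom, start, end in rows:
            tads.setdefault(chrom, []).append([int(start), int(end)])
        return cls(
            tads={c: np.asarray(v, dtype=np.int64) for c, v in tads.items()},
            bin_size=bin_size,
        )

    @property
    def chroms(self) -> list[str]:
        return list(self.tads)

    def boundaries(self, chrom: str) -> np.ndarray:
        """Sorted unique start/end coordinates of the chromosome's TADs."""
        if chrom not in self.tads:
            return np.zeros(0, dtype=np.int64)
        return np.unique(self.tads[chrom].ravel())

    def count(self) -> int:
        return sum(len(a) for a in self.tads.values())


@dataclass
class Rearrangement:
    interval: GenomicInterval
    pre_tad_count: int
    post_tad_count: int
    category: str


def _concordant(b: np.ndarray, other: np.ndarray, radius: int) -> np.ndarray:
    """Boolean mask: each boundary in ``b`` has an ``other`` boundary
    within ``radius`` bp (inclusive)."""
    if len(other) == 0:
        return np.zeros(len(b), dtype=bool)
    pos = np.searchsorted(other, b)
    left = other[np.clip(pos - 1, 0, len(other) - 1)]
    right = other[np.clip(pos, 0, len(other) - 1)]
    dist = np.minimum(np.abs(b - left), np.abs(b - right))
    return dist <= radius


def _resolve_radius(pre: TADSet, post: TADSet, radius: int | None) -> int:
    if radius is not None:
        return radius
    if pre.bin_size != post.bin_size:
        warnings.warn(
            "pre/post TAD sets have different bin sizes; using the pre "
            "set's bin size as the concordance radius",
            stacklevel=3,
        )
    return pre.bin_size


def match_boundaries(
    pre: TADSet, post: TADSet, radius: int | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: concordance masks for (pre boundaries, post
    boundaries). Matching is a pure proximity test — no one-to-one
    assignment."""
    radius = _resolve_radius(pre, post, radius)
    out = {}
    for chrom in sorted(set(pre.chroms) | set(post.chroms)):
        bp = pre.boundaries(chrom)
        bq = post.boundaries(chrom)
        out[chrom] = (_concordant(bp, bq, radius), _concordant(bq, bp, radius))
    return out


def find_rearrangements(
    pre: TADSet,
    post: TADSet,
    layout: GenomeLayout,
    radius: int | None = None,
) -> list[GenomicInterval]:
    """Candidate rearrangement intervals.

    Anchors are the concordant *pre* boundaries plus the chromosome ends
    (so terminal discordance is classifiable). Every interval between
    consecutive anchors containing >= 1 discordant boundary (either set)
    is a candidate, except those overlapping a centromere.
    """
    radius = _resolve_radius(pre, post, radius)
    conc = match_boundaries(pre, post, radius)
    candidates: list[GenomicInterval] = []
    for chrom, (pre_ok, post_ok) in conc.items():
        if chrom not in layout.chrom_lengths:
            raise ValueError(f"TADs on chromosome {chrom!r} absent from layout")
        bp = pre.boundaries(chrom)
        bq = post.boundaries(chrom)
        length = layout.chrom_lengths[chrom]
        anchors = np.unique(
            np.concatenate([bp[pre_ok], [0, length]])
        )
        discordant = np.sort(np.concatenate([bp[~pre_ok], bq[~post_ok]]))
        if len(discordant) == 0:
            continue
        cen = layout.centromere_interval(chrom)
        for a1, a2 in zip(anchors[:-1], anchors[1:]):
            inside = np.searchsorted(discordant, a1, "right") < np.searchsorted(
                discordant, a2, "left"
            )
            if not inside:
                continue
            cand = GenomicInterval(chrom, int(a1), int(a2))
            if cen is not None and overlap_bp(cand, cen) > 0:
                continue
            candidates.append(cand)
    return candidates


def _intersect_count(region: GenomicInterval, tads: TADSet) -> int:
    arr = tads.tads.get(region.chrom)
    if arr is None:
        return 0
    return int(
        np.count_nonzero(
            (arr[:, 0] < region.end) & (arr[:, 1] > region.start)
        )
    )


def classify_rearrangement(
    region: GenomicInterval, pre: TADSet, post: TADSet
) -> tuple[str, int, int]:
    """Classify a candidate region; returns ``(category, m, k)`` where
    ``m``/``k`` are the pre/post TAD counts intersecting it (>= 1 bp)."""
    m = _intersect_count(region, pre)
    k = _intersect_count(region, post)
    if m == 0 or k == 0:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} intersects "
            f"no TADs (m={m}, k={k})"
        )
    if m > 1 and k == 1:
        cat = "simple_merge"
    elif m == 1 and k > 1:
        cat = "simple_split"
    elif m > k >= 2:
        cat = "complex_merge"
    elif 2 <= m < k:
        cat = "complex_split"
    else:  # m == k (>= 2, or the degenerate gapped m == k == 1 case)
        cat = "balanced_shift"
    return cat, m, k


def find_and_classify(
    pre: TADSet,
    post: TADSet,
    layout: GenomeLayout,
    radius: int | None = None,
) -> list[Rearrangement]:
    """Detect and classify all TAD rearrangements between two call sets."""
    out = []
    for region in find_rearrangements(pre, post, layout, radius):
        cat, m, k = classify_rearrangement(region, pre, post)
        out.append(
            Rearrangement(
                interval=region, pre_tad_count=m, post_tad_count=k,
                category=cat,
            )
        )
    return out


def rearrangement_summary(
    rearrangements: list[Rearrangement], layout: GenomeLayout
) -> pd.DataFrame:
    """Counts and base coverage per category, plus the unrearranged rest
    of the genome. Rearrangement intervals are disjoint by construction,
    so the per-category base totals partition the rearranged bases."""
    rows = []
    total = layout.total_bp
    covered = 0
    for cat in CATEGORIES:
        members = [r for r in rearrangements if r.category == cat]
        bp = sum(r.interval.length for r in members)
        covered += bp
        rows.append(
            {"category": cat, "count": len(members), "bp": bp,
             "fraction": bp / total}
        )
    rows.append(
        {
            "category": "not_rearranged",
            "count": 0,
            "bp": total - covered,
            "fraction": (total - covered) / total,
        }
    )
    return pd.DataFrame(rows)
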