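"""Co-localization statistics relating DEG clusters, TAD rearrangements,
chromatin loops, and accessibility peaks.

All interval overlap here is half-open, >= 1 bp. The loop odds ratio for a
cluster compares the odds that a loop contacting the cluster is
significant after versus before the perturbation, with the
Haldane–Anscombe +0.5 applied to every cell of the 2x2 table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, GenomicInterval, overlap_bp
from .scan import Cluster, EnrichmentTrack
from .tads import CATEGORIES, Rearrangement

STRATA = ("genome", "up_clusters", "down_clusters")


def _merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals (clusters from one scan can
    physically overlap when the step is smaller than the window width)."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: i.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def overlap_fractions(
    clusters: list[Cluster],
    rearrangements: list[Rearrangement],
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Fraction of bases per stratum (whole genome, up-clusters,
    down-clusters) falling in each rearrangement category.

    Rows sum to 1 for non-empty strata; an empty cluster stratum yields a
    NaN row. Rearrangement intervals are disjoint, so categories
    partition the rearranged bases.
    """
    strata_intervals: dict[str, list[GenomicInterval]] = {
        "genome": [layout.chrom_interval(c) for c in layout.chroms],
        "up_clusters": _merge_intervals(
            [c.interval for c in clusters if c.direction == "upregulated"]
        ),
        "down_clusters": _merge_intervals(
            [c.interval for c in clusters if c.direction == "downregulated"]
        ),
    }
    rows = {}
    for stratum, ivs in strata_intervals.items():
        total = sum(iv.length for iv in ivs)
        if total == 0:
            rows[stratum] = {c: np.nan for c in CATEGORIES + ("not_rearranged",)}
            continue
        row = {}
        covered = 0
        for cat in CATEGORIES:
            bp = sum(
                overlap_bp(iv, r.interval)
                for r in rearrangements
                if r.category == cat
                for iv in ivs
            )
            covered += bp
            row[cat] = bp / total
        row["not_rearranged"] = (total - covered) / total
        rows[stratum] = row
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(STRATA)]


# ---------------------------------------------------------------------------
# loops


def _anchor_overlaps(
    loops: pd.DataFrame, interval: GenomicInterval
) -> np.ndarray:
    """Mask of loops with either anchor overlapping ``interval`` (>= 1 bp)."""
    same = loops["chrom"].to_numpy() == interval.chrom
    a = (loops["start1"].to_numpy() < interval.end) & (
        loops["end1"].to_numpy() > interval.start
    )
    b = (loops["start2"].to_numpy() < interval.end) & (
        loops["end2"].to_numpy() > interval.start
    )
    return same & (a | b)


def loop_odds_ratio(loops: pd.DataFrame, cluster: Cluster) -> float:
    """Odds ratio (post vs pre significance) over loops contacting the
    cluster; NaN when no loop contacts it.

    ``loops`` needs columns ``chrom, start1, end1, start2, end2,
    significant_pre, significant_post`` (intra-chromosomal loops).
    """
    mask = _anchor_overlaps(loops, cluster.interval)
    if not mask.any():
        return float("nan")
    sub = loops.loc[mask]
    a_post = int(sub["significant_post"].sum())
    b_post = int((~sub["significant_post"].astype(bool)).sum())
    a_pre = int(sub["significant_pre"].sum())
    b_pre = int((~sub["significant_pre"].astype(bool)).sum())
    return ((a_post + 0.5) / (b_post + 0.5)) / ((a_pre + 0.5) / (b_pre + 0.5))


def cluster_odds_table(
    loops: pd.DataFrame,
    clusters: list[Cluster],
    rearrangements: list[Rearrangement] | None = None,
) -> pd.DataFrame:
    """Per-cluster loop odds ratios with log2 values and contacting-loop
    counts.

    When ``rearrangements`` are given, each cluster is additionally
    labelled with the category of the rearrangement it overlaps most
    (``none`` if it overlaps no rearrangement), for stratified views of
    the odds ratios.
    """
    rows = []
    for c in clusters:
        mask = _anchor_overlaps(loops, c.interval)
        orr = loop_odds_ratio(loops, c)
        row = {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "direction": c.direction,
            "n_loops": int(mask.sum()),
            "odds_ratio": orr,
            "log2_odds_ratio": np.log2(orr) if np.isfinite(orr) else np.nan,
        }
        if rearrangements is not None:
            best, best_bp = "none", 0
            for r in rearrangements:
                bp = overlap_bp(c.interval, r.interval)
                if bp > best_bp:
                    best, best_bp = r.category, bp
            row["rearrangement_category"] = best
        rows.append(row)
    return pd.DataFrame(rows)


def compare_cluster_odds(up_ors, down_ors) -> dict:
    """Two-sided Mann–Whitney U comparing up- vs down-cluster odds
    ratios; reports the p-value and per-group medians."""
    up = np.asarray([v for v in up_ors if np.isfinite(v)], dtype=float)
    down = np.asarray([v for v in down_ors if np.isfinite(v)], dtype=float)
    if len(up) == 0 or len(down) == 0:
        raise ValueError("both odds-ratio lists must be non-empty")
    res = stats.mannwhitneyu(up, down, alternative="two-sided")
    return {
        "p_value": float(res.pvalue),
        "median_up": float(np.median(up)),
        "median_down": float(np.median(down)),
    }


# ---------------------------------------------------------------------------
# peaks and genes


def count_peaks_in_clusters(
    peaks: pd.DataFrame, clusters: list[Cluster], fdr_thresh: float = 0.05
) -> int:
    """Number of peaks with ``fdr < fdr_thresh`` whose interval overlaps
    any cluster by >= 1 bp; each peak counted once.

    ``peaks`` needs columns ``chrom, start, end, fdr``.
    """
    if len(peaks) == 0 or not clusters:
        return 0
    sig = peaks[peaks["fdr"] < fdr_thresh]
    hit = np.zeros(len(sig), dtype=bool)
    chrom = sig["chrom"].to_numpy()
    start = sig["start"].to_numpy()
    end = sig["end"].to_numpy()
    for c in clusters:
        hit |= (
            (chrom == c.interval.chrom)
            & (start < c.interval.end)
            & (end > c.interval.start)
        )
    return int(hit.sum())


def inside_outside_comparison(
    genes: pd.DataFrame, clusters: list[Cluster], direction: str
) -> dict:
    """Mann–Whitney U tests comparing -log10(p) and log2FC of
    direction-matching regulated genes inside vs outside the cluster
    intervals. NaN p-values when either group is empty."""
    statuses = {
        "upregulated": {"up"},
        "downregulated": {"down"},
        "mixed": {"up", "down"},
    }[direction]
    degs = genes[genes["status"].isin(statuses)]
    inside = np.zeros(len(degs), dtype=bool)
    chrom = degs["chrom"].to_numpy()
    tss = degs["tss"].to_numpy()
    for c in clusters:
        inside |= (
            (chrom == c.interval.chrom)
            & (tss >= c.interval.start)
            & (tss < c.interval.end)
        )
    result = {"n_inside": int(inside.sum()), "n_outside": int((~inside).sum())}
    if result["n_inside"] == 0 or result["n_outside"] == 0:
        result["p_significance"] = float("nan")
        result["p_log2fc"] = float("nan")
        return result
    neglogp = -np.log10(np.clip(degs["p_value"].to_numpy(), 1e-300, None))
    lfc = degs["log2fc"].to_numpy()
    result["p_significance"] = float(
        stats.mannwhitneyu(neglogp[inside], neglogp[~inside],
                           alternative="two-sided").pvalue
    )
    result["p_log2fc"] = float(
        stats.mannwhitneyu(lfc[inside], lfc[~inside],
                           alternative="two-sided").pvalue
    )
    return result


def track_correlation(track_a: EnrichmentTrack, track_b: EnrichmentTrack) -> float:
    """Spearman rank correlation of per-window p-values between two scans
    on the identical grid; NaN for constant tracks."""
    ga, gb = track_a.grid, track_b.grid
    same = (
        ga.width == gb.width
        and ga.step == gb.step
        and len(ga.windows) == len(gb.windows)
        and ga.windows[["arm", "start", "end"]].equals(
            gb.windows[["arm", "start", "end"]]
        )
    )
    if not same:
        raise ValueError("tracks are on different window grids")
    pa = track_a.table["p"].to_numpy()
    pb = track_b.table["p"].to_numpy()
    if np.all(pa == pa[0]) or np.all(pb == pb[0]):
        return float("nan")
    return float(stats.spearmanr(pa, pb).statistic)
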