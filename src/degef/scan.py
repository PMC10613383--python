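"""The enrichment scan: window grid, enrichment scores, null models,
Benjamini–Hochberg correction, cluster calling.

Each chromosome arm is tiled with equally spaced, equal-width sliding
windows (width ``w``, step ``s``). The enrichment score of a window is the
sum of the raw scores of all genes whose TSS falls in it. Significance is
assessed against one of two nulls:

* ``count`` scoring — genes are i.i.d. Bernoulli with success probability
  estimated genome-wide; the window sum is Binomial(n, p_hat) and its
  p-value is the upper tail of the plain normal approximation
  ``N(n*p_hat, n*p_hat*(1-p_hat))`` (no continuity correction).
* ``significance`` / ``foldchange`` scoring — an empirical null built by
  bootstrapping sums of ``n`` raw scores from the genome-wide score pool
  when ``n < t``, switching to the CLT Gaussian ``N(n*mu, sigma*sqrt(n))``
  when ``n >= t``.

Window p-values are BH-adjusted once genome-wide, and maximal runs of
grid-adjacent windows with adjusted p below the FDR threshold are reported
as clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeLayout, GenomicInterval
from .scoring import ScanConfig, prepare_genes, raw_scores

#: floor for Gaussian tail p-values (numeric underflow safety)
P_FLOOR = 1e-300


@dataclass
class WindowGrid:
    """Sliding-window grid over chromosome arms.

    ``windows`` has columns ``arm, chrom, start, end, idx`` where ``idx``
    is the window's ordinal position on its arm (used for contiguity).
    """

    windows: pd.DataFrame
    width: int
    step: int

    def __len__(self) -> int:
        return len(self.windows)


def build_grid(layout: GenomeLayout, width: int, step: int) -> WindowGrid:
    """Tile every arm with windows ``[a + k*s, min(a + k*s + w, b))`` for
    ``k = 0, 1, ...`` while the window start lies inside the arm. The final
    windows on an arm may be truncated at the arm end; an arm shorter than
    ``w`` yields truncated windows only.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if step > width:
        raise ValueError("step must not exceed width")
    records = []
    for arm_id, arm in layout.arms():
        starts = np.arange(arm.start, arm.end, step, dtype=np.int64)
        ends = np.minimum(starts + width, arm.end)
        for k, (ws, we) in enumerate(zip(starts, ends)):
            records.append((arm_id, arm.chrom, int(ws), int(we), k))
    windows = pd.DataFrame(
        records, columns=["arm", "chrom", "start", "end", "idx"]
    )
    return WindowGrid(windows=windows, width=width, step=step)


@dataclass
class NullModel:
    """Genome-wide null for window enrichment scores.

    For ``count`` scoring only ``p_hat`` is meaningful; for the score-based
    methods the raw-score ``pool`` (all scanned genes, zeros included) with
    its population mean ``mu`` and standard deviation ``sigma``, the
    bootstrap count ``x`` and the CLT switch threshold ``t``.
    """

    method: str
    p_hat: float = 0.0
    pool: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mu: float = 0.0
    sigma: float = 0.0
    t: int = 30
    x: int = 6400


def fit_null(genes: pd.DataFrame, config: ScanConfig) -> NullModel:
    """Estimate the null from all scanned genes.

    ``genes`` must carry ``status`` (and ``log2fc``/``fdr`` for the
    score-based methods). The score pool includes zero-scored genes: the
    exchangeable unit is *any* gene, since window ``n`` counts all genes.
    """
    if len(genes) == 0:
        raise ValueError("cannot fit a null model on an empty gene table")
    scores = raw_scores(
        genes["status"], genes["log2fc"], genes["fdr"],
        config.method, config.direction,
    )
    if config.method == "count":
        return NullModel(
            method="count", p_hat=float(scores.mean()),
            t=config.t, x=config.x,
        )
    return NullModel(
        method=config.method,
        pool=scores,
        mu=float(scores.mean()),
        sigma=float(scores.std(ddof=0)),
        t=config.t,
        x=config.x,
    )


@dataclass
class EnrichmentTrack:
    """Per-window scan results.

    ``table`` extends the grid's window frame with ``n`` (gene count),
    ``es`` (enrichment score), and — after the significance/correction
    stages — ``p`` and ``fdr``. ``genes`` is the arm-sorted gene table;
    windows reference their member genes through the half-open index
    ranges ``[lo, hi)`` into it.
    """

    grid: WindowGrid
    table: pd.DataFrame
    genes: pd.DataFrame
    lo: np.ndarray
    hi: np.ndarray

    def window_gene_ids(self, i: int) -> list[str]:
        return list(self.genes["gene_id"].iloc[self.lo[i]: self.hi[i]])


def enrichment_scores(
    grid: WindowGrid,
    genes: pd.DataFrame,
    method: str,
    direction: str,
) -> EnrichmentTrack:
    """Sum raw scores per window (TSS membership, half-open).

    ``genes`` must be arm-annotated and sorted by (arm, tss) — the output
    of :func:`degef.scoring.prepare_genes`. ``n`` counts *all* genes in
    the window, including zero-scored ones.
    """
    scores = raw_scores(
        genes["status"], genes["log2fc"], genes["fdr"], method, direction
    )
    cum = np.concatenate([[0.0], np.cumsum(scores)])

    tss = genes["tss"].to_numpy(dtype=np.int64)
    arm_codes = genes["arm"].to_numpy()
    # first row index of each arm in the sorted gene table
    arm_offset: dict[str, tuple[int, int]] = {}
    if len(genes):
        change = np.flatnonzero(arm_codes[1:] != arm_codes[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(genes)]])
        for i in range(len(bounds) - 1):
            arm_offset[arm_codes[bounds[i]]] = (int(bounds[i]), int(bounds[i + 1]))

    table = grid.windows.copy()
    lo = np.zeros(len(table), dtype=np.int64)
    hi = np.zeros(len(table), dtype=np.int64)
    for arm_id, sub in table.groupby("arm", sort=False):
        o = arm_offset.get(arm_id)
        if o is None:
            continue
        a0, a1 = o
        arm_tss = tss[a0:a1]
        rows = sub.index.to_numpy()
        lo[rows] = a0 + np.searchsorted(arm_tss, sub["start"].to_numpy(), "left")
        hi[rows] = a0 + np.searchsorted(arm_tss, sub["end"].to_numpy(), "left")
    table["n"] = hi - lo
    table["es"] = cum[hi] - cum[lo]
    return EnrichmentTrack(grid=grid, table=table, genes=genes, lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# window p-values


def window_pvalue_count(es, n, null: NullModel):
    """Upper-tail p under the count-mode null ``N(n*p, n*p*(1-p))``.

    No continuity correction. Windows with ``n = 0`` or degenerate
    variance return p = 1. Accepts scalars or arrays.
    """
    if null.method != "count":
        raise ValueError("null model is not count-mode")
    es = np.asarray(es, dtype=float)
    n = np.asarray(n, dtype=float)
    p = null.p_hat
    var = n * p * (1 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.norm.sf(es, loc=n * p, scale=np.sqrt(var))
    pvals = np.where((n == 0) | (var == 0), 1.0, pvals)
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    return float(pvals) if pvals.ndim == 0 else pvals


def _gauss_clt_pvalues(es: np.ndarray, n: np.ndarray, null: NullModel):
    """CLT tail ``N(n*mu, sigma*sqrt(n))`` with degenerate-sigma handling."""
    if null.sigma == 0:
        return np.where(es <= n * null.mu, 1.0, P_FLOOR)
    sd = null.sigma * np.sqrt(n)
    return np.clip(stats.norm.sf(es, loc=n * null.mu, scale=sd), P_FLOOR, 1.0)


def window_pvalue_empirical(
    es: float, n: int, null: NullModel, rng: np.random.Generator
) -> float:
    """p-value for one window under the empirical (score-pool) null.

    ``n < t``: bootstrap — draw ``x`` sums of ``n`` scores sampled with
    replacement from the pool and report ``(1 + #{sums >= es}) / (1 + x)``.
    ``n >= t``: CLT Gaussian tail. ``n = 0`` returns 1.
    """
    if null.method == "count":
        raise ValueError("null model is count-mode; use window_pvalue_count")
    if n == 0:
        return 1.0
    if n >= null.t:
        return float(_gauss_clt_pvalues(np.asarray(es, float),
                                        np.asarray(n, float), null))
    idx = rng.integers(0, len(null.pool), size=(null.x, n))
    sums = null.pool[idx].sum(axis=1)
    k = int(np.count_nonzero(sums >= es))
    return (1 + k) / (1 + null.x)


def empirical_pvalues(
    es: np.ndarray, n: np.ndarray, null: NullModel, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised empirical-null p-values for a whole track.

    One bootstrap null sample (``x`` sums) is drawn per *distinct* window
    gene count ``n < t``, in ascending-n order, and shared by all windows
    with that ``n`` — deterministic for a given RNG state and much cheaper
    than a fresh null per window.
    """
    if null.method == "count":
        raise ValueError("null model is count-mode; use window_pvalue_count")
    es = np.asarray(es, dtype=float)
    n = np.asarray(n, dtype=np.int64)
    pvals = np.ones(len(es), dtype=float)

    clt = n >= null.t
    if clt.any():
        pvals[clt] = _gauss_clt_pvalues(es[clt], n[clt].astype(float), null)

    boot_ns = np.unique(n[(n > 0) & ~clt])
    for nn in boot_ns:
        idx = rng.integers(0, len(null.pool), size=(null.x, int(nn)))
        sums = np.sort(null.pool[idx].sum(axis=1))
        sel = n == nn
        k = null.x - np.searchsorted(sums, es[sel], side="left")
        pvals[sel] = (1 + k) / (1 + null.x)
    return pvals


def bh_correct(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1),
    applied once over all windows genome-wide."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cluster calling


@dataclass
class Cluster:
    """A maximal run of grid-adjacent significant windows."""

    interval: GenomicInterval
    direction: str
    min_fdr: float
    gene_ids: list[str]
    de_gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def call_clusters(
    track: EnrichmentTrack, fdr_thresh: float, direction: str
) -> list[Cluster]:
    """Decompose significant windows (``fdr < fdr_thresh``) into maximal
    runs of adjacent grid indices per arm; each run becomes a cluster
    spanning the union of its windows.

    Member genes are all genes with TSS in the cluster interval;
    direction-matching regulated genes are additionally listed in
    ``de_gene_ids``.
    """
    t = track.table
    sig = t[t["fdr"] < fdr_thresh]
    clusters: list[Cluster] = []
    de_statuses = {
        "upregulated": {"up"},
        "downregulated": {"down"},
        "mixed": {"up", "down"},
    }[direction]
    for arm_id, sub in sig.groupby("arm", sort=False):
        idx = sub["idx"].to_numpy()
        order = np.argsort(idx)
        idx = idx[order]
        rows = sub.index.to_numpy()[order]
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(np.arange(len(idx)), breaks):
            rr = rows[run]
            start = int(t.loc[rr, "start"].min())
            end = int(t.loc[rr, "end"].max())
            chrom = t.loc[rr[0], "chrom"]
            interval = GenomicInterval(chrom, start, end)
            g = track.genes
            in_cluster = (
                (g["chrom"] == chrom)
                & (g["tss"] >= start)
                & (g["tss"] < end)
            )
            members = g.loc[in_cluster]
            de = members.loc[members["status"].isin(de_statuses)]
            clusters.append(
                Cluster(
                    interval=interval,
                    direction=direction,
                    min_fdr=float(t.loc[rr, "fdr"].min()),
                    gene_ids=list(members["gene_id"]),
                    de_gene_ids=list(de["gene_id"]),
                )
            )
    return clusters


# ---------------------------------------------------------------------------
# orchestration


def run_scan(
    genes: pd.DataFrame,
    layout: GenomeLayout,
    config: ScanConfig | None = None,
) -> tuple[EnrichmentTrack, list[Cluster]]:
    """Full scan: classify -> grid -> enrichment -> null -> p -> BH ->
    clusters. Returns the per-window track and the called clusters.

    ``genes`` needs columns ``gene_id, chrom, tss, log2fc, fdr`` (a
    ``status`` column, if present, is honoured as-is).
    """
    config = config or ScanConfig()
    prepared = prepare_genes(
        genes, layout, p_thresh=config.p_thresh, fc_thresh=config.fc_thresh
    )
    grid = build_grid(layout, config.window_width, config.step)
    track = enrichment_scores(grid, prepared, config.method, config.direction)
    null = fit_null(prepared, config)
    es = track.table["es"].to_numpy()
    n = track.table["n"].to_numpy()
    if config.method == "count":
        pvals = window_pvalue_count(es, n, null)
    else:
        rng = np.random.default_rng(config.seed)
        pvals = empirical_pvalues(es, n, null, rng)
    track.table["p"] = pvals
    track.table["fdr"] = bh_correct(pvals)
    clusters = call_clusters(track, config.fdr_thresh, config.direction)
    return track, clusters
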