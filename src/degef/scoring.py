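"""Per-gene regulation calls and raw scores.

A gene is *upregulated* when its BH-adjusted p-value (FDR) is at or below
the significance threshold and its fold change is at least the fold-change
threshold (``log2fc >= log2(fc_thresh)``); *downregulated* symmetrically
(``log2fc <= -log2(fc_thresh)``); otherwise *not significant* (``ns``).

Raw scores feed the window enrichment statistic and come in three flavours:

``count``
    1 for a gene whose call matches the scan direction, else 0.
``significance``
    ``-log10(FDR)`` for a matching gene, else 0.
``foldchange``
    ``|log2FC|`` for a matching gene, else 0.

In ``mixed`` direction both up- and down-regulated genes match. All raw
scores are nonnegative by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout

logger = logging.getLogger(__name__)

DIRECTIONS = ("upregulated", "downregulated", "mixed")
METHODS = ("count", "significance", "foldchange")

#: floor applied to FDR values before -log10 (guards limma underflow to 0)
FDR_FLOOR = 1e-300


@dataclass
class ScanConfig:
    """Run-time parameters of the enrichment scan.

    Defaults follow the method's published parameterisation: 500 kb
    windows stepped every 20 kb, adjusted-p threshold 0.05, fold-change
    threshold 2.0, bootstrap count ``x = 6400`` with a CLT switch at
    ``t = 30`` genes per window, and a cluster-calling FDR of 0.05.
    """

    direction: str = "upregulated"
    method: str = "count"
    p_thresh: float = 0.05
    fc_thresh: float = 2.0
    window_width: int = 500_000
    step: int = 20_000
    t: int = 30
    x: int = 6400
    fdr_thresh: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.step > self.window_width:
            raise ValueError("step must not exceed window_width")
        if self.window_width <= 0 or self.step <= 0:
            raise ValueError("window_width and step must be positive")
        if not (0 < self.p_thresh < 1) or not (0 < self.fdr_thresh < 1):
            raise ValueError("p_thresh and fdr_thresh must lie in (0, 1)")
        if self.fc_thresh < 1:
            raise ValueError("fc_thresh must be >= 1")
        if self.t < 1 or self.x < 1:
            raise ValueError("t and x must be >= 1")


def classify_genes(
    log2fc,
    fdr,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
) -> np.ndarray:
    """Vectorised regulation call: array of ``{"up", "down", "ns"}``.

    Both threshold comparisons are inclusive (FDR <= p_thresh; FC >= 2 or
    FC <= 1/2 at the default fold-change threshold).
    """
    if fc_thresh < 1:
        raise ValueError("fc_thresh must be >= 1")
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if np.any((fdr < 0) | (fdr > 1)):
        raise ValueError("fdr values must lie in [0, 1]")
    lfc_thresh = np.log2(fc_thresh)
    sig = fdr <= p_thresh
    status = np.full(log2fc.shape, "ns", dtype=object)
    status[sig & (log2fc >= lfc_thresh)] = "up"
    status[sig & (log2fc <= -lfc_thresh)] = "down"
    return status


def classify_gene(
    log2fc: float, fdr: float, p_thresh: float = 0.05, fc_thresh: float = 2.0
) -> str:
    """Scalar convenience wrapper around :func:`classify_genes`."""
    return classify_genes([log2fc], [fdr], p_thresh, fc_thresh)[0]


def raw_scores(
    status, log2fc, fdr, method: str, direction: str
) -> np.ndarray:
    """Per-gene raw scores for a (method, direction) pair.

    ``status`` must already hold the regulation calls (see
    :func:`classify_genes`).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    status = np.asarray(status, dtype=object)
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)

    match_up = (status == "up") & (direction in ("upregulated", "mixed"))
    match_down = (status == "down") & (direction in ("downregulated", "mixed"))

    if method == "count":
        return (match_up | match_down).astype(float)
    if method == "significance":
        neglog = -np.log10(np.clip(fdr, FDR_FLOOR, None))
        return np.where(match_up | match_down, neglog, 0.0)
    # foldchange: log2FC for up, -log2FC for down; both nonnegative
    scores = np.zeros(len(status), dtype=float)
    scores[match_up] = log2fc[match_up]
    scores[match_down] = -log2fc[match_down]
    return scores


def raw_score(gene: pd.Series, method: str, direction: str) -> float:
    """Raw score of a single gene record (row with status/log2fc/fdr)."""
    return float(
        raw_scores(
            [gene["status"]], [gene["log2fc"]], [gene["fdr"]], method, direction
        )[0]
    )


def prepare_genes(
    genes: pd.DataFrame,
    layout: GenomeLayout,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
) -> pd.DataFrame:
    """Classify genes, map each TSS to a chromosome arm, and drop genes
    off the layout (unplaced contigs, centromeric TSS).

    Returns a copy sorted by (arm, tss) with ``status`` and ``arm``
    columns added; the dropped count is logged.
    """
    genes = genes.copy()
    if "status" not in genes.columns:
        genes["status"] = classify_genes(
            genes["log2fc"], genes["fdr"], p_thresh, fc_thresh
        )
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in table")
    arms = [
        layout.arm_of(c, int(t))
        for c, t in zip(genes["chrom"], genes["tss"])
    ]
    genes["arm"] = arms
    n_dropped = sum(a is None for a in arms)
    if n_dropped:
        logger.info(
            "dropped %d gene(s) outside the genome layout", n_dropped
        )
    genes = genes[genes["arm"].notna()]
    return genes.sort_values(["arm", "tss"], kind="mergesort").reset_index(
        drop=True
    )
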