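"""Readers and writers for the text formats the tool consumes/produces:
DE tables (TSV), TADs (BED), loops (BEDPE / flagged TSV), peaks
(narrowPeak), plus cluster BED/TSV and per-window bedGraph output."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scan import Cluster, EnrichmentTrack
from .tads import Rearrangement, TADSet

#: default column names of an upstream differential-expression table
DEG_COLUMN_MAP = {
    "gene_id": "gene_id",
    "chrom": "chrom",
    "log2fc": "logFC",
    "p_value": "P.Value",
    "fdr": "adj.P.Val",
}


def read_deg_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a differential-expression TSV into the canonical gene frame
    (gene_id, chrom, tss, strand, log2fc, p_value, fdr).

    The TSS is taken from a ``tss`` column when present; otherwise from
    ``start``/``end`` strand-aware (start for ``+``, end for ``-``, start
    when the strand is unknown). ``column_map`` remaps canonical names to
    the file's own headers on top of the limma-style defaults.
    """
    cmap = dict(DEG_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame()
    for canon in ("gene_id", "chrom", "log2fc", "p_value", "fdr"):
        col = cmap.get(canon, canon)
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
        out[canon] = df[col]
    strand_col = cmap.get("strand", "strand")
    strand = df[strand_col] if strand_col in df.columns else "."
    out["strand"] = strand
    tss_col = cmap.get("tss", "tss")
    if tss_col in df.columns:
        out["tss"] = df[tss_col].astype(np.int64)
    else:
        start_col, end_col = cmap.get("start", "start"), cmap.get("end", "end")
        if start_col not in df.columns or end_col not in df.columns:
            raise ValueError(
                f"{path}: need a 'tss' column or 'start'/'end' columns"
            )
        start = df[start_col].astype(np.int64)
        end = df[end_col].astype(np.int64)
        out["tss"] = np.where(out["strand"] == "-", end, start)
    return out[
        ["gene_id", "chrom", "tss", "strand", "log2fc", "p_value", "fdr"]
    ]


def read_tads(path, bin_size: int) -> TADSet:
    """Read TAD intervals from a BED (first three columns used)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return TADSet.from_intervals(df, bin_size=bin_size)


def read_loops_bedpe(
    pre_path, post_path, q_thresh: float = 0.01, q_column: int = 6
) -> pd.DataFrame:
    """Build a matched loop table from two BEDPE files (pre/post) carrying
    a q-value column (0-based index ``q_column``, FitHiChIP convention).

    Loops are matched across conditions by exact anchor coordinates; a
    loop present in only one file counts as non-significant in the other.
    """
    def load(path):
        recs = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                p = line.split("\t")
                key = (p[0], int(p[1]), int(p[2]), int(p[4]), int(p[5]))
                if p[0] != p[3]:
                    continue  # inter-chromosomal loops are out of scope
                recs[key] = float(p[q_column]) <= q_thresh
        return recs

    pre, post = load(pre_path), load(post_path)
    rows = []
    for key in sorted(set(pre) | set(post)):
        chrom, s1, e1, s2, e2 = key
        rows.append({
            "chrom": chrom, "start1": s1, "end1": e1,
            "start2": s2, "end2": e2,
            "significant_pre": pre.get(key, False),
            "significant_post": post.get(key, False),
        })
    return pd.DataFrame(
        rows, columns=["chrom", "start1", "end1", "start2", "end2",
                       "significant_pre", "significant_post"]
    )


def read_loops_tsv(path) -> pd.DataFrame:
    """Read a flagged loop TSV (the simulator's output format)."""
    df = pd.read_csv(path, sep="\t")
    df["significant_pre"] = df["significant_pre"].astype(bool)
    df["significant_post"] = df["significant_post"].astype(bool)
    return df


def read_narrowpeak(path) -> pd.DataFrame:
    """Read a MACS-style narrowPeak; column 9 (-log10 q) becomes ``fdr``."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) < 9:
                raise ValueError(f"{path}: malformed line {lineno}")
            rows.append((p[0], int(p[1]), int(p[2]), 10.0 ** -float(p[8])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fdr"])


# ---------------------------------------------------------------------------
# writers


def _neglog10(x: float) -> float:
    return float(-np.log10(max(x, 1e-300)))


def write_cluster_bed(clusters: list[Cluster], path) -> None:
    """BED: chrom, start, end, name, -log10(min FDR), direction."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters, start=1):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\tcluster_{i}\t{_neglog10(c.min_fdr):.4f}\t{c.direction}\n"
            )


def write_cluster_table(clusters: list[Cluster], path) -> None:
    """TSV with one row per cluster: coordinates, lowest FDR, and member
    genes (regulated members starred)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tmin_fdr\tn_genes\tgenes\n")
        for c in clusters:
            de = set(c.de_gene_ids)
            genes = ",".join(
                g + "*" if g in de else g for g in c.gene_ids
            )
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.direction}\t{c.min_fdr:.6g}\t{c.n_genes}\t{genes}\n"
            )


def write_track_bedgraphs(track: EnrichmentTrack, prefix) -> None:
    """Four bedGraphs per scan: es, -log10 p, -log10 fdr, n."""
    t = track.table
    cols = {
        "es": t["es"],
        "neglog10_p": [-np.log10(max(v, 1e-300)) for v in t["p"]],
        "neglog10_fdr": [-np.log10(max(v, 1e-300)) for v in t["fdr"]],
        "n": t["n"],
    }
    for name, values in cols.items():
        with open(f"{prefix}.{name}.bedgraph", "w") as fh:
            for (chrom, start, end), v in zip(
                zip(t["chrom"], t["start"], t["end"]), values
            ):
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def write_rearrangement_bed(rearrs: list[Rearrangement], path) -> None:
    """BED of rearrangements: category in the name field, pre/post TAD
    counts as extra columns."""
    with open(path, "w") as fh:
        for r in rearrs:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.category}\t{r.pre_tad_count}\t{r.post_tad_count}\n"
            )


def read_rearrangement_bed(path) -> list[Rearrangement]:
    from .genome import GenomicInterval

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            out.append(
                Rearrangement(
                    interval=GenomicInterval(p[0], int(p[1]), int(p[2])),
                    category=p[3],
                    pre_tad_count=int(p[4]) if len(p) > 4 else 0,
                    post_tad_count=int(p[5]) if len(p) > 5 else 0,
                )
            )
    return out


def read_cluster_bed(path) -> list[Cluster]:
    """Read clusters back from the BED this package writes (member gene
    lists are not recoverable from BED and come back empty)."""
    from .genome import GenomicInterval

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            out.append(
                Cluster(
                    interval=GenomicInterval(p[0], int(p[1]), int(p[2])),
                    direction=p[5] if len(p) > 5 else "mixed",
                    min_fdr=10.0 ** -float(p[4]) if len(p) > 4 else float("nan"),
                    gene_ids=[],
                    de_gene_ids=[],
                )
            )
    return out
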