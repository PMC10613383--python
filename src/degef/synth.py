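"""Synthetic data with known ground truth.

Generates (i) differential-expression tables whose genes sit at uniform
TSS positions with i.i.d. regulation calls outside planted clusters and an
elevated rate inside them, (ii) paired TAD call sets with archetypal
planted rearrangements (merge / split / complex variants / balanced
shift), and (iii) chromatin loops whose post- (or pre-) perturbation
significance probability is elevated inside planted up- (down-) clusters.

Everything is driven by a single seed; identical spec + seed gives
byte-identical outputs. Adjusted p-values are drawn directly on the
regulated/unregulated sides of the significance threshold rather than
derived from simulated counts: the scan consumes the upstream model's
output interface, so emulating its distributional shape exercises every
code path.

The default genome — three 50 Mb chromosomes with a 1 Mb centromere at the
midpoint and 10 genes/Mb (~1500 genes, ~7000 default windows) — is a
desk-scale stand-in for a mammalian genome. The default background
regulation probability of 0.10 per direction mirrors a strong stimulation
contrast in which roughly a tenth of genes respond in each direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GenomicInterval, overlap_bp
from .tads import CATEGORIES, TADSet

DEFAULT_CHROMS = {"chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000}


def _default_centromeres() -> dict[str, tuple[int, int]]:
    return {c: (24_500_000, 25_500_000) for c in DEFAULT_CHROMS}


@dataclass(frozen=True)
class PlantedCluster:
    chrom: str
    start: int
    end: int
    direction: str  # "up" or "down"
    de_prob: float
    log2fc_mean: float = 2.0
    log2fc_sd: float = 0.5

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class PlantedRearrangement:
    chrom: str
    start: int
    end: int
    category: str

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


#: baseline TADs consumed per planted category
_TADS_NEEDED = {
    "simple_merge": 2,
    "simple_split": 1,
    "complex_merge": 3,
    "complex_split": 2,
    "balanced_shift": 2,
}


@dataclass
class SynthSpec:
    """Ground-truth description of one synthetic dataset."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMS)
    )
    centromeres: dict[str, tuple[int, int]] = field(
        default_factory=_default_centromeres
    )
    genes_per_mb: float = 10.0
    background_up: float = 0.10
    background_down: float = 0.10
    de_fdr_max: float = 0.05       # regulated genes: FDR ~ U(0, de_fdr_max)
    de_log2fc_min: float = 1.0     # |log2FC| floor so calls match truth
    null_log2fc_sd: float = 0.2
    clusters: list[PlantedCluster] = field(default_factory=list)
    rearrangements: list[PlantedRearrangement] = field(default_factory=list)
    tad_bin_size: int = 100_000
    tad_size_bins: int = 10
    n_loops: int = 0
    loop_anchor_width: int = 5_000
    loop_base_sig: float = 0.3
    loop_boost_sig: float = 0.8    # elevated side inside planted clusters
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.background_up, self.background_down, self.loop_base_sig,
            self.loop_boost_sig,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        layout = self.layout
        for pc in self.clusters:
            if not 0 <= pc.de_prob <= 1:
                raise ValueError("cluster de_prob must lie in [0, 1]")
            if pc.direction not in ("up", "down"):
                raise ValueError(f"cluster direction {pc.direction!r}")
            self._check_interval(pc.interval, layout, "cluster")
        for pr in self.rearrangements:
            if pr.category not in CATEGORIES:
                raise ValueError(f"unknown category {pr.category!r}")
            self._check_interval(pr.interval, layout, "rearrangement")
        ordered = sorted(
            self.rearrangements, key=lambda r: (r.chrom, r.start)
        )
        for a, b in zip(ordered[:-1], ordered[1:]):
            if a.chrom == b.chrom and b.start - a.end < self.tad_bin_size:
                raise ValueError(
                    "planted rearrangements closer than one bin: "
                    f"{a.chrom}:{a.end} vs {b.start}"
                )

    @staticmethod
    def _check_interval(iv: GenomicInterval, layout: GenomeLayout, what: str):
        if iv.chrom not in layout.chrom_lengths:
            raise ValueError(f"planted {what} on unknown chromosome {iv.chrom}")
        if iv.end > layout.chrom_lengths[iv.chrom]:
            raise ValueError(f"planted {what} exceeds chromosome {iv.chrom}")
        cen = layout.centromere_interval(iv.chrom)
        if cen is not None and overlap_bp(iv, cen) > 0:
            raise ValueError(f"planted {what} overlaps the centromere")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            chrom_lengths=dict(self.chrom_lengths),
            centromeres=dict(self.centromeres),
        )

    def with_seed(self, seed: int) -> "SynthSpec":
        return replace(self, seed=seed)


def default_clusters(
    n: int = 5,
    width: int = 1_500_000,
    de_prob: float = 0.5,
    direction: str = "up",
) -> list[PlantedCluster]:
    """Evenly spread planted clusters over the default genome's arms,
    clear of centromeres."""
    chroms = list(DEFAULT_CHROMS)
    anchors = [
        ("chr1", 5_000_000), ("chr1", 35_000_000), ("chr2", 10_000_000),
        ("chr2", 40_000_000), ("chr3", 15_000_000), ("chr3", 30_000_000),
        ("chr1", 15_000_000), ("chr2", 30_000_000), ("chr3", 5_000_000),
    ]
    if n > len(anchors):
        raise ValueError(f"at most {len(anchors)} default clusters")
    assert all(c in chroms for c, _ in anchors)
    return [
        PlantedCluster(c, s, s + width, direction, de_prob)
        for c, s in anchors[:n]
    ]


def default_rearrangements() -> list[PlantedRearrangement]:
    """One planted rearrangement of each category on the default genome.

    Intervals are aligned to the default 1 Mb baseline TAD tiling that
    :func:`generate_tad_pair` lays down (TADs start at 0 on the p arm and
    at 25.5 Mb on the q arm).
    """
    return [
        PlantedRearrangement("chr1", 2_000_000, 4_000_000, "simple_merge"),
        PlantedRearrangement("chr1", 8_000_000, 9_000_000, "simple_split"),
        PlantedRearrangement("chr2", 2_000_000, 5_000_000, "complex_merge"),
        PlantedRearrangement("chr2", 8_000_000, 10_000_000, "complex_split"),
        PlantedRearrangement("chr3", 2_000_000, 4_000_000, "balanced_shift"),
    ]


# ---------------------------------------------------------------------------
# DEG table


def generate_deg_table(spec: SynthSpec) -> tuple[pd.DataFrame, dict]:
    """Gene table (gene_id, chrom, tss, strand, log2fc, p_value, fdr,
    true_status) plus a truth dict describing the planted clusters.

    TSS positions are uniform per arm at ``genes_per_mb``; regulation is
    Bernoulli(background) outside planted clusters and
    Bernoulli(cluster rate) for the cluster's direction inside (the
    opposite direction keeps its background rate inside clusters).
    Regulated genes draw FDR ~ U(0, de_fdr_max) and |log2FC| ~
    N(log2fc_mean, log2fc_sd) floored at ``de_log2fc_min``; unregulated
    genes draw FDR ~ U(de_fdr_max, 1) and small log2FC.
    """
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout
    frames = []
    counter = 0
    for arm_id, arm in layout.arms():
        n = int(round(arm.length * spec.genes_per_mb / 1e6))
        tss = np.sort(rng.integers(arm.start, arm.end, size=n))
        status = np.full(n, "ns", dtype=object)
        u = rng.random(n)
        # background assignment
        status[u < spec.background_up] = "up"
        status[(u >= spec.background_up)
               & (u < spec.background_up + spec.background_down)] = "down"
        # planted clusters override genes inside them
        for pc in spec.clusters:
            if pc.chrom != arm.chrom:
                continue
            inside = (tss >= pc.start) & (tss < pc.end)
            if not inside.any():
                continue
            v = rng.random(int(inside.sum()))
            other = "down" if pc.direction == "up" else "up"
            other_bg = (
                spec.background_down if pc.direction == "up"
                else spec.background_up
            )
            s = np.full(len(v), "ns", dtype=object)
            s[v < pc.de_prob] = pc.direction
            s[(v >= pc.de_prob) & (v < pc.de_prob + other_bg)] = other
            status[inside] = s

        is_de = status != "ns"
        n_de = int(is_de.sum())
        fdr = rng.uniform(spec.de_fdr_max, 1.0, size=n)
        fdr[is_de] = rng.uniform(0.0, spec.de_fdr_max, size=n_de)
        log2fc = rng.normal(0.0, spec.null_log2fc_sd, size=n)
        mag = np.maximum(
            rng.normal(2.0, 0.5, size=n_de), spec.de_log2fc_min
        )
        # per-cluster fold-change distributions where planted
        for pc in spec.clusters:
            if pc.chrom != arm.chrom:
                continue
            in_pc = is_de & (tss >= pc.start) & (tss < pc.end) & (
                status == pc.direction
            )
            k = int(in_pc.sum())
            if k:
                sub = np.maximum(
                    rng.normal(pc.log2fc_mean, pc.log2fc_sd, size=k),
                    spec.de_log2fc_min,
                )
                mag_idx = np.cumsum(is_de) - 1
                mag[mag_idx[in_pc]] = sub
        sign = np.where(status[is_de] == "up", 1.0, -1.0)
        log2fc[is_de] = sign * mag
        p_value = fdr * rng.random(n)

        frames.append(pd.DataFrame({
            "gene_id": [f"g{counter + i:05d}" for i in range(n)],
            "chrom": arm.chrom,
            "tss": tss,
            "strand": ".",
            "log2fc": log2fc,
            "p_value": p_value,
            "fdr": fdr,
            "true_status": status,
        }))
        counter += n
    genes = pd.concat(frames, ignore_index=True)
    truth = {
        "clusters": [
            {"chrom": pc.chrom, "start": pc.start, "end": pc.end,
             "direction": pc.direction, "de_prob": pc.de_prob}
            for pc in spec.clusters
        ],
        "n_genes": int(len(genes)),
        "background_up": spec.background_up,
        "background_down": spec.background_down,
    }
    return genes, truth


# ---------------------------------------------------------------------------
# TAD pairs


def _baseline_tads(spec: SynthSpec) -> dict[str, np.ndarray]:
    """Gapless tiling of each arm with ``tad_size_bins``-bin TADs aligned
    to the bin grid; a short remainder is absorbed into the last TAD."""
    layout = spec.layout
    b = spec.tad_bin_size
    size = spec.tad_size_bins * b
    tads: dict[str, list[list[int]]] = {}
    for arm_id, arm in layout.arms():
        start = -(-arm.start // b) * b           # ceil to bin grid
        end = (arm.end // b) * b                 # floor to bin grid
        edges = list(range(start, end + 1, size))
        if len(edges) < 2:
            continue
        if end - edges[-1] >= b:
            edges.append(end)
        else:
            edges[-1] = end
        for a, c in zip(edges[:-1], edges[1:]):
            tads.setdefault(arm.chrom, []).append([a, c])
    return {c: np.asarray(v, dtype=np.int64) for c, v in tads.items()}


def _edit_region(
    pre: np.ndarray, category: str, bin_size: int
) -> tuple[np.ndarray, GenomicInterval | None]:
    """Apply one archetypal edit to the first TADs of ``pre`` (the TADs
    inside one planted interval); returns the edited (post) intervals and
    the expected rearrangement region."""
    need = _TADS_NEEDED[category]
    if len(pre) < need:
        raise ValueError(
            f"category {category} needs {need} baseline TADs, found {len(pre)}"
        )
    snap = lambda x: int(round(x / bin_size)) * bin_size
    if category == "simple_merge":
        a, c = pre[0][0], pre[1][1]
        return np.array([[a, c]] + pre[2:].tolist()), None
    if category == "simple_split":
        a, b_ = pre[0]
        m = snap((a + b_) / 2)
        return np.array([[a, m], [m, b_]] + pre[1:].tolist()), None
    if category == "complex_merge":
        a, d = pre[0][0], pre[2][1]
        e = snap((a + d) / 2)
        return np.array([[a, e], [e, d]] + pre[3:].tolist()), None
    if category == "complex_split":
        a, c = pre[0][0], pre[1][1]
        e1 = snap(a + (c - a) / 3)
        e2 = snap(a + 2 * (c - a) / 3)
        return np.array([[a, e1], [e1, e2], [e2, c]] + pre[2:].tolist()), None
    # balanced_shift
    a, b_ = pre[0]
    c = pre[1][1]
    e = b_ + 2 * bin_size
    if e >= c - bin_size:
        raise ValueError("balanced shift needs wider TADs")
    return np.array([[a, e], [e, c]] + pre[2:].tolist()), None


def generate_tad_pair(
    spec: SynthSpec,
) -> tuple[TADSet, TADSet, list[PlantedRearrangement]]:
    """Baseline TAD tiling plus category-archetypal edits inside each
    planted interval; outside them pre == post exactly.

    The returned truth list carries the realised rearrangement regions
    (flanked by the unedited concordant boundaries).
    """
    base = _baseline_tads(spec)
    post: dict[str, list[list[int]]] = {
        c: arr.tolist() for c, arr in base.items()
    }
    truth: list[PlantedRearrangement] = []
    for pr in spec.rearrangements:
        arr = np.asarray(post[pr.chrom], dtype=np.int64)
        inside = (arr[:, 0] >= pr.start) & (arr[:, 1] <= pr.end)
        idx = np.flatnonzero(inside)
        need = _TADS_NEEDED[pr.category]
        if len(idx) < need:
            raise ValueError(
                f"planted {pr.category} at {pr.chrom}:{pr.start}-{pr.end} "
                f"covers {len(idx)} baseline TADs, needs {need}"
            )
        if len(idx) and np.any(np.diff(idx) != 1):
            raise ValueError("planted interval spans non-adjacent TADs")
        i0 = idx[0]
        region_tads = arr[i0: i0 + need]
        block, _ = _edit_region(region_tads, pr.category, spec.tad_bin_size)
        block = block[: _edited_len(pr.category)]
        new = np.vstack([arr[:i0], block, arr[i0 + need:]])
        post[pr.chrom] = new.tolist()
        truth.append(
            PlantedRearrangement(
                pr.chrom, int(region_tads[0][0]), int(region_tads[-1][1]),
                pr.category,
            )
        )
    pre_set = TADSet(
        tads={c: a.copy() for c, a in base.items()}, bin_size=spec.tad_bin_size
    )
    post_set = TADSet(
        tads={c: np.asarray(v, dtype=np.int64) for c, v in post.items()},
        bin_size=spec.tad_bin_size,
    )
    return pre_set, post_set, truth


def _edited_len(category: str) -> int:
    return {
        "simple_merge": 1, "simple_split": 2, "complex_merge": 2,
        "complex_split": 3, "balanced_shift": 2,
    }[category]


# ---------------------------------------------------------------------------
# loops


def generate_loops(
    spec: SynthSpec, cluster_truth: list[dict] | None = None
) -> pd.DataFrame:
    """Intra-chromosomal loops with pre/post significance flags.

    Anchors are uniform; loops touching a planted up-cluster get an
    elevated post-perturbation significance probability (pre stays at
    base), and symmetrically for down-clusters.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if cluster_truth is None:
        cluster_truth = [
            {"chrom": pc.chrom, "start": pc.start, "end": pc.end,
             "direction": pc.direction}
            for pc in spec.clusters
        ]
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    w = spec.loop_anchor_width
    rows = []
    for _ in range(spec.n_loops):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        length = spec.chrom_lengths[chrom]
        span = int(rng.uniform(50_000, 2_000_000))
        s1 = int(rng.integers(0, max(1, length - span - w)))
        s2 = s1 + span
        p_pre, p_post = spec.loop_base_sig, spec.loop_base_sig
        for ct in cluster_truth:
            if ct["chrom"] != chrom:
                continue
            touches = (s1 < ct["end"] and s1 + w > ct["start"]) or (
                s2 < ct["end"] and s2 + w > ct["start"]
            )
            if touches:
                if ct["direction"] == "up":
                    p_post = spec.loop_boost_sig
                else:
                    p_pre = spec.loop_boost_sig
                break
        rows.append({
            "chrom": chrom, "start1": s1, "end1": s1 + w,
            "start2": s2, "end2": s2 + w,
            "significant_pre": bool(rng.random() < p_pre),
            "significant_post": bool(rng.random() < p_post),
        })
    return pd.DataFrame(
        rows,
        columns=["chrom", "start1", "end1", "start2", "end2",
                 "significant_pre", "significant_post"],
    )


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(spec: SynthSpec, outdir) -> None:
    """Write the synthetic dataset in the same text formats the analysis
    commands read, plus a ``truth.json``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    layout = spec.layout
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for c, ln in layout.chrom_lengths.items():
            fh.write(f"{c}\t{ln}\n")
    with open(os.path.join(outdir, "centromeres.bed"), "w") as fh:
        for c, (cs, ce) in layout.centromeres.items():
            fh.write(f"{c}\t{cs}\t{ce}\tcen\n")

    genes, truth = generate_deg_table(spec)
    deg = genes.rename(columns={
        "log2fc": "logFC", "p_value": "P.Value", "fdr": "adj.P.Val",
    })
    deg.to_csv(os.path.join(outdir, "deg_table.tsv"), sep="\t", index=False)

    pre, post, tad_truth = generate_tad_pair(spec)
    for name, ts in (("tads_pre.bed", pre), ("tads_post.bed", post)):
        with open(os.path.join(outdir, name), "w") as fh:
            for chrom in ts.chroms:
                for s, e in ts.tads[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    loops = generate_loops(spec, truth["clusters"])
    loops.to_csv(os.path.join(outdir, "loops.tsv"), sep="\t", index=False)

    truth["rearrangements"] = [
        {"chrom": r.chrom, "start": r.start, "end": r.end,
         "category": r.category}
        for r in tad_truth
    ]
    truth["tad_bin_size"] = spec.tad_bin_size
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
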