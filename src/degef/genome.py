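"""Genome coordinate model: chromosomes, centromeres, arms, and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED
convention. Chromosome arms are the two maximal intervals flanking the
centromere; chromosomes without a centromere annotation are treated as a
single arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True iff ``pos`` lies in the half-open interval."""
        return self.start <= pos < self.end


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length (bp) of the intersection of two intervals; 0 if disjoint
    or on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class GenomeLayout:
    """Chromosome lengths plus optional centromere intervals.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp (all > 0).
    centromeres
        Mapping chromosome name -> ``(start, end)`` of the centromere,
        strictly inside the chromosome. Chromosomes absent from this
        mapping are single-arm.
    """

    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(
                    f"centromere on unknown chromosome {chrom!r}"
                )
            if not (0 < cs < ce < self.chrom_lengths[chrom]):
                raise ValueError(
                    f"centromere [{cs}, {ce}) not strictly inside {chrom}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def chrom_interval(self, chrom: str) -> GenomicInterval:
        return GenomicInterval(chrom, 0, self.chrom_lengths[chrom])

    def centromere_interval(self, chrom: str) -> GenomicInterval | None:
        if chrom not in self.centromeres:
            return None
        cs, ce = self.centromeres[chrom]
        return GenomicInterval(chrom, cs, ce)

    def arms(self) -> list[tuple[str, GenomicInterval]]:
        """Ordered ``(arm_id, interval)`` pairs.

        A chromosome with a centromere yields ``chrom:p`` (before) and
        ``chrom:q`` (after); otherwise a single arm named after the
        chromosome.
        """
        out: list[tuple[str, GenomicInterval]] = []
        for chrom, length in self.chrom_lengths.items():
            if chrom in self.centromeres:
                cs, ce = self.centromeres[chrom]
                out.append((f"{chrom}:p", GenomicInterval(chrom, 0, cs)))
                out.append((f"{chrom}:q", GenomicInterval(chrom, ce, length)))
            else:
                out.append((chrom, GenomicInterval(chrom, 0, length)))
        return out

    def arm_of(self, chrom: str, pos: int) -> str | None:
        """Arm id containing position ``pos``, or None (off-layout or
        inside the centromere)."""
        if chrom not in self.chrom_lengths:
            return None
        if not 0 <= pos < self.chrom_lengths[chrom]:
            return None
        if chrom in self.centromeres:
            cs, ce = self.centromeres[chrom]
            if pos < cs:
                return f"{chrom}:p"
            if pos >= ce:
                return f"{chrom}:q"
            return None
        return chrom


def load_layout(chrom_sizes_path, centromere_path=None) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from a two-column ``chrom.sizes`` TSV
    and an optional centromere BED.

    Unknown chromosomes in the centromere file and malformed lines raise
    ``ValueError`` naming the offender / line number.
    """
    lengths: dict[str, int] = {}
    with open(chrom_sizes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{chrom_sizes_path}: malformed line {lineno}: {line!r}"
                )
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{chrom_sizes_path}: malformed line {lineno}: {line!r}"
                ) from exc

    centromeres: dict[str, tuple[int, int]] = {}
    if centromere_path is not None:
        with open(centromere_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{centromere_path}: malformed line {lineno}: {line!r}"
                    )
                chrom = parts[0]
                if chrom not in lengths:
                    raise ValueError(
                        f"{centromere_path}: line {lineno}: centromere on "
                        f"unknown chromosome {chrom!r}"
                    )
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{centromere_path}: malformed line {lineno}: {line!r}"
                    ) from exc
                if chrom in centromeres:
                    # UCSC splits centromeres into multiple records; merge.
                    cs, ce = centromeres[chrom]
                    start, end = min(start, cs), max(end, ce)
                centromeres[chrom] = (start, end)

    return GenomeLayout(chrom_lengths=lengths, centromeres=centromeres)
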