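"""Genomic intervals, probe maps and coverage queries.

Coordinates are 0-based half-open (BED convention) everywhere inside the
package.  Inputs recorded in 1-based inclusive coordinates must be declared
as such at read time (``one_based=True``) and are converted on entry.
Strand is ignored throughout: copy number is strand-symmetric.

Coverage queries (:func:`probes_in`, :func:`coverage_gaps`) are the
primitives behind the discordance taxonomy — a platform can only call an
abnormality where it has probes, and an uncovered intra-gene gap (such as
the ~42 kb probe-free stretch inside IKZF1 intron 3 on SNP6.0-class arrays)
changes how focal events present to a segmentation algorithm.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must exceed start ({self.start}) for {self.name or self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ArrayProbe:
    """A single SNP-array probe: a width-1 locus with optional GC context.

    ``gc_fraction`` is the GC content of the window surrounding the probe,
    used as the covariate for wave correction of LRR values.
    """

    probe_id: str
    locus: GenomicInterval
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.locus.width != 1:
            raise ValueError(f"array probe {self.probe_id} locus must have width 1")
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction out of [0,1] for probe {self.probe_id}")

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def pos(self) -> int:
        return self.locus.start


@dataclass(frozen=True)
class MLPAProbe:
    """An MLPA kit probe targeting one exon of one gene."""

    probe_id: str
    gene: str
    exon_label: str
    locus: GenomicInterval


@dataclass(frozen=True)
class GeneRegion:
    """A comparison region: gene span plus its ordered, disjoint exons."""

    name: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom:
                raise ValueError(f"{self.name}: exon chromosome differs from span")
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(f"{self.name}: exon {exon} outside gene span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"{self.name}: exons overlap or are unsorted")
            prev_end = exon.end

    def exon_index(self, interval: GenomicInterval) -> tuple[str, str] | None:
        """Labels of the first and last exon overlapped by ``interval``."""
        hit = [e for e in self.exons if e.overlaps(interval)]
        if not hit:
            return None
        return hit[0].name or "1", hit[-1].name or str(len(self.exons))


def read_bed(
    path: str | Path,
    one_based: bool = False,
) -> list[GenomicInterval]:
    """Read a BED file (>=3 tab-separated columns) into intervals.

    Column 4, when present, becomes the interval ``name``.  With
    ``one_based=True`` the start column is interpreted as 1-based inclusive
    and shifted to the internal 0-based half-open convention.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            name = fields[3] if len(fields) > 3 else ""
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return intervals


def sort_probes(probes: Iterable[ArrayProbe]) -> list[ArrayProbe]:
    return sorted(probes, key=lambda p: (p.chrom, p.pos))


def _check_sorted(probes: Sequence[ArrayProbe]) -> None:
    for a, b in zip(probes, probes[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError("probe map must be sorted by (chrom, position)")


def probes_in(
    interval: GenomicInterval, probes: Sequence[ArrayProbe]
) -> tuple[int, list[ArrayProbe]]:
    """Probes whose position falls in [interval.start, interval.end).

    ``probes`` must be sorted by (chrom, position); lookup is by bisection.
    Returns (count, probes).
    """
    _check_sorted(probes)
    keys = [(p.chrom, p.pos) for p in probes]
    lo = bisect.bisect_left(keys, (interval.chrom, interval.start))
    hi = bisect.bisect_left(keys, (interval.chrom, interval.end))
    hits = list(probes[lo:hi])
    return len(hits), hits


def coverage_gaps(
    region: GeneRegion,
    probes: Sequence[ArrayProbe],
    gap_threshold: int = 10_000,
) -> list[GenomicInterval]:
    """Maximal probe-free sub-intervals of the region span longer than
    ``gap_threshold`` bases.

    The span edges count as boundaries, so a probe-free margin at either
    end of the span is reported too.  With ``gap_threshold=0`` every
    non-empty inter-probe interval is returned.
    """
    _, inside = probes_in(region.span, probes)
    chrom = region.span.chrom
    candidates: list[tuple[int, int]] = []
    if not inside:
        candidates.append((region.span.start, region.span.end))
    else:
        candidates.append((region.span.start, inside[0].pos))
        for a, b in zip(inside, inside[1:]):
            candidates.append((a.pos + 1, b.pos))
        candidates.append((inside[-1].pos + 1, region.span.end))
    return [
        GenomicInterval(chrom, s, e, "gap")
        for s, e in candidates
        if e - s > gap_threshold
    ]
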