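"""Readers and writers for the pipeline's tabular interchange formats.

All files are plain text: BED for probe and region maps, TSV for the LRR
matrix (``probe_id, chrom, pos, <sample...>``), the long-format MLPA ratio
table (``sample, probe_id, gene, exon_label, peak_ratio``), and the stage
outputs (segments, calls).  Coordinates follow the package-wide 0-based
half-open convention; declare 1-based inputs with ``one_based=True``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .array_calls import GeneCall
from .intervals import (
    ArrayProbe,
    GeneRegion,
    GenomicInterval,
    MLPAProbe,
    read_bed,
    sort_probes,
)
from .segmentation import Segment


def read_array_probes(path: str | Path, one_based: bool = False) -> list[ArrayProbe]:
    """Array probe BED: chrom, start, end (=start+1), probe_id[, gc_fraction]."""
    probes = []
    with open(path) as fh:
        header = fh.readline()
    n_cols = len(header.rstrip("\n").split("\t"))
    intervals = read_bed(path, one_based=one_based)
    if n_cols >= 5:
        gc_col = pd.read_csv(path, sep="\t", header=None, usecols=[4])[4].tolist()
    else:
        gc_col = [None] * len(intervals)
    for iv, gc in zip(intervals, gc_col):
        probes.append(
            ArrayProbe(
                iv.name,
                GenomicInterval(iv.chrom, iv.start, iv.start + 1),
                None if gc is None else float(gc),
            )
        )
    return sort_probes(probes)


def read_mlpa_probes(path: str | Path, one_based: bool = False) -> list[MLPAProbe]:
    """MLPA probe BED: chrom, start, end, probe_id, gene, exon_label."""
    probes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path} line {lineno}: MLPA probe BED needs 6 columns "
                    "(chrom, start, end, probe_id, gene, exon_label)"
                )
            chrom, start, end, probe_id, gene, exon = fields[:6]
            s = int(start) - (1 if one_based else 0)
            probes.append(
                MLPAProbe(probe_id, gene, exon, GenomicInterval(chrom, s, int(end)))
            )
    return sorted(probes, key=lambda p: (p.locus.chrom, p.locus.start))


def read_regions(
    regions_bed: str | Path,
    exons_bed: str | Path,
    one_based: bool = False,
) -> list[GeneRegion]:
    """Gene spans plus exon BED (exon names formatted ``<gene>_ex<label>``)."""
    spans = read_bed(regions_bed, one_based=one_based)
    exons = read_bed(exons_bed, one_based=one_based)
    regions = []
    for span in spans:
        mine = []
        for e in exons:
            gene, _, label = e.name.rpartition("_ex")
            if gene == span.name:
                mine.append(GenomicInterval(e.chrom, e.start, e.end, label))
        mine.sort(key=lambda e: e.start)
        regions.append(GeneRegion(span.name, span, tuple(mine)))
    return regions


def read_lrr_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"LRR matrix needs columns {sorted(required)}")
    return df


def read_mlpa_ratios(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "probe_id", "gene", "exon_label", "peak_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"MLPA ratio table needs columns {sorted(required)}")
    return df


def sample_columns(lrr: pd.DataFrame) -> list[str]:
    return [c for c in lrr.columns if c not in ("probe_id", "chrom", "pos")]


def write_array_probes(probes: Sequence[ArrayProbe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            gc = "" if p.gc_fraction is None else f"\t{p.gc_fraction:.4f}"
            fh.write(f"{p.chrom}\t{p.pos}\t{p.pos + 1}\t{p.probe_id}{gc}\n")


def write_mlpa_probes(probes: Sequence[MLPAProbe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(
                f"{p.locus.chrom}\t{p.locus.start}\t{p.locus.end}\t"
                f"{p.probe_id}\t{p.gene}\t{p.exon_label}\n"
            )


def write_regions(regions: Sequence[GeneRegion], regions_path, exons_path) -> None:
    with open(regions_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.span.chrom}\t{r.span.start}\t{r.span.end}\t{r.name}\n")
    with open(exons_path, "w") as fh:
        for r in regions:
            for e in r.exons:
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{r.name}_ex{e.name}\n")


def segments_frame(
    per_sample: dict[tuple[str, str], tuple[Sequence[Segment], Sequence[ArrayProbe]]],
) -> pd.DataFrame:
    """Flatten {(sample, chrom): (segments, probes)} into the segment TSV layout."""
    rows = []
    for (sample, chrom), (segs, probes) in sorted(per_sample.items()):
        for s in segs:
            rows.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "start_idx": s.start_idx,
                    "end_idx": s.end_idx,
                    "start_pos": probes[s.start_idx].pos,
                    "end_pos": probes[s.end_idx - 1].pos + 1,
                    "n_markers": s.n_markers,
                    "mean_lrr": round(s.mean_lrr, 6),
                    "copy_value": round(s.copy_value, 6),
                }
            )
    return pd.DataFrame(rows)


def gene_calls_frame(calls: Sequence[GeneCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": c.sample_id,
                "gene": c.gene,
                "state": c.state.value,
                "sub_state": c.sub_state.value if c.sub_state else "",
                "provenance": c.provenance,
                "exon_first": c.exon_first or "",
                "exon_last": c.exon_last or "",
            }
        )
    return pd.DataFrame(rows)
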