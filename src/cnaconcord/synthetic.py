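"""Paired synthetic SNP-array / MLPA cohorts with known copy-number truth.

The toy genome holds the nine comparison regions on nine pseudo-
chromosomes, with probe geometries copied in spirit from the real
platforms so that every discordance category is constructible by design:

* an IKZF1 analogue whose array map has an ~11 kb probe-free hole inside
  intron 3, so focal deletions flanking the hole stress segmentation;
* a CDKN2A analogue with no array probes internal to the gene (events are
  MLPA-only: category I);
* a CDKN2B analogue carried by a single MLPA kit probe (category II);
* a PAX5 analogue whose exon-7 analogue has no MLPA probe (category V);
* an EBF1 analogue with sparse MLPA coverage (kit probes on four of 16
  exons);
* a PAR1 analogue where the array covers only the proximal fifth of the
  region.

The LRR signal model is the standard clonal mixture: a probe inside an
event of copy change ``delta_cn`` present in fraction ``f`` of cells
shifts by log2((2 + f*delta_cn)/2); MLPA peak ratios take the value
(2 + f*delta_cn)/2 at kit probes inside the event.  Gaussian noise is
added on both platforms (LRR sd 0.15 emulating decent-quality array data,
ratio sd 0.08 as typical assay variability).  At the 20%-cells detection
floor a heterozygous deletion shifts LRR by only log2(0.9) = -0.152,
below the default loss threshold — subclonal attenuation degrades
detection here exactly as it does on real data.

Cohort generation is fully deterministic given the spec seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import ArrayProbe, GeneRegion, GenomicInterval, MLPAProbe

# ---------------------------------------------------------------------------
# toy genome layout


@dataclass(frozen=True)
class EventTemplate:
    """An injectable abnormality: an exon range with its copy change.

    ``pad`` extends the event beyond the exon boundaries (bases); widen it
    to pull flanking array probes into an event confined to one exon.
    """

    exon_first: int
    exon_last: int
    delta_cn: int
    clonal_fraction: float = 1.0
    pad: int = 500


@dataclass(frozen=True)
class RegionDesign:
    """Geometry of one synthetic region and its probe maps."""

    name: str
    chrom: str
    n_exons: int
    exon_spacing: int
    array_spacing: int
    holes_between_exons: tuple[tuple[int, int], ...] = ()  # (exon_a, exon_b)
    extra_holes: tuple[tuple[int, int], ...] = ()  # explicit (start, end) holes
    array_blind: bool = False  # no array probes inside the gene span at all
    array_proximal_only: bool = False  # probes only over the first fifth
    mlpa_exons: tuple[int, ...] | None = None  # None = every exon
    templates: tuple[EventTemplate, ...] = ()
    span_start: int = 50_000
    exon_width: int = 1_000
    flank: int = 20_000

    @property
    def span(self) -> GenomicInterval:
        end = self.span_start + (self.n_exons - 1) * self.exon_spacing + self.exon_width
        return GenomicInterval(self.chrom, self.span_start, end, self.name)

    def exons(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(
                self.chrom,
                self.span_start + (k - 1) * self.exon_spacing,
                self.span_start + (k - 1) * self.exon_spacing + self.exon_width,
                str(k),
            )
            for k in range(1, self.n_exons + 1)
        )

    def hole_intervals(self) -> tuple[GenomicInterval, ...]:
        exons = self.exons()
        span = self.span
        holes = []
        if self.array_blind:
            holes.append(GenomicInterval(self.chrom, span.start, span.end, "hole"))
        if self.array_proximal_only:
            cut = span.start + span.width // 5
            holes.append(GenomicInterval(self.chrom, cut, span.end, "hole"))
        for a, b in self.holes_between_exons:
            holes.append(
                GenomicInterval(self.chrom, exons[a - 1].end, exons[b - 1].start, "hole")
            )
        for s, e in self.extra_holes:
            holes.append(GenomicInterval(self.chrom, s, e, "hole"))
        return tuple(holes)

    def region(self) -> GeneRegion:
        return GeneRegion(self.name, self.span, self.exons())

    def event_interval(self, t: EventTemplate) -> GenomicInterval:
        exons = self.exons()
        return GenomicInterval(
            self.chrom,
            exons[t.exon_first - 1].start - t.pad,
            exons[t.exon_last - 1].end + t.pad,
            f"{self.name}_ex{t.exon_first}-{t.exon_last}",
        )


def _gc_at(pos: int) -> float:
    # deterministic pseudo-random GC fraction in [0.35, 0.65]
    mixed = ((pos * 2654435761) % (2**32)) >> 16
    return 0.35 + 0.3 * (mixed % 1000) / 999.0


def default_region_designs() -> tuple[RegionDesign, ...]:
    """The nine-region toy genome (pseudo-chromosomes chr1..chr9)."""
    return (
        RegionDesign(
            "IKZF1", "chr1", n_exons=8, exon_spacing=12_000, array_spacing=1_000,
            holes_between_exons=((3, 4),),
            templates=(
                EventTemplate(4, 7, -1),
                EventTemplate(2, 7, -1),
                EventTemplate(4, 8, -1),
            ),
        ),
        RegionDesign(
            "CDKN2A", "chr2", n_exons=3, exon_spacing=10_000, array_spacing=1_000,
            array_blind=True,
            # pad 0 keeps the event wholly inside the probe-free span
            templates=(EventTemplate(1, 3, -2, 0.9, pad=0),),
        ),
        RegionDesign(
            "CDKN2B", "chr3", n_exons=2, exon_spacing=12_000, array_spacing=1_000,
            mlpa_exons=(1,),
            templates=(EventTemplate(1, 2, -1),),
        ),
        RegionDesign(
            "PAX5", "chr4", n_exons=10, exon_spacing=9_000, array_spacing=1_200,
            mlpa_exons=(1, 2, 3, 4, 5, 6, 8, 9, 10),
            templates=(EventTemplate(1, 10, -1), EventTemplate(3, 8, -1)),
        ),
        RegionDesign(
            "EBF1", "chr5", n_exons=16, exon_spacing=6_000, array_spacing=1_200,
            mlpa_exons=(1, 10, 14, 16),
            templates=(EventTemplate(1, 16, -1), EventTemplate(8, 16, -1)),
        ),
        RegionDesign(
            "ETV6", "chr6", n_exons=8, exon_spacing=11_000, array_spacing=1_000,
            templates=(EventTemplate(1, 5, -1), EventTemplate(1, 8, -1)),
        ),
        RegionDesign(
            "BTG1", "chr7", n_exons=2, exon_spacing=14_000, array_spacing=1_000,
            templates=(EventTemplate(1, 2, -1),),
        ),
        RegionDesign(
            "RB1", "chr8", n_exons=10, exon_spacing=10_000, array_spacing=1_200,
            mlpa_exons=(1, 2, 3, 4, 5, 6, 9, 10),
            templates=(EventTemplate(1, 10, -1), EventTemplate(2, 9, -1)),
        ),
        RegionDesign(
            "PAR1", "chr9", n_exons=3, exon_spacing=35_000, array_spacing=1_000,
            array_proximal_only=True,
            # the distal two gene analogues, past the array-covered fifth
            templates=(EventTemplate(2, 3, 1, pad=0),),
        ),
    )


def ikzf1_focal_design() -> RegionDesign:
    """IKZF1-like geometry whose probe hole swallows most of an exons-4-7
    deletion, leaving only four covered array probes immediately downstream
    of the hole — too few for segmentation (min_markers 5) but enough for
    the focal-rescue window.  The hole runs from the end of the exon-3
    analogue to 2 kb upstream of the exon-7 analogue (~45 kb)."""
    return RegionDesign(
        "IKZF1", "chr1", n_exons=8, exon_spacing=12_000, array_spacing=1_000,
        extra_holes=((75_000, 120_000),),
        templates=(EventTemplate(4, 7, -1),),
    )


def taxonomy_region_designs() -> tuple[RegionDesign, ...]:
    """Region variants whose default events exercise the discordance
    taxonomy: MLPA-only events in array-blind regions (category I), a
    single-kit-probe focal loss over normal array data (II), a
    hole-flanking focal deletion only rescue can call (III), and
    array-only events in MLPA coverage holes (V)."""
    out = []
    for d in default_region_designs():
        if d.name == "IKZF1":
            out.append(ikzf1_focal_design())
        elif d.name == "CDKN2B":
            # exon-1-only loss: one MLPA kit probe, ~2 array probes
            out.append(replace(d, templates=(EventTemplate(1, 1, -1),)))
        elif d.name == "PAX5":
            # confined to the MLPA-uncovered exon-7 analogue, padded to
            # span enough array probes for segmentation
            out.append(replace(d, templates=(EventTemplate(7, 7, -1, pad=3_500),)))
        elif d.name == "EBF1":
            # between the kit probes at exons 1 and 10
            out.append(replace(d, templates=(EventTemplate(2, 9, -1),)))
        else:
            out.append(d)
    return tuple(out)


def build_array_probes(design: RegionDesign) -> list[ArrayProbe]:
    """Evenly spaced width-1 probes over the flanked span, minus holes."""
    span = design.span
    holes = design.hole_intervals()
    probes = []
    start = span.start - design.flank
    stop = span.end + design.flank
    i = 0
    for pos in range(start, stop, design.array_spacing):
        if any(h.start <= pos < h.end for h in holes):
            continue
        probes.append(
            ArrayProbe(
                f"{design.name}_p{i:04d}",
                GenomicInterval(design.chrom, pos, pos + 1),
                gc_fraction=_gc_at(pos),
            )
        )
        i += 1
    return probes


def build_mlpa_probes(design: RegionDesign) -> list[MLPAProbe]:
    exon_ids = design.mlpa_exons or tuple(range(1, design.n_exons + 1))
    probes = []
    for k in exon_ids:
        exon = design.exons()[k - 1]
        mid = (exon.start + exon.end) // 2
        probes.append(
            MLPAProbe(
                f"{design.name}_mlpa_ex{k}",
                design.name,
                str(k),
                GenomicInterval(design.chrom, mid - 30, mid + 30),
            )
        )
    return probes


# ---------------------------------------------------------------------------
# signal model


def expected_lrr(delta_cn: int, f: float) -> float:
    """LRR shift of a copy change ``delta_cn`` present in cell fraction f.

    Clonal mixture on a diploid baseline: log2((2 + f*delta_cn)/2).
    """
    mixture = 2.0 + f * delta_cn
    if mixture <= 0:
        raise ValueError("mixture copy number must be positive")
    return math.log2(mixture / 2.0)


def expected_ratio(delta_cn: int, f: float) -> float:
    """MLPA peak ratio of the same mixture: (2 + f*delta_cn)/2."""
    mixture = 2.0 + f * delta_cn
    if mixture < 0:
        raise ValueError("mixture copy number must be non-negative")
    return mixture / 2.0


@dataclass(frozen=True)
class SyntheticCNA:
    """One injected abnormality (a truth-table row)."""

    region: str
    interval: GenomicInterval
    delta_cn: int
    clonal_fraction: float

    def __post_init__(self) -> None:
        if 2 + self.delta_cn < 0:
            raise ValueError("delta_cn cannot remove more copies than exist")
        if not 0 < self.clonal_fraction <= 1:
            raise ValueError("clonal_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one simulated cohort.

    ``event_rate`` is the per-sample per-region probability of injecting
    one abnormality, drawn uniformly from the region's templates; pass a
    mapping to override per region (e.g. to silence array-blind regions in
    a detection-benchmark cohort).
    """

    n_samples: int = 50
    noise_sd: float = 0.15
    mlpa_sd: float = 0.08
    gc_coeff: float = 0.0
    event_rate: float | Mapping[str, float] = 0.3
    seed: int = 0
    regions: tuple[RegionDesign, ...] = field(default_factory=default_region_designs)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0 or self.mlpa_sd < 0:
            raise ValueError("noise levels must be >= 0")

    def rate_for(self, region: str) -> float:
        if isinstance(self.event_rate, Mapping):
            return float(self.event_rate.get(region, 0.0))
        return float(self.event_rate)

    @classmethod
    def recovery_benchmark(cls, n_samples: int = 50, seed: int = 0) -> "SyntheticCohortSpec":
        """Cohort of clonal, array-detectable events spanning >= 10 probes.

        Regions whose geometry makes array detection impossible by design
        (the array-blind CDKN2A analogue, the mostly-uncovered PAR1
        analogue) are silenced, since they measure probe design rather
        than the calling pipeline.
        """
        designs = default_region_designs()
        rates = {d.name: 0.3 for d in designs}
        rates["CDKN2A"] = 0.0
        rates["PAR1"] = 0.0
        return cls(n_samples=n_samples, event_rate=rates, seed=seed, regions=designs)

    @classmethod
    def taxonomy_benchmark(cls, n_samples: int = 30, seed: int = 0) -> "SyntheticCohortSpec":
        """Cohort whose injected events exercise the discordance taxonomy
        (categories I, II, III and V arise by probe-design construction)."""
        return cls(
            n_samples=n_samples,
            event_rate=0.4,
            seed=seed,
            regions=taxonomy_region_designs(),
        )


@dataclass
class SyntheticCohort:
    """Generated cohort: data matrices, probe maps, and the ground truth."""

    lrr: pd.DataFrame  # probe_id, chrom, pos, <sample...>
    mlpa: pd.DataFrame  # sample, probe_id, gene, exon_label, peak_ratio
    truth: pd.DataFrame  # sample, region, chrom, start, end, delta_cn, clonal_fraction
    array_probes: dict[str, list[ArrayProbe]]  # per region name
    mlpa_probes: dict[str, list[MLPAProbe]]
    regions: dict[str, GeneRegion]

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.lrr.columns if c not in ("probe_id", "chrom", "pos")]


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Simulate paired LRR and MLPA data plus the event truth table."""
    rng = np.random.default_rng(spec.seed)
    samples = [f"s{i + 1:03d}" for i in range(spec.n_samples)]

    array_probes = {d.name: build_array_probes(d) for d in spec.regions}
    mlpa_probes = {d.name: build_mlpa_probes(d) for d in spec.regions}
    regions = {d.name: d.region() for d in spec.regions}

    truth_rows = []
    lrr_cols: dict[str, np.ndarray] = {}
    mlpa_rows = []

    # per-region probe position arrays for vectorised event injection
    pos_arrays = {
        name: np.array([p.pos for p in probes]) for name, probes in array_probes.items()
    }
    gc_arrays = {
        name: np.array([p.gc_fraction for p in probes])
        for name, probes in array_probes.items()
    }

    events: dict[tuple[str, str], SyntheticCNA] = {}
    for sample in samples:
        for d in spec.regions:
            if d.templates and rng.random() < spec.rate_for(d.name):
                t = d.templates[rng.integers(len(d.templates))]
                events[(sample, d.name)] = SyntheticCNA(
                    d.name, d.event_interval(t), t.delta_cn, t.clonal_fraction
                )

    for sample in samples:
        chunks = []
        for d in spec.regions:
            pos = pos_arrays[d.name]
            vals = rng.normal(0.0, spec.noise_sd, len(pos)) if spec.noise_sd else np.zeros(len(pos))
            if spec.gc_coeff:
                gc = gc_arrays[d.name]
                vals = vals + spec.gc_coeff * (gc - gc.mean())
            ev = events.get((sample, d.name))
            if ev is not None:
                inside = (pos >= ev.interval.start) & (pos < ev.interval.end)
                vals[inside] += expected_lrr(ev.delta_cn, ev.clonal_fraction)
                truth_rows.append(
                    {
                        "sample": sample,
                        "region": ev.region,
                        "chrom": ev.interval.chrom,
                        "start": ev.interval.start,
                        "end": ev.interval.end,
                        "delta_cn": ev.delta_cn,
                        "clonal_fraction": ev.clonal_fraction,
                    }
                )
            chunks.append(vals)
            for probe in mlpa_probes[d.name]:
                ratio = 1.0
                if ev is not None and probe.locus.overlaps(ev.interval):
                    ratio = expected_ratio(ev.delta_cn, ev.clonal_fraction)
                if spec.mlpa_sd:
                    ratio += rng.normal(0.0, spec.mlpa_sd)
                mlpa_rows.append(
                    {
                        "sample": sample,
                        "probe_id": probe.probe_id,
                        "gene": probe.gene,
                        "exon_label": probe.exon_label,
                        "peak_ratio": max(ratio, 0.0),
                    }
                )
        lrr_cols[sample] = np.concatenate(chunks)

    meta_rows = []
    for d in spec.regions:
        for p in array_probes[d.name]:
            meta_rows.append({"probe_id": p.probe_id, "chrom": p.chrom, "pos": p.pos})
    lrr = pd.DataFrame(meta_rows)
    for sample in samples:
        lrr[sample] = lrr_cols[sample]

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "region", "chrom", "start", "end", "delta_cn", "clonal_fraction"],
    )
    mlpa = pd.DataFrame(
        mlpa_rows, columns=["sample", "probe_id", "gene", "exon_label", "peak_ratio"]
    )
    return SyntheticCohort(lrr, mlpa, truth, array_probes, mlpa_probes, regions)


# ---------------------------------------------------------------------------
# packaged reference tables

_EXPECTED_SHA256 = {
    "concordance_by_gene.csv": "0f9e19be5d39e6855787a4a01a47ff4b7edc0127f18b4555483989c7bbf8337f",
    "discordant_calls.csv": "64da53d9361bf3b916bbfe77ab98743f442f38f982199adc471c46a63ec63e82",
}


def _fixture_path(name: str):
    return resources.files("cnaconcord.data").joinpath(name)


def load_reference_tables(verify: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the packaged published-cohort tables.

    Returns (by_gene, discordant): the per-gene call-group table from a
    published 143-sample SNP6.0-vs-MLPA comparison (one row per identical
    (mlpa, snp_cbs, snp_manual) call combination with its count), and the
    25 discordant calls with their categories and per-mode risk labels.
    Checksums guard against accidental edits of the transcription.
    """
    frames = []
    for name in ("concordance_by_gene.csv", "discordant_calls.csv"):
        raw = _fixture_path(name).read_bytes()
        if verify:
            digest = hashlib.sha256(raw).hexdigest()
            if digest != _EXPECTED_SHA256[name]:
                raise ValueError(
                    f"reference table {name} checksum mismatch: {digest}"
                )
        frames.append(pd.read_csv(_fixture_path(name), keep_default_na=False))
    by_gene, discordant = frames
    return by_gene, discordant
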