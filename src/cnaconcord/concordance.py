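"""Cross-platform call comparison and the discordance taxonomy.

A (sample, gene) pair is concordant when both platforms call normal or
both call abnormal; direction is aggregated, so a loss on one platform
and a gain on the other still count as two abnormal calls.  Discordant
pairs are assigned exactly one of five categories:

I    the array has no probes inside the abnormality, so the event is
     invisible to it by design;
II   the MLPA call rests on a single kit probe while numerous array
     probes in the same interval read normal;
III  segmentation missed a focal event that manual-style review of the
     LRR scatter recovers (the rescued call agrees with MLPA);
IV   genuine disagreement despite sufficient probe coverage on both
     platforms (the residual category);
V    the array detects an event in a region the MLPA kit does not cover.

The cascade is evaluated in the order I, II, III, V, with IV as the
fallback, since IV is defined residually.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .array_calls import CNAState, GeneCall
from .intervals import ArrayProbe, GeneRegion, GenomicInterval, MLPAProbe, probes_in
from .mlpa_calls import MLPAGeneCall


class DiscordanceCategory(enum.Enum):
    I_NO_SNP_PROBES = "i"
    II_SINGLE_MLPA_PROBE = "ii"
    III_CBS_MISSED_FOCAL = "iii"
    IV_TRUE_DISAGREEMENT = "iv"
    V_NO_MLPA_PROBES = "v"


@dataclass(frozen=True)
class CallPair:
    """One (sample, gene) comparison cell across both platforms."""

    sample_id: str
    gene: str
    snp_state: CNAState
    snp_state_manual: CNAState
    mlpa_state: CNAState
    mlpa_single_probe: bool = False
    snp_interval: GenomicInterval | None = None
    mlpa_interval: GenomicInterval | None = None

    def snp_for_mode(self, mode: str) -> CNAState:
        if mode == "cbs":
            return self.snp_state
        if mode == "manual":
            return self.snp_state_manual
        raise ValueError(f"unknown mode {mode!r}; expected 'cbs' or 'manual'")

    def concordant(self, mode: str) -> bool:
        return self.snp_for_mode(mode).abnormal == self.mlpa_state.abnormal


@dataclass(frozen=True)
class ContingencyTable:
    """Per-gene 2x2 Normal/Abnormal counts, MLPA (columns) x SNP (rows)."""

    gene: str
    nn: int  # SNP normal,   MLPA normal
    na: int  # SNP normal,   MLPA abnormal
    an: int  # SNP abnormal, MLPA normal
    aa: int  # SNP abnormal, MLPA abnormal

    def __post_init__(self) -> None:
        if min(self.nn, self.na, self.an, self.aa) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.nn + self.na + self.an + self.aa

    @property
    def discordant(self) -> int:
        return self.na + self.an


@dataclass(frozen=True)
class DiscordanceRecord:
    pair: CallPair
    category: DiscordanceCategory
    abnormality_interval: GenomicInterval | None
    n_snp_probes: int
    n_mlpa_probes: int


def compare(
    snp_calls: Mapping[tuple[str, str], GeneCall],
    snp_manual_calls: Mapping[tuple[str, str], GeneCall],
    mlpa_calls: Mapping[tuple[str, str], MLPAGeneCall],
) -> list[CallPair]:
    """Pair up per-(sample, gene) calls from both platforms.

    All three mappings must cover the same grid of keys; a missing cell is
    an error naming the missing keys, because a silent drop would bias the
    concordance percentage.
    """
    keys = set(snp_calls)
    for name, other in (("manual", snp_manual_calls), ("mlpa", mlpa_calls)):
        missing = keys.symmetric_difference(other)
        if missing:
            raise KeyError(
                f"{name} call set does not match grid; mismatched keys: "
                f"{sorted(missing)[:10]}"
            )
    pairs = []
    for sample_id, gene in sorted(keys):
        snp = snp_calls[(sample_id, gene)]
        manual = snp_manual_calls[(sample_id, gene)]
        mlpa = mlpa_calls[(sample_id, gene)]
        mlpa_iv = mlpa.supporting_interval if mlpa.state.abnormal else None
        snp_iv = manual.supporting_interval if manual.state.abnormal else None
        pairs.append(
            CallPair(
                sample_id,
                gene,
                snp_state=snp.state,
                snp_state_manual=manual.state,
                mlpa_state=mlpa.state,
                mlpa_single_probe=mlpa.single_probe_evidence,
                snp_interval=snp_iv,
                mlpa_interval=mlpa_iv,
            )
        )
    return pairs


def concordance_percent(pairs: Sequence[CallPair], mode: str) -> tuple[float, int]:
    """(raw percentage, nearest-integer percentage) of concordant pairs."""
    if not pairs:
        raise ValueError("need at least one pair")
    disc = sum(not p.concordant(mode) for p in pairs)
    raw = 100.0 * (1.0 - disc / len(pairs))
    return raw, round(raw)


def tabulate(pairs: Sequence[CallPair], mode: str) -> list[ContingencyTable]:
    """Per-gene 2x2 contingency tables (SNP rows x MLPA columns)."""
    counts: dict[str, Counter] = {}
    for p in pairs:
        cell = (
            "a" if p.snp_for_mode(mode).abnormal else "n",
            "a" if p.mlpa_state.abnormal else "n",
        )
        counts.setdefault(p.gene, Counter())[cell] += 1
    tables = []
    for gene in sorted(counts):
        c = counts[gene]
        tables.append(
            ContingencyTable(
                gene,
                nn=c[("n", "n")],
                na=c[("n", "a")],
                an=c[("a", "n")],
                aa=c[("a", "a")],
            )
        )
    return tables


def mlpa_abnormality_interval(
    call: MLPAGeneCall,
    kit_probes: Sequence[MLPAProbe],
    region: "GeneRegion | None" = None,
) -> GenomicInterval | None:
    """Extent of an MLPA-detected event for coverage queries.

    Span from the first to last abnormal kit probe, padded on each side by
    half the distance to the nearest flanking kit probe of the same gene.
    Where no kit probe flanks the event (e.g. a one-probe gene or an
    event covering the whole kit), the extent falls back to the gene span
    boundary when a region is given, else to one probe width.
    """
    iv = call.abnormal_interval or call.supporting_interval
    if iv is None:
        return None
    gene_probes = sorted(
        (p for p in kit_probes if p.gene == call.gene), key=lambda p: p.locus.start
    )
    before = [p for p in gene_probes if p.locus.end <= iv.start]
    after = [p for p in gene_probes if p.locus.start >= iv.end]
    if before:
        start = iv.start - max((iv.start - before[-1].locus.end) // 2, 0)
    elif region is not None:
        start = min(region.span.start, iv.start)
    else:
        start = iv.start - iv.width
    if after:
        end = iv.end + max((after[0].locus.start - iv.end) // 2, 0)
    elif region is not None:
        end = max(region.span.end, iv.end)
    else:
        end = iv.end + iv.width
    return GenomicInterval(iv.chrom, start, end)


def classify_discordance(
    pair: CallPair,
    array_probes: Sequence[ArrayProbe],
    mlpa_probes: Sequence[MLPAProbe],
    min_snp_probes_for_ii: int = 5,
) -> DiscordanceRecord:
    """Assign exactly one category to a cbs-mode discordant pair.

    The abnormality interval is the MLPA event extent when MLPA called the
    event, otherwise the array's supporting-segment span.
    """
    if pair.concordant("cbs"):
        raise ValueError("pair is concordant; nothing to classify")

    interval = pair.mlpa_interval if pair.mlpa_state.abnormal else pair.snp_interval
    n_snp = n_mlpa = 0
    if interval is not None:
        n_snp, _ = probes_in(interval, array_probes)
        n_mlpa = sum(
            1
            for p in mlpa_probes
            if p.locus.chrom == interval.chrom
            and p.locus.start < interval.end
            and interval.start < p.locus.end
        )

    mlpa_abn = pair.mlpa_state.abnormal
    snp_abn = pair.snp_state.abnormal
    manual_abn = pair.snp_state_manual.abnormal

    if mlpa_abn and n_snp == 0:
        cat = DiscordanceCategory.I_NO_SNP_PROBES
    elif (
        mlpa_abn
        and pair.mlpa_single_probe
        and not snp_abn
        and n_snp >= min_snp_probes_for_ii
    ):
        cat = DiscordanceCategory.II_SINGLE_MLPA_PROBE
    elif mlpa_abn and not snp_abn and manual_abn:
        cat = DiscordanceCategory.III_CBS_MISSED_FOCAL
    elif snp_abn and not mlpa_abn and n_mlpa == 0:
        cat = DiscordanceCategory.V_NO_MLPA_PROBES
    else:
        cat = DiscordanceCategory.IV_TRUE_DISAGREEMENT
    return DiscordanceRecord(pair, cat, interval, n_snp, n_mlpa)


def category_counts(
    records: Sequence[DiscordanceRecord],
) -> dict[DiscordanceCategory, int]:
    counts = {cat: 0 for cat in DiscordanceCategory}
    for rec in records:
        counts[rec.category] += 1
    return counts
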