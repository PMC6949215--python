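"""Per-probe and per-gene CNA calls from MLPA peak ratios.

MLPA reports, for each kit probe (one exon of one gene), a peak ratio
normalised against reference probes: ~1.0 at normal copy number, ~0.5 at a
heterozygous deletion, ~1.5 at a single-copy gain, attenuated toward 1 in
subclonal samples.  A gene is normally called abnormal only when at least
two adjacent kit probes agree in direction; genes represented by a single
probe in the kit (a CDKN2B-style design) are callable from that probe but
the call is flagged, because a single-probe observation is error prone
(MLPA probes do not tolerate SNPs under the ligation site) and feeds its
own discordance category downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .array_calls import CNAState, SubState
from .intervals import GenomicInterval, MLPAProbe

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLPAMeasurement:
    """One probe's peak ratio in one sample."""

    sample_id: str
    probe: MLPAProbe
    peak_ratio: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.peak_ratio) or self.peak_ratio < 0:
            raise ValueError(
                f"peak ratio must be finite and >= 0, got {self.peak_ratio}"
            )


@dataclass(frozen=True)
class MLPAThresholds:
    """Peak-ratio cut-offs; 1.0 is the normal ratio.

    Defaults are standard MLPA conventions (loss below 0.75, deletion
    below 0.25, gain above 1.3, amplification above 2.0), configurable.
    """

    loss_max: float = 0.75
    deletion_max: float = 0.25
    gain_min: float = 1.3
    amp_min: float = 2.0

    def __post_init__(self) -> None:
        if not (self.deletion_max <= self.loss_max < 1 < self.gain_min <= self.amp_min):
            raise ValueError(
                "need deletion_max <= loss_max < 1 < gain_min <= amp_min"
            )


@dataclass(frozen=True)
class MLPAGeneCall:
    """Gene-level MLPA call with its supporting-probe bookkeeping.

    ``supporting_interval`` spans the adjacent run that made the call;
    ``abnormal_interval`` spans first-to-last kit probe abnormal in the
    call's direction (a noisy probe inside a real event can split the
    run, so the full extent is the honest coverage-query interval).
    """

    sample_id: str
    gene: str
    state: CNAState
    sub_state: SubState | None = None
    n_supporting_probes: int = 0
    single_probe_evidence: bool = False
    supporting_interval: GenomicInterval | None = None
    abnormal_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.single_probe_evidence and self.n_supporting_probes != 1:
            raise ValueError("single_probe_evidence requires exactly one supporting probe")


def call_probe(m: MLPAMeasurement, t: MLPAThresholds) -> CNAState:
    """Categorical state of a single probe ratio."""
    if m.peak_ratio <= t.loss_max:
        return CNAState.LOSS_DELETION
    if m.peak_ratio >= t.gain_min:
        return CNAState.GAIN_AMPLIFICATION
    return CNAState.NORMAL


def _sub_state(ratio: float, t: MLPAThresholds) -> SubState | None:
    if ratio <= t.loss_max:
        return SubState.DELETION if ratio <= t.deletion_max else SubState.LOSS
    if ratio >= t.gain_min:
        return SubState.AMPLIFICATION if ratio >= t.amp_min else SubState.GAIN
    return None


def call_gene_mlpa(
    measurements: Sequence[MLPAMeasurement],
    t: MLPAThresholds,
    min_adjacent: int = 2,
) -> MLPAGeneCall:
    """Gene call from one sample's kit probes for that gene.

    ``measurements`` must be ordered by probe genomic position (the kit
    order).  The gene is abnormal when >= min_adjacent consecutive probes
    share an abnormal direction, applied to losses and gains alike.  A
    one-probe gene is called from its single probe with
    ``single_probe_evidence`` set.
    """
    if not measurements:
        raise ValueError("no MLPA measurements supplied for gene")
    genes = {m.probe.gene for m in measurements}
    if len(genes) != 1:
        raise ValueError(f"measurements span multiple genes: {sorted(genes)}")
    gene = genes.pop()
    sample = measurements[0].sample_id
    states = [call_probe(m, t) for m in measurements]

    best_run: list[int] | None = None
    needed = 1 if len(measurements) == 1 else min_adjacent
    for direction in (CNAState.LOSS_DELETION, CNAState.GAIN_AMPLIFICATION):
        run: list[int] = []
        for idx, st in enumerate(states + [CNAState.NORMAL]):
            if st is direction:
                run.append(idx)
            else:
                if len(run) >= needed and (best_run is None or len(run) > len(best_run)):
                    best_run = list(run)
                run = []
    if best_run is None:
        return MLPAGeneCall(sample, gene, CNAState.NORMAL)

    run_meas = [measurements[i] for i in best_run]
    ratios = sorted(m.peak_ratio for m in run_meas)
    mid = ratios[len(ratios) // 2] if len(ratios) % 2 else 0.5 * (
        ratios[len(ratios) // 2 - 1] + ratios[len(ratios) // 2]
    )
    state = states[best_run[0]]
    first, last = run_meas[0].probe.locus, run_meas[-1].probe.locus
    same_direction = [i for i, st in enumerate(states) if st is state]
    lo = measurements[same_direction[0]].probe.locus
    hi = measurements[same_direction[-1]].probe.locus
    return MLPAGeneCall(
        sample,
        gene,
        state,
        sub_state=_sub_state(mid, t),
        n_supporting_probes=len(best_run),
        single_probe_evidence=(len(measurements) == 1),
        supporting_interval=GenomicInterval(first.chrom, first.start, last.end),
        abnormal_interval=GenomicInterval(lo.chrom, lo.start, hi.end),
    )


def mlpa_to_lrr(ratio: float, floor: float = -5.0) -> float:
    """Convert a peak ratio to the LRR scale: log2(ratio).

    A ratio of exactly 0 (complete absence) has no finite log; the
    configured floor is returned with a warning.
    """
    if ratio < 0:
        raise ValueError("peak ratio must be >= 0")
    if ratio == 0:
        logger.warning("peak ratio 0 mapped to LRR floor %.1f", floor)
        return floor
    return math.log2(ratio)
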