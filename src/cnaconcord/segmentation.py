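"""Circular binary segmentation (CBS) of per-sample Log R Ratio vectors.

LRR is the log2 ratio of observed to expected probe intensity: 0 at the
diploid baseline, about -1 at a clonal single-copy loss, about +0.58 at a
single-copy gain.  CBS recursively searches each segment for the circular
arc whose mean differs most from its complement (a two-sample t-statistic
maximised over all arcs) and accepts the split when a permutation test
declares it significant.  Detected segments shorter than ``min_markers``
probes are merged away afterwards, implementing the minimum-marker
detection cut-off (default five probes) as a filter on emitted events
rather than a constraint inside the arc search.

The permutation reference distribution is the exact one (index shuffles of
the working sub-vector); no tail approximation or hybrid scheme is used.
Within :func:`segment` the permutation loop stops early as soon as the
exceedance count already guarantees ``p >= alpha`` — decision-identical to
the full test and much faster on flat segments, which dominate real data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import ArrayProbe

logger = logging.getLogger(__name__)

_PERM_CHUNK = 256


@dataclass
class ArrayProfile:
    """Ordered per-probe LRR observations for one sample on one chromosome."""

    sample_id: str
    chrom: str
    probes: tuple[ArrayProbe, ...]
    lrr: np.ndarray

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=float)
        if len(self.lrr) != len(self.probes):
            raise ValueError("lrr and probes must have equal length")
        if not np.all(np.isfinite(self.lrr)):
            raise ValueError("LRR values must be finite")
        pos = [p.pos for p in self.probes]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("probes must be strictly increasing in position")
        if any(p.chrom != self.chrom for p in self.probes):
            raise ValueError("all probes must lie on the profile chromosome")


@dataclass(frozen=True)
class SegmentationParams:
    """CBS tuning knobs.

    alpha
        significance level for accepting a candidate split (default 0.01).
    nperm
        permutations drawn for the reference distribution (default 10,000).
    min_markers
        minimum probes an emitted event must span (default 5); shorter
        segments are merged into their closest-mean neighbour.
    baseline_copies
        assumed ploidy at LRR 0; copy values are baseline * 2**mean_lrr.
    """

    alpha: float = 0.01
    nperm: int = 10_000
    min_markers: int = 5
    seed: int = 0
    baseline_copies: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.nperm < 100:
            raise ValueError("nperm must be >= 100")
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")


@dataclass(frozen=True)
class Segment:
    """A contiguous probe run [start_idx, end_idx) with its mean LRR."""

    start_idx: int
    end_idx: int
    mean_lrr: float
    baseline_copies: float = 2.0

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("segment must contain at least one probe")

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def copy_value(self) -> float:
        return self.baseline_copies * 2.0**self.mean_lrr


def gc_correct(profile: ArrayProfile) -> ArrayProfile:
    """Remove a linear GC-content wave from the LRR vector.

    Fits lrr ~ a + b*gc by least squares and returns the residuals
    re-centred on the input median, so the diploid baseline is preserved.
    Profiles whose probes have no GC variance are returned unchanged.
    """
    if len(profile.lrr) < 10:
        raise ValueError("gc_correct needs >= 10 probes")
    gc = np.array([p.gc_fraction for p in profile.probes], dtype=float)
    if np.any(np.isnan(gc)):
        raise ValueError("every probe needs gc_fraction for GC correction")
    if np.ptp(gc) == 0.0:
        logger.warning(
            "sample %s chrom %s: zero GC variance, skipping correction",
            profile.sample_id,
            profile.chrom,
        )
        return profile
    design = np.column_stack([np.ones_like(gc), gc])
    coef, *_ = np.linalg.lstsq(design, profile.lrr, rcond=None)
    resid = profile.lrr - design @ coef
    corrected = resid + np.median(profile.lrr)
    return replace(profile, lrr=corrected)


def arc_statistic(values: np.ndarray, i: int, j: int) -> float:
    """Two-sample t-statistic between the arc values[i:j] and its complement.

    Returns |mean(arc) - mean(rest)| / (s * sqrt(1/k + 1/(n-k))) with s the
    pooled standard deviation.  Degenerate conventions: 0 when the pooled
    spread and the mean difference both vanish (constant data, or n == 2
    leaving no degrees of freedom), +inf when the arc separates the data
    perfectly (s == 0 but the means differ).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not (0 <= i < j <= n):
        raise ValueError("need 0 <= i < j <= n")
    k = j - i
    if k >= n:
        raise ValueError("arc must be a proper subset of the vector")
    arc = values[i:j]
    rest = np.concatenate([values[:i], values[j:]])
    m1, m2 = arc.mean(), rest.mean()
    if n == 2:
        return 0.0 if m1 == m2 else math.inf
    ss = float(np.sum((arc - m1) ** 2) + np.sum((rest - m2) ** 2))
    s2 = ss / (n - 2)
    if s2 <= 0.0:
        return 0.0 if m1 == m2 else math.inf
    return abs(m1 - m2) / math.sqrt(s2 * (1.0 / k + 1.0 / (n - k)))


def _tmax_rows(cumsum: np.ndarray, n: int, total: float, ssq: float) -> np.ndarray:
    """Row-wise max arc statistic for a batch of vectors sharing multiset.

    ``cumsum`` has shape (batch, n+1).  Permutations preserve the total sum
    and sum of squares, so those are passed once.
    """
    batch = cumsum.shape[0]
    best = np.zeros(batch)
    denom_df = n - 2
    if denom_df <= 0:
        return best
    for k in range(1, n):
        arcsum = cumsum[:, k:] - cumsum[:, :-k]  # (batch, n-k+1)
        m1 = arcsum / k
        m2 = (total - arcsum) / (n - k)
        # pooled SS = ssq - k*m1^2 - (n-k)*m2^2
        s2 = (ssq - k * m1**2 - (n - k) * m2**2) / denom_df
        np.maximum(s2, 0.0, out=s2)
        scale = s2 * (1.0 / k + 1.0 / (n - k))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m1 - m2) / np.sqrt(scale)
        t[np.isnan(t)] = 0.0  # 0/0: no spread, no mean difference
        row_max = t.max(axis=1)
        np.maximum(best, row_max, out=best)
    return best


def max_arc(values: np.ndarray) -> tuple[int, int, float]:
    """Arg-max of the arc statistic over all admissible arcs (i, j).

    Ties are broken toward the smallest i, then the smallest j.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values to search for an arc")
    cs = np.concatenate([[0.0], np.cumsum(values)])
    total = cs[-1]
    ssq = float(np.sum((values - values.mean()) ** 2) + n * values.mean() ** 2)
    best_t = -1.0
    best_i, best_j = 0, 1
    if n == 2:
        return 0, 1, 0.0
    for k in range(1, n):
        arcsum = cs[k:] - cs[:-k]
        m1 = arcsum / k
        m2 = (total - arcsum) / (n - k)
        s2 = (ssq - k * m1**2 - (n - k) * m2**2) / (n - 2)
        s2 = np.maximum(s2, 0.0)
        scale = s2 * (1.0 / k + 1.0 / (n - k))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m1 - m2) / np.sqrt(scale)
        t[np.isnan(t)] = 0.0
        # first index achieving the row max = smallest i for this width
        idx = int(np.argmax(t))
        t_k = float(t[idx])
        if t_k > best_t:
            best_t, best_i, best_j = t_k, idx, idx + k
        elif t_k == best_t and (idx, idx + k) < (best_i, best_j):
            best_i, best_j = idx, idx + k
    return best_i, best_j, max(best_t, 0.0)


def permutation_pvalue(
    values: np.ndarray, t_obs: float, params: SegmentationParams
) -> float:
    """Permutation p-value p = (1 + #{T_perm >= T_obs}) / (nperm + 1)."""
    if t_obs < 0:
        raise ValueError("t_obs must be >= 0")
    rng = np.random.default_rng(params.seed)
    exceed = _count_exceedances(
        np.asarray(values, dtype=float), t_obs, params.nperm, rng, early_stop_at=None
    )
    return (1 + exceed) / (params.nperm + 1)


def _count_exceedances(
    values: np.ndarray,
    t_obs: float,
    nperm: int,
    rng: np.random.Generator,
    early_stop_at: int | None,
) -> int:
    """#{permutations with T_max >= T_obs}, optionally stopping once the
    count reaches ``early_stop_at`` (at which point p >= alpha is settled)."""
    n = len(values)
    total = float(values.sum())
    ssq = float(np.sum(values**2))
    count = 0
    done = 0
    thresh = t_obs - 1e-12  # >= with tolerance for exact ties
    while done < nperm:
        batch = min(_PERM_CHUNK, nperm - done)
        perms = rng.permuted(np.broadcast_to(values, (batch, n)), axis=1)
        cs = np.concatenate(
            [np.zeros((batch, 1)), np.cumsum(perms, axis=1)], axis=1
        )
        tmax = _tmax_rows(cs, n, total, ssq)
        count += int(np.sum(tmax >= thresh))
        done += batch
        if early_stop_at is not None and count >= early_stop_at:
            return count
    return count


def _split_accepted(
    values: np.ndarray, t_obs: float, params: SegmentationParams, rng: np.random.Generator
) -> bool:
    """Early-stopping permutation test of the best arc at level alpha."""
    if t_obs <= 0.0:
        return False
    # p = (1+c)/(nperm+1) < alpha  <=>  c < alpha*(nperm+1) - 1
    limit = params.alpha * (params.nperm + 1) - 1
    if limit <= 0:
        return False
    stop_at = int(math.floor(limit)) + 1  # once c >= stop_at, p >= alpha
    count = _count_exceedances(values, t_obs, params.nperm, rng, early_stop_at=stop_at)
    return (1 + count) / (params.nperm + 1) < params.alpha


def _recurse(
    values: np.ndarray,
    offset: int,
    params: SegmentationParams,
    rng: np.random.Generator,
    breakpoints: set[int],
) -> None:
    n = len(values)
    if n < 4:
        return
    i, j, t_obs = max_arc(values)
    if not _split_accepted(values, t_obs, params, rng):
        return
    cuts = sorted({i, j} - {0, n})
    if not cuts:
        return
    # An interior arc narrower than min_markers is an event too small to
    # detect: the change-points are not emitted (the detection cut-off).
    if len(cuts) == 2 and (j - i) < params.min_markers:
        return
    for c in cuts:
        breakpoints.add(offset + c)
    edges = [0] + cuts + [n]
    for a, b in zip(edges, edges[1:]):
        _recurse(values[a:b], offset + a, params, rng, breakpoints)


def _merge_short_segments(
    values: np.ndarray, edges: list[int], min_markers: int
) -> list[int]:
    """Drop interior breakpoints until no segment is shorter than
    ``min_markers`` (unless a single segment remains).  The shortest
    offending segment is merged into the neighbour with the closer mean."""
    edges = list(edges)
    while len(edges) > 2:
        lengths = [b - a for a, b in zip(edges, edges[1:])]
        short = [(l, idx) for idx, l in enumerate(lengths) if l < min_markers]
        if not short:
            break
        _, idx = min(short)
        means = [values[a:b].mean() for a, b in zip(edges, edges[1:])]
        if idx == 0:
            drop = idx + 1  # merge right
        elif idx == len(lengths) - 1:
            drop = idx  # merge left
        else:
            left_gap = abs(means[idx] - means[idx - 1])
            right_gap = abs(means[idx] - means[idx + 1])
            drop = idx if left_gap <= right_gap else idx + 1
        del edges[drop]
    return edges


def segment(profile: ArrayProfile, params: SegmentationParams) -> list[Segment]:
    """Segment one chromosome of one sample into constant-copy runs.

    The returned segments partition [0, n) in order; each carries the
    arithmetic mean of its LRR values and the derived copy value
    ``baseline_copies * 2**mean_lrr``.
    """
    n = len(profile.lrr)
    if n == 0:
        raise ValueError("cannot segment an empty profile")
    values = np.asarray(profile.lrr, dtype=float)
    rng = np.random.default_rng(params.seed)
    breakpoints: set[int] = set()
    _recurse(values, 0, params, rng, breakpoints)
    edges = [0] + sorted(breakpoints) + [n]
    edges = _merge_short_segments(values, edges, params.min_markers)
    return [
        Segment(a, b, float(values[a:b].mean()), params.baseline_copies)
        for a, b in zip(edges, edges[1:])
    ]
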