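# Methods

## Signal model

A SNP-array probe reports the Log R Ratio (LRR), the log2 of observed
versus expected intensity: 0 at the diploid baseline. A copy change of
`delta_cn` present in a fraction `f` of cells (the clonal fraction)
shifts the LRR of probes inside the event by

    LRR = log2((2 + f * delta_cn) / 2)

so a clonal heterozygous deletion sits near −1, a clonal single-copy gain
near +0.58, and a deletion at the 20 %-cells detection floor at only
log2(0.9) ≈ −0.152. The matching MLPA peak ratio is `(2 + f*delta_cn)/2`
(≈1 normal, ≈0.5 deleted). Both assays add approximately Gaussian noise;
the synthetic generator uses LRR sd 0.15 (decent-quality array data) and
ratio sd 0.08 (typical MLPA assay variability).

## Segmentation

Circular binary segmentation, implemented from first principles. Within
a working segment of n probes, every arc (i, j) with 1 ≤ j−i ≤ n−1 is
scored with the two-sample t-statistic between the arc and its
complement (pooled variance, n−2 degrees of freedom); the maximising arc
is tested by permutation: `p = (1 + #{T_perm ≥ T_obs}) / (nperm + 1)`
over index shuffles of the working sub-vector. A significant split
(p < alpha) yields up to two change-points and the procedure recurses.
No hybrid/tail approximation is used — full permutation is adequate at
panel scale, and inside the recursion the permutation loop stops as soon
as the exceedance count already guarantees p ≥ alpha, which is
decision-identical to the full test.

Degenerate conventions: a constant vector scores 0 for every arc; an arc
that separates the data perfectly (zero pooled variance, unequal means)
scores +inf, so noiseless steps segment correctly. Ties in the arc
search break toward the smallest (i, j).

The minimum-marker rule (default 5 probes) is applied to emitted events:
an interior arc narrower than `min_markers` is an event too small to
detect and its change-points are not emitted; any residual short segment
is merged into the neighbour with the closer mean. Segmentation is per
chromosome per sample; chromosomes are never concatenated; there is no
undo/merge pass. Copy value is `baseline * 2^mean_LRR` with a
configurable baseline (default 2).

Defaults: `alpha = 0.01`, `nperm = 10000` (conventional CBS settings),
`min_markers = 5`. Simulation studies in the test suite and acceptance
script use `nperm` 1000–2000, which resolves alpha = 0.01 comfortably
while keeping hundreds of replicates fast; cohort results are unchanged
at larger nperm.

GC correction regresses LRR on probe GC fraction (ordinary least
squares) and keeps the residuals re-centred on the input median; a
zero-variance GC vector skips correction with a warning.

## Categorical calling

Segment means are thresholded: loss at ≤ −0.2 (deletion ≤ −0.8), gain at
≥ +0.15 (amplification ≥ +0.7), boundaries inclusive toward the abnormal
state. These are standard LRR heuristics; no cohort-level result here
depends on their exact values, and they are fully configurable. A gene's
call is the most extreme abnormal segment that spans ≥ 1 array probe
inside the gene and ≥ min_markers probes overall. Extremity is measured
in copy space — `|copy_value − baseline|`, proportional to
`|2^mean_LRR − 1|` — so when nested events of both directions overlap a
gene, a copy-3.6 gain outranks a nested copy-1.1 deletion even though
the deletion's |mean LRR| is marginally larger. The two rankings agree
whenever all abnormal segments share a direction.

### Focal rescue

The original workflow recovered segmentation misses by eye from LRR
plots. The automated operator scans maximal runs of consecutive probes
inside the gene span, breaking runs at coverage-gap boundaries (default
gap threshold 10 kb, motivated by the ~42 kb probe-free hole in *IKZF1*
intron 3), and fires when

* a run of ≥ `window_k` probes (default 4 — below the 5-marker CBS
  cut-off, above the 2-probe floor below which no automated method
  should call) each crosses the ordinary loss/gain threshold, and
* the run median also crosses a stricter rescue threshold (default
  midway between loss and deletion bounds, i.e. −0.5, and midway between
  gain and amplification bounds, i.e. +0.425).

The median condition is what keeps the operator safe: at noise sd 0.15 a
single probe exceeds +0.15 with probability 0.16, so 4-probe runs of
threshold-crossing noise are common (expected several per hundred
probes), while a run median beyond 2.8 sd is vanishingly rare (measured
false-rescue rate ≪ 1 % of null samples). Clonal single-copy events
(|shift| ≈ 1) always satisfy it; subclonal events near the f = 0.2 floor
do not, and rescue sensitivity degrades there exactly as visual review
would.

## MLPA calling

A probe ratio ≤ 0.75 is a loss (≤ 0.25 deletion), ≥ 1.3 a gain (≥ 2.0
amplification) — standard MLPA conventions, configurable. A gene is
abnormal when ≥ 2 adjacent kit probes (kit order = genomic order) agree
in direction, applied to losses and gains alike; a gene represented by a
single kit probe is callable from it but flagged
(`single_probe_evidence`), feeding discordance category ii. Two
intervals are recorded: the adjacent run that made the call, and the
first-to-last abnormal probe extent, which is the honest interval for
coverage queries because a single noisy probe inside a real event can
split the run.

## Comparison and discordance taxonomy

A (sample, gene) pair is concordant when both platforms call normal or
both call abnormal; direction is aggregated. Discordant pairs (under
automated calling) receive exactly one category via the cascade
I → II → III → V → IV; IV ("the platforms disagree despite adequate
coverage") is the residual and therefore the fallback:

| category | condition |
|---|---|
| i  | MLPA abnormal and zero array probes in the abnormality interval |
| ii | MLPA abnormal on single-probe evidence with ≥ 5 normal array probes in the interval |
| iii| segmentation normal but focal rescue called the event concordant with MLPA |
| v  | array abnormal and zero MLPA probes in the supporting segment |
| iv | anything else |

The abnormality interval for MLPA-detected events spans first-to-last
abnormal kit probe padded by half the distance to the nearest flanking
kit probe (falling back to the gene span when none flanks, as for
one-probe genes); for array-detected events it is the supporting
segment's span. Concordance percentages are reported raw and rounded to
the nearest integer (the headline 98/99 scale).

## Risk classification

The rule engine evaluates an ordered JSON rule list over the 9-region
state vector, first match wins, with a mandatory default. The published
rule content is not restated here — it ships as configuration, and the
packaged example rule set is explicitly illustrative. Cohort-level
reclassification results use the per-mode risk labels carried by the
packaged discordant-call table directly, so no invented rules touch
those numbers. Reporting pools IR and PR (GR vs IR/PR), the granularity
at which good-risk assignment is clinically decisive.
`count_reclassified` counts distinct patients, so a patient discordant
in two adjacent genes (one deletion spanning both) counts once.

## Synthetic cohorts

Nine regions on nine pseudo-chromosomes, 100 kb-scale spans, evenly
spaced width-1 array probes (spacing 1–1.2 kb, ± 20 kb flank) and one
MLPA probe per covered exon. Geometry mirrors the real platforms'
failure modes: an *IKZF1* analogue with an 11 kb probe-free intron-3
hole; an array-blind *CDKN2A*; a one-kit-probe *CDKN2B*; *PAX5*/*EBF1*
analogues with MLPA-uncovered exons; a PAR1 analogue covered by the
array only over its proximal fifth. Events are drawn per region from
templates (exon range, delta_cn, clonal fraction); probes inside
declared holes are absent entirely; generation is byte-deterministic
given the seed.

Two named cohorts define the study conditions used in validation:

* `recovery_benchmark` — clonal events spanning ≥ 10 array probes, with
  the array-blind regions silenced (they measure probe design, not the
  pipeline). The pipeline's measured sensitivity/specificity targets
  (≥ 95 % / ≥ 98 %) are evaluated on per-gene calls pooled across genes.
* `taxonomy_benchmark` — event templates chosen so categories i, ii, iii
  and v each arise by construction (iv, the residual, is exercised by
  unit fixtures).

What passing these cohorts does **not** show: the generator has no
B-allele frequencies, no GC waves beyond a linear covariate, no batch
effects, no probe-specific variance, and its noise is exactly Gaussian —
real arrays are harsher on all counts. The cohort-level published
numbers are reproduced from the packaged tables, not from raw data,
because no patient-level data are deposited.

## Numerical and design notes

* Coordinates are 0-based half-open throughout; 1-based inputs are
  converted at read time (`--one-based`).
* Permutation comparisons use `T_perm ≥ T_obs − 1e-12` so exact ties
  (constant vectors) count as exceedances and p = 1.
* Per-profile RNG seeds are derived from the run seed and the
  (sample, chromosome) pair by CRC32, keeping profiles independent and
  runs reproducible.
* Strand is ignored; copy number is strand-symmetric.
* Known limitations: no B-allele-frequency or LOH modelling, no
  whole-genome ploidy estimation, no breakpoint-level (as opposed to
  gene-level) concordance, no agreement statistics beyond raw
  concordance.
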