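import numpy as np
import pytest

from cnaconcord.intervals import ArrayProbe, GeneRegion, GenomicInterval
from cnaconcord.segmentation import ArrayProfile


def make_profile(lrr, chrom="chr1", spacing=1000, sample="s1", gc=None, start=0):
    """ArrayProfile over evenly spaced width-1 probes."""
    lrr = np.asarray(lrr, dtype=float)
    probes = tuple(
        ArrayProbe(
            f"p{i:04d}",
            GenomicInterval(chrom, start + i * spacing, start + i * spacing + 1),
            gc_fraction=None if gc is None else float(gc[i]),
        )
        for i in range(len(lrr))
    )
    return ArrayProfile(sample, chrom, probes, lrr)


@pytest.fixture
def simple_region():
    """A toy two-exon gene on chr1 spanning probe indices 10..40."""
    span = GenomicInterval("chr1", 10_000, 40_000, "GENE")
    exons = (
        GenomicInterval("chr1", 12_000, 13_000, "1"),
        GenomicInterval("chr1", 30_000, 31_000, "2"),
    )
    return GeneRegion("GENE", span, exons)
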