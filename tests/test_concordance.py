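"""Cross-platform comparison, contingency tables, discordance taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaconcord.array_calls import CNAState
from cnaconcord.concordance import (
    CallPair,
    DiscordanceCategory,
    category_counts,
    classify_discordance,
    concordance_percent,
    tabulate,
)
from cnaconcord.intervals import ArrayProbe, GenomicInterval, MLPAProbe
from cnaconcord.synthetic import load_reference_tables

N = CNAState.NORMAL
L = CNAState.LOSS_DELETION
G = CNAState.GAIN_AMPLIFICATION


def pair(sample, gene, snp=N, manual=None, mlpa=N, single=False, snp_iv=None, mlpa_iv=None):
    return CallPair(
        sample, gene, snp, manual if manual is not None else snp, mlpa, single,
        snp_interval=snp_iv, mlpa_interval=mlpa_iv,
    )


def reference_pairs():
    """Expand the packaged per-gene call-group table into call pairs."""
    by_gene, _ = load_reference_tables()
    s = {"normal": N, "abnormal": L}
    pairs = []
    i = 0
    for row in by_gene.to_dict("records"):
        for _ in range(int(row["count"])):
            i += 1
            pairs.append(
                pair(f"v{i:04d}", row["gene"], s[row["snp_cbs"]],
                     s[row["snp_manual"]], s[row["mlpa"]])
            )
    return pairs


class TestConcordancePercent:
    def test_identical_grids_fully_concordant(self):
        pairs = [pair(f"s{i}", "IKZF1", L, L, L) for i in range(10)]
        raw, rounded = concordance_percent(pairs, "cbs")
        assert raw == 100.0 and rounded == 100

    def test_reference_cohort_cbs_mode(self):
        pairs = reference_pairs()
        assert len(pairs) == 1287
        disc = sum(not p.concordant("cbs") for p in pairs)
        assert disc == 25
        raw, rounded = concordance_percent(pairs, "cbs")
        assert raw == pytest.approx(100 * (1 - 25 / 1287))
        assert rounded == 98

    def test_reference_cohort_manual_mode(self):
        pairs = reference_pairs()
        disc = sum(not p.concordant("manual") for p in pairs)
        assert disc == 16
        _, rounded = concordance_percent(pairs, "manual")
        assert rounded == 99

    def test_manual_discordance_subset_of_cbs(self):
        for p in reference_pairs():
            if not p.concordant("manual"):
                assert not p.concordant("cbs")

    def test_opposite_directions_both_abnormal_is_concordant(self):
        p = pair("s", "RB1", snp=G, mlpa=L)
        assert p.concordant("cbs")


class TestTabulate:
    def test_reference_ikzf1_cells_manual_mode(self):
        tables = {t.gene: t for t in tabulate(reference_pairs(), "manual")}
        ik = tables["IKZF1"]
        assert (ik.nn, ik.na, ik.an, ik.aa) == (113, 1, 0, 29)

    def test_reference_per_gene_totals(self):
        for t in tabulate(reference_pairs(), "cbs"):
            assert t.total == 143

    def test_single_sample_one_cell_per_gene(self):
        tables = tabulate([pair("s1", "ETV6", L, L, L)], "cbs")
        (t,) = tables
        assert (t.nn, t.na, t.an, t.aa) == (0, 0, 0, 1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from([N, L, G]), st.sampled_from([N, L, G])),
                    min_size=1, max_size=60))
    def test_cell_sums_match_cohort_size(self, states):
        pairs = [pair(f"s{i}", "GENE", snp, None, mlpa)
                 for i, (snp, mlpa) in enumerate(states)]
        (t,) = tabulate(pairs, "cbs")
        assert t.total == len(pairs)
        assert t.discordant == sum(not p.concordant("cbs") for p in pairs)


def snp_probes(positions, chrom="chr1"):
    return sorted(
        (ArrayProbe(f"p{p}", GenomicInterval(chrom, p, p + 1)) for p in positions),
        key=lambda p: p.pos,
    )


def kit_probes(positions, gene="GENE", chrom="chr1"):
    return [
        MLPAProbe(f"{gene}_{i}", gene, str(i + 1), GenomicInterval(chrom, p, p + 60))
        for i, p in enumerate(positions)
    ]


class TestClassifyDiscordance:
    def test_mlpa_only_event_without_array_probes_is_category_i(self):
        # focal deletion inside a gene the array does not cover internally
        p = pair("s", "CDKN2A", snp=N, mlpa=L,
                 mlpa_iv=GenomicInterval("chr1", 10_000, 14_000))
        rec = classify_discordance(p, snp_probes([5_000, 20_000]), kit_probes([11_000, 12_000]))
        assert rec.category is DiscordanceCategory.I_NO_SNP_PROBES
        assert rec.n_snp_probes == 0

    def test_single_probe_mlpa_over_covered_normal_array_is_category_ii(self):
        p = pair("s", "CDKN2B", snp=N, mlpa=L, single=True,
                 mlpa_iv=GenomicInterval("chr1", 10_000, 20_000))
        probes = snp_probes(range(10_000, 20_000, 1_000))
        rec = classify_discordance(p, probes, kit_probes([15_000]))
        assert rec.category is DiscordanceCategory.II_SINGLE_MLPA_PROBE

    def test_rescued_focal_event_is_category_iii(self):
        p = pair("s", "IKZF1", snp=N, manual=L, mlpa=L,
                 mlpa_iv=GenomicInterval("chr1", 10_000, 20_000))
        probes = snp_probes(range(10_000, 20_000, 1_000))
        rec = classify_discordance(p, probes, kit_probes([12_000, 15_000]))
        assert rec.category is DiscordanceCategory.III_CBS_MISSED_FOCAL

    def test_array_only_event_without_kit_probes_is_category_v(self):
        p = pair("s", "PAX5", snp=L, mlpa=N,
                 snp_iv=GenomicInterval("chr1", 30_000, 40_000))
        probes = snp_probes(range(30_000, 40_000, 1_000))
        rec = classify_discordance(p, probes, kit_probes([5_000, 50_000]))
        assert rec.category is DiscordanceCategory.V_NO_MLPA_PROBES
        assert rec.n_mlpa_probes == 0

    def test_covered_disagreement_falls_through_to_iv(self):
        p = pair("s", "ETV6", snp=N, mlpa=L,
                 mlpa_iv=GenomicInterval("chr1", 10_000, 20_000))
        probes = snp_probes(range(10_000, 20_000, 1_000))
        rec = classify_discordance(p, probes, kit_probes([12_000, 15_000]))
        assert rec.category is DiscordanceCategory.IV_TRUE_DISAGREEMENT

    def test_concordant_pair_rejected(self):
        with pytest.raises(ValueError):
            classify_discordance(pair("s", "G", L, L, L), [], [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        snp=st.sampled_from([N, L, G]),
        manual_abn=st.booleans(),
        mlpa=st.sampled_from([N, L, G]),
        single=st.booleans(),
        n_probes=st.integers(0, 12),
    )
    def test_every_discordant_pair_gets_exactly_one_category(
        self, snp, manual_abn, mlpa, single, n_probes
    ):
        manual = (L if manual_abn else snp) if snp is N else snp
        if single and mlpa is N:
            single = False
        iv = GenomicInterval("chr1", 10_000, 20_000)
        p = pair("s", "GENE", snp, manual, mlpa, single,
                 snp_iv=iv if snp.abnormal else None,
                 mlpa_iv=iv if mlpa.abnormal else None)
        if p.concordant("cbs"):
            return
        probes = snp_probes(range(10_000, 10_000 + n_probes * 1_000, 1_000))
        rec = classify_discordance(p, probes, kit_probes([12_000, 15_000]))
        assert isinstance(rec.category, DiscordanceCategory)
        # the invariants the categories promise
        if rec.category is DiscordanceCategory.I_NO_SNP_PROBES:
            assert rec.n_snp_probes == 0
        if rec.category is DiscordanceCategory.II_SINGLE_MLPA_PROBE:
            assert p.mlpa_single_probe


class TestCategoryCounts:
    def test_reference_table_counts(self):
        _, discordant = load_reference_tables()
        counts = discordant["category"].value_counts().to_dict()
        assert counts == {"i": 5, "ii": 2, "iii": 9, "iv": 6, "v": 3}
        assert sum(counts.values()) == 25

    def test_empty_records_all_zero(self):
        counts = category_counts([])
        assert all(v == 0 for v in counts.values())
        assert set(counts) == set(DiscordanceCategory)
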