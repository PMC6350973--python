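"""Fisher test, BH correction, eligibility rules and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_stepup_oracle, fisher_tail_oracle
from binscreen.enrichment import (
    ANALYSES,
    ContingencyTable,
    antisense_intronic_analysis,
    fdr_correct,
    fisher_one_sided_greater,
    fisher_pvalues,
    gene_based_analysis,
    inactivating_analysis,
    upstream_analysis,
)
from binscreen.models import SORTED, UNSORTED, GeneModel, GenomeLayout, Insertion
from conftest import make_table


class TestFisher:
    def test_zero_count_gives_p_one(self):
        assert fisher_one_sided_greater(ContingencyTable(0, 100, 17, 200)) == 1.0

    def test_hand_computed_extreme_table(self):
        # all 5 draws in sorted: C(5,5)C(5,0)/C(10,5) = 1/252
        p = fisher_one_sided_greater(ContingencyTable(5, 5, 0, 5))
        assert p == pytest.approx(1 / 252, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            A, B = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            a, b = int(rng.integers(0, A + 1)), int(rng.integers(0, B + 1))
            got = fisher_one_sided_greater(ContingencyTable(a, A, b, B))
            assert got == pytest.approx(fisher_tail_oracle(a, A, b, B), abs=1e-10)

    def test_monotone_nonincreasing_in_a(self):
        A, B, b = 50, 60, 5
        ps = [fisher_one_sided_greater(ContingencyTable(a, A, b, B)) for a in range(A + 1)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_stable_at_screen_scale_totals(self):
        p = fisher_one_sided_greater(ContingencyTable(40, 10_000_000, 2, 10_000_000))
        assert 0 < p < 1e-8  # strong enrichment, no under/overflow to 0 or 1

    def test_no_data_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_one_sided_greater(ContingencyTable(0, 0, 0, 0))

    @pytest.mark.parametrize("a,A,b,B", [(5, 4, 0, 5), (0, 5, 9, 8), (-1, 5, 0, 5)])
    def test_invalid_margins_rejected(self, a, A, b, B):
        with pytest.raises(ValueError):
            ContingencyTable(a, A, b, B)


class TestFdrCorrect:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.01]) == pytest.approx([0.01])

    def test_hand_computed_pair(self):
        # min(2*0.02/1, 2*0.04/2) = 0.04 for both positions
        assert fdr_correct([0.02, 0.04]) == pytest.approx([0.04, 0.04])

    def test_equal_ps_are_a_fixed_point(self):
        assert fdr_correct([0.3] * 7) == pytest.approx([0.3] * 7)

    def test_empty_list(self):
        assert len(fdr_correct([])) == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 0.0])

    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=120,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_definition(self, ps):
        assert fdr_correct(ps) == pytest.approx(bh_stepup_oracle(ps), abs=1e-12)


@pytest.fixture
def screen_layout():
    return GenomeLayout({"chr1": 20_000}, bin_length=250)


@pytest.fixture
def plus_gene():
    # promoter [1000,3000) bins 4-11; 5'UTR [3000,3500); CDS [3500,4000)+[6000,8500)
    # intron [4000,6000) bins 16-23; 3'UTR [8500,9000)
    return GeneModel("geneA", "chr1", "+", 3000, 9000, 3500, 8500, (3000, 6000), (4000, 9000))


def background(n_sorted=20, n_unsorted=20):
    """Far-away insertions (bins 64+) so totals are non-degenerate."""
    ins = [Insertion("chr1", 16_000 + 7 * i, "+", SORTED) for i in range(n_sorted)]
    ins += [Insertion("chr1", 16_000 + 7 * i + 3, "-", UNSORTED) for i in range(n_unsorted)]
    return ins


def result_for_bin(results, idx, bin_length=250):
    hits = [r for r in results if r.start == idx * bin_length]
    return hits[0] if hits else None


class TestAntisenseIntronicEligibility:
    def test_antisense_counts_tested_sense_only_bins_skipped(self, plus_gene, screen_layout):
        ins = background()
        # bin 16: 4 antisense ('-') sorted; bin 17: 3 sense ('+') sorted only
        ins += [Insertion("chr1", 4000 + i, "-", SORTED) for i in range(4)]
        ins += [Insertion("chr1", 4250 + i, "+", SORTED) for i in range(3)]
        table = make_table([plus_gene], ins, screen_layout)
        results = antisense_intronic_analysis(table)
        hit = result_for_bin(results, 16)
        assert hit is not None and (hit.a, hit.b) == (4, 0)
        assert hit.p_raw == pytest.approx(
            fisher_tail_oracle(4, table.total_sorted, 0, table.total_unsorted), abs=1e-10
        )
        assert result_for_bin(results, 17) is None

    def test_mixed_intron_cds_bin_not_tested(self, plus_gene, screen_layout):
        iso2 = GeneModel(
            "geneA", "chr1", "+", 3000, 9000, 3500, 8500,
            (3000, 4500, 6000), (4000, 5000, 9000),
        )
        ins = background() + [Insertion("chr1", 4500 + i, "-", SORTED) for i in range(5)]
        table = make_table([plus_gene, iso2], ins, screen_layout)
        assert result_for_bin(antisense_intronic_analysis(table), 18) is None

    def test_opposite_strand_intron_overlap_excluded(self, screen_layout):
        gene_fwd = GeneModel("fwd", "chr1", "+", 3000, 9000, 3100, 8900, (3000, 6000), (4000, 9000))
        gene_rev = GeneModel("rev", "chr1", "-", 3900, 9500, 4000, 9400, (3900, 9000), (4000, 9500))
        # bin 17 [4250,4500): intron of both genes, opposite strands
        ins = background() + [Insertion("chr1", 4300 + i, "-", SORTED) for i in range(4)]
        table = make_table([gene_fwd, gene_rev], ins, screen_layout)
        ann = table.annotation_for(("chr1", 17))
        assert {t[1] for t in ann.triples} == {"intron"} and not ann.exclusive_intron
        assert result_for_bin(antisense_intronic_analysis(table), 17) is None


class TestUpstreamEligibility:
    def test_both_orientations_summed(self, plus_gene, screen_layout):
        ins = background()
        ins += [Insertion("chr1", 1000 + i, "+", SORTED) for i in range(2)]
        ins += [Insertion("chr1", 1100 + i, "-", SORTED) for i in range(3)]
        table = make_table([plus_gene], ins, screen_layout)
        hit = result_for_bin(upstream_analysis(table), 4)
        assert hit is not None and (hit.a, hit.b) == (5, 0)

    def test_promoter_overlapping_other_genes_utr_not_tested(self, plus_gene, screen_layout):
        # upstream gene whose 3'UTR reaches into geneA's promoter region
        upstream_gene = GeneModel("geneB", "chr1", "+", 200, 1100, 300, 1000, (200,), (1100,))
        ins = background() + [Insertion("chr1", 1001 + i, "+", SORTED) for i in range(4)]
        table = make_table([plus_gene, upstream_gene], ins, screen_layout)
        assert not table.annotation_for(("chr1", 4)).exclusive_promoter
        assert result_for_bin(upstream_analysis(table), 4) is None

    def test_zero_sorted_count_not_tested(self, plus_gene, screen_layout):
        ins = background() + [Insertion("chr1", 1500, "+", UNSORTED)]
        table = make_table([plus_gene], ins, screen_layout)
        assert result_for_bin(upstream_analysis(table), 6) is None


class TestInactivatingEligibility:
    def test_exonic_bin_counts_both_orientations(self, plus_gene, screen_layout):
        ins = background()
        ins += [Insertion("chr1", 3500 + i, "+", SORTED) for i in range(3)]
        ins += [Insertion("chr1", 3600, "-", SORTED)]
        table = make_table([plus_gene], ins, screen_layout)
        hit = result_for_bin(inactivating_analysis(table), 14)
        assert hit is not None and hit.a == 4

    def test_exclusive_intron_bin_counts_sense_only(self, plus_gene, screen_layout):
        ins = background()
        ins += [Insertion("chr1", 4000 + i, "+", SORTED) for i in range(3)]
        ins += [Insertion("chr1", 4100 + i, "-", SORTED) for i in range(2)]
        table = make_table([plus_gene], ins, screen_layout)
        hit = result_for_bin(inactivating_analysis(table), 16)
        assert hit is not None and hit.a == 3

    def test_unsorted_count_uses_same_per_bin_rule(self, plus_gene, screen_layout):
        ins = background()
        ins += [Insertion("chr1", 4000, "+", SORTED)]
        ins += [Insertion("chr1", 4010 + i, "+", UNSORTED) for i in range(2)]
        ins += [Insertion("chr1", 4020 + i, "-", UNSORTED) for i in range(5)]  # antisense ignored
        table = make_table([plus_gene], ins, screen_layout)
        hit = result_for_bin(inactivating_analysis(table), 16)
        assert (hit.a, hit.b) == (1, 2)

    def test_exclusive_promoter_bin_not_tested(self, plus_gene, screen_layout):
        ins = background() + [Insertion("chr1", 1000, "+", SORTED)]
        table = make_table([plus_gene], ins, screen_layout)
        assert result_for_bin(inactivating_analysis(table), 4) is None

    def test_antisense_and_upstream_families_disjoint(self, plus_gene, screen_layout):
        ins = background()
        ins += [Insertion("chr1", 1000, "-", SORTED), Insertion("chr1", 4000, "-", SORTED)]
        table = make_table([plus_gene], ins, screen_layout)
        anti = {r.unit_id for r in antisense_intronic_analysis(table)}
        up = {r.unit_id for r in upstream_analysis(table)}
        assert anti and up and not (anti & up)


class TestGeneBasedAnalysis:
    def test_aggregates_all_features_including_promoter(self, plus_gene, screen_layout):
        ins = background()
        ins += [Insertion("chr1", 3000 + i, "+", SORTED) for i in range(2)]  # 5'UTR
        ins += [Insertion("chr1", 6100 + i, "-", SORTED) for i in range(3)]  # CDS, antisense
        ins += [Insertion("chr1", 1200, "+", SORTED)]  # promoter
        table = make_table([plus_gene], ins, screen_layout)
        (hit,) = [r for r in gene_based_analysis(table) if r.unit_id == "geneA"]
        assert hit.a == 6 and hit.b == 0

    def test_shared_bin_counts_for_both_genes(self, screen_layout):
        gene_fwd = GeneModel("fwd", "chr1", "+", 3000, 9000, 3100, 8900, (3000, 6000), (4000, 9000))
        gene_rev = GeneModel("rev", "chr1", "-", 3900, 9500, 4000, 9400, (3900, 9000), (4000, 9500))
        ins = background() + [Insertion("chr1", 4300, "+", SORTED)]
        table = make_table([gene_fwd, gene_rev], ins, screen_layout)
        by_gene = {r.unit_id: r for r in gene_based_analysis(table)}
        assert by_gene["fwd"].a >= 1 and by_gene["rev"].a >= 1

    def test_gene_without_sorted_insertions_not_tested(self, plus_gene, screen_layout):
        ins = background() + [Insertion("chr1", 4000, "+", UNSORTED)]
        table = make_table([plus_gene], ins, screen_layout)
        assert all(r.unit_id != "geneA" or r.a >= 1 for r in gene_based_analysis(table))
        # the only geneA evidence is unsorted, so geneA is absent
        assert "geneA" not in {r.unit_id for r in gene_based_analysis(table)}


class TestRanking:
    def test_ranks_ascending_by_corrected_p_with_stable_ties(self, plus_gene, screen_layout):
        rng = np.random.default_rng(2)
        ins = background(200, 200)
        for start in (4000, 4250, 4500, 4750):
            for i in range(int(rng.integers(1, 6))):
                ins.append(Insertion("chr1", start + i, "-", SORTED))
        table = make_table([plus_gene], ins, screen_layout)
        results = antisense_intronic_analysis(table)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))
        fdrs = [r.p_fdr for r in results]
        assert fdrs == sorted(fdrs)
        # rerun is byte-identical (deterministic tie-breaking)
        again = antisense_intronic_analysis(table)
        assert results == again

    def test_input_order_invariance(self, plus_gene, screen_layout):
        ins = background() + [Insertion("chr1", 4000 + i, "-", SORTED) for i in range(4)]
        t1 = make_table([plus_gene], ins, screen_layout)
        t2 = make_table([plus_gene], ins[::-1], screen_layout)
        assert antisense_intronic_analysis(t1) == antisense_intronic_analysis(t2)

    def test_all_analyses_registered(self):
        assert set(ANALYSES) == {"antisense-intronic", "upstream", "inactivating", "gene"}
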