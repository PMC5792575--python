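"""Unique-haplotype discrimination, multi-locus barcodes, greedy selection."""

import itertools

import numpy as np
import pytest

from plastoscreen import (
    evaluate_multilocus,
    greedy_locus_selection,
    identified_taxa,
    pct_identified,
    summarize_region,
    superbarcode,
)
from plastoscreen.errors import ConfigError
from plastoscreen.genome import Region
from plastoscreen.simulate import FIXTURE_MULTILOCUS
from plastoscreen.variation import map_region


class TestIdentifiedTaxa:
    def test_all_distinct_all_identified(self, make_aln):
        rows = [f"{b1}{b2}AA" for b1, b2 in
                itertools.product("ACGT", "ACGT")][:19]
        # make rows pairwise distinct over 4 columns
        rows = ["".join(p) + "A" for p in itertools.product("ACGT", repeat=3)][:19]
        aln = make_aln(rows, taxa=[f"t{k}" for k in range(19)])
        res = identified_taxa(aln, (0, 4))
        assert res.n_identified == 19 and not res.failures

    def test_identical_pair_of_taxa_both_fail(self, make_aln):
        rows = ["AAAA", "AAAA", "CAAA", "GAAA"]
        aln = make_aln(rows, taxa=["t1", "t2", "t3", "t4"])
        res = identified_taxa(aln, (0, 4))
        assert res.failures == {"t1", "t2"}
        assert res.identified == {"t3", "t4"}
        assert res.unresolved_classes == (frozenset({"t1", "t2"}),)
        assert res.n_resolved_units == 3  # the merged pair counts once

    def test_conspecific_divergence_does_not_disqualify(self, make_aln):
        # two individuals of t1 differ from each other but match no other taxon
        rows = ["AAAA", "AATA", "CAAA"]
        aln = make_aln(rows, taxa=["t1", "t1", "t2"])
        res = identified_taxa(aln, (0, 4))
        assert res.identified == {"t1", "t2"}

    def test_indel_only_difference_discriminates(self, make_aln):
        rows = ["AA-A", "AAAA", "CAAA"]
        aln = make_aln(rows, taxa=["t1", "t2", "t3"])
        res = identified_taxa(aln, (0, 4))
        assert res.n_identified == 3

    def test_constructed_seven_unique_taxa(self, make_aln):
        """Exactly 7 of 10 taxa carry locus haplotypes unique to them."""
        unique = [f"{b}AAA" for b in "ACGT"] + ["TTTA", "TTTC", "TTTG"]
        shared = ["GGGG"] * 3
        aln = make_aln(unique + shared, taxa=[f"t{k}" for k in range(10)])
        res = identified_taxa(aln, (0, 4))
        assert res.n_identified == 7
        assert res.failures == {"t7", "t8", "t9"}


class TestPctIdentified:
    @pytest.mark.parametrize("m,n,prose,expected", [
        (13, 19, True, 68.4),
        (7, 19, False, 36.84),
        (5, 19, False, 26.32),
        (6, 19, False, 31.58),
        (10, 19, False, 52.63),
        (0, 19, False, 0.0),
    ])
    def test_arithmetic(self, m, n, prose, expected):
        assert pct_identified(m, n, prose=prose) == expected

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            pct_identified(5, 4)


class TestMultilocus:
    def test_six_locus_concatenation_lengths_and_pics(self, fixture_pop,
                                                      fixture_regions):
        loci = [fixture_regions[n] for n in FIXTURE_MULTILOCUS]
        result = evaluate_multilocus(fixture_pop.alignment, loci)
        s = result.summary
        assert s.length_bp == 4508
        assert (s.n_snp, s.n_indel, s.pic) == (31, 15, 46)
        # the formula value of P_V for 46 PICs over 4508 bp
        assert s.p_v == 1.02

    def test_single_locus_identical_to_region_summary(self, fixture_pop,
                                                      fixture_regions):
        r = fixture_regions["rpl23"]
        ml = evaluate_multilocus(fixture_pop.alignment, [r]).summary
        s = summarize_region(fixture_pop.alignment, r)
        assert (ml.length_bp, ml.n_snp, ml.n_indel, ml.p_v) == (
            s.length_bp, s.n_snp, s.n_indel, s.p_v
        )
        assert ml.pi == pytest.approx(s.pi)
        assert ml.n_identified == s.n_identified

    def test_duplicate_locus_fatal(self, fixture_pop, fixture_regions):
        r = fixture_regions["rpl23"]
        with pytest.raises(ConfigError):
            evaluate_multilocus(fixture_pop.alignment, [r, r])

    def test_concatenation_is_monotone(self, fixture_pop, fixture_regions):
        aln = fixture_pop.alignment
        loci = [fixture_regions[n] for n in FIXTURE_MULTILOCUS]
        full = evaluate_multilocus(aln, loci).discrimination.identified
        for k in range(1, len(loci)):
            sub = evaluate_multilocus(aln, loci[:k]).discrimination.identified
            assert sub <= full


class TestSuperbarcode:
    def test_all_identical_zero_identified(self, make_aln):
        aln = make_aln(["ACGT" * 10] * 4, taxa=list("abcd"))
        res, matrix = superbarcode(aln)
        assert res.n_identified == 0
        assert (matrix.values == 0).all()

    def test_equals_exhaustive_region_concatenation(self, fixture_pop):
        aln = fixture_pop.alignment
        res_super, _ = superbarcode(aln)
        res_concat = evaluate_multilocus(aln, fixture_pop.regions).discrimination
        assert res_super.identified == res_concat.identified

    def test_masking_never_increases_pairwise_differences(self, fixture_pop):
        aln = fixture_pop.alignment
        _, full = superbarcode(aln)
        L = aln.reference_length
        _, masked = superbarcode(aln, mask_ir2=(L // 2, L))
        assert (masked.values <= full.values).all()


class TestGreedySelection:
    def _summaries(self, aln, regions):
        return [summarize_region(aln, r) for r in regions]

    def test_single_dominating_locus(self, make_aln):
        # locus A (cols 0-4) separates all taxa; locus B (cols 4-8) none
        rows = [x + "AAAA" for x in ("AAAA", "CCCC", "GGGG", "TTTT")]
        aln = make_aln(rows, taxa=[f"t{k}" for k in range(4)])
        regions = [Region("A", "spacer", ((0, 4),)),
                   Region("B", "spacer", ((4, 8),))]
        chosen = greedy_locus_selection(self._summaries(aln, regions), k=2)
        assert chosen == ["A"]

    def test_disjoint_sets_selected_by_size(self, make_aln):
        # locus A identifies t0,t1,t2 (others share); locus B identifies t3
        rows = ["AAA X", "CCC X", "GGG X", "TTT Y"]
        rows = ["AAAA", "CCCA", "GGGA", "TTTC"]
        # cols 0-3: all distinct -> not disjoint; build explicitly instead
        rows = [
            "AA" + "AA",   # t0: locus A unique, locus B shared
            "CC" + "AA",   # t1: locus A unique, locus B shared
            "GG" + "CC",   # t2: locus A shared with t3, locus B unique
            "GG" + "GG",   # t3: locus A shared with t2, locus B unique
        ]
        aln = make_aln(rows, taxa=[f"t{k}" for k in range(4)])
        regions = [Region("A", "spacer", ((0, 2),)),
                   Region("B", "spacer", ((2, 4),))]
        chosen = greedy_locus_selection(self._summaries(aln, regions), k=2)
        assert chosen == ["A", "B"]

    def test_greedy_at_least_best_single_locus(self, fixture_pop):
        """Concatenating the greedy picks never identifies fewer taxa than
        the best single locus (checked against exhaustive search)."""
        aln = fixture_pop.alignment
        pool = [r for r in fixture_pop.regions
                if r.label in FIXTURE_MULTILOCUS]
        summaries = [summarize_region(aln, r) for r in pool]
        chosen = greedy_locus_selection(summaries, k=3)
        by_label = {r.label: r for r in pool}
        greedy_n = evaluate_multilocus(
            aln, [by_label[n] for n in chosen]
        ).discrimination.n_identified
        best_single = max(s.n_identified for s in summaries)
        assert greedy_n >= best_single
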