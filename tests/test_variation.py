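"""SNP/indel calling, P_V, nucleotide diversity, effects and pairwise distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastoscreen import (
    AnnotatedPlastome,
    Feature,
    MultipleAlignment,
    Region,
    call_indel_events,
    call_snp_sites,
    classify_snp_effect,
    detect_pseudogenization,
    map_region,
    nucleotide_diversity,
    pairwise_difference_matrix,
    percent_variation,
    summarize_region,
)
from plastoscreen.simulate import MutationRecord, build_alignment
from plastoscreen.variation import (
    assess_reading_frame,
    count_indel_events,
    count_snp_sites,
)


def region(*parts, strand="+", kind="coding", name="r"):
    return Region(name, kind, tuple(parts), strand=strand)


class TestMapRegion:
    def test_identity_when_ungapped(self, make_aln):
        aln = make_aln(["ACGTACGTACGTACGTACGTACGT"] * 2)
        assert map_region(aln, region((10, 20))) == [(10, 20)]

    def test_offset_by_leading_reference_gaps(self, make_aln):
        ref = "---" + "ACGTACGTACGTACGTACGT"
        other = "TTT" + "ACGTACGTACGTACGTACGT"
        aln = make_aln([ref, other])
        assert map_region(aln, region((10, 20))) == [(13, 23)]

    def test_round_trip_through_random_gaps(self, make_aln):
        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACGT"), size=120))
        # interleave random insertion columns (gap in reference)
        cols, ref_row, other_row = [], [], []
        for ch in base:
            if rng.random() < 0.15:
                ref_row.append("-")
                other_row.append("A")
            ref_row.append(ch)
            other_row.append(ch)
        aln = make_aln(["".join(ref_row), "".join(other_row)])
        for start, end in [(0, 10), (17, 54), (100, 120)]:
            (a, b), = map_region(aln, region((start, end)))
            ungapped = "".join(
                c for c in "".join(ref_row)[a:b] if c != "-"
            )
            assert ungapped == base[start:end]


class TestSnpSites:
    def test_monomorphic_block_is_empty(self, make_aln):
        aln = make_aln(["ACGT", "ACGT", "ACGT"])
        assert call_snp_sites(aln, (0, 4)) == []

    def test_gap_neither_creates_nor_suppresses(self, make_aln):
        aln = make_aln(["AAAA", "AAAA", "GAAA", "-AAA"])
        sites = call_snp_sites(aln, (0, 4))
        assert len(sites) == 1
        assert set(sites[0].alleles) == {"A", "G"}
        # a gap against a monomorphic column is not a SNP
        aln2 = make_aln(["AAAA", "A-AA"])
        assert call_snp_sites(aln2, (0, 4)) == []

    def test_n_is_missing_data(self, make_aln):
        aln = make_aln(["ANAA", "ANAA", "ANAA"])
        assert call_snp_sites(aln, (0, 4)) == []
        aln2 = make_aln(["ANAA", "AGAA", "ATAA"])
        assert len(call_snp_sites(aln2, (0, 4))) == 1

    def test_multiallelic_column_is_one_site(self, make_aln):
        aln = make_aln(["AAAA", "CAAA", "GAAA", "TAAA"])
        assert count_snp_sites(aln, (0, 4)) == 1


class TestIndelEvents:
    def test_gapless_block_empty(self, make_aln):
        aln = make_aln(["ACGT", "ACGT"])
        assert call_indel_events(aln, (0, 4)) == []

    def test_adjacent_gap_columns_one_event(self, make_aln):
        aln = make_aln(["AC--GT", "ACAAGT", "ACAAGT"])
        events = call_indel_events(aln, (0, 6))
        assert len(events) == 1
        assert events[0].length == 2
        assert events[0].gapped == ("s1",)

    def test_disjoint_single_gaps_two_events(self, make_aln):
        aln = make_aln(["A-CGAT", "ACCG-T", "ACCGAT"])
        assert len(call_indel_events(aln, (0, 6))) == 2

    def test_changing_gap_set_splits_runs(self, make_aln):
        # columns 1-2 gapped in s1 only, column 3 gapped in s1+s2: two events
        aln = make_aln(["A---AA", "AAA-AA", "AAAAAA"])
        events = call_indel_events(aln, (0, 6))
        assert [(e.start_col, e.end_col, e.gapped) for e in events] == [
            (1, 3, ("s1",)),
            (3, 4, ("s1", "s2")),
        ]

    def test_boundary_run_counted_in_each_window(self, make_aln):
        aln = make_aln(["AA--AA", "AAAAAA"])
        assert count_indel_events(aln, (0, 3)) == 1
        assert count_indel_events(aln, (3, 6)) == 1
        assert count_indel_events(aln, (0, 6)) == 1

    def test_matches_brute_force_on_random_gap_matrices(self, make_aln):
        rng = np.random.default_rng(42)
        for _ in range(100):
            rows = _random_gap_matrix(rng, n=10, L=50)
            aln = make_aln(rows)
            assert count_indel_events(aln, (0, 50)) == _brute_force_events(rows)


def _random_gap_matrix(rng, n, L):
    rows = []
    for i in range(n):
        row = list(rng.choice(list("ACGT"), size=L))
        if i > 0:  # keep one row gap-free so no column is all-gap
            for _ in range(rng.integers(0, 5)):
                s = rng.integers(0, L - 3)
                for k in range(rng.integers(1, 4)):
                    row[s + k] = "-"
        rows.append("".join(row))
    return rows


def _brute_force_events(rows):
    """Independent run-segmentation oracle over explicit column gap sets."""
    L = len(rows[0])
    sets = [frozenset(i for i, r in enumerate(rows) if r[c] == "-")
            for c in range(L)]
    events, prev = 0, frozenset()
    for s in sets:
        if s and s != prev:
            events += 1
        prev = s
    return events


class TestPercentVariation:
    @pytest.mark.parametrize(
        "snp,indel,length,expected",
        [
            (8, 1, 285, 3.16),
            (4, 2, 160, 3.75),
            (0, 0, 600, 0.00),
            (7, 3, 600, 1.67),
            (10, 3, 600, 2.17),
            (1, 0, 800, 0.13),  # exact .125 rounds half-up
        ],
    )
    def test_values(self, snp, indel, length, expected):
        assert percent_variation(snp, indel, length) == expected

    def test_zero_length_fatal(self):
        with pytest.raises(ValueError):
            percent_variation(1, 0, 0)


class TestNucleotideDiversity:
    def test_identical_rows_zero(self, make_aln):
        aln = make_aln(["ACGT" * 25] * 4)
        assert nucleotide_diversity(aln, (0, 100)) == 0.0

    def test_two_individuals_closed_form(self, make_aln):
        a = "A" * 100
        b = "A" * 99 + "G"
        aln = make_aln([a, b])
        assert nucleotide_diversity(aln, (0, 100)) == pytest.approx(0.01)

    def test_matches_brute_force_enumeration(self, make_aln):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rows = _random_gap_matrix(rng, n=rng.integers(2, 7), L=40)
            aln = make_aln(rows)
            assert nucleotide_diversity(aln, (0, 40)) == pytest.approx(
                _brute_force_pi(rows)
            )

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_row_order(self, seed):
        rng = np.random.default_rng(seed)
        rows = _random_gap_matrix(rng, n=5, L=30)
        ids = [f"s{i}" for i in range(5)]
        aln = MultipleAlignment(ids, rows)
        perm = rng.permutation(5)
        aln2 = MultipleAlignment([ids[i] for i in perm], [rows[i] for i in perm])
        assert nucleotide_diversity(aln, (0, 30)) == pytest.approx(
            nucleotide_diversity(aln2, (0, 30))
        )


def _brute_force_pi(rows):
    n = len(rows)
    total = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            comp = diff = 0
            for a, b in zip(rows[i], rows[j]):
                if a in "ACGT" and b in "ACGT":
                    comp += 1
                    diff += a != b
            total += diff / comp if comp else 0.0
            pairs += 1
    return total / pairs


class TestEffectClassification:
    @pytest.mark.parametrize(
        "codon,pos,alt,classification,ref_aa,alt_aa",
        [
            ("CTT", 0, "T", "nonsynonymous", "L", "F"),  # Leu -> Phe
            ("GCT", 2, "C", "synonymous", "A", "A"),
            ("CCA", 1, "A", "nonsynonymous", "P", "Q"),  # Pro -> Gln
        ],
    )
    def test_plus_strand_cases(self, codon, pos, alt, classification, ref_aa, alt_aa):
        gene = Feature("g", "CDS", ((0, 3),), "+")
        call = classify_snp_effect(gene, codon, alt, pos)
        assert call.classification == classification
        assert (call.ref_aa, call.alt_aa) == (ref_aa, alt_aa)

    def test_stop_gain_flagged(self):
        gene = Feature("g", "CDS", ((0, 3),), "+")
        call = classify_snp_effect(gene, "TGG", "A", 2)  # Trp -> stop (TGA)
        assert call.stop_gained and call.classification == "nonsynonymous"

    def test_minus_strand_orientation(self):
        # genome holds revcomp(CTT) = AAG; the gene reads CTT on '-'
        gene = Feature("g", "CDS", ((0, 3),), "-")
        # genome position 2 is codon position 0; genome alt 'A' reads as 'T'
        call = classify_snp_effect(gene, "AAG", "A", 2)
        assert (call.ref_codon, call.alt_codon) == ("CTT", "TTT")
        assert call.classification == "nonsynonymous"

    def test_spliced_gene_codon_assembly(self):
        # exons [0,2) + [5,9): CDS = AT GGCT AA -> ATG GCT AA? use 6nt CDS
        seq = "AT---GGCTAA"
        gene = Feature("g", "CDS", ((0, 2), (5, 9)), "+")
        call = classify_snp_effect(gene, seq, "C", 6)  # CDS idx 3 -> GCT codon pos 0
        assert call.ref_codon == "GCT"
        assert call.alt_codon == "CCT"


class TestPseudogenization:
    def test_intact_cds(self):
        assert assess_reading_frame("ATGGCTGCTTAA", 12) == (False, 0, False)

    def test_single_insertion_frameshifts(self, make_aln):
        ref = "ATGGCTGCTGCTGCTTAA"
        events = [MutationRecord("insertion", 6, 1, ("s2",), "g", alt="A")]
        genome = AnnotatedPlastome("t", ref, [])
        aln, seqs = build_alignment(genome, events, ["s1", "s2"],
                                    {"s1": "a", "s2": "b"}, "s1")
        reg = region((0, 18), name="g")
        rep = detect_pseudogenization(aln, reg, "s2")
        assert rep.frameshift
        # oracle: translate the shifted sequence and count internal stops
        from Bio.Seq import Seq

        mutated = seqs["s2"]
        n_codons = len(mutated) // 3
        oracle = str(Seq(mutated[: 3 * n_codons]).translate(table=11))[:-1].count("*")
        assert rep.internal_stops == oracle
        assert not detect_pseudogenization(aln, reg, "s1").frameshift

    def test_inframe_deletion_not_frameshift(self, make_aln):
        ref = "ATGGCTGCTGCTGCTTAA"
        events = [MutationRecord("deletion", 6, 3, ("s2",), "g")]
        genome = AnnotatedPlastome("t", ref, [])
        aln, _ = build_alignment(genome, events, ["s1", "s2"],
                                 {"s1": "a", "s2": "b"}, "s1")
        rep = detect_pseudogenization(aln, region((0, 18), name="g"), "s2")
        assert not rep.frameshift
        assert rep.internal_stops == 0

    def test_degenerate_cds_flagged(self, make_aln):
        aln = make_aln(["AC", "AC"])
        rep = detect_pseudogenization(aln, region((0, 2), name="g"), "s1")
        assert rep.degenerate


class TestPairwiseDifferences:
    def test_duplicate_rows_zero(self, make_aln):
        aln = make_aln(["ACGTAC" * 10] * 3)
        m = pairwise_difference_matrix(aln)
        assert (m.values == 0).all()

    def test_constructed_15_substitutions_13_indels(self):
        """Mirrors a pair differing by 15 substitutions plus 13 indel events."""
        rng = np.random.default_rng(9)
        ref = "".join(rng.choice(list("ACGT"), size=2000))
        genome = AnnotatedPlastome("t", ref, [])
        events = []
        pos_pool = list(range(10, 1990, 12))
        rng.shuffle(pos_pool)
        for k in range(15):
            p = pos_pool.pop()
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref[p]]
            events.append(MutationRecord("substitution", p, 1, ("s2",), "r", alt=alt))
        for k in range(13):
            p = pos_pool.pop()
            ln = 2 if k < 2 else 1  # two double-base indels, rest single
            typ = "insertion" if k % 2 else "deletion"
            alt = "AT"[:ln] if typ == "insertion" else ""
            events.append(MutationRecord(typ, p, ln, ("s2",), "r", alt=alt))
        aln, _ = build_alignment(genome, events, ["s1", "s2"],
                                 {"s1": "a", "s2": "b"}, "s1")
        m = pairwise_difference_matrix(aln)
        assert m.loc["s1", "s2"] == 28

    def test_symmetry_and_zero_diagonal(self, make_aln):
        rng = np.random.default_rng(10)
        rows = _random_gap_matrix(rng, n=6, L=60)
        aln = make_aln(rows)
        m = pairwise_difference_matrix(aln).values
        assert (m == m.T).all()
        assert (np.diag(m) == 0).all()


class TestSummarizeRegion:
    def test_invariant_region_all_zero(self, make_aln):
        aln = make_aln(["ACGT" * 30] * 4, taxa=["a", "b", "c", "d"])
        s = summarize_region(aln, region((0, 120)))
        assert (s.n_snp, s.n_indel, s.p_v, s.pi) == (0, 0, 0.0, 0.0)
        assert s.n_identified == 0

    def test_pic_is_definitional(self, make_aln):
        rng = np.random.default_rng(13)
        for _ in range(10):
            rows = _random_gap_matrix(rng, n=6, L=50)
            aln = make_aln(rows)
            s = summarize_region(aln, region((0, 50)), discriminate=False)
            assert s.pic == s.n_snp + s.n_indel
            assert s.p_v == percent_variation(s.n_snp, s.n_indel, 50)
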