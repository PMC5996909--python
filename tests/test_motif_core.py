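"""Unit and property tests for motif composition, decomposition, CpG
accounting, classification and cohort summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatlens.errors import (
    AlphabetError,
    DecompositionError,
    StructureError,
    UsageError,
)
from repeatlens.motif_core import (
    DEFAULT_ALPHABET,
    AffectedStatus,
    AlleleClass,
    AlleleStructure,
    ClassificationConfig,
    DiploidGenotype,
    Insertion,
    classify_allele,
    classify_genotype,
    compose_allele,
    count_cpg,
    cpg_positions,
    decompose_sequence,
    enumerate_tilings,
    format_nomenclature,
    parse_nomenclature,
    reverse_complement,
    summarize_cohort,
)

CA18 = DEFAULT_ALPHABET.sequence("CA18")
CACA20 = DEFAULT_ALPHABET.sequence("CACA20")
CGCA20 = DEFAULT_ALPHABET.sequence("CGCA20")

motif_ids = st.sampled_from(DEFAULT_ALPHABET.ids)
structures = st.lists(motif_ids, min_size=1, max_size=17).map(
    lambda m: AlleleStructure(tuple(m))
)


class TestAlphabet:
    def test_default_sequences_are_the_printed_motifs(self):
        assert CA18 == "TCGGCAGCGGCAGCGAGG" and len(CA18) == 18
        assert CACA20 == "TCGGCAGCGGCACAGCGAGG" and len(CACA20) == 20
        assert CGCA20 == "TCGGCAGCGGCGCAGCGAGG" and len(CGCA20) == 20
        # shared 10-nt head, then divergence
        assert CA18[:10] == CACA20[:10] == CGCA20[:10] == "TCGGCAGCGG"
        assert len({CA18, CACA20, CGCA20}) == 3

    def test_unknown_motif_raises(self):
        with pytest.raises(AlphabetError):
            DEFAULT_ALPHABET.sequence("XYZ")


class TestComposeDecompose:
    def test_published_4_repeat_construct(self):
        s = AlleleStructure(("CACA20", "CACA20", "CACA20", "CA18"))
        seq = compose_allele(s)
        assert seq == 3 * CACA20 + CA18
        assert len(seq) == 78
        d = decompose_sequence(seq)
        assert d.motifs == s.motifs and d.repeat_count == 4

    def test_single_motif_identity(self):
        assert compose_allele(AlleleStructure(("CA18",))) == CA18
        assert decompose_sequence(CA18).motifs == ("CA18",)

    def test_insertion_splice(self):
        s = AlleleStructure(("CGCA20",), (Insertion(0, "AAAA"),))
        assert compose_allele(s) == CGCA20 + "AAAA"

    def test_insertion_out_of_range(self):
        s = AlleleStructure(("CA18",), (Insertion(3, "AAAA"),))
        with pytest.raises(StructureError):
            compose_allele(s)

    def test_untileable_reports_offset(self):
        seq = CA18 + "ACAC" + CA18
        with pytest.raises(DecompositionError) as exc:
            decompose_sequence(seq)
        assert exc.value.offset == 18

    def test_insertion_roundtrip(self):
        s = AlleleStructure(("CACA20", "CA18"), (Insertion(0, "GATTACAGATTA"),))
        seq = compose_allele(s)
        d = decompose_sequence(seq, allow_insertions=True)
        assert d.motifs == s.motifs
        assert d.insertions == s.insertions
        assert classify_allele(d) is AlleleClass.ATYPICAL_INSERTION

    def test_insertion_longer_than_limit_rejected(self):
        s = AlleleStructure(("CACA20", "CA18"), (Insertion(0, "A" * 25),))
        seq = compose_allele(s)
        with pytest.raises(DecompositionError):
            decompose_sequence(seq, allow_insertions=True, max_insertion_len=20)

    def test_auto_orient_recovers_reverse_complement(self):
        s = AlleleStructure(("CACA20", "CGCA20", "CA18"))
        seq = reverse_complement(compose_allele(s))
        with pytest.raises(DecompositionError):
            decompose_sequence(seq)
        assert decompose_sequence(seq, auto_orient=True).motifs == s.motifs

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(structures)
    def test_roundtrip_property(self, s):
        assert decompose_sequence(compose_allele(s)).motifs == s.motifs

    def test_tiling_unique_up_to_6_motifs(self):
        """Exhaustive re-tiling of every composition of up to 6 motifs finds
        exactly one tiling (boundaries only at GG|TC junctions)."""
        for n in range(1, 7):
            for combo in itertools.product(DEFAULT_ALPHABET.ids, repeat=n):
                seq = compose_allele(AlleleStructure(combo))
                tilings = enumerate_tilings(seq, limit=4)
                assert len(tilings) == 1
                assert tilings[0].motifs == combo


class TestCpG:
    @pytest.mark.parametrize(
        "motif,expected", [("CA18", 3), ("CACA20", 3), ("CGCA20", 4)]
    )
    def test_per_motif_counts(self, motif, expected):
        assert count_cpg(DEFAULT_ALPHABET.sequence(motif)) == expected

    def test_gain_of_37_between_pathogenic_and_control(self, pathogenic_16, control_8):
        assert count_cpg(pathogenic_16) - count_cpg(control_8) == 37

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(structures)
    def test_additive_over_motifs(self, s):
        """No junction CpGs for the default alphabet: counts are additive."""
        expected = sum(DEFAULT_ALPHABET.cpg_count(m) for m in s.motifs)
        assert count_cpg(s) == expected

    def test_positions_match_count(self, pathogenic_16):
        seq = compose_allele(pathogenic_16)
        assert len(cpg_positions(seq)) == count_cpg(seq)


class TestClassification:
    def test_16_repeat_disease_allele(self, pathogenic_16):
        assert classify_allele(pathogenic_16) is AlleleClass.PATHOGENIC_CANDIDATE

    def test_17_repeat_allele_pathogenic(self):
        s = parse_nomenclature("2xCACA20+14xCGCA20+CA18")
        assert s.repeat_count == 17
        assert classify_allele(s) is AlleleClass.PATHOGENIC_CANDIDATE

    def test_common_7_repeat_control(self, control_7):
        assert classify_allele(control_7) is AlleleClass.CONTROL_TYPICAL

    def test_11_repeat_carrier(self):
        s = parse_nomenclature("CACA20+8xCGCA20+CACA20+CA18")
        assert classify_allele(s) is AlleleClass.DISEASE_MOTIF_CARRIER

    def test_14_repeats_without_disease_motif_not_pathogenic(self):
        s = parse_nomenclature("13xCACA20+CA18")
        assert classify_allele(s) is AlleleClass.CONTROL_TYPICAL

    def test_indeterminate_zone_flag(self):
        cfg = ClassificationConfig()
        assert cfg.indeterminate_zone(13)
        assert not cfg.indeterminate_zone(12) and not cfg.indeterminate_zone(14)

    def test_genotype_recessive_model(self, pathogenic_16, control_7):
        carrier = parse_nomenclature("CACA20+8xCGCA20+CACA20+CA18")
        aff = DiploidGenotype(pathogenic_16, pathogenic_16)
        car = DiploidGenotype(pathogenic_16, control_7)
        una = DiploidGenotype(control_7, control_7)
        non_path_car = DiploidGenotype(carrier, control_7)
        assert classify_genotype(aff) is AffectedStatus.AFFECTED
        assert classify_genotype(car) is AffectedStatus.CARRIER
        assert classify_genotype(una) is AffectedStatus.UNAFFECTED
        assert classify_genotype(non_path_car) is AffectedStatus.UNAFFECTED

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(structures, structures)
    def test_genotype_classification_symmetric(self, a, b):
        assert classify_genotype(DiploidGenotype(a, b)) == classify_genotype(
            DiploidGenotype(b, a)
        )


class TestCohortSummary:
    def test_carrier_percent_whole_rounding(self, control_7):
        """8 carrier alleles of 760 round to 1% at whole-percent precision."""
        carrier = parse_nomenclature("CACA20+8xCGCA20+CACA20+CA18")
        genotypes = [DiploidGenotype(carrier, control_7, sample_id=f"c{i}") for i in range(8)]
        genotypes += [
            DiploidGenotype(control_7, control_7, sample_id=f"s{i}") for i in range(372)
        ]
        summary = summarize_cohort(genotypes)
        assert summary.n_alleles == 760
        assert summary.carrier_percent(whole=True) == 1
        assert summary.carrier_percent() == pytest.approx(round(800 / 760, 2))

    def test_single_homozygote(self, control_7):
        s = summarize_cohort([DiploidGenotype(control_7, control_7)])
        assert s.distinct_alleles == 1 and s.heterozygosity == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(UsageError):
            summarize_cohort([])

    def test_frequencies_match_multinomial_counts(self, control_7, control_8):
        genotypes = [DiploidGenotype(control_7, control_8)] * 3 + [
            DiploidGenotype(control_8, control_8)
        ]
        s = summarize_cohort(genotypes)
        assert s.structure_freqs[format_nomenclature(control_8)] == pytest.approx(5 / 8)
        assert s.heterozygosity == pytest.approx(0.75)
        assert s.repeat_count_freqs[7] == pytest.approx(3 / 8)


class TestNomenclature:
    @pytest.mark.parametrize(
        "nom",
        [
            "CA18",
            "3xCACA20+CA18",
            "4xCACA20+CA18+CACA20+CA18",
            "CACA20+13xCGCA20+CACA20+CA18",
            "2xCA18+[ins:GATTACA]+3xCGCA20",
        ],
    )
    def test_parse_format_inverse(self, nom):
        assert format_nomenclature(parse_nomenclature(nom)) == nom

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(structures)
    def test_format_parse_inverse(self, s):
        assert parse_nomenclature(format_nomenclature(s)).motifs == s.motifs

    def test_unknown_motif_token_rejected(self):
        with pytest.raises(AlphabetError):
            parse_nomenclature("3xFOO+CA18")
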