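"""Variant detection, characterization, description and QC flags."""

import random

import pytest
from Bio.Seq import Seq

from hlanovel.errors import AlignmentUnsupportedError
from hlanovel.fixtures import characterization_from_fixture_row
from hlanovel.gene_model import FeatureKind
from hlanovel.synthetic import induce_mutation
from hlanovel.variants import (
    GERMLINE_CONFIRMATION_REQUIRED,
    MULTIPLE_EXONIC_NOVELTIES,
    MutationClass,
    ObservedVariant,
    Specimen,
    VariantKind,
    characterize,
    describe_mutation,
    detect_variants,
    flag_suspect,
)


class TestDetectVariants:
    def test_identical_sequences_yield_nothing(self, b56_model):
        assert detect_variants(b56_model.sequence, b56_model.sequence) == []

    def test_single_snp(self, b56_model):
        ref = b56_model.sequence
        cons = ref[:792] + "C" + ref[793:]
        assert detect_variants(ref, cons) == [ObservedVariant(793, "A", "C")]

    def test_multiple_snps(self):
        assert detect_variants("ACGTACGT", "ACGAACGC") == [
            ObservedVariant(4, "T", "A"), ObservedVariant(8, "T", "C")]

    def test_insertion_reported_at_preceding_base(self):
        # G inserted after reference position 4
        [v] = detect_variants("ACGTACGT", "ACGTGACGT")
        assert v.variant_kind is VariantKind.INSERTION
        assert (v.pos, v.alt_base) == (4, "G")

    def test_deletion_reported_at_first_deleted_base(self):
        [v] = detect_variants("ACGTACGT", "ACGCGT")  # TA deleted at 4-5
        assert v.variant_kind is VariantKind.DELETION
        assert (v.pos, v.ref_base) == (4, "TA")

    def test_induced_insertion_roundtrip(self, synthetic_models):
        model = synthetic_models[0]
        rng = random.Random(11)
        pos = rng.randint(2, len(model.sequence))
        cons = model.sequence[:pos] + "G" + model.sequence[pos:]
        [v] = detect_variants(model.sequence, cons)
        assert v.variant_kind is VariantKind.INSERTION
        # a run of identical bases makes the anchor left-shift; the inserted
        # string must still reconstruct the consensus
        rebuilt = (model.sequence[:v.pos] + v.alt_base
                   + model.sequence[v.pos:])
        assert rebuilt == cons

    def test_irreconcilable_pair_raises(self):
        with pytest.raises(AlignmentUnsupportedError):
            detect_variants("ACGTACGT", "TTTTACGTT")  # indel + substitutions

    def test_mirror_under_reverse_complement(self, b56_model):
        """Annotating the flipped strand mirrors positions and bases."""
        ref = b56_model.sequence
        cons = ref[:792] + "C" + ref[793:]
        [v] = detect_variants(str(Seq(ref).reverse_complement()),
                              str(Seq(cons).reverse_complement()))
        assert v.pos == len(ref) - 793 + 1
        assert (v.ref_base, v.alt_base) == ("T", "G")  # complements of A, C


class TestCharacterize:
    def test_missense_in_alpha3_arm(self, b48_model):
        c = characterize(b48_model, ObservedVariant(1701, "A", "G"))
        assert c.mutation_class is MutationClass.MISSENSE
        assert c.region.index == 4 and not c.key_exon
        cc = c.codon_change
        assert (cc.codon_position, cc.ref_codon, cc.alt_codon) == (228, "ACT", "GCT")
        assert (cc.ref_aa, cc.alt_aa) == ("T", "A")

    def test_leader_stop_gain_is_nonsense(self, dpa1_model):
        c = characterize(dpa1_model, ObservedVariant(79, "C", "T"))
        assert c.mutation_class is MutationClass.NONSENSE
        assert c.region.index == 1
        assert (c.codon_change.codon_position, c.codon_change.ref_codon,
                c.codon_change.alt_codon) == (-5, "CGA", "TGA")

    def test_intronic_snp_near_acceptor_is_splice_proximal(self, dqa1_model):
        ref = dqa1_model.sequence[4026]
        alt = "A" if ref != "A" else "G"
        c = characterize(dqa1_model, ObservedVariant(4027, ref, alt))
        assert c.mutation_class is MutationClass.INTRONIC
        assert c.region.kind is FeatureKind.INTRON and c.region.index == 2
        assert c.splice_proximal
        # a mid-intron position is not proximal
        mid = (c.region.start + c.region.end) // 2
        ref2 = dqa1_model.sequence[mid - 1]
        c2 = characterize(dqa1_model,
                          ObservedVariant(mid, ref2, "A" if ref2 != "A" else "G"))
        assert not c2.splice_proximal

    def test_exonic_insertion_is_frameshift(self, b48_model):
        exon2 = b48_model.exons[1]
        v = ObservedVariant(exon2.start + 5,
                            b48_model.sequence[exon2.start + 4], "G",
                            VariantKind.INSERTION)
        c = characterize(b48_model, v)
        assert c.mutation_class is MutationClass.FRAMESHIFT

    def test_in_frame_deletion(self, b48_model):
        exon2 = b48_model.exons[1]
        start = exon2.start + 3
        v = ObservedVariant(start, b48_model.sequence[start - 1:start + 2],
                            "-", VariantKind.DELETION)
        c = characterize(b48_model, v)
        assert c.mutation_class is MutationClass.IN_FRAME_INDEL

    def test_utr_variant(self, b48_model):
        ref = b48_model.sequence[9]
        c = characterize(b48_model,
                         ObservedVariant(10, ref, "A" if ref != "A" else "G"))
        assert c.mutation_class is MutationClass.UTR
        assert c.codon_change is None

    def test_key_exon_flag_class_i_vs_ii(self, b56_model, dqa1_model):
        c = characterize(b56_model, ObservedVariant(793, "A", "C"))
        assert c.key_exon  # exon 3 is key for class I
        exon3 = dqa1_model.exons[2]
        ref = dqa1_model.sequence[exon3.start - 1]
        c2 = characterize(dqa1_model, ObservedVariant(
            exon3.start, ref, "A" if ref != "A" else "G"))
        assert not c2.key_exon  # exon 3 is NOT key for class II


class TestInducedRecovery:
    def test_recovery_exact_over_many_draws(self, synthetic_models):
        """Induce a variant of a requested class, detect it from the raw
        sequences and characterize it: position, bases and class must be
        recovered exactly on every draw."""
        rng = random.Random(20240)
        classes = [MutationClass.MISSENSE, MutationClass.SILENT,
                   MutationClass.NONSENSE, MutationClass.INTRONIC]
        n_trials = 500
        for trial in range(n_trials):
            model = synthetic_models[trial % len(synthetic_models)]
            target = classes[trial % len(classes)]
            consensus, truth_variant, truth = induce_mutation(
                model, target, rng)
            [found] = detect_variants(model.sequence, consensus)
            assert found == truth_variant
            c = characterize(model, found)
            assert c == truth
            assert c.mutation_class is target


class TestDescribeMutation:
    def test_registration_sentence_verbatim(self, b48_model):
        c = characterize(b48_model, ObservedVariant(1701, "A", "G"))
        assert describe_mutation("VGH002", "B*48:01:01:01", c) == (
            "VGH002 has 1 nt change from B*48:01:01:01 at nt 1701 where "
            "A > G (codon 228 ACT > GCT), resulting in a coding change "
            "228 Thr is changed to Ala.")

    def test_silent_branch(self, dqa1_model):
        c = characterize(dqa1_model, ObservedVariant(3809, "C", "T"))
        assert c.mutation_class is MutationClass.SILENT
        sentence = describe_mutation("VGH043", "DQA1*02:01:01:01", c)
        assert "no coding change" in sentence

    def test_nonsense_branch(self, dpa1_model):
        c = characterize(dpa1_model, ObservedVariant(79, "C", "T"))
        sentence = describe_mutation("VGH035", "DPA1*01:03:01:02", c)
        assert "codon -5 CGA > TGA" in sentence
        assert sentence.endswith("-5 Arg is changed to a stop codon.")

    def test_intronic_branch(self, dqa1_model):
        ref = dqa1_model.sequence[4026]
        c = characterize(dqa1_model,
                         ObservedVariant(4027, ref, "A" if ref != "A" else "G"))
        assert "in intron 2" in describe_mutation("S1", "DQA1*02:01", c)


class TestFlagSuspect:
    def test_single_novelty_buccal_clean(self, b48_model):
        c = characterize(b48_model, ObservedVariant(1701, "A", "G"))
        assert flag_suspect([c], Specimen.BUCCAL, False) == []

    def test_heme_malignancy_peripheral_blood(self, b48_model):
        c = characterize(b48_model, ObservedVariant(1701, "A", "G"))
        flags = flag_suspect([c], Specimen.PERIPHERAL_BLOOD, True)
        assert flags == [GERMLINE_CONFIRMATION_REQUIRED]

    def test_multiple_exonic_novelties(self, b48_model):
        c = characterize(b48_model, ObservedVariant(1701, "A", "G"))
        flags = flag_suspect([c, c, c], Specimen.PERIPHERAL_BLOOD, False)
        assert flags == [MULTIPLE_EXONIC_NOVELTIES]


class TestFixtureReplay:
    def test_mutation_types_reproduced_for_all_29_alleles(self, allele_table):
        """Deriving the class from the amino-acid effect reproduces the
        recorded mutation type for every allele in the bundled cohort."""
        for row in allele_table.itertuples():
            c = characterization_from_fixture_row(row)
            assert c.mutation_class.value == row.mutation_type.lower(), row.allele

    def test_domains_match_recorded_protein_locations(self, allele_table):
        from hlanovel.fixtures import location_to_domain
        from hlanovel.gene_model import default_domain_map, locus_to_class
        from hlanovel.gene_model import HLAClass
        n_exons = {HLAClass.CLASS_I: 7, HLAClass.CLASS_II_ALPHA: 4,
                   HLAClass.CLASS_II_BETA: 5}
        for row in allele_table.itertuples():
            hla_class = locus_to_class(row.allele.split("*")[0])
            dmap = default_domain_map(hla_class, n_exons[hla_class])
            assert dmap[row.exon] is location_to_domain(row.location_on_protein), \
                row.allele
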