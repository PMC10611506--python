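"""Gene structure and codon arithmetic."""

import pytest

from hlanovel.errors import (
    ModelDefinitionError,
    NotCodingError,
    PositionOutOfRangeError,
    UnsupportedBaseError,
)
from hlanovel.gene_model import (
    STOP,
    FeatureInterval,
    FeatureKind,
    GeneModel,
    HLAClass,
    ProteinDomain,
    raw_to_mature,
    read_gene_model,
    render_aa,
    translate_codon,
    write_gene_model,
)
from hlanovel.synthetic import make_gene_model


def codon_walk_oracle(model):
    """Brute-force oracle: walk the CDS base by base, assigning codon
    numbers, and return {genomic position: (codon, offset)}."""
    positions = []
    for f in model.features:
        if f.kind is FeatureKind.EXON:
            positions.extend(range(f.start, f.end + 1))
    out = {}
    for i, pos in enumerate(positions):
        raw = i // 3 + 1
        out[pos] = (raw_to_mature(raw, model.leader_length), i % 3)
    return out


class TestTranslate:
    @pytest.mark.parametrize("codon,aa", [
        ("CGA", "R"),   # arginine, the leader codon hit by the null allele
        ("TGA", STOP),  # its stop-gained counterpart
        ("ACT", "T"), ("GCT", "A"),  # the Thr228Ala pair
        ("ATG", "M"), ("TAA", STOP), ("TAG", STOP),
    ])
    def test_standard_code(self, codon, aa):
        assert translate_codon(codon) == aa

    def test_stop_renders_as_x(self):
        assert render_aa(translate_codon("TGA")) == "X"
        assert render_aa("R") == "R"

    @pytest.mark.parametrize("bad", ["CG", "CGAA", "CGN", "cgx"])
    def test_rejects_non_triplets_and_ambiguity(self, bad):
        with pytest.raises(UnsupportedBaseError):
            translate_codon(bad)


class TestLocateRegion:
    def test_leader_position_in_exon1(self, dpa1_model):
        region = dpa1_model.locate_region(79)
        assert region.kind is FeatureKind.EXON and region.index == 1

    def test_first_position_is_first_feature(self, dpa1_model):
        assert dpa1_model.locate_region(1) == dpa1_model.features[0]

    def test_out_of_range(self, dpa1_model):
        with pytest.raises(PositionOutOfRangeError):
            dpa1_model.locate_region(0)
        with pytest.raises(PositionOutOfRangeError):
            dpa1_model.locate_region(len(dpa1_model.sequence) + 1)

    def test_every_position_maps_to_exactly_one_feature(self, synthetic_models):
        for model in synthetic_models[:5]:
            for pos in range(1, len(model.sequence) + 1):
                region = model.locate_region(pos)
                assert region.start <= pos <= region.end
                containing = [f for f in model.features
                              if f.start <= pos <= f.end]
                assert containing == [region]


class TestGenomicToCodon:
    def test_leader_nonsense_site(self, dpa1_model):
        addr = dpa1_model.genomic_to_codon(79)
        assert addr.codon_position == -5 and addr.offset_in_codon == 0
        assert dpa1_model.codon_triplet(-5) == "CGA"

    def test_leader_start_of_numbering(self, dpa1_model):
        # genomic 5 is the middle base of leader codon -30
        addr = dpa1_model.genomic_to_codon(5)
        assert addr.codon_position == -30 and addr.offset_in_codon == 1

    def test_no_leader_first_base_is_codon_one(self):
        model = GeneModel(
            "HLA-X", HLAClass.CLASS_II_ALPHA, "ATG" * 40 + "TAA" + "G" * 17,
            [FeatureInterval(FeatureKind.EXON, 1, 1, 123),
             FeatureInterval(FeatureKind.THREE_PRIME_UTR, None, 124, 140)],
            leader_length=0,
            domain_map={1: ProteinDomain.LEADER_PEPTIDE})
        addr = model.genomic_to_codon(1)
        assert addr.codon_position == 1 and addr.offset_in_codon == 0

    def test_intronic_position_raises(self, dpa1_model):
        with pytest.raises(NotCodingError):
            dpa1_model.genomic_to_codon(100)  # intron 1

    def test_matches_base_walk_oracle(self, synthetic_models):
        for model in synthetic_models:
            oracle = codon_walk_oracle(model)
            for pos, (codon, off) in oracle.items():
                addr = model.genomic_to_codon(pos)
                assert (addr.codon_position, addr.offset_in_codon) == (codon, off)

    def test_never_returns_codon_zero(self, synthetic_models):
        for model in synthetic_models:
            for exon in model.exons:
                for pos in range(exon.start, exon.end + 1):
                    assert model.genomic_to_codon(pos).codon_position != 0

    def test_minus_one_to_plus_one_is_three_bases(self, dpa1_model):
        """Numbering skips zero: codons -1 and +1 are adjacent in the CDS."""
        last_leader = dpa1_model.codon_genomic_positions(-1)
        first_mature = dpa1_model.codon_genomic_positions(1)
        # within exon 1 / exon boundary-free region the CDS is contiguous
        cds = dpa1_model.cds_sequence()
        off_leader = dpa1_model.cds_offset(last_leader[0])
        off_mature = dpa1_model.cds_offset(first_mature[0])
        assert off_mature - off_leader == 3
        assert cds[off_leader:off_leader + 3] == dpa1_model.codon_triplet(-1)

    def test_codon_span_roundtrip(self, synthetic_models):
        for model in synthetic_models[:8]:
            for exon in model.exons:
                for pos in (exon.start, (exon.start + exon.end) // 2, exon.end):
                    addr = model.genomic_to_codon(pos)
                    span = model.codon_genomic_positions(addr.codon_position)
                    assert pos in span


class TestDomainOf:
    @pytest.mark.parametrize("hla_class,exon,domain", [
        (HLAClass.CLASS_I, 7, ProteinDomain.CYTOPLASMIC_TAIL),
        (HLAClass.CLASS_I, 2, ProteinDomain.ANTIGEN_BINDING_ALPHA1),
        (HLAClass.CLASS_I, 4, ProteinDomain.EXTRACELLULAR_ARM_ALPHA3),
        (HLAClass.CLASS_II_ALPHA, 3, ProteinDomain.EXTRACELLULAR_ARM_ALPHA2),
        (HLAClass.CLASS_II_ALPHA, 4, ProteinDomain.TRANSMEMBRANE_CYTOPLASMIC),
        (HLAClass.CLASS_II_BETA, 2, ProteinDomain.ANTIGEN_BINDING_BETA1),
        (HLAClass.CLASS_II_BETA, 4, ProteinDomain.TRANSMEMBRANE),
    ])
    def test_default_maps(self, hla_class, exon, domain, small_config):
        from hlanovel.gene_model import default_domain_map
        n = {HLAClass.CLASS_I: 7, HLAClass.CLASS_II_ALPHA: 4,
             HLAClass.CLASS_II_BETA: 5}[hla_class]
        assert default_domain_map(hla_class, n)[exon] is domain

    def test_unknown_exon_raises(self, dpa1_model):
        with pytest.raises(KeyError):
            dpa1_model.domain_of(99)


class TestModelValidation:
    def test_rejects_gap_in_features(self):
        with pytest.raises(ModelDefinitionError):
            GeneModel("HLA-X", HLAClass.CLASS_II_ALPHA, "A" * 100,
                      [FeatureInterval(FeatureKind.EXON, 1, 1, 50),
                       FeatureInterval(FeatureKind.EXON, 2, 60, 100)],
                      leader_length=0)

    def test_rejects_cds_not_multiple_of_three(self):
        with pytest.raises(ModelDefinitionError):
            GeneModel("HLA-X", HLAClass.CLASS_II_ALPHA, "A" * 100,
                      [FeatureInterval(FeatureKind.EXON, 1, 1, 100)],
                      leader_length=0)

    def test_rejects_non_acgt(self):
        with pytest.raises(UnsupportedBaseError):
            GeneModel("HLA-X", HLAClass.CLASS_II_ALPHA, "AN" * 51,
                      [FeatureInterval(FeatureKind.EXON, 1, 1, 102)],
                      leader_length=0)


class TestModelIO:
    def test_yaml_roundtrip(self, tmp_path, dqa1_model):
        path = tmp_path / "dqa1.yaml"
        write_gene_model(dqa1_model, path)
        loaded = read_gene_model(path)
        assert loaded.sequence == dqa1_model.sequence
        assert loaded.features == dqa1_model.features
        assert loaded.leader_length == dqa1_model.leader_length
        assert loaded.hla_class is dqa1_model.hla_class

    def test_reader_rejects_bad_partition(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "locus: HLA-X\nhla_class: class_II_alpha\nleader_length: 0\n"
            "sequence: " + "A" * 60 + "\n"
            "features:\n"
            "- {kind: exon, index: 1, start: 1, end: 30}\n"
            "- {kind: exon, index: 2, start: 40, end: 60}\n")
        with pytest.raises(ModelDefinitionError):
            read_gene_model(path)
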