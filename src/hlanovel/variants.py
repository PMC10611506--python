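"""Variant detection and characterization.

Given a reference allele sequence and an observed consensus, this module
finds the nucleotide difference(s) and produces the full annotation a
histocompatibility laboratory reports for a novel allele: the gene region
(exon/intron/UTR), the protein domain, the codon change in mature-protein
numbering, the mutation class (missense / silent / nonsense / frameshift /
in-frame indel / intronic / UTR), whether the change sits in a key exon
(the exons encoding the antigen-binding site), a splice-proximity flag for
intronic variants, and the standard written description sentence used when
registering the allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqUtils import seq3

from .errors import AlignmentUnsupportedError, ClassificationError
from .gene_model import (
    STOP,
    FeatureInterval,
    FeatureKind,
    GeneModel,
    HLAClass,
    ProteinDomain,
    translate_codon,
)

#: Bases of an intron considered splice-proximal by default (the canonical
#: GT/AG splice dinucleotides at each end).
DEFAULT_SPLICE_WINDOW = 2

DELETION_MARKER = "-"


class VariantKind(str, Enum):
    SNP = "snp"
    INSERTION = "insertion"
    DELETION = "deletion"


class MutationClass(str, Enum):
    MISSENSE = "missense"
    SILENT = "silent"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    IN_FRAME_INDEL = "in_frame_indel"
    INTRONIC = "intronic"
    UTR = "utr"


@dataclass(frozen=True)
class ObservedVariant:
    """One difference between reference and consensus, on reference coords.

    For a SNP, ``ref_base`` and ``alt_base`` are single bases.  For an
    insertion, ``pos`` is the reference base immediately *before* the
    inserted material and ``alt_base`` holds the inserted string.  For a
    deletion, ``pos`` is the first deleted base, ``ref_base`` holds the
    deleted string and ``alt_base`` is ``"-"``.
    """

    pos: int
    ref_base: str
    alt_base: str
    variant_kind: VariantKind = VariantKind.SNP

    def __post_init__(self) -> None:
        if self.variant_kind is VariantKind.SNP and self.ref_base == self.alt_base:
            raise ValueError("SNP with identical ref and alt")
        if self.variant_kind is VariantKind.INSERTION and not self.alt_base:
            raise ValueError("insertion with empty inserted string")

    @property
    def indel_length(self) -> int:
        if self.variant_kind is VariantKind.INSERTION:
            return len(self.alt_base)
        if self.variant_kind is VariantKind.DELETION:
            return len(self.ref_base)
        return 0


@dataclass(frozen=True)
class CodonChange:
    codon_position: int
    ref_codon: str
    alt_codon: str
    ref_aa: str  # one-letter; "*" for stop
    alt_aa: str


@dataclass(frozen=True)
class MutationCharacterization:
    """Full annotation of one variant against one gene model."""

    variant: ObservedVariant
    region: FeatureInterval
    domain: ProteinDomain | None
    codon_change: CodonChange | None
    mutation_class: MutationClass
    key_exon: bool
    splice_proximal: bool

    @property
    def exon_index(self) -> int | None:
        if self.region.kind is FeatureKind.EXON:
            return self.region.index
        return None


class PatientCategory(str, Enum):
    SOLID_ORGAN_PATIENT = "solid_organ_patient"
    SOLID_ORGAN_DONOR = "solid_organ_donor"
    HSCT_PATIENT = "hsct_patient"
    HSCT_DONOR = "hsct_donor"
    DISEASE_ASSOCIATION = "disease_association"


class Ethnicity(str, Enum):
    AFA = "AFA"  # African American
    API = "API"  # Asian Pacific Islander
    CAU = "CAU"  # Caucasian
    HIS = "HIS"  # Hispanic
    NAM = "NAM"  # Native American
    UNKNOWN = "unknown"


class Specimen(str, Enum):
    PERIPHERAL_BLOOD = "peripheral_blood"
    BUCCAL = "buccal"


@dataclass(frozen=True)
class SampleNovelty:
    """One sample carrying one characterized novelty, plus its metadata."""

    sample_id: str
    allele_name: str
    characterization: MutationCharacterization
    patient_category: PatientCategory
    ethnicity: Ethnicity = Ethnicity.UNKNOWN
    specimen: Specimen = Specimen.PERIPHERAL_BLOOD

    @property
    def locus(self) -> str:
        return self.allele_name.split("*")[0]


# ---------------------------------------------------------------------------
# variant detection
# ---------------------------------------------------------------------------

def detect_variants(reference: str, consensus: str) -> list[ObservedVariant]:
    """Differences between a reference allele and an observed consensus.

    This is a purpose-built comparator for the desk-scale regime in which a
    novel allele differs from its nearest catalogued allele by point
    substitutions, or by a single short insertion/deletion: equal-length
    inputs are compared position-wise; unequal lengths are reconciled by
    longest common prefix/suffix trimming.  Anything messier raises
    :class:`AlignmentUnsupportedError` (supply pre-called variants instead).
    """
    reference, consensus = reference.upper(), consensus.upper()
    if not reference or not consensus:
        raise AlignmentUnsupportedError("empty sequence")
    if len(reference) == len(consensus):
        return [
            ObservedVariant(i + 1, r, c)
            for i, (r, c) in enumerate(zip(reference, consensus))
            if r != c
        ]
    # single indel: prefix + suffix must explain the whole difference
    shorter = min(len(reference), len(consensus))
    p = 0
    while p < shorter and reference[p] == consensus[p]:
        p += 1
    s = 0
    while s < shorter - p and reference[-1 - s] == consensus[-1 - s]:
        s += 1
    if p + s != shorter:
        raise AlignmentUnsupportedError(
            "sequences differ by more than substitutions plus one short "
            "indel; supply pre-called variants")
    if len(consensus) > len(reference):  # insertion
        inserted = consensus[p:len(consensus) - s]
        if p == 0:
            raise AlignmentUnsupportedError(
                "insertion before the first reference base is unsupported")
        return [ObservedVariant(p, reference[p - 1], inserted,
                                VariantKind.INSERTION)]
    deleted = reference[p:len(reference) - s]
    return [ObservedVariant(p + 1, deleted, DELETION_MARKER,
                            VariantKind.DELETION)]


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

def is_key_exon(hla_class: HLAClass, exon_index: int) -> bool:
    """Key exons encode the antigen-binding site: exons 2 and 3 for class I,
    exon 2 for class II."""
    if hla_class is HLAClass.CLASS_I:
        return exon_index in (2, 3)
    return exon_index == 2


def classify_substitution(ref_aa: str, alt_aa: str) -> MutationClass:
    """Mutation class of a coding substitution from its amino-acid effect."""
    if ref_aa == STOP:
        raise ClassificationError(
            "reference codon is the terminator; stop-loss substitutions have "
            "no class in this scheme")
    if ref_aa == alt_aa:
        return MutationClass.SILENT
    if alt_aa == STOP:
        return MutationClass.NONSENSE
    return MutationClass.MISSENSE


def characterize(
    model: GeneModel,
    variant: ObservedVariant,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> MutationCharacterization:
    """Annotate one variant against a gene model.

    ``splice_window`` is the number of intron bases at each intron end
    regarded as splice-proximal (default 2, the canonical GT/AG
    dinucleotides); the resulting flag is advisory.
    """
    region = model.locate_region(variant.pos)
    in_exon = region.kind is FeatureKind.EXON
    domain = model.domain_of(region.index) if in_exon else None
    codon_change = None
    splice_proximal = False

    if region.kind is FeatureKind.INTRON:
        mutation_class = MutationClass.INTRONIC
        splice_proximal = (
            variant.pos - region.start < splice_window
            or region.end - variant.pos < splice_window
        )
    elif not in_exon:
        mutation_class = MutationClass.UTR
    elif variant.variant_kind is not VariantKind.SNP:
        mutation_class = (
            MutationClass.IN_FRAME_INDEL
            if variant.indel_length % 3 == 0
            else MutationClass.FRAMESHIFT
        )
    else:
        addr = model.genomic_to_codon(variant.pos)
        ref_codon = model.codon_triplet(addr.codon_position)
        if ref_codon[addr.offset_in_codon] != variant.ref_base:
            raise ClassificationError(
                f"reference base mismatch at position {variant.pos}: model "
                f"has {ref_codon[addr.offset_in_codon]}, variant says "
                f"{variant.ref_base}")
        alt_codon = (ref_codon[: addr.offset_in_codon]
                     + variant.alt_base
                     + ref_codon[addr.offset_in_codon + 1:])
        ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
        mutation_class = classify_substitution(ref_aa, alt_aa)
        codon_change = CodonChange(addr.codon_position, ref_codon, alt_codon,
                                   ref_aa, alt_aa)

    key = in_exon and is_key_exon(model.hla_class, region.index)
    return MutationCharacterization(
        variant=variant,
        region=region,
        domain=domain,
        codon_change=codon_change,
        mutation_class=mutation_class,
        key_exon=key,
        splice_proximal=splice_proximal,
    )


# ---------------------------------------------------------------------------
# written description
# ---------------------------------------------------------------------------

def _aa3(aa: str) -> str:
    return "a stop codon" if aa == STOP else seq3(aa)


def describe_mutation(
    sample_id: str,
    base_allele: str,
    char: MutationCharacterization,
    n_changes: int = 1,
) -> str:
    """The standard one-sentence mutation description used when registering
    a novel allele, e.g.::

        VGH002 has 1 nt change from B*48:01:01:01 at nt 1701 where A > G
        (codon 228 ACT > GCT), resulting in a coding change 228 Thr is
        changed to Ala.

    Positions are printed without a thousands separator.  Silent variants
    end "with no coding change"; nonsense variants end "... is changed to a
    stop codon"; intronic/UTR variants name the region instead of a codon.
    """
    v = char.variant
    head = (f"{sample_id} has {n_changes} nt change from {base_allele} "
            f"at nt {v.pos} where {v.ref_base} > {v.alt_base}")
    cc = char.codon_change
    if cc is not None:
        codon_part = (f" (codon {cc.codon_position} "
                      f"{cc.ref_codon} > {cc.alt_codon})")
        if char.mutation_class is MutationClass.SILENT:
            return head + codon_part + ", with no coding change."
        tail = (f", resulting in a coding change {cc.codon_position} "
                f"{_aa3(cc.ref_aa)} is changed to {_aa3(cc.alt_aa)}.")
        return head + codon_part + tail
    region = char.region
    if region.kind is FeatureKind.INTRON:
        where = f"intron {region.index}"
    elif region.kind is FeatureKind.EXON:
        where = f"exon {region.index}"
    else:
        where = "the 5'UTR" if region.kind is FeatureKind.FIVE_PRIME_UTR \
            else "the 3'UTR"
    return head + f" in {where}."


# ---------------------------------------------------------------------------
# QC flags
# ---------------------------------------------------------------------------

MULTIPLE_EXONIC_NOVELTIES = "multiple_exonic_novelties"
GERMLINE_CONFIRMATION_REQUIRED = "germline_confirmation_required"


def flag_suspect(
    characterizations: Sequence[MutationCharacterization],
    specimen: Specimen,
    has_heme_malignancy: bool,
) -> list[str]:
    """QC flags for one sample's set of novelties.

    More than one exonic novelty in a single sample is an indicator of
    inaccurate novelty identification; and a peripheral-blood specimen from
    a patient with a hematological malignancy can carry somatic mutations
    from the malignant cell line, so germline (e.g. buccal) confirmation is
    required before reporting.
    """
    flags = []
    n_exonic = sum(
        1 for c in characterizations if c.region.kind is FeatureKind.EXON)
    if n_exonic > 1:
        flags.append(MULTIPLE_EXONIC_NOVELTIES)
    if has_heme_malignancy and specimen is Specimen.PERIPHERAL_BLOOD:
        flags.append(GERMLINE_CONFIRMATION_REQUIRED)
    return flags


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_variant_table(path) -> pd.DataFrame:
    """Read a pre-called variant table (TSV: sample_id, allele, pos, ref,
    alt, kind)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "allele": str})
    required = {"sample_id", "allele", "pos", "ref", "alt", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df


def characterizations_to_frame(samples: Iterable[SampleNovelty]) -> pd.DataFrame:
    """Cohort table mirroring the standard novel-allele report columns."""
    from .gene_model import DOMAIN_DISPLAY  # cycle-free local import

    rows = []
    for s in samples:
        c = s.characterization
        cc = c.codon_change
        rows.append({
            "sample_id": s.sample_id,
            "allele": s.allele_name,
            "mutation_type": c.mutation_class.value,
            "region": (f"{c.region.kind.value} {c.region.index}"
                       if c.region.index else c.region.kind.value),
            "location_on_protein": DOMAIN_DISPLAY[c.domain] if c.domain else "",
            "nucleotide_change": f"{c.variant.ref_base} > {c.variant.alt_base}",
            "genomic_position": c.variant.pos,
            "codon_position": cc.codon_position if cc else "",
            "codon_change": f"{cc.ref_codon} > {cc.alt_codon}" if cc else "",
            "key_exon": c.key_exon,
            "splice_proximal": c.splice_proximal,
            "patient_category": s.patient_category.value,
            "ethnicity": s.ethnicity.value,
        })
    return pd.DataFrame(rows)
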