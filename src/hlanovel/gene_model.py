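"""HLA-like gene structure and coordinate arithmetic.

An HLA gene model is the annotated genomic sequence of one locus: UTR, exon
and intron intervals; the length of the leader (signal) peptide; and a map
from exon index to the protein domain it encodes.  All downstream annotation
rests on two conversions implemented here:

* genomic position -> feature interval (which exon/intron/UTR contains it);
* genomic position -> codon address in mature-protein numbering, in which
  leader-peptide codons are numbered -L..-1, mature codons 1..M, and there is
  no codon 0 (-1 immediately precedes +1).  This is the numbering used for
  HLA protein positions in clinical reports and the IPD-IMGT/HLA database.

Coordinates are 1-based and inclusive on both ends throughout.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio.Data.CodonTable import standard_dna_table

from .errors import (
    ModelDefinitionError,
    NotCodingError,
    PositionOutOfRangeError,
    UnsupportedBaseError,
)

STOP = "*"  #: internal sentinel for a stop codon; rendered "X" in alignments

_VALID_BASES = frozenset("ACGT")


class HLAClass(str, Enum):
    """The three structural classes of classical HLA genes."""

    CLASS_I = "class_I"
    CLASS_II_ALPHA = "class_II_alpha"
    CLASS_II_BETA = "class_II_beta"


class FeatureKind(str, Enum):
    FIVE_PRIME_UTR = "five_prime_UTR"
    EXON = "exon"
    INTRON = "intron"
    THREE_PRIME_UTR = "three_prime_UTR"


class ProteinDomain(str, Enum):
    """Protein regions encoded by individual exons, as named on clinical
    reports (antigen-binding domains, extracellular arms, membrane regions)."""

    LEADER_PEPTIDE = "leader_peptide"
    ANTIGEN_BINDING_ALPHA1 = "antigen_binding_alpha1"
    ANTIGEN_BINDING_ALPHA2 = "antigen_binding_alpha2"
    ANTIGEN_BINDING_BETA1 = "antigen_binding_beta1"
    EXTRACELLULAR_ARM_ALPHA2 = "extracellular_arm_alpha2"
    EXTRACELLULAR_ARM_ALPHA3 = "extracellular_arm_alpha3"
    EXTRACELLULAR_ARM_BETA2 = "extracellular_arm_beta2"
    TRANSMEMBRANE = "transmembrane"
    CYTOPLASMIC_TAIL = "cytoplasmic_tail"
    TRANSMEMBRANE_CYTOPLASMIC = "transmembrane_cytoplasmic"


#: Human-readable domain labels as they appear on typing reports.
DOMAIN_DISPLAY = {
    ProteinDomain.LEADER_PEPTIDE: "Leader peptide",
    ProteinDomain.ANTIGEN_BINDING_ALPHA1: "Antigen-binding site, α1",
    ProteinDomain.ANTIGEN_BINDING_ALPHA2: "Antigen-binding site, α2",
    ProteinDomain.ANTIGEN_BINDING_BETA1: "Antigen-binding site, β1",
    ProteinDomain.EXTRACELLULAR_ARM_ALPHA2: "α2 extracellular arm",
    ProteinDomain.EXTRACELLULAR_ARM_ALPHA3: "α3 extracellular arm",
    ProteinDomain.EXTRACELLULAR_ARM_BETA2: "β2 extracellular arm",
    ProteinDomain.TRANSMEMBRANE: "Transmembrane",
    ProteinDomain.CYTOPLASMIC_TAIL: "Cytoplasmic tail",
    ProteinDomain.TRANSMEMBRANE_CYTOPLASMIC: "Transmembrane/cytoplasmic tail",
}

#: Locus name -> structural class for the 11 classical genes.
LOCUS_CLASS: Mapping[str, HLAClass] = {
    "HLA-A": HLAClass.CLASS_I,
    "HLA-B": HLAClass.CLASS_I,
    "HLA-C": HLAClass.CLASS_I,
    "HLA-DPA1": HLAClass.CLASS_II_ALPHA,
    "HLA-DQA1": HLAClass.CLASS_II_ALPHA,
    "HLA-DPB1": HLAClass.CLASS_II_BETA,
    "HLA-DQB1": HLAClass.CLASS_II_BETA,
    "HLA-DRB1": HLAClass.CLASS_II_BETA,
    "HLA-DRB3": HLAClass.CLASS_II_BETA,
    "HLA-DRB4": HLAClass.CLASS_II_BETA,
    "HLA-DRB5": HLAClass.CLASS_II_BETA,
}


def locus_to_class(locus: str) -> HLAClass:
    """Structural class for a locus name ('HLA-DPA1' or bare 'DPA1')."""
    key = locus if locus.startswith("HLA-") else f"HLA-{locus}"
    try:
        return LOCUS_CLASS[key]
    except KeyError:
        raise KeyError(f"unknown HLA locus: {locus!r}") from None


def default_domain_map(hla_class: HLAClass, n_exons: int) -> dict[int, ProteinDomain]:
    """Canonical exon -> protein-domain map for a class.

    Class I genes carry the leader in exon 1, the two antigen-binding domains
    in exons 2-3, the alpha-3 arm in exon 4, the transmembrane segment in
    exon 5 and the cytoplasmic tail in the remaining exons.  Class II alpha
    genes compress the membrane and cytoplasmic regions into exon 4; class II
    beta genes keep them separate (exons 4 and 5).
    """
    D = ProteinDomain
    if hla_class is HLAClass.CLASS_I:
        if n_exons < 5:
            raise ModelDefinitionError("class I models need at least 5 exons")
        m = {1: D.LEADER_PEPTIDE, 2: D.ANTIGEN_BINDING_ALPHA1,
             3: D.ANTIGEN_BINDING_ALPHA2, 4: D.EXTRACELLULAR_ARM_ALPHA3,
             5: D.TRANSMEMBRANE}
        for i in range(6, n_exons + 1):
            m[i] = D.CYTOPLASMIC_TAIL
        return m
    if hla_class is HLAClass.CLASS_II_ALPHA:
        if n_exons < 4:
            raise ModelDefinitionError("class II alpha models need at least 4 exons")
        m = {1: D.LEADER_PEPTIDE, 2: D.ANTIGEN_BINDING_ALPHA1,
             3: D.EXTRACELLULAR_ARM_ALPHA2}
        for i in range(4, n_exons + 1):
            m[i] = D.TRANSMEMBRANE_CYTOPLASMIC
        return m
    if n_exons < 5:
        raise ModelDefinitionError("class II beta models need at least 5 exons")
    m = {1: D.LEADER_PEPTIDE, 2: D.ANTIGEN_BINDING_BETA1,
         3: D.EXTRACELLULAR_ARM_BETA2, 4: D.TRANSMEMBRANE}
    for i in range(5, n_exons + 1):
        m[i] = D.CYTOPLASMIC_TAIL
    return m


@dataclass(frozen=True)
class FeatureInterval:
    """One annotated interval of the gene (closed, 1-based)."""

    kind: FeatureKind
    index: int | None  # exon/intron ordinal; None for UTRs
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelDefinitionError(
                f"feature start {self.start} > end {self.end}")
        if self.kind in (FeatureKind.EXON, FeatureKind.INTRON):
            if self.index is None or self.index < 1:
                raise ModelDefinitionError(
                    f"{self.kind.value} requires a positive ordinal index")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CodonAddress:
    """A CDS position expressed as (codon, offset) in mature-protein numbering.

    ``codon_position`` is negative within the leader peptide (-L..-1) and
    positive in the mature protein (1..M); 0 never occurs.  ``offset_in_codon``
    is 0, 1 or 2 for the first, second and third base of the codon.
    """

    codon_position: int
    offset_in_codon: int

    def __post_init__(self) -> None:
        if self.codon_position == 0:
            raise ValueError("codon 0 does not exist in mature-protein numbering")
        if self.offset_in_codon not in (0, 1, 2):
            raise ValueError("offset_in_codon must be 0, 1 or 2")


def raw_to_mature(raw: int, leader_length: int) -> int:
    """1-based raw CDS codon index -> signed mature-protein codon number."""
    return raw - leader_length if raw > leader_length else raw - leader_length - 1


def mature_to_raw(codon_position: int, leader_length: int) -> int:
    """Inverse of :func:`raw_to_mature`."""
    if codon_position == 0:
        raise ValueError("codon 0 does not exist")
    if codon_position > 0:
        return codon_position + leader_length
    return codon_position + leader_length + 1


def translate_codon(triplet: str) -> str:
    """Translate one codon under the standard genetic code.

    Returns a one-letter amino acid, or the stop sentinel ``"*"`` (rendered
    as ``"X"`` in alignment strings, the convention on HLA sequence reports).
    """
    triplet = triplet.upper()
    if len(triplet) != 3 or not set(triplet) <= _VALID_BASES:
        raise UnsupportedBaseError(
            f"codon must be 3 bases over A/C/G/T, got {triplet!r}")
    if triplet in standard_dna_table.stop_codons:
        return STOP
    return standard_dna_table.forward_table[triplet]


def render_aa(aa: str) -> str:
    """One-letter rendering for alignments: stop sentinel becomes 'X'."""
    return "X" if aa == STOP else aa


@dataclass
class GeneModel:
    """An annotated HLA-like gene.

    Parameters
    ----------
    locus_name
        e.g. ``"HLA-DPA1"``.
    hla_class
        Structural class; decides the default exon -> domain map.
    sequence
        Genomic sense-strand sequence over A/C/G/T.
    features
        UTR/exon/intron intervals that exactly partition the sequence.
    leader_length
        Number of leader-peptide codons (codons -leader_length..-1).
    domain_map
        exon index -> :class:`ProteinDomain`; defaults to the canonical map
        for the class.
    full_cds
        True when the concatenated exons are the complete coding sequence
        (length divisible by 3, numbering anchored at the initiator codon).
    first_codon_raw
        For partial-coverage models (e.g. DRB1 sequenced from partial intron
        1), the raw codon index of the first fully covered codon; codon
        numbering is anchored there.
    """

    locus_name: str
    hla_class: HLAClass
    sequence: str
    features: list[FeatureInterval]
    leader_length: int
    domain_map: dict[int, ProteinDomain] = field(default_factory=dict)
    full_cds: bool = True
    first_codon_raw: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise UnsupportedBaseError(f"sequence contains non-ACGT bases: {bad}")
        self._check_partition()
        if self.leader_length < 0:
            raise ModelDefinitionError("leader_length must be >= 0")
        if self.full_cds:
            if self.cds_length % 3 != 0:
                raise ModelDefinitionError(
                    f"full-CDS model has CDS length {self.cds_length} "
                    "not divisible by 3")
            if self.leader_length * 3 > self.cds_length:
                raise ModelDefinitionError("leader longer than the CDS")
        if not self.domain_map:
            self.domain_map = default_domain_map(self.hla_class, self.n_exons)
        missing = [e.index for e in self.exons if e.index not in self.domain_map]
        if missing:
            raise ModelDefinitionError(f"exons without a domain label: {missing}")

    # -- structure ---------------------------------------------------------

    def _check_partition(self) -> None:
        if not self.features:
            raise ModelDefinitionError("a model needs at least one feature")
        expected = 1
        for f in self.features:
            if f.start != expected:
                raise ModelDefinitionError(
                    f"features do not partition the sequence: expected a "
                    f"feature starting at {expected}, got {f.start}")
            expected = f.end + 1
        if expected - 1 != len(self.sequence):
            raise ModelDefinitionError(
                f"features end at {expected - 1} but the sequence has "
                f"{len(self.sequence)} bases")
        for kind in (FeatureKind.EXON, FeatureKind.INTRON):
            idx = [f.index for f in self.features if f.kind is kind]
            if idx != sorted(idx) or len(idx) != len(set(idx)):
                raise ModelDefinitionError(
                    f"{kind.value} indices must strictly increase")

    @property
    def exons(self) -> list[FeatureInterval]:
        return [f for f in self.features if f.kind is FeatureKind.EXON]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e.length for e in self.exons)

    @cached_property
    def _exon_cum(self) -> list[int]:
        """Cumulative exonic base counts before each exon (CDS offsets)."""
        cum, total = [], 0
        for e in self.exons:
            cum.append(total)
            total += e.length
        return cum

    # -- operations --------------------------------------------------------

    def locate_region(self, pos: int) -> FeatureInterval:
        """Feature interval containing genomic position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise PositionOutOfRangeError(
                f"position {pos} outside 1..{len(self.sequence)}")
        starts = [f.start for f in self.features]
        return self.features[bisect.bisect_right(starts, pos) - 1]

    def cds_offset(self, pos: int) -> int:
        """Count of exonic bases strictly before ``pos`` within the CDS."""
        region = self.locate_region(pos)
        if region.kind is not FeatureKind.EXON:
            raise NotCodingError(
                f"position {pos} is in a {region.kind.value}, not an exon")
        exon_rank = self.exons.index(region)
        return self._exon_cum[exon_rank] + (pos - region.start)

    def genomic_to_codon(self, pos: int) -> CodonAddress:
        """Codon address (mature-protein numbering) of an exonic position."""
        offset = self.cds_offset(pos)
        raw = offset // 3 + self.first_codon_raw
        return CodonAddress(raw_to_mature(raw, self.leader_length), offset % 3)

    def codon_genomic_positions(self, codon_position: int) -> tuple[int, int, int]:
        """Genomic positions of the three bases of a codon (may span introns)."""
        raw = mature_to_raw(codon_position, self.leader_length)
        first_offset = (raw - self.first_codon_raw) * 3
        if first_offset < 0 or first_offset + 2 >= self.cds_length:
            raise NotCodingError(f"codon {codon_position} outside the covered CDS")
        out = []
        for off in (first_offset, first_offset + 1, first_offset + 2):
            rank = bisect.bisect_right(self._exon_cum, off) - 1
            exon = self.exons[rank]
            out.append(exon.start + (off - self._exon_cum[rank]))
        return tuple(out)  # type: ignore[return-value]

    def codon_triplet(self, codon_position: int) -> str:
        """Reference codon triplet at a mature-protein codon position."""
        return "".join(self.sequence[p - 1]
                       for p in self.codon_genomic_positions(codon_position))

    def domain_of(self, exon_index: int) -> ProteinDomain:
        """Protein domain encoded by an exon."""
        try:
            return self.domain_map[exon_index]
        except KeyError:
            raise KeyError(
                f"{self.locus_name} model has no exon {exon_index}") from None

    def cds_sequence(self) -> str:
        return "".join(self.sequence[e.start - 1:e.end] for e in self.exons)


# -- gene-model document I/O ------------------------------------------------

def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Serialize a model as a YAML document (sequence inline)."""
    doc = {
        "locus": model.locus_name,
        "hla_class": model.hla_class.value,
        "leader_length": model.leader_length,
        "full_cds": model.full_cds,
        "first_codon_raw": model.first_codon_raw,
        "sequence": model.sequence,
        "features": [
            {"kind": f.kind.value, "index": f.index, "start": f.start, "end": f.end}
            for f in model.features
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_gene_model(path: str | Path) -> GeneModel:
    """Parse a gene-model document; rejects non-partitioning feature sets."""
    doc = yaml.safe_load(Path(path).read_text())
    features = [
        FeatureInterval(FeatureKind(f["kind"]), f.get("index"),
                        int(f["start"]), int(f["end"]))
        for f in doc["features"]
    ]
    return GeneModel(
        locus_name=doc["locus"],
        hla_class=HLAClass(doc["hla_class"]),
        sequence=doc["sequence"],
        features=features,
        leader_length=int(doc["leader_length"]),
        full_cds=bool(doc.get("full_cds", True)),
        first_codon_raw=int(doc.get("first_codon_raw", 1)),
    )


def build_model_from_segments(
    locus_name: str,
    hla_class: HLAClass,
    leader_length: int,
    segments: Iterable[tuple[FeatureKind, str]],
    **kwargs,
) -> GeneModel:
    """Assemble a model from ordered (kind, subsequence) segments.

    Exon/intron indices are assigned in order; convenience used by the
    synthetic generator and the bundled worked-example models.
    """
    features: list[FeatureInterval] = []
    parts: list[str] = []
    pos = 1
    counters = {FeatureKind.EXON: 0, FeatureKind.INTRON: 0}
    for kind, seq in segments:
        idx = None
        if kind in counters:
            counters[kind] += 1
            idx = counters[kind]
        features.append(FeatureInterval(kind, idx, pos, pos + len(seq) - 1))
        parts.append(seq)
        pos += len(seq)
    return GeneModel(locus_name, hla_class, "".join(parts), features,
                     leader_length, **kwargs)
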