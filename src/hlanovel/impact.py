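"""Physicochemical impact scoring of missense novelties.

Each missense novelty receives one "+" per criterion met, from "+" to
"++++":

1. the mutation changes an amino acid (always true for missense);
2. the replacement residue belongs to a different physicochemical category
   (nonpolar aliphatic / nonpolar aromatic / polar uncharged / basic /
   acidic) than the original;
3. the altered residue lies in the antigen-binding site (a key exon:
   exons 2-3 for class I, exon 2 for class II);
4. the mutation affects an eplet — it either sits at a position/residue pair
   that constitutes a known eplet expressed by the original allele, or the
   new residue introduces one.

Category comparison is at the five-subcategory level: an aliphatic-to-
aromatic swap counts as a property change even though both are nonpolar.
Silent and nonsense mutations are reported but not "+"-scored.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import seq1

from .errors import NotScorableError
from .gene_model import STOP
from .variants import MutationCharacterization, MutationClass


class PropertyCategory(str, Enum):
    NONPOLAR_ALIPHATIC = "nonpolar_aliphatic"
    NONPOLAR_AROMATIC = "nonpolar_aromatic"
    POLAR_UNCHARGED = "polar_uncharged"
    BASIC = "basic"
    ACIDIC = "acidic"


#: Display names used in reports.
CATEGORY_DISPLAY = {
    PropertyCategory.NONPOLAR_ALIPHATIC: "Nonpolar aliphatic",
    PropertyCategory.NONPOLAR_AROMATIC: "Nonpolar aromatic",
    PropertyCategory.POLAR_UNCHARGED: "Polar uncharged",
    PropertyCategory.BASIC: "Basic",
    PropertyCategory.ACIDIC: "Acidic",
}

_STANDARD_AAS = set("ACDEFGHIKLMNPQRSTVWY")


class PropertyTable:
    """Mapping of the 20 standard amino acids to physicochemical categories."""

    def __init__(self, mapping: Mapping[str, PropertyCategory]):
        mapping = {k.upper(): PropertyCategory(v) for k, v in mapping.items()}
        missing = _STANDARD_AAS - set(mapping)
        extra = set(mapping) - _STANDARD_AAS
        if missing or extra:
            raise ValueError(
                f"property table must cover exactly the 20 standard amino "
                f"acids (missing {sorted(missing)}, extra {sorted(extra)})")
        self._mapping = mapping

    def category(self, aa: str) -> PropertyCategory:
        """Category of a residue given as one- or three-letter code."""
        aa = aa.strip()
        if len(aa) == 3:
            aa = seq1(aa.capitalize())
        aa = aa.upper()
        if aa not in _STANDARD_AAS:
            raise NotScorableError(f"not a standard amino acid: {aa!r}")
        return self._mapping[aa]

    @classmethod
    def from_file(cls, path) -> "PropertyTable":
        """Load a two-column (residue, category) TSV."""
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls({seq1(r.residue): PropertyCategory(r.category)
                    for r in df.itertuples()})


@dataclass(frozen=True)
class Eplet:
    """A small patch of residues (within ~3.0-3.5 Å) forming an
    antibody-accessible HLA epitope; constituents are (mature-protein
    position, one-letter residue) pairs."""

    name: str
    locus_group: str  # e.g. "ABC", "DRB", "DQ", "DP"
    constituents: frozenset[tuple[int, str]]

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError(f"eplet {self.name} has no constituents")


@dataclass(frozen=True)
class ImpactScore:
    aa_change: bool
    property_change: bool
    binding_site: bool
    eplet_effect: bool

    @property
    def total(self) -> int:
        return sum((self.aa_change, self.property_change,
                    self.binding_site, self.eplet_effect))

    @property
    def rendered(self) -> str:
        return "+" * self.total


def locus_group_of(locus: str) -> str:
    """Eplet-registry locus group of an HLA locus: the class I loci share
    one group (ABC); DRB, DQ and DP loci each form their own."""
    locus = locus.removeprefix("HLA-")
    if locus in ("A", "B", "C"):
        return "ABC"
    if locus.startswith("DRB"):
        return "DRB"
    if locus.startswith("DQ"):
        return "DQ"
    if locus.startswith("DP"):
        return "DP"
    raise KeyError(f"unknown HLA locus: {locus!r}")


def property_changed(table: PropertyTable, ref_aa: str, alt_aa: str) -> bool:
    """True iff the two residues fall in different five-way categories."""
    return table.category(ref_aa) != table.category(alt_aa)


def affects_eplet(
    registry: Sequence[Eplet],
    position: int,
    ref_aa: str,
    alt_aa: str,
    locus_group: str | None = None,
) -> bool:
    """True iff the substitution disrupts an eplet expressed by the original
    allele or introduces a new one.

    When ``locus_group`` is given, only eplets of that group are consulted;
    otherwise the whole registry is.
    """
    ref_aa, alt_aa = ref_aa.upper(), alt_aa.upper()
    if len(ref_aa) == 3:
        ref_aa = seq1(ref_aa.capitalize())
    if len(alt_aa) == 3:
        alt_aa = seq1(alt_aa.capitalize())
    for eplet in registry:
        if locus_group is not None and eplet.locus_group != locus_group:
            continue
        if (position, ref_aa) in eplet.constituents:
            return True
        if (position, alt_aa) in eplet.constituents:
            return True
    return False


def score_impact(
    char: MutationCharacterization,
    table: PropertyTable,
    registry: Sequence[Eplet],
    locus_group: str | None = None,
) -> ImpactScore:
    """Score a missense characterization on the four criteria."""
    if char.mutation_class is not MutationClass.MISSENSE:
        raise NotScorableError(
            f"only missense mutations are scored, got "
            f"{char.mutation_class.value}")
    cc = char.codon_change
    if cc is None or STOP in (cc.ref_aa, cc.alt_aa):
        raise NotScorableError("missense characterization lacks a valid "
                               "amino-acid change")
    return ImpactScore(
        aa_change=True,
        property_change=property_changed(table, cc.ref_aa, cc.alt_aa),
        binding_site=char.key_exon,
        eplet_effect=affects_eplet(registry, cc.codon_position,
                                   cc.ref_aa, cc.alt_aa, locus_group),
    )


# ---------------------------------------------------------------------------
# bundled defaults
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("hlanovel") / "data" / name)


def default_property_table() -> PropertyTable:
    """The packaged five-category classification (Lehninger-style: Gly, Ala,
    Val, Leu, Ile, Met, Pro aliphatic; Phe, Trp, Tyr aromatic; Ser, Thr,
    Cys, Asn, Gln polar uncharged; Lys, Arg, His basic; Asp, Glu acidic)."""
    return PropertyTable.from_file(_data_path("aa_properties.tsv"))


def read_eplet_registry(path) -> list[Eplet]:
    """Read an eplet registry file.

    TSV columns: name, locus_group, constituents — the latter a
    comma-separated list of position:residue tokens, e.g. ``116:F,114:H``.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"name": str, "locus_group": str})
    registry = []
    for row in df.itertuples():
        pairs = []
        for token in str(row.constituents).split(","):
            pos, aa = token.strip().split(":")
            pairs.append((int(pos), aa.upper()))
        registry.append(Eplet(row.name, row.locus_group, frozenset(pairs)))
    return registry


def demo_eplet_registry() -> list[Eplet]:
    """The packaged synthetic eplet registry (a small stand-in set of
    position/residue definitions plus decoys; production use should load a
    current registry with :func:`read_eplet_registry`)."""
    return read_eplet_registry(_data_path("eplet_registry_synthetic.tsv"))
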