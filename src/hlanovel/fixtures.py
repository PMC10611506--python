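"""Packaged reference data and worked-example gene models.

The package ships three small tables describing a published-style clinical
cohort of 29 unique novel HLA alleles found in 41 samples over 18 months of
routine NGS typing:

* ``novel_alleles.tsv`` — one row per unique novel allele: mutation type,
  exon, protein location, nucleotide change and genomic position;
* ``missense_changes.tsv`` — scoring inputs for the 16 missense novelties:
  codon position, original/novel residues and categories, and the recorded
  "+" impact score;
* ``cohort_samples_synthetic.tsv`` — a SYNTHETIC sample-level table: the
  per-sample allele, patient-category and ethnicity assignments are
  reconstructed to match the cohort's marginal counts only (the real
  sample list is not redistributed here).

It also builds self-consistent gene models for the cohort's worked
examples.  Genomic coordinates in these models are chosen so that every
recorded (genomic position, codon position, codon) anchor of the respective
locus verifies; they are NOT real IMGT coordinates.
"""

from __future__ import annotations

import hashlib
import random
from functools import lru_cache
from pathlib import Path

import importlib.resources
import pandas as pd

from .errors import ModelDefinitionError
from .gene_model import (
    STOP,
    DOMAIN_DISPLAY,
    FeatureInterval,
    FeatureKind,
    GeneModel,
    HLAClass,
    ProteinDomain,
    build_model_from_segments,
    locus_to_class,
    translate_codon,
)
from .synthetic import random_cds, _random_intron
from .variants import (
    CodonChange,
    Ethnicity,
    MutationCharacterization,
    MutationClass,
    ObservedVariant,
    PatientCategory,
    SampleNovelty,
    Specimen,
    classify_substitution,
    is_key_exon,
)

_CHECKSUMS = {
    "aa_properties.tsv":
        "e8bf7cb41e5d58ac741267afeaa8ba2adc32a083ddfc79dc2c577269bda40639",
    "eplet_registry_synthetic.tsv":
        "482561b730d898f95b36c5913d230afb6a895b0fdcbef883d336e32b472dd417",
    "novel_alleles.tsv":
        "4d73023e9086c80d86179ce929386aac750d8ec9d67d3c50bd4be229b07338af",
    "missense_changes.tsv":
        "ea868a594b45e5fc68c26dc3367e6fedec4d2693ee0d4ab40c3550acd0e47d07",
    "cohort_samples_synthetic.tsv":
        "b7873b61ff5d5a9f03bf3063568fb188c5d7f1d95e14d52bcbd4f146b189d0e6",
}

#: Observation window of the bundled cohort, in months.
COHORT_MONTHS = 18.0


def data_path(name: str) -> Path:
    """Path of a packaged data file, after verifying its pinned checksum."""
    path = Path(importlib.resources.files("hlanovel") / "data" / name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"packaged data file {name} is corrupted "
            f"(sha256 {digest}, expected {_CHECKSUMS[name]})")
    return path


# ---------------------------------------------------------------------------
# table loaders
# ---------------------------------------------------------------------------

def load_novel_allele_table() -> pd.DataFrame:
    """The 29 unique novel alleles (allele-level table)."""
    df = pd.read_csv(data_path("novel_alleles.tsv"), sep="\t")
    if len(df) != 29:
        raise RuntimeError(f"expected 29 novel-allele rows, got {len(df)}")
    return df


def load_missense_table() -> pd.DataFrame:
    """Scoring inputs and recorded scores for the 16 missense novelties."""
    df = pd.read_csv(data_path("missense_changes.tsv"), sep="\t")
    if len(df) != 16:
        raise RuntimeError(f"expected 16 missense rows, got {len(df)}")
    return df


def load_sample_table() -> pd.DataFrame:
    """The synthetic 41-row sample-level table (see module docstring)."""
    df = pd.read_csv(data_path("cohort_samples_synthetic.tsv"), sep="\t")
    if len(df) != 41:
        raise RuntimeError(f"expected 41 sample rows, got {len(df)}")
    return df


# ---------------------------------------------------------------------------
# display-label mapping and codon synthesis
# ---------------------------------------------------------------------------

def _norm_location(label: str) -> str:
    return (label.replace("Antigen binding site", "Antigen-binding site")
                 .replace("Extracellular arm, α2", "α2 extracellular arm")
                 .replace("Extracellular arm, α3", "α3 extracellular arm")
                 .replace("Extracellular arm, β2", "β2 extracellular arm")
                 .strip())


_LOCATION_TO_DOMAIN = {_norm_location(v): k for k, v in DOMAIN_DISPLAY.items()}


def location_to_domain(label: str) -> ProteinDomain:
    """Map a display 'Location on protein' label to the domain enum."""
    return _LOCATION_TO_DOMAIN[_norm_location(label)]


_AA1 = {"Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
        "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
        "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
        "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
        "Stop": STOP}


def synthesize_codon_pair(
    ref_base: str,
    alt_base: str,
    ref_aa: str | None = None,
    alt_aa: str | None = None,
) -> tuple[str, str, int]:
    """Find a codon pair consistent with a recorded substitution.

    Returns ``(ref_codon, alt_codon, offset_in_codon)`` such that the codons
    differ only at ``offset`` where ``ref_base`` becomes ``alt_base``, and
    translate to the requested amino acids (one-letter; ``None`` for the
    ref means any residue, ``None`` for the alt means synonymous).  The
    first match in lexicographic (codon, offset) order is returned, making
    the synthesis deterministic.
    """
    for codon in sorted(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"):
        r = translate_codon(codon)
        if r == STOP or (ref_aa is not None and r != ref_aa):
            continue
        for off in range(3):
            if codon[off] != ref_base:
                continue
            alt_codon = codon[:off] + alt_base + codon[off + 1:]
            a = translate_codon(alt_codon)
            if alt_aa is None:
                if a == r:
                    return codon, alt_codon, off
            elif a == alt_aa:
                return codon, alt_codon, off
    raise ValueError(
        f"no codon pair realizes {ref_base}>{alt_base} "
        f"({ref_aa or 'any'} -> {alt_aa or 'synonymous'})")


@lru_cache(maxsize=1)
def _missense_aa_map() -> dict[str, tuple[str, str, int]]:
    df = load_missense_table()
    return {r.allele: (_AA1[r.ref_aa], _AA1[r.alt_aa], int(r.codon_position))
            for r in df.itertuples()}


def characterization_from_fixture_row(row) -> MutationCharacterization:
    """Build a :class:`MutationCharacterization` from one novel-allele row.

    The genomic interval of the containing exon is not recorded in the
    table, so the region is carried as a degenerate interval at the recorded
    genomic position.  Amino-acid changes come from the missense table where
    available; for silent and nonsense rows a codon pair consistent with the
    recorded nucleotide change is synthesized.  The mutation class itself is
    always *derived* from the amino acids by :func:`classify_substitution`,
    never copied from the table.
    """
    locus = row.allele.split("*")[0]
    hla_class = locus_to_class(locus)
    exon = int(row.exon)
    domain = location_to_domain(row.location_on_protein)
    missense = _missense_aa_map().get(row.allele)
    if missense is not None:
        ref_aa, alt_aa, codon_position = missense
        ref_codon, alt_codon, _ = synthesize_codon_pair(
            row.ref_base, row.alt_base, ref_aa, alt_aa)
    elif row.mutation_type == "Nonsense":
        # the cohort's single null allele: Arg -> stop at leader codon -5
        ref_codon, alt_codon, _ = synthesize_codon_pair(
            row.ref_base, row.alt_base, "R", STOP)
        ref_aa, alt_aa = "R", STOP
        codon_position = -5
    else:
        ref_codon, alt_codon, _ = synthesize_codon_pair(
            row.ref_base, row.alt_base)
        ref_aa = alt_aa = translate_codon(ref_codon)
        # codon numbers are not recorded for silent rows; keep the sign
        # consistent with the region (leader exon 1 vs mature protein)
        codon_position = -1 if exon == 1 else 1
    region = FeatureInterval(FeatureKind.EXON, exon,
                             int(row.genomic_position),
                             int(row.genomic_position))
    codon_change = CodonChange(codon_position, ref_codon, alt_codon,
                               ref_aa, alt_aa)
    return MutationCharacterization(
        variant=ObservedVariant(int(row.genomic_position),
                                row.ref_base, row.alt_base),
        region=region,
        domain=domain,
        codon_change=codon_change,
        mutation_class=classify_substitution(ref_aa, alt_aa),
        key_exon=is_key_exon(hla_class, exon),
        splice_proximal=False,
    )


def load_reference_cohort() -> list[SampleNovelty]:
    """The bundled cohort as 41 :class:`SampleNovelty` records (sample table
    joined to the allele-level characterizations)."""
    alleles = {r.allele: characterization_from_fixture_row(r)
               for r in load_novel_allele_table().itertuples()}
    out = []
    for r in load_sample_table().itertuples():
        out.append(SampleNovelty(
            sample_id=r.sample_id,
            allele_name=r.allele,
            characterization=alleles[r.allele],
            patient_category=PatientCategory(r.patient_category),
            ethnicity=Ethnicity(r.ethnicity),
            specimen=Specimen(r.specimen),
        ))
    return out


# ---------------------------------------------------------------------------
# worked-example gene models
# ---------------------------------------------------------------------------

def _designed_model(
    locus: str,
    hla_class: HLAClass,
    leader_length: int,
    layout: list[tuple[FeatureKind, int]],
    codon_overrides: dict[int, str],
    seed: int,
) -> GeneModel:
    """Build a model from a (kind, length) layout with specified codons.

    The CDS is random sense codons under ``seed`` except at the overridden
    raw codon indices; introns carry canonical GT/AG ends.
    """
    rng = random.Random(seed)
    exon_lens = [ln for kind, ln in layout if kind is FeatureKind.EXON]
    total = sum(exon_lens)
    if total % 3:
        raise ModelDefinitionError("designed exon lengths not divisible by 3")
    cds = random_cds(total // 3, rng, codon_overrides)
    segments = []
    offset = 0
    for kind, ln in layout:
        if kind is FeatureKind.EXON:
            segments.append((kind, cds[offset:offset + ln]))
            offset += ln
        elif kind is FeatureKind.INTRON:
            segments.append((kind, _random_intron(ln, rng)))
        else:
            segments.append(
                (kind, "".join(rng.choice("ACGT") for _ in range(ln))))
    return build_model_from_segments(locus, hla_class, leader_length, segments)


E, I = FeatureKind.EXON, FeatureKind.INTRON
U5, U3 = FeatureKind.FIVE_PRIME_UTR, FeatureKind.THREE_PRIME_UTR


@lru_cache(maxsize=1)
def dpa1_leader_model() -> GeneModel:
    """DPA1-like model anchored on the cohort's DPA1*01 novelties.

    Exon 1 holds the 31 leader codons starting at genomic position 1, so
    genomic 5 is the middle base of codon -30 (CGC) and genomic 79 the first
    base of codon -5 (CGA) — the site of the cohort's nonsense novelty,
    where C>T turns CGA into the TGA stop.  Exon 3/4 anchors place codon
    149 (CAC) at genomic 4463 and codon 224 (CGG) at genomic 4901.
    """
    layout = [(E, 93), (I, 1907), (E, 246), (I, 2017), (E, 282),
              (I, 214), (E, 162), (U3, 179)]
    overrides = {
        2: "CGC",    # codon -30: Arg, G>A at genomic 5 gives CAC (His)
        17: "CCC",   # codon -15: Pro, silent C>T at genomic 51
        27: "CGA",   # codon -5: Arg, C>T at genomic 79 gives the TGA stop
        180: "CAC",  # codon 149: His, A>G at genomic 4463 gives CGC (Arg)
        194: "GCC",  # codon 163: Ala, silent C>T at genomic 4506
        255: "CGG",  # codon 224: Arg, C>T at genomic 4901 gives TGG (Trp)
    }
    return _designed_model("HLA-DPA1", HLAClass.CLASS_II_ALPHA, 31,
                           layout, overrides, seed=20230)


@lru_cache(maxsize=1)
def b48_model() -> GeneModel:
    """HLA-B-like model of total length 5626 anchored on the B*48:55
    novelty: genomic 1701 is the first base of codon 228 (ACT), where A>G
    gives GCT (Thr -> Ala)."""
    layout = [(U5, 50), (E, 73), (I, 150), (E, 270), (I, 250), (E, 276),
              (I, 497), (E, 276), (I, 600), (E, 117), (I, 700), (E, 33),
              (I, 600), (E, 44), (U3, 1690)]
    overrides = {252: "ACT"}  # codon 228 with a 24-codon leader
    return _designed_model("HLA-B", HLAClass.CLASS_I, 24,
                           layout, overrides, seed=20231)


@lru_cache(maxsize=1)
def b56_model() -> GeneModel:
    """HLA-B-like model anchored on the B*56:88 novelty: genomic 793 is the
    third base of codon 116 (TTA), where A>C gives TTC (Leu -> Phe)."""
    layout = [(U5, 30), (E, 73), (I, 140), (E, 270), (I, 203), (E, 276),
              (I, 500), (E, 276), (I, 500), (E, 117), (I, 500), (E, 33),
              (I, 500), (E, 44), (U3, 438)]
    overrides = {140: "TTA"}  # codon 116 with a 24-codon leader
    return _designed_model("HLA-B", HLAClass.CLASS_I, 24,
                           layout, overrides, seed=20232)


@lru_cache(maxsize=1)
def dqa1_intron_model() -> GeneModel:
    """DQA1-like model anchored on the DQA1 novelties: silent exon-1 and
    exon-2 sites, plus intron 2 ending at genomic 4028 so that the
    co-occurring intronic SNP at genomic 4027 is splice-proximal."""
    layout = [(E, 81), (I, 3670), (E, 249), (I, 28), (E, 282),
              (I, 189), (E, 159), (U3, 142)]
    overrides = {
        12: "GCC",   # codon -12: silent C>G at genomic 36
        16: "ACC",   # codon -8: silent C>T at genomic 48
        23: "GGT",   # codon -1: silent T>A at genomic 69
        47: "CTG",   # codon 24: silent C>T at genomic 3809
        102: "ACC",  # codon 78: silent C>A at genomic 3976
    }
    return _designed_model("HLA-DQA1", HLAClass.CLASS_II_ALPHA, 23,
                           layout, overrides, seed=20233)
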