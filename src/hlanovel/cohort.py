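"""Cohort statistics over a set of characterized novelties.

Tallies follow the two natural denominators of a novel-allele cohort:
mutation-class, locus and exon-category counts are computed over *unique
novel alleles* (the allele-level catalogue), while patient-category and
ethnicity breakdowns are computed over *samples* (several related samples
can carry the same novel allele).  Detection rates divide by the
observation window in months.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import HlaNovelError
from .gene_model import FeatureKind, HLAClass, locus_to_class
from .variants import MutationCharacterization, SampleNovelty


class ExonCategory(str, Enum):
    """Disjoint exon buckets used in cohort reporting."""

    KEY_EXON = "key_exon"          # antigen-binding-site exons
    EXON1_LEADER = "exon1_leader"  # leader peptide
    EXON3_NONKEY = "exon3_nonkey"  # class II alpha-2 / beta-2 arms
    EXON4 = "exon4"
    EXON7 = "exon7"
    OTHER = "other"


def exon_category(char: MutationCharacterization) -> ExonCategory:
    """Disjoint exon bucket of a characterization (key-exon rule first)."""
    if char.region.kind is not FeatureKind.EXON:
        return ExonCategory.OTHER
    if char.key_exon:
        return ExonCategory.KEY_EXON
    idx = char.region.index
    if idx == 1:
        return ExonCategory.EXON1_LEADER
    if idx == 3:
        return ExonCategory.EXON3_NONKEY
    if idx == 4:
        return ExonCategory.EXON4
    if idx == 7:
        return ExonCategory.EXON7
    return ExonCategory.OTHER


@dataclass(frozen=True)
class CohortSummary:
    n_samples: int
    n_unique_alleles: int
    by_mutation_class: dict[str, int]      # over unique alleles
    by_locus: dict[str, int]               # over unique alleles
    by_exon: dict[int, int]                # raw exon index, unique alleles
    by_exon_category: dict[str, int]       # disjoint buckets, unique alleles
    by_patient_category: dict[str, int]    # over samples
    by_ethnicity_pct: dict[str, int]       # over samples, rounded percent
    rate_samples_per_month: float
    rate_unique_per_month: float
    pct_class_II_alpha: int

    def report(self) -> str:
        """Human-readable multi-line summary."""
        lines = [
            f"Samples with a novelty: {self.n_samples}",
            f"Unique novel alleles:   {self.n_unique_alleles}",
            f"Detection rate: {self.rate_samples_per_month}/month (samples), "
            f"{self.rate_unique_per_month}/month (unique alleles)",
            f"Class II alpha share:   {self.pct_class_II_alpha}% of unique alleles",
            "Mutation classes (unique alleles): " + ", ".join(
                f"{k}={v}" for k, v in self.by_mutation_class.items()),
            "Loci (unique alleles): " + ", ".join(
                f"{k}={v}" for k, v in self.by_locus.items()),
            "Exon categories (unique alleles): " + ", ".join(
                f"{k}={v}" for k, v in self.by_exon_category.items()),
            "Patient categories (samples): " + ", ".join(
                f"{k}={v}" for k, v in self.by_patient_category.items()),
            "Ethnicity (samples, %): " + ", ".join(
                f"{k}={v}" for k, v in self.by_ethnicity_pct.items()),
        ]
        return "\n".join(lines)


def summarize(cohort: Sequence[SampleNovelty], months: float) -> CohortSummary:
    """Summarize a characterized cohort observed over ``months`` months.

    Unique alleles are deduplicated by allele name (the first sample
    carrying an allele is its representative).  Percentages are rounded to
    the nearest integer and rates to one decimal, both round-half-even.
    """
    if not cohort:
        raise HlaNovelError("cannot summarize an empty cohort")
    if months <= 0:
        raise HlaNovelError("observation window must be positive")

    unique: dict[str, SampleNovelty] = {}
    for s in cohort:
        unique.setdefault(s.allele_name, s)
    n_samples, n_unique = len(cohort), len(unique)

    by_class = Counter(
        s.characterization.mutation_class.value for s in unique.values())
    by_locus = Counter(s.locus for s in unique.values())
    by_exon = Counter(
        s.characterization.exon_index for s in unique.values()
        if s.characterization.exon_index is not None)
    by_cat = Counter(
        exon_category(s.characterization).value for s in unique.values())
    by_patient = Counter(s.patient_category.value for s in cohort)
    eth = Counter(s.ethnicity.value for s in cohort)
    def _is_alpha(s: SampleNovelty) -> bool:
        try:
            return locus_to_class(s.locus) is HLAClass.CLASS_II_ALPHA
        except KeyError:  # non-classical / synthetic locus names
            return False

    n_alpha = sum(1 for s in unique.values() if _is_alpha(s))

    return CohortSummary(
        n_samples=n_samples,
        n_unique_alleles=n_unique,
        by_mutation_class=dict(by_class),
        by_locus=dict(by_locus),
        by_exon=dict(sorted(by_exon.items())),
        by_exon_category=dict(by_cat),
        by_patient_category=dict(by_patient),
        by_ethnicity_pct={k: round(100 * v / n_samples)
                          for k, v in eth.items()},
        rate_samples_per_month=round(n_samples / months, 1),
        rate_unique_per_month=round(n_unique / months, 1),
        pct_class_II_alpha=round(100 * n_alpha / n_unique),
    )


def summarize_reference_cohort() -> CohortSummary:
    """Summary of the bundled 41-sample / 29-allele cohort over its
    18-month observation window."""
    from .fixtures import COHORT_MONTHS, load_reference_cohort

    return summarize(load_reference_cohort(), COHORT_MONTHS)
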