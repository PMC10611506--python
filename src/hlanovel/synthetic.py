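"""Synthetic gene models, induced mutations and simulated cohorts.

Every other module is testable offline against models produced here: multi-
exon HLA-like genes with a valid reading frame (ATG start, terminal stop, no
internal stop codons), canonical GT/AG intron ends, and UTRs; plus induced
single-nucleotide variants of a requested mutation class bundled with the
ground-truth annotation they must characterize to.

Models are structurally realistic (exon counts and domain layout follow the
HLA class; default length ranges bracket the classical loci) but make no
attempt at real polymorphism spectra or IMGT coordinates.  All outputs are
deterministic functions of the configured seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .errors import ConfigError, InfeasibleError
from .gene_model import (
    STOP,
    FeatureKind,
    GeneModel,
    HLAClass,
    build_model_from_segments,
    translate_codon,
)
from .variants import (
    CodonChange,
    Ethnicity,
    MutationCharacterization,
    MutationClass,
    ObservedVariant,
    PatientCategory,
    SampleNovelty,
    Specimen,
    VariantKind,
    DEFAULT_SPLICE_WINDOW,
    is_key_exon,
)

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if translate_codon(a + b + c) != STOP
)
_STOP_CODONS = ("TAA", "TAG", "TGA")

#: Exonic mutation-class proportions default to those observed in the study
#: cohort (55% missense / 41% silent / 3% nonsense), with a small residual
#: weight on co-occurring intronic SNPs.
DEFAULT_CLASS_WEIGHTS = {
    MutationClass.MISSENSE: 0.55,
    MutationClass.SILENT: 0.41,
    MutationClass.NONSENSE: 0.03,
    MutationClass.INTRONIC: 0.01,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic generator.

    Ranges are inclusive.  ``exon_count_range`` applies to class I models;
    class II alpha and beta genes always get their canonical 4 and 5 exons
    so the class-specific domain maps apply.  The same seed always yields
    byte-identical outputs.
    """

    seed: int = 0
    n_models: int = 10
    hla_class_mix: dict[HLAClass, float] = field(default_factory=lambda: {
        HLAClass.CLASS_I: 0.31,        # 9/29 unique novelties were class I
        HLAClass.CLASS_II_ALPHA: 0.52,  # 15/29
        HLAClass.CLASS_II_BETA: 0.17,   # 5/29
    })
    exon_count_range: tuple[int, int] = (5, 8)
    exon_length_range: tuple[int, int] = (60, 280)
    intron_length_range: tuple[int, int] = (40, 600)
    utr_length_range: tuple[int, int] = (0, 300)
    leader_length_range: tuple[int, int] = (16, 31)
    mutation_class_weights: dict[MutationClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    n_samples: int = 41
    months: float = 18.0

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_length_range",
                     "intron_length_range", "utr_length_range",
                     "leader_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigError(f"empty or negative {name}: ({lo}, {hi})")
        for name, weights in (("hla_class_mix", self.hla_class_mix),
                              ("mutation_class_weights",
                               self.mutation_class_weights)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9 or min(weights.values()) < 0:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        if self.months <= 0:
            raise ConfigError("months must be positive")


def _model_rng(config: SimulationConfig, index: int) -> random.Random:
    return random.Random(config.seed * 1_000_003 + index)


def random_cds(n_codons: int, rng: random.Random,
               overrides: dict[int, str] | None = None) -> str:
    """A CDS of ``n_codons`` codons: ATG start, terminal stop, internal
    codons drawn from the 61 sense codons, with optional per-codon overrides
    (1-based raw codon index -> triplet)."""
    if n_codons < 2:
        raise ConfigError("a CDS needs at least a start and a stop codon")
    codons = ["ATG"]
    codons += [rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2)]
    codons.append(rng.choice(_STOP_CODONS))
    for raw, triplet in (overrides or {}).items():
        if not 1 <= raw <= n_codons:
            raise ConfigError(f"override codon {raw} outside 1..{n_codons}")
        if raw < n_codons and translate_codon(triplet) == STOP:
            raise ConfigError(f"override would place an internal stop at {raw}")
        codons[raw - 1] = triplet
    return "".join(codons)


def _random_intron(length: int, rng: random.Random) -> str:
    body = "".join(rng.choice("ACGT") for _ in range(max(length - 4, 0)))
    if length >= 4:
        return "GT" + body + "AG"
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_gene_model(config: SimulationConfig, index: int) -> GeneModel:
    """Generate the ``index``-th synthetic gene model of a configuration."""
    rng = _model_rng(config, index)
    classes = list(config.hla_class_mix)
    hla_class = rng.choices(
        classes, weights=[config.hla_class_mix[c] for c in classes])[0]
    if hla_class is HLAClass.CLASS_II_ALPHA:
        n_exons = 4
    elif hla_class is HLAClass.CLASS_II_BETA:
        n_exons = 5
    else:
        lo, hi = config.exon_count_range
        if hi < 5:
            raise ConfigError("class I models need exon_count_range up to >= 5")
        n_exons = rng.randint(max(lo, 5), hi)

    exon_lens = [rng.randint(*config.exon_length_range) for _ in range(n_exons)]
    total = sum(exon_lens)
    exon_lens[-1] -= total % 3
    if exon_lens[-1] < 3:
        exon_lens[-1] += 3
    n_codons = sum(exon_lens) // 3
    lo, hi = config.leader_length_range
    max_leader = n_codons - 2  # at least one mature codon plus the stop
    if lo > max_leader:
        raise ConfigError("leader_length_range infeasible for the CDS length")
    leader = rng.randint(lo, min(hi, max_leader))

    cds = random_cds(n_codons, rng)
    segments: list[tuple[FeatureKind, str]] = []
    utr5 = rng.randint(*config.utr_length_range)
    if utr5:
        segments.append((FeatureKind.FIVE_PRIME_UTR,
                         "".join(rng.choice("ACGT") for _ in range(utr5))))
    offset = 0
    for i, ln in enumerate(exon_lens):
        segments.append((FeatureKind.EXON, cds[offset:offset + ln]))
        offset += ln
        if i < n_exons - 1:
            segments.append((FeatureKind.INTRON, _random_intron(
                rng.randint(*config.intron_length_range), rng)))
    utr3 = rng.randint(*config.utr_length_range)
    if utr3:
        segments.append((FeatureKind.THREE_PRIME_UTR,
                         "".join(rng.choice("ACGT") for _ in range(utr3))))
    return build_model_from_segments(
        f"SYN-{hla_class.value}-{index}", hla_class, leader, segments)


# ---------------------------------------------------------------------------
# induced mutations with bundled truth
# ---------------------------------------------------------------------------

def _truth_for_exonic(model: GeneModel, pos: int, ref: str, alt: str,
                      codon_position: int, ref_codon: str, alt_codon: str,
                      mutation_class: MutationClass) -> MutationCharacterization:
    region = model.locate_region(pos)
    variant = ObservedVariant(pos, ref, alt)
    return MutationCharacterization(
        variant=variant,
        region=region,
        domain=model.domain_of(region.index),
        codon_change=CodonChange(codon_position, ref_codon, alt_codon,
                                 translate_codon(ref_codon),
                                 translate_codon(alt_codon)),
        mutation_class=mutation_class,
        key_exon=is_key_exon(model.hla_class, region.index),
        splice_proximal=False,
    )


def induce_mutation(
    model: GeneModel,
    target_class: MutationClass,
    rng: random.Random,
) -> tuple[str, ObservedVariant, MutationCharacterization]:
    """Introduce one substitution of the requested class into a model.

    Returns ``(consensus, variant, truth)`` where ``consensus`` differs from
    the model sequence at exactly one position and ``truth`` is the
    characterization that annotation must recover.  The search over codons
    (or introns) is randomized under ``rng``; raises
    :class:`InfeasibleError` when the class is unreachable.
    """
    if target_class is MutationClass.INTRONIC:
        introns = [f for f in model.features if f.kind is FeatureKind.INTRON]
        if not introns:
            raise InfeasibleError("model has no introns")
        intron = rng.choice(introns)
        pos = rng.randint(intron.start, intron.end)
        ref = model.sequence[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        variant = ObservedVariant(pos, ref, alt)
        truth = MutationCharacterization(
            variant=variant, region=intron, domain=None, codon_change=None,
            mutation_class=MutationClass.INTRONIC, key_exon=False,
            splice_proximal=(pos - intron.start < DEFAULT_SPLICE_WINDOW
                             or intron.end - pos < DEFAULT_SPLICE_WINDOW))
        consensus = model.sequence[:pos - 1] + alt + model.sequence[pos:]
        return consensus, variant, truth

    if target_class not in (MutationClass.MISSENSE, MutationClass.SILENT,
                            MutationClass.NONSENSE):
        raise InfeasibleError(
            f"cannot induce {target_class.value} via a single substitution")

    n_codons = model.cds_length // 3
    raws = list(range(1, n_codons))  # exclude the terminal stop codon
    rng.shuffle(raws)
    from .gene_model import raw_to_mature

    for raw in raws:
        mature = raw_to_mature(raw, model.leader_length)
        ref_codon = model.codon_triplet(mature)
        if translate_codon(ref_codon) == STOP:
            continue
        offsets = [0, 1, 2]
        rng.shuffle(offsets)
        for off in offsets:
            bases = [b for b in "ACGT" if b != ref_codon[off]]
            rng.shuffle(bases)
            for alt_base in bases:
                alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1:]
                ref_aa, alt_aa = (translate_codon(ref_codon),
                                  translate_codon(alt_codon))
                if alt_aa == STOP:
                    achieved = MutationClass.NONSENSE
                elif ref_aa == alt_aa:
                    achieved = MutationClass.SILENT
                else:
                    achieved = MutationClass.MISSENSE
                if achieved is not target_class:
                    continue
                pos = model.codon_genomic_positions(mature)[off]
                truth = _truth_for_exonic(
                    model, pos, ref_codon[off], alt_base, mature,
                    ref_codon, alt_codon, achieved)
                consensus = (model.sequence[:pos - 1] + alt_base
                             + model.sequence[pos:])
                return consensus, truth.variant, truth
    raise InfeasibleError(
        f"no single substitution yields {target_class.value} in this model")


# ---------------------------------------------------------------------------
# simulated cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSample:
    sample: SampleNovelty
    model: GeneModel
    consensus: str
    truth: MutationCharacterization


def simulate_cohort(config: SimulationConfig) -> list[SimulatedSample]:
    """Simulate ``config.n_samples`` samples, each carrying one induced
    novelty on one of ``config.n_models`` synthetic gene models."""
    rng = random.Random(config.seed * 7_368_787 + 1)
    models = [make_gene_model(config, i) for i in range(config.n_models)]
    classes = list(config.mutation_class_weights)
    weights = [config.mutation_class_weights[c] for c in classes]
    out = []
    for i in range(config.n_samples):
        model = models[i % len(models)]
        target = rng.choices(classes, weights=weights)[0]
        consensus, _, truth = induce_mutation(model, target, rng)
        locus = {HLAClass.CLASS_I: "B", HLAClass.CLASS_II_ALPHA: "DQA1",
                 HLAClass.CLASS_II_BETA: "DRB1"}[model.hla_class]
        sample = SampleNovelty(
            sample_id=f"SIM{i + 1:03d}",
            allele_name=f"{locus}*SYN:{i + 1:02d}",
            characterization=truth,
            patient_category=rng.choice(list(PatientCategory)),
            ethnicity=rng.choice(list(Ethnicity)),
            specimen=Specimen.PERIPHERAL_BLOOD,
        )
        out.append(SimulatedSample(sample, model, consensus, truth))
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: a copy of ``config`` under a different seed."""
    return replace(config, seed=seed)
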