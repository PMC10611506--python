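# hlanovel

Desk-side management of **novel HLA alleles** detected by clinical
next-generation-sequencing (NGS) typing.

Histocompatibility laboratories that sequence the 11 classical HLA genes at
full length now stumble on alleles absent from IPD-IMGT/HLA at a steady
clip — roughly one to two per month in a mid-size transplant program. Once
the sequencing pipeline flags a novelty, a chain of careful bookkeeping
follows: locating the nucleotide change on the gene structure, expressing
it as a codon change in mature-protein numbering, classifying the mutation,
judging its likely effect on the protein, preparing the files a sequence
repository needs before IPD-IMGT/HLA will assign an official name, and
keeping cohort-level statistics. `hlanovel` implements that chain as a
typed, tested Python library.

## What it computes

**Coordinate arithmetic** (`hlanovel.gene_model`). A `GeneModel` holds a
locus's UTR/exon/intron intervals (1-based, closed), leader-peptide length
and exon→domain map. Genomic position *g* maps to a codon via its CDS
offset *o* (exonic bases strictly before *g*): the raw codon index is
⌊*o*/3⌋+1, and mature-protein numbering subtracts the leader length *L*,
skipping zero — leader codons are −*L*…−1, mature codons 1…*M*. A stop
codon is rendered `X`.

**Variant characterization** (`hlanovel.variants`). `detect_variants`
compares a reference allele against an observed consensus (substitutions,
or one short indel by prefix/suffix trimming); `characterize` produces the
exon/domain, the codon change and the mutation class (missense, silent,
nonsense, frameshift, in-frame indel, intronic, UTR), the key-exon flag
(exons 2–3 for class I, exon 2 for class II encode the antigen-binding
site), an advisory splice-proximity flag for intronic variants, plus QC
flags (multiple exonic novelties in one sample; germline confirmation for
hematological-malignancy patients typed from peripheral blood).
`describe_mutation` renders the standard registration sentence.

**Impact scoring** (`hlanovel.impact`). Each missense novelty scores one
`+` per criterion met, `+` to `++++`:

1. amino-acid change (always true for missense);
2. change of physicochemical category — compared at the five-way level
   (nonpolar aliphatic / nonpolar aromatic / polar uncharged / basic /
   acidic), so an aliphatic→aromatic swap counts;
3. located in the antigen-binding site (key exon);
4. affects an eplet — disrupts a (position, residue) pair of a known eplet
   or introduces a new one.

**Submission building** (`hlanovel.submission`). Master FASTA
(`>SeqID [organism=Homo sapiens] description`) plus a five-column feature
table per sequence (gene spanning the whole submission, mRNA = UTRs+exons,
CDS = exons only), with byte-exact round-trip parsers and a manifest of
written mutation sentences.

**Cohort summarization** (`hlanovel.cohort`). Mutation-class / locus /
exon-category tallies over unique alleles, patient-category and ethnicity
breakdowns over samples, and monthly detection rates.

**Synthetic data** (`hlanovel.synthetic`). Deterministic generators for
HLA-like gene models with valid reading frames, induced mutations of a
requested class bundled with ground-truth annotations, and simulated
cohorts. `hlanovel.fixtures` ships a bundled reference cohort (29 unique
novel alleles, 41 samples, 18 months) together with self-consistent
worked-example gene models; the sample-level table is a synthetic
reconstruction matching the cohort's marginal counts.

## Worked example

```python
from hlanovel import characterize, describe_mutation, detect_variants
from hlanovel.fixtures import b48_model

model = b48_model()
consensus = model.sequence[:1700] + "G" + model.sequence[1701:]
[variant] = detect_variants(model.sequence, consensus)
char = characterize(model, variant)
print(char.region.index, char.codon_change, char.mutation_class.value)
print(describe_mutation("VGH002", "B*48:01:01:01", char))
```

prints

```
4 CodonChange(codon_position=228, ref_codon='ACT', alt_codon='GCT', ref_aa='T', alt_aa='A') missense
VGH002 has 1 nt change from B*48:01:01:01 at nt 1701 where A > G (codon 228 ACT > GCT), resulting in a coding change 228 Thr is changed to Ala.
```

— the A>G at genomic position 1701 falls in exon 4 (the α3 extracellular
arm, not a key exon) and substitutes alanine for threonine at mature
position 228; with a property change but no binding-site or eplet
involvement it scores `++`. The `examples/` directory holds one short
script per capability (characterization, leader-peptide nonsense
arithmetic, impact scoring, submission bundles, cohort summary,
simulation); each prints the numbers it computes and a line on what they
mean. A thin CLI (`hlanovel simulate|summary|submit`) wraps the
simulation, summary and submission paths.

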