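# Methods

This note records the scientific conventions, numerical choices and open
design decisions behind `hlanovel`, in the spirit of a model-description
document: what is computed, under which assumptions, and what the bundled
data and tests do and do not establish.

## Gene model and coordinate conventions

A gene model is the annotated sense-strand genomic sequence of one HLA-like
locus. Coordinates are 1-based and inclusive on both ends; the UTR, exon
and intron intervals must partition `[1, len(sequence)]` exactly (the
constructor rejects gaps, overlaps and misordered ordinals). For a full-CDS
model the concatenated exons must be a multiple of 3.

Codon addressing uses **mature-protein numbering**: with leader length *L*
(codons of the signal peptide, cleaved before surface expression), raw CDS
codon *r* maps to *r* − *L* when *r* > *L* and to *r* − *L* − 1 otherwise,
so the leader occupies −*L*…−1, the mature protein 1…*M*, and codon 0 does
not exist. This matches clinical usage, where leader positions print as
negative numbers. The inverse mapping is exact and property-tested.

Partial-coverage models (loci sequenced from partial intron 1, as some
DRB genes are) carry a `first_codon_raw` anchor; codon numbering for them
is relative to the first fully covered codon.

Stop codons are carried internally as `*` and rendered `X` in alignment
strings, the convention on HLA sequence reports.

The bundled worked-example models (`hlanovel.fixtures`) are **synthetic
reconstructions**: exon/intron lengths are chosen so that every recorded
(genomic position, codon position, codon triplet) anchor of the respective
allele family is simultaneously satisfied, and the remaining sequence is
deterministic random sense codons. They are not real IMGT reference
sequences, and their coordinates are self-consistent rather than
authoritative. Notably, joint consistency of the DPA1 anchors (genomic 79 ↔
leader codon −5, first base of CGA; genomic 5 ↔ leader codon −30, middle
base of CGC; leader length 31) requires exon 1 to begin at genomic
position 1, i.e. no 5′UTR bases precede the CDS in that numbering — the
DPA1-like model is built accordingly.

## Variant detection

`detect_variants` is a purpose-built comparator, not a general aligner,
because the clinical input regime is narrow: a consensus differs from its
nearest catalogued allele by point substitutions or a single short indel.
Equal-length inputs are compared position-wise; unequal lengths are
reconciled by longest-common-prefix/suffix trimming, and the difference
must be exactly one inserted/deleted block (otherwise the caller is
directed to supply pre-called variants). Insertions are reported at the
reference base immediately before the inserted material; deletions at the
first deleted base. In repeat runs the anchor left-shifts; reconstruction
of the consensus from the reported variant is the tested invariant.

## Mutation classification

Exonic SNPs are classified purely from the amino-acid effect of the codon
substitution: silent (identical residue), nonsense (stop gained), missense
(otherwise). A stop-gain inside the leader peptide still classifies as
nonsense even though the residue precedes the mature protein — a truncated
leader yields a null allele. A substitution in the terminal stop codon
(stop-loss) has no bucket in this scheme and raises an error; the bundled
cohort contains none. Exonic indels classify as frameshift unless their
length is a multiple of 3 (in-frame). Intronic variants are flagged
splice-proximal when they fall within a configurable number of bases
(default 2, the canonical GT/AG dinucleotides) of either intron end; the
flag is advisory — expression suffixes (N/Q) are a reporting decision,
never applied silently.

The key-exon rule encodes where the antigen-binding site lives: exons 2
and 3 for class I, exon 2 for class II.

## Impact score

The score assigns one `+` per criterion: (1) amino-acid change, true for
every scored (missense) mutation, so totals run 1–4; (2) physicochemical
category change, compared at the **five-subcategory** level (nonpolar
aliphatic, nonpolar aromatic, polar uncharged, basic, acidic) — the only
reading consistent with every recorded score in the bundled table, e.g.
Leu→Phe (both nonpolar) earns the property `+`; (3) location in a key
exon; (4) eplet effect, true when the (mature position, residue) pair of
either the original or the novel residue constitutes a known eplet —
covering both disruption of an expressed eplet and introduction of a new
one. The acidic category has no example in the bundled cohort and
participates symmetrically.

The packaged residue table follows the standard five-way classification
(Gly/Ala/Val/Leu/Ile/Met/Pro aliphatic; Phe/Trp/Tyr aromatic;
Ser/Thr/Cys/Asn/Gln polar uncharged; Lys/Arg/His basic; Asp/Glu acidic).
The packaged eplet registry is a small **synthetic** stand-in: it contains
the four position/residue pairs needed by the bundled cohort plus decoys
chosen not to collide with any scored position, and exists so the scoring
path is exercised offline; production use should load a current registry
file (`read_eplet_registry`). When a locus group is supplied, only eplets
of that group are consulted (class I loci share one group; DRB, DQ and DP
form their own); without one the whole registry is searched.

Silent and nonsense mutations are reported but not `+`-scored.

## Submission artifacts

FASTA headers are `>{seq_id} [organism={organism}] {description}` with
sequence wrapped at 70 columns (configurable). Feature tables follow the
five-column convention: `start TAB end TAB key` opens a feature,
continuation intervals carry `start TAB end`, qualifiers are three empty
columns then `key TAB value`; the mRNA's UTR sub-annotations are emitted as
their own `5'UTR`/`3'UTR` blocks directly after the mRNA feature and folded
back on parsing. Published examples of these files do not fix every
whitespace detail, so the dialect is defined here and **round-trip
byte-identity** (write → parse → write) is the correctness criterion,
enforced in tests. The gene feature spans positions 1 to the sequence
length; mRNA intervals equal CDS intervals plus UTRs, disjoint. Optional
demographics travel only in the sidecar manifest, never in the FASTA.

## Cohort summary

Two denominators coexist deliberately: mutation-class, locus and
exon-category tallies run over **unique alleles** (deduplicated by allele
name; related samples often share one novelty), while patient-category and
ethnicity run over **samples**. This split reproduces all recorded
statistics of the bundled cohort. Percentages round to integers and rates
to one decimal, both round-half-even (29/18 → 1.6, 41/18 → 2.3 unique and
sample rates per month). The exon report carries both the raw per-exon
tally (where exon 3 counts class I key-exon rows) and disjoint buckets
(key exon first, then exon 1 / non-key exon 3 / exon 4 / exon 7 / other).
A single 18-month observation window is used for the bundled cohort;
per-sample accrual dates are not modelled.

## Synthetic generator

Generated models have an ATG start, a terminal stop, no internal stop
codons, GT…AG introns, and exon counts fixed by class — 4 for class II
alpha, 5 for class II beta, sampled within the configured range (≥5) for
class I — so the canonical domain maps always apply. Default
mutation-class weights for induced variants follow the bundled cohort's
exonic proportions (0.55 missense / 0.41 silent / 0.03 nonsense) with a
0.01 residual on intronic SNPs; default structural ranges bracket the
classical loci at compact sizes. Induction searches codons in seeded random
order for a substitution achieving the requested class (nonsense requires
a codon one substitution from TAA/TAG/TGA) and returns the consensus with
the constructed ground truth; infeasibility raises rather than degrades.
Every generator output is a deterministic function of the seed.

The generator is structurally, not phylogenetically, realistic: it makes no
attempt at real HLA polymorphism spectra, haplotype structure, or IMGT
coordinates. Passing recovery tests therefore demonstrate the correctness
of the annotation arithmetic on well-formed gene structures — they do not
validate performance on degraded sequencing data, phasing errors, or the
upstream genotype-calling step, all of which are out of scope.

## Bundled cohort data

The allele-level and missense tables record a published-style 18-month
clinical cohort (29 unique novel alleles, 16 missense with recorded
impact scores). The 41-row sample table is a **synthetic reconstruction**:
only its marginal counts (patient categories 11/9/3/17/1; ethnicity
proportions 51/32/12/2/2%; six multi-sample alleles including one carried
by seven related/unrelated samples) are faithful, and individual row
assignments are invented; the file is named accordingly. Data files are
checksum-pinned and validated on load. For table rows whose codons are not
recorded (silent changes), a codon pair consistent with the recorded
nucleotide change is synthesized deterministically; the mutation class is
always re-derived from the amino acids, never copied from the table.

## Problem sizes in tests and the acceptance script

Property tests run 500 induced-mutation recovery trials over 20 compact
models (exons 30–120 nt) and verify codon arithmetic against a base-walk
oracle on every exonic position of 100 generated models; the whole suite
and the acceptance script each complete in seconds. These sizes were chosen
as comfortably exhaustive for structures of this shape — every exon of
every model is crossed by the position sweeps — rather than as a sampling
compromise.

## Known limitations

* No genotype calling, phasing, read-level QC or assay simulation; inputs
  are consensus sequences or pre-called variants.
* Intronic novelties are characterized and recorded but reporting policy is
  left to the caller; splice assessment is a proximity flag, not a model.
* The binding-site criterion is exon-based, not residue-structure-based;
  identical for all bundled cases but coarser in principle.
* Stop-loss and multi-indel events are rejected rather than annotated.
* Official WHO allele naming, accession handling and any network
  interaction with repositories are out of scope; only file generation is
  implemented.
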