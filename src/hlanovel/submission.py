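"""Submission-ready artifacts for registering novel alleles.

Sequence repositories (GenBank via BankIt, ENA, DDBJ) accept a batch of
novel allele sequences as one master FASTA plus one five-column feature
table per sequence; an accession number from one of them is a prerequisite
for official allele naming by IPD-IMGT/HLA.  This module builds those files
from a characterized sample and its gene model, and parses them back.

Dialect (documented; the round-trip tests define correctness):

* FASTA headers are ``>{seq_id} [organism={organism}] {description}``;
  sequence lines wrap at 70 columns by default.
* A feature table starts with ``>Feature {seq_id}``; each feature opens
  with ``start<TAB>end<TAB>key``, continuation intervals carry only
  ``start<TAB>end``, and qualifiers are written as three empty columns
  followed by ``key<TAB>value``.  The UTR sub-annotations of the mRNA are
  emitted as their own ``5'UTR``/``3'UTR`` blocks immediately after it.

The gene feature spans the whole submitted sequence; the mRNA feature lists
UTR plus exon intervals; the CDS feature lists exon intervals only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import BatchError, ConsistencyError
from .gene_model import FeatureKind, GeneModel
from .variants import SampleNovelty, describe_mutation

DEFAULT_WRAP = 70
_UTR_KEYS = {"5'UTR": FeatureKind.FIVE_PRIME_UTR,
             "3'UTR": FeatureKind.THREE_PRIME_UTR}


@dataclass
class FeatureEntry:
    """One gene/mRNA/CDS feature with its interval list and qualifiers."""

    feature_kind: str  # "gene" | "mRNA" | "CDS"
    intervals: list[tuple[int, int]]
    qualifiers: list[tuple[str, str]] = field(default_factory=list)
    utr_annotations: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ConsistencyError(
                f"{self.feature_kind} feature without intervals")
        for start, end in self.intervals:
            if start > end or start < 1:
                raise ConsistencyError(
                    f"bad interval ({start}, {end}) in {self.feature_kind}")


@dataclass
class SubmissionRecord:
    seq_id: str
    description: str
    sequence: str
    features: list[FeatureEntry] = field(default_factory=list)
    organism: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ConsistencyError("seq_id must be non-empty")


def build_submission(
    sample: SampleNovelty,
    model: GeneModel,
    consensus: str,
) -> SubmissionRecord:
    """Assemble a submission record for one sample's novel allele.

    ``consensus`` is the full-length observed sequence carrying the novelty;
    it must match the gene model's span so the model's intervals annotate it
    directly.
    """
    consensus = consensus.upper()
    if len(consensus) != len(model.sequence):
        raise ConsistencyError(
            f"consensus length {len(consensus)} does not match the "
            f"{model.locus_name} model span {len(model.sequence)}")
    length = len(consensus)
    exons = [(f.start, f.end) for f in model.features
             if f.kind is FeatureKind.EXON]
    utrs = [(f.kind, f.start, f.end) for f in model.features
            if f.kind in (FeatureKind.FIVE_PRIME_UTR,
                          FeatureKind.THREE_PRIME_UTR)]
    mrna = sorted(exons + [(s, e) for _, s, e in utrs])
    c = sample.characterization
    v = c.variant
    description = (f"{model.locus_name} gene, novel allele most closely "
                   f"related to {sample.allele_name}, "
                   f"{v.pos}{v.ref_base}>{v.alt_base}")
    gene_q = [("gene", model.locus_name)]
    features = [
        FeatureEntry("gene", [(1, length)], list(gene_q)),
        FeatureEntry("mRNA", mrna, list(gene_q),
                     [("5'UTR" if k is FeatureKind.FIVE_PRIME_UTR else "3'UTR",
                       s, e) for k, s, e in utrs]),
        FeatureEntry("CDS", exons, list(gene_q) + [
            ("product", f"{model.locus_name} protein")]),
    ]
    return SubmissionRecord(sample.sample_id, description, consensus, features)


# ---------------------------------------------------------------------------
# FASTA dialect
# ---------------------------------------------------------------------------

def _check_batch(records: Sequence[SubmissionRecord]) -> None:
    if not records:
        raise BatchError("empty submission batch")
    ids = [r.seq_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise BatchError(f"duplicate seq_id in batch: {dupes}")


def format_fasta(records: Sequence[SubmissionRecord],
                 wrap: int = DEFAULT_WRAP) -> str:
    """The master-FASTA text for a batch."""
    _check_batch(records)
    chunks = []
    for r in records:
        chunks.append(f">{r.seq_id} [organism={r.organism}] {r.description}\n")
        for i in range(0, len(r.sequence), wrap):
            chunks.append(r.sequence[i:i + wrap] + "\n")
    return "".join(chunks)


def write_fasta(records: Sequence[SubmissionRecord], destination,
                wrap: int = DEFAULT_WRAP) -> None:
    Path(destination).write_text(format_fasta(records, wrap))


def parse_fasta(source) -> list[SubmissionRecord]:
    """Parse a master FASTA written by :func:`write_fasta` (features are
    not part of the FASTA and come back empty)."""
    text = Path(source).read_text() if not isinstance(source, str) or \
        "\n" not in source else source
    records: list[SubmissionRecord] = []
    seq_lines: list[str] = []
    header: tuple[str, str, str] | None = None

    def flush():
        if header is not None:
            sid, organism, desc = header
            records.append(SubmissionRecord(sid, desc, "".join(seq_lines),
                                            organism=organism))

    for line in text.splitlines():
        if line.startswith(">"):
            flush()
            seq_lines = []
            head = line[1:]
            sid, rest = head.split(" ", 1)
            if not rest.startswith("[organism="):
                raise ConsistencyError(f"malformed FASTA header: {line!r}")
            organism, desc = rest[len("[organism="):].split("] ", 1)
            header = (sid, organism, desc)
        elif line.strip():
            seq_lines.append(line.strip())
    flush()
    if not records:
        raise BatchError("no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# feature-table dialect
# ---------------------------------------------------------------------------

def format_feature_table(record: SubmissionRecord) -> str:
    """The five-column feature-table text for one record."""
    lines = [f">Feature {record.seq_id}"]
    for feat in record.features:
        (s0, e0), rest = feat.intervals[0], feat.intervals[1:]
        lines.append(f"{s0}\t{e0}\t{feat.feature_kind}")
        lines.extend(f"{s}\t{e}" for s, e in rest)
        for key, value in feat.qualifiers:
            lines.append(f"\t\t\t{key}\t{value}")
        for utr_kind, s, e in feat.utr_annotations:
            lines.append(f"{s}\t{e}\t{utr_kind}")
    return "\n".join(lines) + "\n"


def write_feature_table(record: SubmissionRecord, destination) -> None:
    Path(destination).write_text(format_feature_table(record))


def parse_feature_table(source) -> tuple[str, list[FeatureEntry]]:
    """Parse a feature table back into (seq_id, features); UTR blocks are
    folded into the preceding mRNA entry, inverting the writer."""
    text = Path(source).read_text() if not isinstance(source, str) or \
        "\n" not in source else source
    lines = text.splitlines()
    if not lines or not lines[0].startswith(">Feature "):
        raise ConsistencyError("feature table must start with '>Feature '")
    seq_id = lines[0][len(">Feature "):]
    features: list[FeatureEntry] = []
    current: FeatureEntry | None = None
    for line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        if line.startswith("\t\t\t"):
            if current is None:
                raise ConsistencyError("qualifier before any feature")
            current.qualifiers.append((cols[3], cols[4]))
        elif len(cols) == 3:
            start, end, key = int(cols[0]), int(cols[1]), cols[2]
            if key in _UTR_KEYS:
                if current is None or current.feature_kind != "mRNA":
                    raise ConsistencyError(
                        f"{key} block outside an mRNA feature")
                current.utr_annotations.append((key, start, end))
            else:
                current = FeatureEntry(key, [(start, end)])
                features.append(current)
        elif len(cols) == 2:
            if current is None:
                raise ConsistencyError("continuation interval before a feature")
            current.intervals.append((int(cols[0]), int(cols[1])))
        else:
            raise ConsistencyError(f"unparseable feature-table line: {line!r}")
    return seq_id, features


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def validate_submission(record: SubmissionRecord) -> None:
    """Cross-check a record's features against its sequence.

    The gene feature must span position 1 to the sequence length; mRNA
    intervals must equal CDS intervals plus the UTR annotations, disjoint.
    """
    length = len(record.sequence)
    by_kind = {f.feature_kind: f for f in record.features}
    gene = by_kind.get("gene")
    if gene is None or gene.intervals != [(1, length)]:
        raise ConsistencyError(
            f"gene feature must span (1, {length}) exactly")
    mrna, cds = by_kind.get("mRNA"), by_kind.get("CDS")
    if mrna is None or cds is None:
        raise ConsistencyError("record needs mRNA and CDS features")
    utrs = [(s, e) for _, s, e in mrna.utr_annotations]
    if sorted(cds.intervals + utrs) != sorted(mrna.intervals):
        raise ConsistencyError(
            "mRNA intervals must be the CDS intervals plus the UTRs")
    covered = sorted(mrna.intervals)
    for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
        if s2 <= e1:
            raise ConsistencyError("mRNA intervals overlap")


def write_submission_bundle(
    samples_models: Iterable[tuple[SampleNovelty, GeneModel, str]],
    outdir,
    wrap: int = DEFAULT_WRAP,
) -> dict[str, Path]:
    """Emit the full submission bundle for a batch.

    Writes ``master.fasta``, one ``{seq_id}.tbl`` per record, and a
    ``manifest.tsv`` of seq_id, description and the written mutation
    sentence.  Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, sentences = [], []
    for sample, model, consensus in samples_models:
        record = build_submission(sample, model, consensus)
        validate_submission(record)
        records.append(record)
        sentences.append(describe_mutation(
            sample.sample_id, sample.allele_name, sample.characterization))
    _check_batch(records)
    paths = {"fasta": outdir / "master.fasta"}
    write_fasta(records, paths["fasta"], wrap)
    for record in records:
        p = outdir / f"{record.seq_id}.tbl"
        write_feature_table(record, p)
        paths[f"tbl:{record.seq_id}"] = p
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("seq_id\tdescription\tmutation_sentence\n")
        for record, sentence in zip(records, sentences):
            fh.write(f"{record.seq_id}\t{record.description}\t{sentence}\n")
    paths["manifest"] = manifest
    return paths
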