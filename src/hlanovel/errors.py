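"""Exception hierarchy.

Errors subclass the builtin the situation corresponds to (ValueError for bad
values, KeyError for missing keys) so callers that do not know this package
still fail in the idiomatic way.
"""


class HlaNovelError(Exception):
    """Base class for all errors raised by hlanovel."""


class PositionOutOfRangeError(HlaNovelError, ValueError):
    """A genomic position falls outside the gene model."""


class NotCodingError(HlaNovelError, ValueError):
    """A codon was requested for a position that is not in the CDS."""


class UnsupportedBaseError(HlaNovelError, ValueError):
    """A nucleotide outside {A, C, G, T} was encountered."""


class AlignmentUnsupportedError(HlaNovelError, ValueError):
    """Reference and consensus differ by more than the supported regime
    (substitutions plus at most one short indel); supply pre-called variants."""


class ClassificationError(HlaNovelError, ValueError):
    """A substitution cannot be assigned a mutation class (e.g. stop-loss)."""


class NotScorableError(HlaNovelError, ValueError):
    """Impact scoring was requested for a non-missense characterization or a
    non-standard residue."""


class ModelDefinitionError(HlaNovelError, ValueError):
    """A gene-model definition violates its invariants."""


class ConsistencyError(HlaNovelError, ValueError):
    """Submission record pieces disagree (lengths, intervals, identifiers)."""


class BatchError(HlaNovelError, ValueError):
    """A submission batch is empty or contains duplicate sequence IDs."""


class ConfigError(HlaNovelError, ValueError):
    """A simulation configuration is infeasible or inconsistent."""


class InfeasibleError(HlaNovelError, RuntimeError):
    """A requested mutation class cannot be induced in the given model."""
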