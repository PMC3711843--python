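"""Typed exceptions shared across the pipeline.

Every parser and simulator failure mode raises one of these rather than a
bare ValueError, so callers (and the test suite) can distinguish a malformed
input from a genuine bug.
"""


class MarkermineError(Exception):
    """Base class for all package errors."""


class SequenceFormatError(MarkermineError):
    """Malformed FASTA/FASTQ content (bad character, duplicate id, ...)."""


class TableFormatError(MarkermineError):
    """Malformed TSV table (missing positions, bad copy class, ...)."""


class CoordinateError(TableFormatError):
    """A position violates the 1-based inclusive convention of emitted tables."""


class SizingError(MarkermineError):
    """A simulation config that cannot admit the required marker geometry."""


class CleanFlankSpacingError(MarkermineError):
    """Clean-flank mode requested at a SNP rate too high for 102 bp spacing."""


class ClassificationError(MarkermineError):
    """A paralog family that cannot be classified (e.g. single line only)."""


class PipelineInputError(MarkermineError):
    """A pipeline stage is enabled but its inputs cannot be produced."""


class MappingError(MarkermineError):
    """Invalid genotype data or marker map for two-point analysis."""
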