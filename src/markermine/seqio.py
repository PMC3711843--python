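"""Readers and writers for every on-disk format the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; this module adds the strict
validation the pipeline relies on (unique ids, restricted alphabet with the
error position reported) plus the raw-read quality filter used upstream of
assembly: reads with more than 30% of bases below Phred 20 are removed on
the full-length read, and the low-quality 31-base tail is then trimmed from
each survivor.

TSV writers emit a leading ``# markermine-schema:`` comment naming the
schema version; readers skip comment lines.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import CoordinateError, SequenceFormatError, TableFormatError

SCHEMA_VERSION = "1"

#: bases permitted in simulated alleles and contigs
STRICT_ALPHABET = frozenset("ACGTN")
#: full nucleotide ambiguity alphabet, permitted only in assay outputs
IUPAC_ALPHABET = frozenset("ACGTNRYSWKMBDHV")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (uppercase, validated alphabet)."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise SequenceFormatError(
                f"read {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _validate_sequence(seq_id: str, seq: str, alphabet: frozenset) -> None:
    for offset, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceFormatError(
                f"record {seq_id!r}: invalid character {ch!r} at offset {offset}"
            )


def read_fasta(path, alphabet: str = "strict") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Parameters
    ----------
    alphabet:
        ``"strict"`` permits A/C/G/T/N only (simulated alleles, contigs);
        ``"iupac"`` additionally permits ambiguity codes (assay outputs).

    Raises
    ------
    SequenceFormatError
        On a duplicate id or a character outside the chosen alphabet,
        naming the offending id and offset.
    """
    allowed = STRICT_ALPHABET if alphabet == "strict" else IUPAC_ALPHABET
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise SequenceFormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise SequenceFormatError(f"record {rec.id!r}: empty sequence")
            _validate_sequence(rec.id, seq, allowed)
            desc = rec.description[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream Sanger (Phred+33) FASTQ reads."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


@dataclass
class QCReport:
    """Bookkeeping for :func:`filter_reads`."""

    n_input: int = 0
    n_dropped_lowq: int = 0
    n_dropped_short: int = 0
    n_surviving: int = 0


def filter_reads(
    reads: Iterable[ReadRecord],
    max_lowq_fraction: float = 0.30,
    lowq_threshold: int = 20,
    tail_trim: int = 31,
) -> tuple[list[ReadRecord], QCReport]:
    """Quality-filter raw reads, then trim the low-quality tail.

    A read is dropped when strictly more than ``max_lowq_fraction`` of its
    bases (evaluated on the full, untrimmed length) have Phred quality below
    ``lowq_threshold``; a read at exactly the boundary fraction is kept.
    Survivors lose their final ``tail_trim`` bases.  A read that passes the
    fraction test but is not longer than ``tail_trim`` is dropped and
    counted separately.  Input order is preserved.
    """
    report = QCReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        n = len(read.sequence)
        n_low = sum(1 for q in read.qualities if q < lowq_threshold)
        if n_low > max_lowq_fraction * n:
            report.n_dropped_lowq += 1
            continue
        if n < tail_trim + 1:
            report.n_dropped_short += 1
            continue
        kept.append(
            ReadRecord(
                read.id,
                read.sequence[: n - tail_trim],
                list(read.qualities[: n - tail_trim]),
            )
        )
        report.n_surviving += 1
    return kept, report


def filter_read_pairs(
    reads1: Iterable[ReadRecord],
    reads2: Iterable[ReadRecord],
    **kwargs,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], QCReport, QCReport]:
    """Filter both mates and keep only pairs in which both survive.

    Reads whose mate failed the quality filter are dropped (no orphans),
    mirroring paired-end bookkeeping after low-quality read removal.
    """
    kept1, rep1 = filter_reads(reads1, **kwargs)
    kept2, rep2 = filter_reads(reads2, **kwargs)
    by_id1 = {r.id: r for r in kept1}
    pairs = [(by_id1[r2.id], r2) for r2 in kept2 if r2.id in by_id1]
    return pairs, rep1, rep2


# ---------------------------------------------------------------------------
# TSV schemas


def _write_tsv(df: pd.DataFrame, path, schema: str) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# markermine-schema: {schema} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_depth_table(depths: dict[str, np.ndarray], path) -> None:
    """Write per-base depth as (contig_id, position_1based, depth) rows."""
    frames = []
    for contig_id, arr in depths.items():
        frames.append(
            pd.DataFrame(
                {
                    "contig_id": contig_id,
                    "position": np.arange(1, len(arr) + 1),
                    "depth": np.asarray(arr, dtype=int),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["contig_id", "position", "depth"]
    )
    _write_tsv(table, path, "depth")


def read_depth_table(path) -> dict[str, np.ndarray]:
    """Read a per-base depth TSV into one array per contig.

    Positions must be 1-based and contiguous from 1 for each contig;
    gaps or a position 0 raise :class:`CoordinateError` listing the contig.
    """
    df = _read_tsv(path)
    required = {"contig_id", "position", "depth"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"depth table missing columns {sorted(required - set(df.columns))}"
        )
    out: dict[str, np.ndarray] = {}
    for contig_id, sub in df.groupby("contig_id", sort=False):
        pos = sub["position"].to_numpy()
        if (pos < 1).any():
            raise CoordinateError(
                f"contig {contig_id!r}: positions must be 1-based (found "
                f"{int(pos.min())})"
            )
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(np.sort(pos), expected):
            missing = sorted(set(range(1, int(pos.max()) + 1)) - set(pos.tolist()))
            raise CoordinateError(
                f"contig {contig_id!r}: missing positions {missing[:10]}"
            )
        depth = np.empty(len(pos), dtype=int)
        depth[pos - 1] = sub["depth"].to_numpy()
        if (depth < 0).any():
            raise TableFormatError(f"contig {contig_id!r}: negative depth")
        out[str(contig_id)] = depth
    return out


def validate_depth_against_fasta(
    depths: dict[str, np.ndarray], contigs: Iterable[SequenceRecord]
) -> None:
    """Check that every depth array matches its contig's length exactly."""
    lengths = {r.id: len(r.sequence) for r in contigs}
    for contig_id, arr in depths.items():
        if contig_id not in lengths:
            raise TableFormatError(f"depth for unknown contig {contig_id!r}")
        if len(arr) != lengths[contig_id]:
            raise TableFormatError(
                f"contig {contig_id!r}: depth length {len(arr)} != sequence "
                f"length {lengths[contig_id]}"
            )


def write_paralog_table(table: pd.DataFrame, path) -> None:
    _write_tsv(
        table[["gene_id", "family_id", "copy_class", "paralog_index"]],
        path,
        "paralog",
    )


def read_paralog_table(path) -> pd.DataFrame:
    """Read the gene → family map; every gene appears once, copy class 1–3."""
    df = _read_tsv(path)
    required = {"gene_id", "family_id", "copy_class", "paralog_index"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"paralog table missing columns {sorted(required - set(df.columns))}"
        )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise TableFormatError(f"gene {dup!r} listed more than once")
    bad = ~df["copy_class"].isin([1, 2, 3])
    if bad.any():
        gene = df.loc[bad, "gene_id"].iloc[0]
        cls = df.loc[bad, "copy_class"].iloc[0]
        raise TableFormatError(f"gene {gene!r}: copy class {cls} outside {{1,2,3}}")
    return df
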