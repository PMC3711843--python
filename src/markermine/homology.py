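"""Assign de-novo contigs to reference gene models by local alignment.

A contig is homologous to a gene model when some local alignment reaches
>= 80% identity over >= 100 aligned columns (both strands searched).  All
contigs of one line matching a gene model form that line's *homolog* of the
gene; genes are then summarised by paralog copy class (single / two / three
copies).

Alignment uses exact k-mer seeding to select candidate gene models and
Biopython's ``PairwiseAligner`` (Smith–Waterman, affine gaps) for the actual
extension.  Identity is computed over aligned columns *including* gap
columns, and N never counts as a match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: scoring used by both the production aligner and the test oracle
MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -7.0
GAP_EXTEND = -2.0


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentHit:
    """One local alignment between a contig (query) and a gene model."""

    query_id: str
    subject_id: str
    identity: float            # matches / aligned columns (gaps are columns)
    matches: int
    aligned_length: int        # aligned columns including gap columns
    q_start: int               # 1-based inclusive, original query orientation
    q_end: int
    s_start: int
    s_end: int
    strand: str                # '+' or '-'
    score: float
    # ungapped blocks, 0-based half-open, query in *aligned* orientation
    blocks: tuple = ()
    line: str | None = None


@dataclass
class HomologGroup:
    """All contigs (per line) assigned to one reference gene model."""

    gene_id: str
    copy_class: int
    members: dict = field(default_factory=dict)  # line -> list[AlignmentHit]

    def contig_ids(self, line: str) -> list[str]:
        return [h.query_id for h in self.members.get(line, [])]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _count_columns(subject: str, query: str, s_blocks, q_blocks):
    """Matches and total columns of an alignment given its ungapped blocks."""
    matches = 0
    columns = 0
    for i, ((ss, se), (qs, qe)) in enumerate(zip(s_blocks, q_blocks)):
        a = np.frombuffer(subject[ss:se].encode(), dtype="S1")
        b = np.frombuffer(query[qs:qe].encode(), dtype="S1")
        valid = (a != b"N") & (b != b"N")
        matches += int(np.count_nonzero((a == b) & valid))
        columns += se - ss
        if i > 0:
            columns += (ss - s_blocks[i - 1][1]) + (qs - q_blocks[i - 1][1])
    return matches, columns


def align_pair(
    subject: str, query: str, aligner: Align.PairwiseAligner | None = None
):
    """Best local alignment of ``query`` against ``subject`` (one strand).

    Returns ``(score, matches, columns, s_interval, q_interval, blocks)``
    with 0-based half-open intervals, or ``None`` when no positive-scoring
    alignment exists.
    """
    aligner = aligner or _make_aligner()
    alns = aligner.align(subject, query)
    try:
        if alns.score <= 0:
            return None
        aln = alns[0]  # first co-optimal alignment; never enumerate them all
    except (IndexError, AttributeError):
        return None
    s_blocks, q_blocks = (
        [tuple(map(int, b)) for b in aln.aligned[0]],
        [tuple(map(int, b)) for b in aln.aligned[1]],
    )
    matches, columns = _count_columns(subject, query, s_blocks, q_blocks)
    s_iv = (s_blocks[0][0], s_blocks[-1][1])
    q_iv = (q_blocks[0][0], q_blocks[-1][1])
    blocks = tuple(
        (qs, qe, ss, se) for (ss, se), (qs, qe) in zip(s_blocks, q_blocks)
    )
    return aln.score, matches, columns, s_iv, q_iv, blocks


def _kmer_index(genes: Mapping[str, str], k: int) -> dict[str, set]:
    index: dict[str, set] = {}
    for gene_id, seq in genes.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(gene_id)
    return index


def _as_dict(records) -> dict[str, str]:
    if isinstance(records, Mapping):
        return dict(records)
    return {r.id: r.sequence for r in records}


def align_contigs(
    contigs,
    gene_models,
    min_identity: float = 0.80,
    min_length: int = 100,
    k: int = 15,
    min_seeds: int = 2,
    line: str | None = None,
) -> list[AlignmentHit]:
    """Align every contig to candidate gene models on both strands.

    Candidates are gene models sharing at least ``min_seeds`` exact
    ``k``-mers with the contig (in either orientation); lowering ``k`` or
    ``min_seeds`` trades speed for sensitivity, down to near-exhaustive
    search.  Hits below ``(min_identity, min_length)`` are suppressed.
    Gene models shorter than ``min_length`` are skipped with a warning.
    """
    contigs = _as_dict(contigs)
    genes = _as_dict(gene_models)
    usable = {}
    for gene_id, seq in genes.items():
        if len(seq) < min_length:
            logger.warning(
                "gene %s shorter than min_length=%d; skipped", gene_id, min_length
            )
            continue
        usable[gene_id] = seq
    index = _kmer_index(usable, k)
    aligner = _make_aligner()
    hits: list[AlignmentHit] = []
    for contig_id in sorted(contigs):
        cseq = contigs[contig_id]
        for strand in "+-":
            oriented = cseq if strand == "+" else revcomp(cseq)
            seed_counts: dict[str, int] = {}
            for i in range(len(oriented) - k + 1):
                for gene_id in index.get(oriented[i : i + k], ()):
                    seed_counts[gene_id] = seed_counts.get(gene_id, 0) + 1
            candidates = {g for g, c in seed_counts.items() if c >= min_seeds}
            for gene_id in sorted(candidates):
                res = align_pair(usable[gene_id], oriented, aligner)
                if res is None:
                    continue
                score, matches, columns, s_iv, q_iv, blocks = res
                if columns < min_length:
                    continue
                identity = matches / columns
                if identity < min_identity:
                    continue
                if strand == "+":
                    q_start, q_end = q_iv[0] + 1, q_iv[1]
                else:
                    n = len(cseq)
                    q_start, q_end = n - q_iv[1] + 1, n - q_iv[0]
                hits.append(
                    AlignmentHit(
                        query_id=contig_id,
                        subject_id=gene_id,
                        identity=identity,
                        matches=matches,
                        aligned_length=columns,
                        q_start=q_start,
                        q_end=q_end,
                        s_start=s_iv[0] + 1,
                        s_end=s_iv[1],
                        strand=strand,
                        score=float(score),
                        blocks=blocks,
                        line=line,
                    )
                )
    return hits


def _hit_rank(hit: AlignmentHit):
    # highest identity, then longest alignment, then smallest gene id
    return (-hit.identity, -hit.aligned_length, hit.subject_id)


def assign_homologs(
    hits: Sequence[AlignmentHit],
    paralog_table: pd.DataFrame,
    min_identity: float = 0.80,
    min_length: int = 100,
) -> tuple[list[HomologGroup], list[str]]:
    """Assign each contig to its single best gene model and group by gene.

    The best gene for a contig is the qualifying hit with the highest
    identity, ties broken by longer aligned length, then by lexicographic
    gene id — a deterministic, input-order-free rule.  Contigs with no
    qualifying hit are returned unassigned.
    """
    copy_class = dict(
        zip(paralog_table["gene_id"], paralog_table["copy_class"].astype(int))
    )
    by_contig: dict[tuple, list[AlignmentHit]] = {}
    all_contigs: set[tuple] = set()
    for hit in hits:
        key = (hit.line, hit.query_id)
        all_contigs.add(key)
        if hit.identity >= min_identity and hit.aligned_length >= min_length:
            by_contig.setdefault(key, []).append(hit)
    groups: dict[str, HomologGroup] = {}
    unassigned: list[str] = []
    for key in sorted(all_contigs, key=lambda t: (t[0] or "", t[1])):
        line, contig_id = key
        qualifying = by_contig.get(key)
        if not qualifying:
            unassigned.append(contig_id)
            continue
        best = min(qualifying, key=_hit_rank)
        gene = best.subject_id
        if gene not in copy_class:
            raise KeyError(f"gene {gene!r} missing from paralog table")
        group = groups.setdefault(gene, HomologGroup(gene, copy_class[gene]))
        group.members.setdefault(line or "default", []).append(best)
    return [groups[g] for g in sorted(groups)], unassigned


def summarize_copy_classes(
    groups: Iterable[HomologGroup], paralog_table: pd.DataFrame
) -> pd.DataFrame:
    """Count genes with >= 1 assigned contig per line, split by copy class.

    Returns a line × copy-class DataFrame (columns 1, 2, 3).
    """
    known = set(paralog_table["gene_id"])
    lines: set[str] = set()
    rows: list[tuple[str, str, int]] = []
    for group in groups:
        if group.gene_id not in known:
            raise KeyError(f"gene {group.gene_id!r} missing from paralog table")
        for line, members in group.members.items():
            if members:
                lines.add(line)
                rows.append((line, group.gene_id, group.copy_class))
    table = pd.DataFrame(rows, columns=["line", "gene_id", "copy_class"])
    out = pd.DataFrame(0, index=sorted(lines), columns=[1, 2, 3])
    if len(table):
        counts = (
            table.drop_duplicates()
            .groupby(["line", "copy_class"])["gene_id"]
            .nunique()
        )
        for (line, cls), n in counts.items():
            out.loc[line, cls] = int(n)
    return out


def hits_to_table(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    """BLAST outfmt-6 style 12-column table of hits."""
    rows = []
    for h in hits:
        mismatches = h.aligned_length - h.matches  # includes gap columns
        s_start, s_end = (h.s_start, h.s_end)
        if h.strand == "-":
            s_start, s_end = s_end, s_start
        rows.append(
            (
                h.query_id,
                h.subject_id,
                round(100.0 * h.identity, 2),
                h.aligned_length,
                mismatches,
                max(0, len(h.blocks) - 1),
                h.q_start,
                h.q_end,
                s_start,
                s_end,
                0.0,
                h.score,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )
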