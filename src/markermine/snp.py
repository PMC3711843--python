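"""Inter-line SNV calling from homolog alignments, with depth filtering.

Variants are read off mismatching columns of the local alignment between a
reference gene model and a line's contig (the alignment-based route).  The
comparison is asymmetric, mirroring a reference-CDS versus assembled-contig
design: read depth applies to the contig line only, while the reference is
treated as fully supported.  Sites are then filtered at depth >= 7 and
quality >= 40, and partitioned by paralog copy class.

Columns within ``gap_guard`` bases of an alignment gap are never called —
indel-adjacent columns are alignment artifacts more often than variants.
When no quality column is supplied, a deterministic depth-derived stand-in
``q = min(60, 10 + 5 * depth)`` is used; it is labelled as imputed in all
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import AlignmentHit, revcomp

BASES = frozenset("ACGT")


def imputed_quality(depth: int) -> int:
    """Deterministic stand-in consensus quality derived from depth."""
    return min(60, 10 + 5 * int(depth))


@dataclass
class VariantSite:
    """A single-nucleotide difference between two lines at one gene position."""

    gene_id: str
    position: int              # 1-based, gene-model coordinates
    ref_base: str
    alt_base: str
    line: str | None = None
    contig_id: str | None = None
    contig_position: int | None = None  # 1-based, original contig orientation
    depth: int = 0
    quality: int = 0
    quality_imputed: bool = True
    classification: str = "allelic_snp"   # allelic_snp | psv | conflict
    copy_class: int = 1
    family_id: str | None = None
    paralog_index: int | None = None


@dataclass
class CallReport:
    n_pairs: int = 0
    n_skipped_low_identity: int = 0
    skip_reasons: list = field(default_factory=list)


def call_snps(
    gene_seq: str,
    contig_seq: str,
    hit: AlignmentHit,
    depth: np.ndarray | None = None,
    quality: Mapping[int, int] | None = None,
    min_identity: float = 0.90,
    gap_guard: int = 5,
) -> tuple[list[VariantSite], str | None]:
    """Call unfiltered variant sites from one gene/contig alignment.

    Returns ``(sites, skip_reason)``; ``skip_reason`` is non-None when the
    pair falls below the ``min_identity`` floor and no sites are called.
    Mismatching columns give one site each; columns within ``gap_guard``
    bases of an inter-block gap are excluded.  ``depth`` is indexed in the
    contig's original orientation; ``quality`` maps 1-based gene positions
    to explicit scores and overrides the depth-derived stand-in.
    """
    if hit.identity < min_identity:
        return [], (
            f"identity {hit.identity:.3f} below floor {min_identity:.2f} "
            f"for {hit.query_id} vs {hit.subject_id}"
        )
    if depth is not None and len(depth) < len(contig_seq):
        raise ValueError(
            f"depth track shorter than contig {hit.query_id!r}: "
            f"{len(depth)} < {len(contig_seq)}"
        )
    oriented = contig_seq if hit.strand == "+" else revcomp(contig_seq)
    n_contig = len(contig_seq)
    sites: list[VariantSite] = []
    blocks = hit.blocks
    for bi, (qs, qe, ss, se) in enumerate(blocks):
        lo = qs + gap_guard if bi > 0 else qs
        hi = qe - gap_guard if bi < len(blocks) - 1 else qe
        for q in range(lo, hi):
            s = ss + (q - qs)
            a, b = gene_seq[s], oriented[q]
            if a == b or a not in BASES or b not in BASES:
                continue
            orig_q = q if hit.strand == "+" else n_contig - 1 - q
            d = int(depth[orig_q]) if depth is not None else 0
            gene_pos = s + 1
            if quality is not None and gene_pos in quality:
                qual, imput = int(quality[gene_pos]), False
            else:
                qual, imput = imputed_quality(d), True
            sites.append(
                VariantSite(
                    gene_id=hit.subject_id,
                    position=gene_pos,
                    ref_base=a,
                    alt_base=b,  # gene-frame base of the contig line
                    line=hit.line,
                    contig_id=hit.query_id,
                    contig_position=orig_q + 1,
                    depth=d,
                    quality=qual,
                    quality_imputed=imput,
                )
            )
    sites.sort(key=lambda v: v.position)
    return sites, None


@dataclass
class FilterReport:
    n_input: int = 0
    n_depth_fail: int = 0
    n_quality_fail: int = 0
    n_retained: int = 0


def filter_snps(
    sites: Sequence[VariantSite],
    min_depth: int = 7,
    min_quality: int = 40,
) -> tuple[list[VariantSite], FilterReport]:
    """Retain sites with depth >= ``min_depth`` and quality >= ``min_quality``.

    Both boundaries are inclusive (depth 7 / quality 40 pass; depth 6 or
    quality 39 fail).  The report counts failures of each criterion
    independently, so a site can contribute to both counts.
    """
    report = FilterReport(n_input=len(sites))
    retained = []
    for site in sites:
        depth_ok = site.depth >= min_depth
        quality_ok = site.quality >= min_quality
        if not depth_ok:
            report.n_depth_fail += 1
        if not quality_ok:
            report.n_quality_fail += 1
        if depth_ok and quality_ok:
            retained.append(site)
    report.n_retained = len(retained)
    return retained, report


def partition_by_copy_class(
    sites: Sequence[VariantSite], paralog_table: pd.DataFrame
) -> dict[str, int]:
    """Count sites by the copy class of their gene (Table-4-style split)."""
    copy_class = dict(
        zip(paralog_table["gene_id"], paralog_table["copy_class"].astype(int))
    )
    counts = {"total": len(sites), "single": 0, "two": 0, "three": 0,
              "unclassified": 0}
    names = {1: "single", 2: "two", 3: "three"}
    for site in sites:
        cls = copy_class.get(site.gene_id)
        if cls is None:
            counts["unclassified"] += 1
        else:
            counts[names[cls]] += 1
    return counts


def per_gene_snp_presence(
    sites: Sequence[VariantSite], groups
) -> dict[int, float | None]:
    """Fraction of genes per copy class carrying >= 1 retained SNP.

    The numerator counts genes, not sites.  A copy class with no grouped
    genes yields ``None`` (undefined), never 0.
    """
    genes_with_snp = {s.gene_id for s in sites}
    per_class: dict[int, list[str]] = {1: [], 2: [], 3: []}
    for group in groups:
        per_class[group.copy_class].append(group.gene_id)
    out: dict[int, float | None] = {}
    for cls, genes in per_class.items():
        if not genes:
            out[cls] = None
        else:
            out[cls] = sum(g in genes_with_snp for g in genes) / len(genes)
    return out


def sites_to_table(sites: Iterable[VariantSite]) -> pd.DataFrame:
    rows = [
        (
            s.gene_id, s.position, s.ref_base, s.alt_base, s.line,
            s.contig_id, s.contig_position, s.depth, s.quality,
            "imputed" if s.quality_imputed else "supplied",
            s.copy_class, s.classification,
        )
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "position", "ref_base", "alt_base", "line",
            "contig_id", "contig_position", "depth", "quality",
            "quality_source", "copy_class", "classification",
        ],
    )
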