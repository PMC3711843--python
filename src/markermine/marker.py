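"""The three-criteria marker filter and KASP-style assay target design.

A candidate SNP becomes a marker when
(1) it is flanked by 50 bp of strictly conserved sequence on both sides
    (no substitution, no gap, no N in the 100 flank columns),
(2) the 101 bp window with the variable base at position 51 contains no
    exon–intron junction when placed on the gene's genomic copy, and
(3) the read depth at the SNP base is >= 7 (with quality >= 40).

For genes with two or three paralogs, sites are first classified into
allelic SNPs (one paralog segregates between lines, the others are
line-invariant), paralog-specific variations (PSVs: fixed differences
between paralogs, identical across lines) and conflicts.  An allelic SNP
in a multi-copy gene is accepted only when each sibling paralog can be
discriminated by at least one PSV inside the 50 bp flanks, so that
locus-specific primers can be anchored on the target copy.

Accepted markers are emitted as 101 bp target sequences with the SNP in
bracket notation ``[ref/alt]`` and IUPAC degeneracy codes at residual
(non-discriminating) variable flank positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError
from .homology import AlignmentHit, HomologGroup, align_pair, revcomp
from .snp import VariantSite, call_snps

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

WINDOW = 101
FLANK = 50


@dataclass
class MarkerCandidate:
    """One SNP moving through the filter cascade."""

    variant: VariantSite
    window: str = ""             # contig-line bases, gene frame, 101 bp
    ref_window: str = ""         # reference gene-model bases, 101 bp
    flank_conserved: bool | None = None
    junction_free: bool | None = None
    depth_ok: bool | None = None
    rejection: str | None = None
    classification: str = "allelic_snp"
    psv_offsets: list = field(default_factory=list)  # signed offsets from SNP

    @property
    def marker_id(self) -> str:
        v = self.variant
        return f"{v.line}:{v.gene_id}:{v.position}"

    @property
    def accepted_by_criteria(self) -> bool:
        return bool(self.flank_conserved and self.junction_free and self.depth_ok)


@dataclass
class AssayDesign:
    """A marker's final assay target in bracket notation."""

    marker_id: str
    gene_id: str
    contig_id: str
    direction: str
    snp_position_gene: int
    snp_position_contig: int
    ref_allele: str
    alt_allele: str
    target_sequence: str            # 50 + "[X/Y]" + 50 characters
    depth_acgt: dict
    paralog_specific: bool = False
    psv_annotation: list = field(default_factory=list)


def extract_window(
    sequence: str, position: int, flank: int = FLANK
) -> tuple[str | None, str | None]:
    """Excise the (2*flank + 1) bp window centred on a 1-based position.

    Returns ``(window, None)`` or ``(None, "insufficient_flank")`` when
    fewer than ``flank`` bases exist on either side.  A position outside
    the sequence raises ``ValueError``.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    i = position - 1
    if i < flank or len(sequence) - i - 1 < flank:
        return None, "insufficient_flank"
    return sequence[i - flank : i + flank + 1], None


def check_flank_conservation(
    gene_seq: str,
    oriented_contig: str,
    hit: AlignmentHit,
    position: int,
    flank: int = FLANK,
) -> tuple[bool, str | None, str, str]:
    """Test strict identity of the 100 flank columns through the alignment.

    ``position`` is 1-based in gene coordinates.  Conservation requires the
    whole window to fall inside a single ungapped alignment block (a gap in
    a flank breaks identity) with every flank column matching and free of N.
    Returns ``(conserved, reason, contig_window, ref_window)``; ``reason``
    is ``"uncovered_window"`` when the alignment does not span the window.
    """
    s = position - 1
    lo, hi = s - flank, s + flank  # inclusive gene range of the window
    covering = None
    for qs, qe, ss, se in hit.blocks:
        if ss <= lo and hi < se:
            covering = (qs, qe, ss, se)
            break
    if covering is None:
        span_lo, span_hi = hit.blocks[0][2], hit.blocks[-1][3] - 1
        if lo < span_lo or hi > span_hi:
            return False, "uncovered_window", "", ""
        # covered but split by a gap: gap inside the window breaks identity
        return False, None, "", ""
    qs, qe, ss, se = covering
    q_center = qs + (s - ss)
    contig_window = oriented_contig[q_center - flank : q_center + flank + 1]
    ref_window = gene_seq[lo : hi + 1]
    left_ok = contig_window[:flank] == ref_window[:flank]
    right_ok = contig_window[flank + 1 :] == ref_window[flank + 1 :]
    clean = "N" not in contig_window and "N" not in ref_window
    return left_ok and right_ok and clean, None, contig_window, ref_window


def check_junctions(
    ref_window: str, genomic_seq: str, flank: int = FLANK
) -> tuple[bool | None, str | None]:
    """Test whether the window sits on the genomic copy without a junction.

    The reference-frame window must occur as one contiguous block in the
    gene's genomic (intron-bearing) sequence.  When it does not, the window
    is probed for split mappability: if some prefix/suffix split places the
    two pieces on the genomic copy separated by intervening (intron) bases,
    a junction interrupts the window and the marker fails.  A window that
    maps neither way is rejected with ``"no_genomic_hit"``.
    """
    if ref_window in genomic_seq:
        return True, None
    for t in range(1, len(ref_window)):
        pa = genomic_seq.find(ref_window[:t])
        if pa == -1:
            continue
        pb = genomic_seq.find(ref_window[t:], pa + t + 1)
        if pb != -1:
            return False, None
    return None, "no_genomic_hit"


# ---------------------------------------------------------------------------
# paralog-aware classification


def classify_column(column: Mapping[str, Mapping[str, str | None]]) -> str:
    """Classify one aligned family column.

    ``column`` maps paralog id -> {line -> base or None (missing)}.
    Returns ``invariant``, ``allelic_snp`` (exactly one paralog segregates
    between lines), ``psv`` (no paralog segregates but paralog consensus
    bases differ) or ``conflict`` (two or more paralogs segregate).
    """
    segregating = []
    consensus = {}
    for paralog, by_line in column.items():
        bases = {b for b in by_line.values() if b is not None}
        if len(bases) > 1:
            segregating.append(paralog)
        elif bases:
            consensus[paralog] = next(iter(bases))
    if len(segregating) >= 2:
        return "conflict"
    if len(segregating) == 1:
        return "allelic_snp"
    if len(set(consensus.values())) > 1:
        return "psv"
    return "invariant"


def classify_paralog_sites(
    family_sequences: Mapping[tuple, str]
) -> list[tuple[int, str]]:
    """Label every segregating column of an aligned paralog family.

    ``family_sequences`` maps ``(paralog_id, line_id)`` to equal-length
    aligned sequences.  Missing members are tolerated (simply absent from
    the mapping) and treated as uninformative.  Returns 1-based positions
    with their labels, excluding invariant columns.

    Raises :class:`ClassificationError` when fewer than two lines are
    present — allelic and paralog-specific variation cannot be told apart
    from a single line.
    """
    lines = {line for (_, line) in family_sequences}
    if len(lines) < 2:
        raise ClassificationError(
            "cannot classify: paralog family observed in a single line"
        )
    lengths = {len(s) for s in family_sequences.values()}
    if len(lengths) != 1:
        raise ClassificationError(
            "family sequences must be aligned to equal length"
        )
    (length,) = lengths
    paralogs = sorted({p for (p, _) in family_sequences})
    out = []
    for i in range(length):
        column = {
            p: {
                line: family_sequences[(p, line)][i]
                for (pp, line) in family_sequences
                if pp == p
            }
            for p in paralogs
        }
        label = classify_column(column)
        if label != "invariant":
            out.append((i + 1, label))
    return out


def design_paralog_specific_marker(
    candidate: MarkerCandidate,
    psv_by_sibling: Mapping[str, Sequence[int]],
    residual_variants: Mapping[int, set] | None = None,
    flank: int = FLANK,
    require_both_flanks: bool = False,
) -> tuple[AssayDesign | None, str | None]:
    """Design a locus-specific assay for an allelic SNP in a multi-copy gene.

    ``psv_by_sibling`` maps each sibling paralog id to the signed offsets
    (relative to the SNP, 0 excluded) of PSVs that discriminate the target
    paralog from that sibling.  The design is accepted only when *every*
    sibling has at least one discriminating PSV within the ``flank`` bp on
    some side (both sides when ``require_both_flanks``): primers anchored
    on those bases amplify the target copy only.  PSV positions keep the
    target paralog's own base — they are the discriminators — while
    ``residual_variants`` (signed offset -> extra bases seen at that flank
    position) are rendered as IUPAC degeneracy codes.
    """
    for sibling, offsets in psv_by_sibling.items():
        inside = [o for o in offsets if o != 0 and -flank <= o <= flank]
        if not inside:
            return None, "no_discriminating_psv"
        if require_both_flanks and not (
            any(o < 0 for o in inside) and any(o > 0 for o in inside)
        ):
            return None, "no_discriminating_psv"
    design = _render_design(
        candidate, residual_variants or {}, paralog_specific=True,
        psv_annotation=sorted(
            {o for offs in psv_by_sibling.values() for o in offs
             if o != 0 and -flank <= o <= flank}
        ),
        flank=flank,
    )
    return design, None


def _render_design(
    candidate: MarkerCandidate,
    residual_variants: Mapping[int, set],
    paralog_specific: bool = False,
    psv_annotation: Sequence[int] = (),
    flank: int = FLANK,
) -> AssayDesign:
    v = candidate.variant
    ref_window = candidate.ref_window
    chars = list(ref_window)
    for offset, bases in residual_variants.items():
        idx = flank + offset
        if 0 <= idx < len(chars) and offset != 0:
            chars[idx] = IUPAC_CODES[frozenset(set(bases) | {ref_window[idx]})]
    left = "".join(chars[:flank])
    right = "".join(chars[flank + 1 :])
    target = f"{left}[{v.ref_base}/{v.alt_base}]{right}"
    depth_acgt = {b: 0 for b in "ACGT"}
    depth_acgt[v.alt_base] = v.depth
    return AssayDesign(
        marker_id=candidate.marker_id,
        gene_id=v.gene_id,
        contig_id=v.contig_id or "",
        direction="+",
        snp_position_gene=v.position,
        snp_position_contig=v.contig_position or 0,
        ref_allele=v.ref_base,
        alt_allele=v.alt_base,
        target_sequence=target,
        depth_acgt=depth_acgt,
        paralog_specific=paralog_specific,
        psv_annotation=list(psv_annotation),
    )


# ---------------------------------------------------------------------------
# the cascade


@dataclass
class FunnelReport:
    """Candidate counts after each criterion, in the narrative order."""

    n_eligible: int = 0        # called SNPs with an extractable window
    n_flank: int = 0           # + conserved 50 bp flanks
    n_junction: int = 0        # + junction-free 101 bp window
    n_depth: int = 0           # + read depth / quality passing
    n_no_window: int = 0       # called but window not extractable
    n_conflict: int = 0        # multi-copy sites with conflicting patterns
    n_psv_rejected: int = 0    # allelic but no discriminating PSV in flanks

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_eligible, self.n_flank, self.n_junction, self.n_depth)


@dataclass
class CascadeResult:
    accepted: list = field(default_factory=list)       # AssayDesign
    candidates: list = field(default_factory=list)     # MarkerCandidate
    funnel: FunnelReport = field(default_factory=FunnelReport)
    skipped_pairs: list = field(default_factory=list)

    @property
    def accepted_ids(self) -> set:
        return {d.marker_id for d in self.accepted}


def _best_hit(group: HomologGroup, line: str) -> AlignmentHit | None:
    members = group.members.get(line)
    if not members:
        return None
    return min(members, key=lambda h: (-h.identity, -h.aligned_length, h.query_id))


def _map_position(blocks, s: int) -> int | None:
    """Map a 0-based subject position through alignment blocks to the query."""
    for qs, qe, ss, se in blocks:
        if ss <= s < se:
            return qs + (s - ss)
    return None


def run_cascade(
    gene_models: Mapping[str, str],
    genomic: Mapping[str, str],
    paralog_table: pd.DataFrame,
    contigs: Mapping[str, str],
    depths: Mapping[str, np.ndarray],
    groups: Sequence[HomologGroup],
    line: str,
    min_pair_identity: float = 0.90,
    flank: int = FLANK,
    min_depth: int = 7,
    min_quality: int = 40,
    gap_guard: int = 5,
    require_both_flank_psv: bool = False,
) -> CascadeResult:
    """Run the full marker filter over one line's homolog groups.

    For every gene with an assigned contig at >= ``min_pair_identity``,
    SNPs are called from the alignment, each gets the three criteria
    evaluated independently (so the funnel is reported in the narrative
    order flank -> junction -> depth while the accepted set is
    order-free), and multi-copy genes additionally pass the PSV gate.
    """
    result = CascadeResult()
    info = paralog_table.set_index("gene_id")
    by_family: dict[str, list[str]] = {}
    for gene_id, row in info.iterrows():
        by_family.setdefault(row["family_id"], []).append(gene_id)
    group_by_gene = {g.gene_id: g for g in groups}
    # pairwise reference maps between paralogs, computed lazily per family
    paralog_maps: dict[tuple, tuple | None] = {}

    def sibling_map(a: str, b: str):
        key = (a, b)
        if key not in paralog_maps:
            res = align_pair(gene_models[b], gene_models[a])
            # store blocks so _map_position maps target-gene -> sibling coords
            paralog_maps[key] = None if res is None else tuple(
                (ss, se, qs, qe) for qs, qe, ss, se in res[5]
            )
        return paralog_maps[key]

    for group in sorted(groups, key=lambda g: g.gene_id):
        hit = _best_hit(group, line)
        if hit is None:
            continue
        gene_id = group.gene_id
        gene_seq = gene_models[gene_id]
        contig_seq = contigs[hit.query_id]
        oriented = contig_seq if hit.strand == "+" else revcomp(contig_seq)
        sites, skip = call_snps(
            gene_seq, contig_seq, hit,
            depth=depths.get(hit.query_id),
            min_identity=min_pair_identity,
            gap_guard=gap_guard,
        )
        if skip is not None:
            result.skipped_pairs.append(skip)
            continue
        row = info.loc[gene_id]
        family = row["family_id"]
        copy_class = int(row["copy_class"])
        siblings = [g for g in by_family[family] if g != gene_id]
        for site in sites:
            site.copy_class = copy_class
            site.family_id = family
            site.paralog_index = int(row["paralog_index"])
            cand = MarkerCandidate(variant=site)
            conserved, reason, window, ref_window = check_flank_conservation(
                gene_seq, oriented, hit, site.position, flank
            )
            if reason == "uncovered_window":
                cand.rejection = reason
                result.funnel.n_no_window += 1
                result.candidates.append(cand)
                continue
            s0 = site.position - 1
            if s0 < flank or len(gene_seq) - s0 - 1 < flank:
                cand.rejection = "insufficient_flank"
                result.funnel.n_no_window += 1
                result.candidates.append(cand)
                continue
            cand.window = window
            cand.ref_window = ref_window or gene_seq[s0 - flank : s0 + flank + 1]
            cand.flank_conserved = conserved
            junction_free, jreason = check_junctions(
                cand.ref_window, genomic[gene_id], flank
            )
            if jreason == "no_genomic_hit":
                cand.rejection = jreason
                cand.junction_free = False
            else:
                cand.junction_free = bool(junction_free)
            cand.depth_ok = site.depth >= min_depth and site.quality >= min_quality
            result.funnel.n_eligible += 1
            if cand.flank_conserved:
                result.funnel.n_flank += 1
                if cand.junction_free:
                    result.funnel.n_junction += 1
                    if cand.depth_ok:
                        result.funnel.n_depth += 1
            if not cand.accepted_by_criteria:
                result.candidates.append(cand)
                continue
            if copy_class == 1:
                result.accepted.append(_render_design(cand, {}))
                result.candidates.append(cand)
                continue
            # multi-copy: classify the column across the family, then gate on PSVs
            column = {gene_id: {"REF": site.ref_base, line: site.alt_base}}
            residual: dict[int, set] = {}
            psv_by_sibling: dict[str, list[int]] = {}
            for sib in siblings:
                smap = sibling_map(gene_id, sib)
                sib_hit = None
                sib_group = group_by_gene.get(sib)
                if sib_group is not None:
                    sib_hit = _best_hit(sib_group, line)
                sib_ref = sib_line = None
                if smap is not None:
                    sp = _map_position(smap, s0)
                    if sp is not None:
                        sib_ref = gene_models[sib][sp]
                        if sib_hit is not None:
                            qp = _map_position(sib_hit.blocks, sp)
                            if qp is not None:
                                sib_oriented = (
                                    contigs[sib_hit.query_id]
                                    if sib_hit.strand == "+"
                                    else revcomp(contigs[sib_hit.query_id])
                                )
                                sib_line = sib_oriented[qp]
                column[sib] = {"REF": sib_ref, line: sib_line}
                # discriminating PSVs and residual sibling variation in window
                offsets: list[int] = []
                if smap is not None:
                    for off in range(-flank, flank + 1):
                        g_pos = s0 + off
                        if g_pos < 0 or g_pos >= len(gene_seq):
                            continue
                        sp = _map_position(smap, g_pos)
                        if sp is None:
                            if off != 0:
                                offsets.append(off)  # indel discriminates
                            continue
                        if off != 0 and gene_models[sib][sp] != gene_seq[g_pos]:
                            offsets.append(off)
                        if sib_hit is not None and off != 0:
                            qp = _map_position(sib_hit.blocks, sp)
                            if qp is not None:
                                sib_oriented = (
                                    contigs[sib_hit.query_id]
                                    if sib_hit.strand == "+"
                                    else revcomp(contigs[sib_hit.query_id])
                                )
                                b = sib_oriented[qp]
                                if b != gene_models[sib][sp] and b in "ACGT":
                                    residual.setdefault(off, set()).add(b)
                psv_by_sibling[sib] = offsets
            label = classify_column(column)
            cand.classification = label
            if label == "conflict":
                cand.rejection = "conflict"
                result.funnel.n_conflict += 1
                result.candidates.append(cand)
                continue
            design, dreason = design_paralog_specific_marker(
                cand, psv_by_sibling,
                residual_variants=residual,
                flank=flank,
                require_both_flanks=require_both_flank_psv,
            )
            if design is None:
                cand.rejection = dreason
                result.funnel.n_psv_rejected += 1
            else:
                cand.psv_offsets = design.psv_annotation
                result.accepted.append(design)
            result.candidates.append(cand)
    return result


# ---------------------------------------------------------------------------
# assay table IO


def emit_assay_table(designs: Iterable[AssayDesign]) -> pd.DataFrame:
    """Tabulate accepted markers with bracketed target sequences.

    Columns mirror a marker-development worksheet: identifiers, alignment
    direction, the SNP position in gene-model and contig frames, per-base
    depth of A/T/G/C at the tagged position, and the rendered target.
    """
    rows = []
    for d in designs:
        rows.append(
            (
                d.marker_id, d.gene_id, d.contig_id, d.direction,
                d.snp_position_gene, d.snp_position_contig,
                d.depth_acgt["A"], d.depth_acgt["T"],
                d.depth_acgt["G"], d.depth_acgt["C"],
                d.paralog_specific,
                ",".join(str(o) for o in d.psv_annotation),
                d.target_sequence,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id", "gene_id", "contig_id", "direction",
            "snp_position_gene", "snp_position_contig",
            "depth_A", "depth_T", "depth_G", "depth_C",
            "paralog_specific", "psv_offsets", "sequence",
        ],
    )


def parse_assay_table(table: pd.DataFrame) -> list[AssayDesign]:
    """Inverse of :func:`emit_assay_table` (round-trip safe)."""
    designs = []
    for _, r in table.iterrows():
        seq = r["sequence"]
        lb = seq.index("[")
        ref, alt = seq[lb + 1], seq[lb + 3]
        psv = (
            [int(x) for x in str(r["psv_offsets"]).split(",") if x not in ("", "nan")]
            if not pd.isna(r["psv_offsets"]) else []
        )
        designs.append(
            AssayDesign(
                marker_id=r["marker_id"],
                gene_id=r["gene_id"],
                contig_id=r["contig_id"],
                direction=r["direction"],
                snp_position_gene=int(r["snp_position_gene"]),
                snp_position_contig=int(r["snp_position_contig"]),
                ref_allele=ref,
                alt_allele=alt,
                target_sequence=seq,
                depth_acgt={
                    "A": int(r["depth_A"]), "T": int(r["depth_T"]),
                    "G": int(r["depth_G"]), "C": int(r["depth_C"]),
                },
                paralog_specific=bool(r["paralog_specific"]),
                psv_annotation=psv,
            )
        )
    return designs
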