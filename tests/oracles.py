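"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available —
full dynamic programming, exhaustive regex enumeration, or direct sequence
diffing — sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import re

import numpy as np
from numba import njit

# scoring mirrors markermine.homology so scores are directly comparable
MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -7.0
GAP_EXTEND = -2.0


@njit(cache=False)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def smith_waterman(a: str, b: str):
    """Optimal local alignment of two sequences by full Gotoh DP.

    Returns ``(score, matches, columns)`` for the best-scoring local
    alignment, tracing back with a diagonal-first preference.
    """
    ac = np.frombuffer(a.encode(), dtype=np.uint8)
    bc = np.frombuffer(b.encode(), dtype=np.uint8)
    H, E, F, best, i, j = _gotoh_fill(ac, bc, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
    matches = 0
    columns = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            s = MATCH if ac[i - 1] == bc[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + s:
                columns += 1
                if ac[i - 1] == bc[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i, j] == H[i, j - 1] + GAP_OPEN:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] + GAP_OPEN:
                state = "H"
            i -= 1
    return best, matches, columns


def _primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def regex_ssrs(sequence: str, minima: dict) -> set:
    """All maximal perfect SSR runs found by exhaustive regex matching.

    Returns a set of ``(start_1based, unit_length, repeat_count)`` triples
    for primitive units only, truncated to whole repeat units.
    """
    found = set()
    for u in range(1, 7):
        mc = minima[u]
        pattern = re.compile(r"([ACGT]{%d})\1{%d,}" % (u, mc - 1))
        for m in pattern.finditer(sequence):
            unit = m.group(1)
            if not _primitive(unit):
                continue
            count = len(m.group(0)) // u
            found.add((m.start() + 1, u, count))
    return found


# ---------------------------------------------------------------------------
# funnel fixture: disjoint planted criterion failures with known counts


def build_funnel_fixture(
    n_pass=55, n_flank_fail=20, n_junction_fail=15, n_depth_fail=10, seed=0
):
    """Single-copy genes with exactly one SNP each and disjoint failures.

    Flank failures carry a 1 bp deletion 30 bp from the SNP, junction
    failures an intron 20 bp inside the window, depth failures a constant
    depth of 6; every other gene passes all three criteria.  Returns
    ``(gene_models, genomic, paralog_table, contigs, depths, funnel)``
    where ``funnel`` is the stage-wise count tuple computed by arithmetic
    on the construction.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def rand(n):
        return rng.choice(bases, size=n).tobytes().decode()

    kinds = (
        ["pass"] * n_pass
        + ["flank"] * n_flank_fail
        + ["junction"] * n_junction_fail
        + ["depth"] * n_depth_fail
    )
    gene_models, genomic, contigs, depths = {}, {}, {}, {}
    rows = []
    for i, kind in enumerate(kinds):
        gene_id = f"G{i:03d}.1"
        gene = rand(401)
        snp_pos = 200  # 0-based
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[gene[snp_pos]]
        contig = gene[:snp_pos] + alt + gene[snp_pos + 1:]
        if kind == "flank":
            contig = contig[:230] + contig[231:]  # deletion at offset +30
        if kind == "junction":
            genomic[gene_id] = gene[:220] + rand(80) + gene[220:]
        else:
            genomic[gene_id] = gene[:390] + rand(80) + gene[390:]
        gene_models[gene_id] = gene
        cid = f"L1@{gene_id}"
        contigs[cid] = contig
        depths[cid] = np.full(len(contig), 6 if kind == "depth" else 10)
        rows.append((gene_id, f"G{i:03d}", 1, 1))
    table = pd.DataFrame(
        rows, columns=["gene_id", "family_id", "copy_class", "paralog_index"]
    )
    n = len(kinds)
    funnel = (
        n,
        n - n_flank_fail,
        n - n_flank_fail - n_junction_fail,
        n - n_flank_fail - n_junction_fail - n_depth_fail,
    )
    return gene_models, genomic, table, contigs, depths, funnel


# ---------------------------------------------------------------------------
# marker-criteria oracle: everything re-derived from raw sequences


def derive_junctions(cds: str, genomic_seq: str, anchor: int = 30) -> tuple:
    """Recover intron insertion offsets by walking genomic vs coding copy.

    Junction positions are well defined because an intron never begins
    with the base that would extend the upstream exon; resumption after an
    intron is located with an ``anchor``-base probe.
    """
    offsets = []
    i = g = 0
    while i < len(cds):
        if genomic_seq[g] == cds[i]:
            i += 1
            g += 1
            continue
        offsets.append(i)
        probe = cds[i : i + min(anchor, len(cds) - i)]
        g = genomic_seq.find(probe, g + 1)
        assert g >= 0, "genomic copy does not contain the coding resumption"
    return tuple(offsets)


def diff_positions(a: str, b: str) -> list:
    assert len(a) == len(b)
    return [i for i in range(len(a)) if a[i] != b[i]]


def brute_force_expected_markers(
    bundle, contigs_by_line: dict, depths_by_line: dict,
    flank: int = 50, min_depth: int = 7,
) -> set:
    """Re-evaluate the three marker criteria and the PSV gate from scratch.

    SNPs are found by exhaustively diffing line alleles against gene
    models, PSVs by diffing paralog gene models against each other,
    junctions by walking the genomic copies, and contig placement by
    substring search — nothing is read from the generator's own truth
    bookkeeping except the allele sequences themselves.
    """
    info = bundle.paralog_table.set_index("gene_id")
    families: dict[str, list[str]] = {}
    for gene_id, row in info.iterrows():
        families.setdefault(row["family_id"], []).append(gene_id)
    junctions = {
        g: derive_junctions(bundle.gene_models[g], bundle.genomic[g])
        for g in bundle.gene_models
    }
    expected = set()
    for line, contigs in contigs_by_line.items():
        alleles = bundle.line_alleles[line]
        # contig placement on its line allele, by substring search
        placement = {}
        for contig_id, cseq in contigs.items():
            gene_id = contig_id.split("@", 1)[1]
            start = alleles[gene_id].find(cseq)
            assert start >= 0
            placement[gene_id] = (contig_id, start, len(cseq))
        snps_by_gene = {
            g: diff_positions(bundle.gene_models[g], alleles[g])
            for g in bundle.gene_models
            if len(bundle.gene_models[g]) == len(alleles[g])
        }
        for gene_id, positions in snps_by_gene.items():
            family = info.loc[gene_id, "family_id"]
            siblings = [g for g in families[family] if g != gene_id]
            for p in positions:
                if gene_id not in placement:
                    continue
                contig_id, start, clen = placement[gene_id]
                if not (start <= p < start + clen):
                    continue
                cpos = p - start
                if cpos < flank or clen - cpos - 1 < flank:
                    continue
                if p < flank or len(bundle.gene_models[gene_id]) - p - 1 < flank:
                    continue
                if any(q != p and abs(q - p) <= flank for q in positions):
                    continue
                if any(p - flank < j < p + flank + 1 for j in junctions[gene_id]):
                    continue
                if depths_by_line[line][contig_id][cpos] < min_depth:
                    continue
                ok = True
                for sib in siblings:
                    sib_snps = snps_by_gene.get(sib, [])
                    if p in sib_snps and sib in placement:
                        s2, c2 = placement[sib][1], placement[sib][2]
                        if s2 <= p < s2 + c2:
                            ok = False  # conflicting column across paralogs
                            break
                    psvs = diff_positions(
                        bundle.gene_models[gene_id], bundle.gene_models[sib]
                    )
                    if not any(q != p and abs(q - p) <= flank for q in psvs):
                        ok = False
                        break
                if ok:
                    expected.add(f"{line}:{gene_id}:{p + 1}")
    return expected
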