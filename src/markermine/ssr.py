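"""Microsatellite (SSR) detection and cross-line polymorphism calling.

Detection follows MISA semantics for perfect repeats: maximal tandem runs
of a 1–6 bp unit, with class minima of 10 repeats for mononucleotide
motifs and 6/5/5/5/5 for di- through hexanucleotide motifs.  A run whose
unit is itself a repetition of a shorter unit is reported once, at the
shortest unit.  Two qualifying SSRs separated by at most
``max_interruption`` bases are additionally labelled as one *complex*
locus.  Runs of N break repeats: an unsequenced base cannot evidence one.

An SSR is polymorphic between two lines only under a stringent rule: the
motifs must be identical, the repeat counts must differ, and the 50 bp of
flanking sequence on *each* side must be exactly identical between the two
lines.  Loci with less than 50 bp of available flank are excluded from the
comparison and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_MINIMA = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest rotation of the repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True when the unit is not a whole repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


@dataclass
class SSRLocus:
    """One perfect microsatellite run (or a complex aggregate)."""

    sequence_id: str
    motif: str                 # canonical rotation
    unit: str                  # unit as it appears at the run start
    unit_length: int
    repeat_count: int
    start: int                 # 1-based inclusive
    end: int                   # 1-based inclusive
    left_flank: str = ""
    right_flank: str = ""
    kind: str = "simple"       # "simple" | "complex"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_ssrs(
    sequence: str,
    sequence_id: str = "",
    minima: Mapping[int, int] | None = None,
    max_interruption: int = 100,
    flank_len: int = 50,
) -> list[SSRLocus]:
    """Find all maximal perfect SSRs of unit length 1–6 in ``sequence``.

    Only full repeat units count: a run is truncated to a whole number of
    units, so ``end - start + 1 == unit_length * repeat_count``.  Flanks of
    up to ``flank_len`` bases are captured for the polymorphism comparison.
    """
    minima = dict(DEFAULT_MINIMA if minima is None else minima)
    seq = sequence
    n = len(seq)
    loci: list[SSRLocus] = []
    for u in range(1, 7):
        min_count = minima.get(u)
        if min_count is None:
            continue
        i = 0
        while i + u * min_count <= n:
            unit = seq[i : i + u]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            # left-maximality at character level: extending one base left
            # would still be part of the same run
            if i > 0 and seq[i - 1] == seq[i + u - 1]:
                i += 1
                continue
            # extend right while the period-u property holds
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            count = (j - i) // u
            if count >= min_count:
                start0 = i
                end0 = i + count * u  # half-open
                loci.append(
                    SSRLocus(
                        sequence_id=sequence_id,
                        motif=canonical_motif(unit),
                        unit=unit,
                        unit_length=u,
                        repeat_count=count,
                        start=start0 + 1,
                        end=end0,
                        left_flank=seq[max(0, start0 - flank_len) : start0],
                        right_flank=seq[end0 : end0 + flank_len],
                    )
                )
                i = end0  # maximal run consumed; next run cannot overlap
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.unit_length))
    loci.extend(_complex_loci(seq, loci, max_interruption, flank_len))
    return loci


def _complex_loci(seq, simple, max_interruption, flank_len):
    """Chain qualifying SSRs separated by <= max_interruption bases."""
    out = []
    run: list[SSRLocus] = []
    for locus in simple:
        if run and locus.start - run[-1].end - 1 <= max_interruption:
            run.append(locus)
        else:
            if len(run) >= 2:
                out.append(_make_complex(seq, run, flank_len))
            run = [locus]
    if len(run) >= 2:
        out.append(_make_complex(seq, run, flank_len))
    return out


def _make_complex(seq, members, flank_len):
    start, end = members[0].start, members[-1].end
    return SSRLocus(
        sequence_id=members[0].sequence_id,
        motif="+".join(m.motif for m in members),
        unit="+".join(m.unit for m in members),
        unit_length=0,
        repeat_count=len(members),
        start=start,
        end=end,
        left_flank=seq[max(0, start - 1 - flank_len) : start - 1],
        right_flank=seq[end : end + flank_len],
        kind="complex",
    )


@dataclass
class SSRComparison:
    """Result of comparing one line pair's SSR loci."""

    polymorphic: list = field(default_factory=list)  # (locus_a, locus_b)
    n_monomorphic: int = 0
    n_short_flank: int = 0


def compare_ssrs(
    loci_a: Sequence[SSRLocus],
    loci_b: Sequence[SSRLocus],
    flank_len: int = 50,
) -> SSRComparison:
    """Call polymorphic SSRs between two lines' homologous sequences.

    Simple loci are paired by exact identity of both ``flank_len`` flanks
    (the flanks anchor the locus; this is also the stringency criterion).
    A matched pair is polymorphic iff the canonical motifs agree and the
    repeat counts differ.  Loci with short flanks are excluded and counted.
    """
    result = SSRComparison()
    usable_b: dict[tuple, SSRLocus] = {}
    for locus in loci_b:
        if locus.kind != "simple":
            continue
        if len(locus.left_flank) < flank_len or len(locus.right_flank) < flank_len:
            result.n_short_flank += 1
            continue
        usable_b[(locus.left_flank[-flank_len:], locus.right_flank[:flank_len])] = locus
    for locus in loci_a:
        if locus.kind != "simple":
            continue
        if len(locus.left_flank) < flank_len or len(locus.right_flank) < flank_len:
            result.n_short_flank += 1
            continue
        key = (locus.left_flank[-flank_len:], locus.right_flank[:flank_len])
        other = usable_b.get(key)
        if other is None or other.motif != locus.motif:
            continue
        if other.repeat_count != locus.repeat_count:
            result.polymorphic.append((locus, other))
        else:
            result.n_monomorphic += 1
    return result


def summarize_ssr_sharing(
    polymorphic_by_pair: Mapping[frozenset, set]
) -> pd.DataFrame:
    """Pairwise and multi-way sharing counts of polymorphic SSR markers.

    ``polymorphic_by_pair`` maps a frozenset of two line names to the set
    of marker keys polymorphic in that pair.  Returns a long-format table
    of every non-empty pair combination (Venn regions), obeying
    inclusion–exclusion by construction.
    """
    pairs = sorted(polymorphic_by_pair, key=sorted)
    rows = []
    for r in range(1, len(pairs) + 1):
        for combo in combinations(pairs, r):
            shared = set.intersection(*(set(polymorphic_by_pair[p]) for p in combo))
            rows.append(
                (
                    " & ".join("-".join(sorted(p)) for p in combo),
                    r,
                    len(shared),
                )
            )
    return pd.DataFrame(rows, columns=["pairs", "n_pairs", "n_markers"])


def loci_to_table(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """MISA-style tabular output."""
    rows = [
        (
            l.sequence_id,
            i + 1,
            f"p{l.unit_length}" if l.kind == "simple" else "c",
            f"({l.motif}){l.repeat_count}" if l.kind == "simple" else l.motif,
            l.length,
            l.start,
            l.end,
        )
        for i, l in enumerate(loci)
    ]
    return pd.DataFrame(
        rows,
        columns=["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"],
    )
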