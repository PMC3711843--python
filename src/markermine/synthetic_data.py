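"""Synthetic reference, line, contig and RIL data with planted ground truth.

The generator emulates the data regime of a paleopolyploid crop
transcriptome study: a reference set of coding sequences organised into
single-, two- and three-copy paralog families (fixed paralog-specific
variations, PSVs, separate the copies), per-line alleles carrying allelic
SNPs and SSR repeat-length edits, genomic copies with introns inserted
between coding bases, partial contigs with per-base read depth, and a
selfed RIL population for linkage validation.

Every planted feature is recorded in a :class:`GroundTruth` object, and
``compute_expected_markers`` evaluates the three marker criteria (50 bp
conserved flanks, junction-free 101 bp window, read depth >= 7) plus the
paralog-discrimination gate directly on that record, independently of the
pipeline code — so pipeline output can be checked for exact recovery.

Internally all coordinates are 0-based half-open; emitted tables are
1-based inclusive.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CleanFlankSpacingError, MappingError, SizingError
from .genmap import GenotypeMatrix
from .seqio import SequenceRecord, write_depth_table, write_fasta, write_paralog_table

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: minimum spacing between planted SNPs in clean-flank mode: two SNPs this
#: far apart can never fall in each other's 101 bp marker window
CLEAN_SPACING = 102


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults describe a desk-scale caricature of the real data regime:
    kilobase coding sequences, ~1% fixed divergence between paralogs,
    ~0.5% allelic divergence between lines, partial contigs and Poisson
    read depth with mean 20.
    """

    n_single: int = 20
    n_two: int = 5
    n_three: int = 2
    cds_len_range: tuple = (600, 1200)
    intron_count_range: tuple = (0, 2)
    intron_len_range: tuple = (80, 250)
    psv_rate: float = 0.01
    snp_rate: float = 0.005
    ssr_plant_spec: tuple = ()          # ((motif, {line: repeat_count}), ...)
    contig_coverage: float = 0.9
    depth_law: tuple = ("poisson", 20.0)
    clean_flanks: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_single", "n_two", "n_three"):
            if getattr(self, name) < 0:
                raise SizingError(f"{name} must be >= 0")
        if not 0.0 <= self.psv_rate <= 1.0 or not 0.0 <= self.snp_rate <= 1.0:
            raise SizingError("psv_rate and snp_rate must lie in [0, 1]")
        lo, hi = self.cds_len_range
        if lo < 201:
            raise SizingError(
                f"cds_len_range minimum {lo} cannot admit a centred 101 bp "
                "window with 50 bp flanks; need >= 201"
            )
        if hi < lo:
            raise SizingError("cds_len_range must be (min, max) with min <= max")
        if not 0.0 < self.contig_coverage <= 1.0:
            raise SizingError("contig_coverage must lie in (0, 1]")
        if self.ssr_plant_spec and self.n_single == 0:
            raise SizingError("SSR planting requires at least one single-copy gene")


@dataclass
class PSVSite:
    family_id: str
    position: int                 # 0-based, family coding coordinates
    bases: dict                   # paralog_index -> base


@dataclass
class SNPSite:
    line: str
    gene_id: str
    family_id: str
    paralog_index: int
    position: int                 # 0-based, gene-model coordinates
    ref_base: str
    alt_base: str

    @property
    def marker_id(self) -> str:
        return f"{self.line}:{self.gene_id}:{self.position + 1}"


@dataclass
class SSRTruth:
    gene_id: str
    anchor: int                   # 0-based insertion offset in the core CDS
    motif: str
    counts: dict                  # line -> repeat count ("REF" = gene model)
    flank_identical: bool = True


@dataclass
class ObservedSNP:
    contig_id: str
    contig_position: int          # 0-based
    depth: int
    depth_ok: bool


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    psv_sites: list = field(default_factory=list)
    junctions: dict = field(default_factory=dict)     # gene -> (offsets,)
    ssr_loci: list = field(default_factory=list)
    snp_sites: list = field(default_factory=list)
    observed: dict = field(default_factory=dict)      # (line, gene, pos0) -> ObservedSNP
    contig_map: dict = field(default_factory=dict)    # contig -> (line, gene, start, length)
    dropped_fragments: list = field(default_factory=list)
    expected_marker_ids: set = field(default_factory=set)
    lines: list = field(default_factory=list)


@dataclass
class ReferenceBundle:
    config: SimulationConfig
    gene_models: dict             # gene -> CDS (includes REF SSR repeats)
    core_models: dict             # gene -> CDS without any SSR insertion
    genomic: dict                 # gene -> intron-bearing copy
    paralog_table: pd.DataFrame
    truth: GroundTruth
    line_alleles: dict = field(default_factory=dict)  # line -> {gene -> seq}


@dataclass
class LineAlleles:
    line_id: str
    sequences: dict


def _rng(seed: int, *tags) -> np.random.Generator:
    parts = [int(seed)]
    for t in tags:
        parts.append(t if isinstance(t, int) else zlib.crc32(str(t).encode()))
    return np.random.default_rng(parts)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[int(rng.integers(0, 3))]


def simulate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the reference bundle: gene models, genomic copies, paralog map.

    Paralog family members differ only at planted PSV positions; every
    pair of paralogs is guaranteed at least one discriminating PSV, so no
    two reference sequences are identical.  Introns are inserted strictly
    between coding bases and their offsets recorded as junctions.
    """
    config.validate()
    rng = _rng(config.seed, 101)
    truth = GroundTruth()
    gene_models: dict[str, str] = {}
    rows = []
    fam_idx = 0
    family_plan = (
        [(1,)] * config.n_single + [(2,)] * config.n_two + [(3,)] * config.n_three
    )
    single_gene_ids = []
    for (copies,) in family_plan:
        fam_idx += 1
        family_id = f"F{fam_idx:04d}"
        lo, hi = config.cds_len_range
        length = int(rng.integers(lo, hi + 1))
        base = list(_random_seq(rng, length))
        paralog_seqs = {i: list(base) for i in range(1, copies + 1)}
        if copies > 1:
            psv_positions = np.flatnonzero(rng.random(length) < config.psv_rate)
            taken = set()
            for pos in psv_positions.tolist():
                deviant = int(rng.integers(1, copies + 1))
                alt = _mutate(rng, base[pos])
                paralog_seqs[deviant][pos] = alt
                taken.add(pos)
                truth.psv_sites.append(
                    PSVSite(
                        family_id, pos,
                        {i: paralog_seqs[i][pos] for i in range(1, copies + 1)},
                    )
                )
            _ensure_pairwise_psvs(
                rng, family_id, paralog_seqs, taken, truth, length
            )
        for i in range(1, copies + 1):
            gene_id = f"{family_id}.{i}"
            gene_models[gene_id] = "".join(paralog_seqs[i])
            rows.append((gene_id, family_id, copies, i))
            if copies == 1:
                single_gene_ids.append(gene_id)
    core_models = dict(gene_models)
    _plant_ssr_loci(config, rng, gene_models, core_models, single_gene_ids, truth)
    genomic = _insert_introns(config, rng, gene_models, truth)
    table = pd.DataFrame(
        rows, columns=["gene_id", "family_id", "copy_class", "paralog_index"]
    )
    return ReferenceBundle(config, gene_models, core_models, genomic, table, truth)


def _ensure_pairwise_psvs(rng, family_id, paralog_seqs, taken, truth, length):
    """Guarantee every paralog pair differs at >= 1 planted PSV."""
    indices = sorted(paralog_seqs)
    for a in indices:
        for b in indices:
            if a >= b:
                continue
            if any(
                s.bases[a] != s.bases[b]
                for s in truth.psv_sites
                if s.family_id == family_id
            ):
                continue
            pos = int(rng.integers(0, length))
            while pos in taken:
                pos = int(rng.integers(0, length))
            taken.add(pos)
            paralog_seqs[b][pos] = _mutate(rng, paralog_seqs[b][pos])
            truth.psv_sites.append(
                PSVSite(family_id, pos, {i: paralog_seqs[i][pos] for i in indices})
            )


def _plant_ssr_loci(config, rng, gene_models, core_models, hosts, truth):
    """Reserve an SSR anchor per spec item; insert the REF repeat if any.

    Guard bases on both sides of the anchor are forced off-motif so that a
    detected run has exactly the planted repeat count.
    """
    for idx, (motif, counts) in enumerate(config.ssr_plant_spec):
        gene_id = hosts[idx % len(hosts)]
        seq = list(core_models[gene_id])
        anchor = len(seq) // 2
        if seq[anchor - 1] == motif[-1]:
            seq[anchor - 1] = _mutate(rng, motif[-1])
        if seq[anchor] == motif[0]:
            seq[anchor] = _mutate(rng, motif[0])
        core_models[gene_id] = "".join(seq)
        gene_models[gene_id] = core_models[gene_id]
        counts = dict(counts)
        if "REF" in counts:
            gene_models[gene_id] = (
                core_models[gene_id][:anchor]
                + motif * counts["REF"]
                + core_models[gene_id][anchor:]
            )
        truth.ssr_loci.append(SSRTruth(gene_id, anchor, motif, counts))


def _insert_introns(config, rng, gene_models, truth):
    genomic = {}
    c_lo, c_hi = config.intron_count_range
    l_lo, l_hi = config.intron_len_range
    for gene_id in sorted(gene_models):
        seq = gene_models[gene_id]
        n_introns = int(rng.integers(c_lo, c_hi + 1))
        if n_introns == 0 or len(seq) < 3:
            genomic[gene_id] = seq
            truth.junctions[gene_id] = ()
            continue
        # exons between junctions keep a 60 bp floor: real internal exons
        # are never a handful of bases, and junction windows stay distinct
        offsets: list[int] = []
        tries = 0
        while len(offsets) < n_introns and tries < 200:
            cand = int(rng.integers(1, len(seq)))
            if all(abs(cand - o) >= 60 for o in offsets) and (
                60 <= cand <= len(seq) - 60
            ):
                offsets.append(cand)
            tries += 1
        offsets.sort()
        if not offsets:
            genomic[gene_id] = seq
            truth.junctions[gene_id] = ()
            continue
        pieces = []
        prev = 0
        for off in offsets:
            pieces.append(seq[prev:off])
            intron = list(_random_seq(rng, int(rng.integers(l_lo, l_hi + 1))))
            # junction positions stay unambiguous: the intron never begins or
            # ends with the base that would extend the adjacent exon
            if intron[0] == seq[off]:
                intron[0] = _mutate(rng, intron[0])
            if intron[-1] == seq[off - 1]:
                intron[-1] = _mutate(rng, intron[-1])
            pieces.append("".join(intron))
            prev = off
        pieces.append(seq[prev:])
        genomic[gene_id] = "".join(pieces)
        truth.junctions[gene_id] = tuple(offsets)
    return genomic


def simulate_line(
    bundle: ReferenceBundle,
    line_id: str,
    snp_rate: float | None = None,
    seed: int | None = None,
    clean_flanks: bool | None = None,
) -> LineAlleles:
    """Derive one line's alleles from the reference.

    Each allele differs from the reference gene model only at recorded SNP
    positions (never inside SSR host genes, whose alleles differ only by
    the repeat-length edit).  In clean-flank mode SNPs are spaced >= 102 bp
    apart and kept >= 50 bp from the coding ends, which makes each marker
    criterion independently decidable for the planted truth.
    """
    if line_id in bundle.line_alleles or line_id == "REF":
        raise ValueError(f"line id {line_id!r} already used")
    config = bundle.config
    rate = config.snp_rate if snp_rate is None else snp_rate
    clean = config.clean_flanks if clean_flanks is None else clean_flanks
    if clean and rate > 1.0 / CLEAN_SPACING:
        raise CleanFlankSpacingError(
            f"clean-flank mode requires snp_rate <= {1.0 / CLEAN_SPACING:.4f} "
            f"(mean spacing >= {CLEAN_SPACING} bp); got {rate}"
        )
    rng = _rng(config.seed, 202, line_id) if seed is None else _rng(seed, 202)
    info = bundle.paralog_table.set_index("gene_id")
    ssr_hosts = {t.gene_id: t for t in bundle.truth.ssr_loci}
    # in clean-flank mode SNPs never land on PSV columns, so a contig is
    # always strictly closest to its own paralog and assignment is exact
    psv_cols: dict[str, set] = {}
    if clean:
        for p in bundle.truth.psv_sites:
            psv_cols.setdefault(p.family_id, set()).add(p.position)
    sequences: dict[str, str] = {}
    for gene_id in sorted(bundle.gene_models):
        core = bundle.core_models[gene_id]
        if gene_id in ssr_hosts:
            t = ssr_hosts[gene_id]
            if line_id in t.counts:
                sequences[gene_id] = (
                    core[: t.anchor] + t.motif * t.counts[line_id] + core[t.anchor :]
                )
            else:
                sequences[gene_id] = core
            continue
        length = len(core)
        draws = rng.random(length)
        seq = list(core)
        row = info.loc[gene_id]
        if clean:
            masked = psv_cols.get(row["family_id"], set())
            positions = []
            last = -CLEAN_SPACING
            for p in range(50, length - 50):
                if p in masked:
                    continue
                if draws[p] < rate and p - last >= CLEAN_SPACING:
                    positions.append(p)
                    last = p
        else:
            positions = np.flatnonzero(draws < rate).tolist()
        for p in positions:
            alt = _mutate(rng, core[p])
            seq[p] = alt
            bundle.truth.snp_sites.append(
                SNPSite(
                    line=line_id,
                    gene_id=gene_id,
                    family_id=row["family_id"],
                    paralog_index=int(row["paralog_index"]),
                    position=p,
                    ref_base=core[p],
                    alt_base=alt,
                )
            )
        sequences[gene_id] = "".join(seq)
    alleles = LineAlleles(line_id, sequences)
    bundle.line_alleles[line_id] = sequences
    bundle.truth.lines.append(line_id)
    return alleles


def _draw_depth(rng: np.random.Generator, law, n: int) -> np.ndarray:
    kind = law[0]
    if kind == "constant":
        return np.full(n, int(law[1]), dtype=int)
    if kind == "poisson":
        return rng.poisson(float(law[1]), size=n).astype(int)
    if kind == "uniform":
        return rng.integers(int(law[1]), int(law[2]) + 1, size=n)
    raise SizingError(f"unknown depth law {law!r}")


def fragment_to_contigs(
    bundle: ReferenceBundle,
    alleles: LineAlleles,
    contig_coverage: float | None = None,
    depth_law=None,
    seed: int | None = None,
) -> tuple[dict, dict]:
    """Cut each line allele into one partial contig with per-base depth.

    Coverage is the fraction of each coding sequence a contig represents;
    fragments shorter than 100 bp (the minimum contig length) are dropped
    and logged, not emitted.  The truth record notes, for every planted
    SNP, whether it landed on a contig and whether its depth reaches 7.
    """
    config = bundle.config
    coverage = config.contig_coverage if contig_coverage is None else contig_coverage
    law = config.depth_law if depth_law is None else depth_law
    if not 0.0 < coverage <= 1.0:
        raise SizingError("contig_coverage must lie in (0, 1]")
    line = alleles.line_id
    rng = _rng(config.seed, 303, line) if seed is None else _rng(seed, 303)
    contigs: dict[str, str] = {}
    depths: dict[str, np.ndarray] = {}
    snps_by_gene: dict[str, list[SNPSite]] = {}
    for s in bundle.truth.snp_sites:
        if s.line == line:
            snps_by_gene.setdefault(s.gene_id, []).append(s)
    for gene_id in sorted(alleles.sequences):
        seq = alleles.sequences[gene_id]
        length = len(seq)
        clen = int(round(coverage * length))
        if clen < 100:
            logger.info("fragment of %s below 100 bp; dropped", gene_id)
            bundle.truth.dropped_fragments.append((line, gene_id))
            continue
        start = int(rng.integers(0, length - clen + 1))
        contig_id = f"{line}@{gene_id}"
        contigs[contig_id] = seq[start : start + clen]
        depth = _draw_depth(rng, law, clen)
        depths[contig_id] = depth
        bundle.truth.contig_map[contig_id] = (line, gene_id, start, clen)
        for s in snps_by_gene.get(gene_id, []):
            if start <= s.position < start + clen:
                cpos = s.position - start
                d = int(depth[cpos])
                bundle.truth.observed[(line, gene_id, s.position)] = ObservedSNP(
                    contig_id, cpos, d, d >= 7
                )
    return contigs, depths


# ---------------------------------------------------------------------------
# the independent expected-marker evaluation over planted truth


def compute_expected_markers(
    bundle: ReferenceBundle, flank: int = 50, min_depth: int = 7
) -> set:
    """Evaluate the marker criteria directly on the planted ground truth.

    A planted SNP is an expected marker iff
    * its contig covers the full 101 bp window (50 bp flank on each side,
      both in contig and in gene coordinates),
    * no other planted variant of the same line and gene lies within 50 bp,
    * no intron junction falls strictly inside the window,
    * the read depth at the SNP base is >= ``min_depth``, and
    * (multi-copy genes) no sibling paralog carries a covered planted SNP
      at the same column, and every sibling is discriminated by >= 1
      planted PSV within the flanks.

    The result is stored on ``bundle.truth.expected_marker_ids``.
    """
    truth = bundle.truth
    info = bundle.paralog_table.set_index("gene_id")
    by_family: dict[str, list[str]] = {}
    for gene_id, row in info.iterrows():
        by_family.setdefault(row["family_id"], []).append(gene_id)
    psv_by_family: dict[str, list[PSVSite]] = {}
    for p in truth.psv_sites:
        psv_by_family.setdefault(p.family_id, []).append(p)
    snp_positions: dict[tuple, set] = {}
    for s in truth.snp_sites:
        snp_positions.setdefault((s.line, s.gene_id), set()).add(s.position)
    covered: dict[tuple, list[tuple]] = {}
    for contig_id, (line, gene_id, start, clen) in truth.contig_map.items():
        covered.setdefault((line, gene_id), []).append((start, clen))
    expected = set()
    for s in truth.snp_sites:
        obs = truth.observed.get((s.line, s.gene_id, s.position))
        if obs is None:
            continue
        gene_len = len(bundle.gene_models[s.gene_id])
        if s.position < flank or gene_len - s.position - 1 < flank:
            continue
        if obs.contig_position < flank:
            continue
        _, _, _, clen = truth.contig_map[obs.contig_id]
        if clen - obs.contig_position - 1 < flank:
            continue
        near = snp_positions[(s.line, s.gene_id)]
        if any(q != s.position and abs(q - s.position) <= flank for q in near):
            continue
        junctions = truth.junctions.get(s.gene_id, ())
        if any(s.position - flank < j < s.position + flank + 1 for j in junctions):
            continue
        if obs.depth < min_depth:
            continue
        siblings = [g for g in by_family[s.family_id] if g != s.gene_id]
        if siblings:
            conflict = False
            for sib in siblings:
                if s.position in snp_positions.get((s.line, sib), set()) and any(
                    st <= s.position < st + cl
                    for st, cl in covered.get((s.line, sib), [])
                ):
                    conflict = True
            if conflict:
                continue
            psvs = psv_by_family.get(s.family_id, [])
            ok = True
            for sib in siblings:
                sib_idx = int(info.loc[sib, "paralog_index"])
                if not any(
                    p.position != s.position
                    and abs(p.position - s.position) <= flank
                    and p.bases[s.paralog_index] != p.bases[sib_idx]
                    for p in psvs
                ):
                    ok = False
                    break
            if not ok:
                continue
        expected.add(s.marker_id)
    truth.expected_marker_ids = expected
    return expected


# ---------------------------------------------------------------------------
# RIL population


def simulate_ril_population(
    marker_map,
    n_individuals: int,
    n_generations: int = 7,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a selfed RIL population under a Haldane crossover process.

    ``marker_map`` is a DataFrame (or records) with columns
    ``marker_id, group, cm``; positions must be sorted within each linkage
    group.  F1 is heterozygous everywhere; each subsequent generation is
    one round of selfing with independent meioses and no crossover
    interference, so residual heterozygosity halves per generation.
    ``n_generations`` is the final generation number (7 = F7, six selfing
    rounds after F1).
    """
    if not isinstance(marker_map, pd.DataFrame):
        marker_map = pd.DataFrame(marker_map, columns=["marker_id", "group", "cm"])
    if n_individuals < 2:
        raise MappingError("need at least 2 individuals")
    if n_generations < 2:
        raise MappingError("n_generations must be >= 2 (F2 or later)")
    groups = marker_map["group"].to_numpy()
    cms = marker_map["cm"].to_numpy(dtype=float)
    for g in pd.unique(groups):
        pos = cms[groups == g]
        if np.any(np.diff(pos) < 0):
            raise MappingError(f"map positions unsorted within group {g!r}")
    m = len(marker_map)
    r_adj = np.full(m, 0.5)
    for i in range(1, m):
        if groups[i] == groups[i - 1]:
            d = cms[i] - cms[i - 1]
            r_adj[i] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    rng = _rng(seed, 404)
    n = n_individuals
    hap = np.zeros((n, 2, m), dtype=np.int8)
    hap[:, 1, :] = 1  # F1: one haplotype from each parent
    for _ in range(n_generations - 1):
        gametes = []
        for _g in range(2):
            switch = rng.random((n, m)) < r_adj
            state = np.logical_xor.accumulate(switch, axis=1)
            gametes.append(np.where(state, hap[:, 1, :], hap[:, 0, :]))
        hap = np.stack(gametes, axis=1)
    total = hap.sum(axis=1)  # 0 = AA, 1 = het, 2 = BB
    calls = np.full((n, m), "H", dtype="<U1")
    calls[total == 0] = "A"
    calls[total == 2] = "B"
    if missing_rate > 0:
        calls[rng.random((n, m)) < missing_rate] = "-"
    matrix = GenotypeMatrix(
        marker_ids=list(marker_map["marker_id"]),
        individual_ids=[f"RIL{i + 1:03d}" for i in range(n)],
        calls=calls.T,
        generation=n_generations,
    )
    return matrix, marker_map.copy()


# ---------------------------------------------------------------------------
# writers


def write_reference_bundle(bundle: ReferenceBundle, outdir) -> dict:
    """Write gene models, genomic copies and the paralog table; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_models": outdir / "gene_models.fasta",
        "genomic": outdir / "genomic.fasta",
        "paralog_table": outdir / "paralog_table.tsv",
    }
    write_fasta(
        [SequenceRecord(g, s) for g, s in sorted(bundle.gene_models.items())],
        paths["gene_models"],
    )
    write_fasta(
        [SequenceRecord(g, s) for g, s in sorted(bundle.genomic.items())],
        paths["genomic"],
    )
    write_paralog_table(bundle.paralog_table, paths["paralog_table"])
    return {k: str(v) for k, v in paths.items()}


def write_line_data(
    line_id: str, contigs: Mapping[str, str], depths: Mapping[str, np.ndarray], outdir
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{line_id}.contigs.fasta"
    depth_path = outdir / f"{line_id}.depth.tsv"
    write_fasta(
        [SequenceRecord(c, s) for c, s in sorted(contigs.items())], fasta
    )
    write_depth_table(dict(sorted(depths.items())), depth_path)
    return {"contigs": str(fasta), "depth": str(depth_path)}


def write_ground_truth(truth: GroundTruth, outdir) -> dict:
    """Dump the planted truth as 1-based TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .seqio import _write_tsv  # shared schema-header writer

    snp = pd.DataFrame(
        [
            (s.line, s.gene_id, s.family_id, s.paralog_index, s.position + 1,
             s.ref_base, s.alt_base)
            for s in truth.snp_sites
        ],
        columns=["line", "gene_id", "family_id", "paralog_index", "position",
                 "ref_base", "alt_base"],
    )
    psv = pd.DataFrame(
        [
            (p.family_id, p.position + 1,
             ";".join(f"{i}:{b}" for i, b in sorted(p.bases.items())))
            for p in truth.psv_sites
        ],
        columns=["family_id", "position", "paralog_bases"],
    )
    ssr = pd.DataFrame(
        [
            (t.gene_id, t.anchor + 1, t.motif,
             ";".join(f"{l}:{c}" for l, c in sorted(t.counts.items())),
             t.flank_identical)
            for t in truth.ssr_loci
        ],
        columns=["gene_id", "anchor", "motif", "counts", "flank_identical"],
    )
    junc = pd.DataFrame(
        [
            (g, ",".join(str(j + 1) for j in offs))
            for g, offs in sorted(truth.junctions.items())
        ],
        columns=["gene_id", "junction_offsets"],
    )
    exp = pd.DataFrame(sorted(truth.expected_marker_ids), columns=["marker_id"])
    paths = {}
    for name, df in [
        ("snp_sites", snp), ("psv_sites", psv), ("ssr_loci", ssr),
        ("junctions", junc), ("expected_markers", exp),
    ]:
        path = outdir / f"{name}.tsv"
        _write_tsv(df, path, name)
        paths[name] = str(path)
    return paths
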