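"""Generator invariants: determinism, truth completeness, planted statistics."""

import numpy as np
import pytest

from markermine import synthetic_data as sd
from markermine.errors import CleanFlankSpacingError, MappingError, SizingError

from oracles import diff_positions


def _bundle(**kw):
    defaults = dict(n_single=4, n_two=2, n_three=1, seed=7)
    defaults.update(kw)
    return sd.simulate_reference(sd.SimulationConfig(**defaults))


class TestSimulateReference:
    def test_single_gene_no_paralogs_no_introns(self):
        b = _bundle(n_single=1, n_two=0, n_three=0, intron_count_range=(0, 0))
        assert len(b.gene_models) == 1
        (gene,) = b.gene_models
        assert b.genomic[gene] == b.gene_models[gene]
        assert b.truth.psv_sites == []

    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = sd.SimulationConfig(n_single=3, n_two=2, n_three=1, psv_rate=0.01, seed=5)
        outs = []
        for d in ("a", "b"):
            b = sd.simulate_reference(cfg)
            sd.simulate_line(b, "X")
            sd.write_reference_bundle(b, tmp_path / d)
            outs.append((tmp_path / d / "gene_models.fasta").read_bytes())
        assert outs[0] == outs[1]

    def test_psv_count_matches_binomial_expectation(self):
        # n_two=10 families at psv_rate 0.01 over ~fixed length
        n, L, rate = 10, 1000, 0.01
        counts = []
        for seed in range(12):
            b = _bundle(n_single=0, n_two=n, n_three=0, psv_rate=rate,
                        cds_len_range=(L, L), seed=seed)
            # subtract forced pairwise-discriminating PSVs? none needed at this rate
            counts.append(len(b.truth.psv_sites))
        mean = np.mean(counts)
        expect = n * L * rate
        sigma = np.sqrt(n * L * rate * (1 - rate) / len(counts))
        assert abs(mean - expect) < 3 * sigma + 1  # +1 for rare forced PSVs

    def test_paralogs_share_high_identity_but_differ(self):
        b = _bundle(n_single=0, n_two=3, n_three=2, psv_rate=0.01)
        fams = b.paralog_table.groupby("family_id")["gene_id"].apply(list)
        for genes in fams:
            for i, a in enumerate(genes):
                for c in genes[i + 1:]:
                    diffs = diff_positions(b.gene_models[a], b.gene_models[c])
                    assert 1 <= len(diffs) <= 0.1 * len(b.gene_models[a])

    def test_introns_strictly_internal(self):
        b = _bundle(intron_count_range=(1, 3))
        for gene, offs in b.truth.junctions.items():
            L = len(b.gene_models[gene])
            assert all(1 <= j <= L - 1 for j in offs)
            assert len(b.genomic[gene]) > L or not offs

    def test_too_short_cds_rejected(self):
        with pytest.raises(SizingError, match="201"):
            sd.SimulationConfig(cds_len_range=(150, 300)).validate()


class TestSimulateLine:
    def test_zero_divergence(self):
        b = _bundle()
        al = sd.simulate_line(b, "L0", snp_rate=0.0)
        assert al.sequences == b.gene_models

    def test_ssr_planting_per_line_counts(self):
        b = _bundle(ssr_plant_spec=((("AG"), {"X": 6, "Y": 8}),))
        x = sd.simulate_line(b, "X", snp_rate=0.0)
        y = sd.simulate_line(b, "Y", snp_rate=0.0)
        (locus,) = b.truth.ssr_loci
        gx = x.sequences[locus.gene_id]
        gy = y.sequences[locus.gene_id]
        assert gx[locus.anchor : locus.anchor + 12] == "AG" * 6
        assert gy[locus.anchor : locus.anchor + 16] == "AG" * 8
        # flanks around the repeat identical across lines
        assert gx[: locus.anchor] == gy[: locus.anchor]
        assert gx[locus.anchor + 12 :] == gy[locus.anchor + 16 :]

    def test_snp_count_in_binomial_interval(self):
        b = _bundle(n_single=10, n_two=0, n_three=0, cds_len_range=(1000, 1000),
                    seed=3)
        total_len = sum(len(s) for s in b.gene_models.values())
        rate = 0.005
        al = sd.simulate_line(b, "L1", snp_rate=rate, clean_flanks=False)
        n = len(b.truth.snp_sites)
        mu = total_len * rate
        sigma = np.sqrt(total_len * rate * (1 - rate))
        assert abs(n - mu) < 3 * sigma

    def test_truth_completeness_exhaustive_diff(self):
        b = _bundle(seed=9)
        al = sd.simulate_line(b, "L1", clean_flanks=False)
        recorded = {
            (s.gene_id, s.position, s.ref_base, s.alt_base)
            for s in b.truth.snp_sites
        }
        observed = set()
        for gene, seq in al.sequences.items():
            for p in diff_positions(b.gene_models[gene], seq):
                observed.add((gene, p, b.gene_models[gene][p], seq[p]))
        assert observed == recorded

    def test_clean_flank_spacing_enforced(self):
        b = _bundle(n_single=6, cds_len_range=(2000, 2000))
        sd.simulate_line(b, "L1", snp_rate=0.008, clean_flanks=True)
        by_gene = {}
        for s in b.truth.snp_sites:
            by_gene.setdefault(s.gene_id, []).append(s.position)
        for positions in by_gene.values():
            positions.sort()
            assert all(b - a >= 102 for a, b in zip(positions, positions[1:]))

    def test_clean_flank_rate_limit_raises(self):
        b = _bundle()
        with pytest.raises(CleanFlankSpacingError, match="102"):
            sd.simulate_line(b, "L9", snp_rate=0.02, clean_flanks=True)


class TestFragmentToContigs:
    def test_full_coverage_constant_depth(self):
        b = _bundle()
        al = sd.simulate_line(b, "L1")
        contigs, depths = sd.fragment_to_contigs(
            b, al, contig_coverage=1.0, depth_law=("constant", 10)
        )
        assert len(contigs) == len(b.gene_models)
        for cid, seq in contigs.items():
            assert seq == al.sequences[b.truth.contig_map[cid][1]]
            assert np.all(depths[cid] == 10)

    def test_depth_below_seven_marked_fail(self):
        b = _bundle(seed=21)
        al = sd.simulate_line(b, "L1", clean_flanks=True)
        sd.fragment_to_contigs(b, al, contig_coverage=1.0, depth_law=("constant", 6))
        assert b.truth.observed  # some SNPs landed on contigs
        assert all(not o.depth_ok for o in b.truth.observed.values())

    def test_coverage_fraction_of_snps_on_contigs(self):
        hit, total = 0, 0
        for seed in range(8):
            b = _bundle(n_single=40, n_two=0, n_three=0, seed=seed + 100)
            al = sd.simulate_line(b, "L1", clean_flanks=False)
            sd.fragment_to_contigs(b, al, contig_coverage=0.6)
            total += len(b.truth.snp_sites)
            hit += len(b.truth.observed)
        frac = hit / total
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / total)

    def test_contigs_are_substrings_at_least_100bp(self):
        b = _bundle()
        al = sd.simulate_line(b, "L1")
        contigs, _ = sd.fragment_to_contigs(b, al, contig_coverage=0.3)
        for cid, seq in contigs.items():
            gene = b.truth.contig_map[cid][1]
            assert len(seq) >= 100
            assert seq in al.sequences[gene]


class TestRILSimulation:
    MAP3 = [(f"m{g}_{i}", f"LG{g}", i * 10.0) for g in range(1, 4) for i in range(5)]

    def test_zero_distance_markers_identical(self):
        m = [("a", "LG1", 0.0), ("b", "LG1", 0.0)]
        matrix, _ = sd.simulate_ril_population(m, 200, 7, seed=1)
        assert np.array_equal(matrix.calls[0], matrix.calls[1])

    def test_f7_heterozygosity_halving(self):
        m = [(f"m{i}", f"LG{i}", 0.0) for i in range(50)]
        matrix, _ = sd.simulate_ril_population(m, 400, 7, seed=2)
        h = matrix.heterozygote_fraction()
        p = 0.5 ** 6
        se = np.sqrt(p * (1 - p) / (400 * 50))
        assert abs(h - p) < 4 * se

    def test_unlinked_markers_near_half_recombinant(self):
        m = [("a", "LG1", 0.0), ("b", "LG2", 0.0)]
        matrix, _ = sd.simulate_ril_population(m, 2000, 7, seed=3)
        a, b = matrix.calls
        inf = np.isin(a, ("A", "B")) & np.isin(b, ("A", "B"))
        r = np.mean(a[inf] != b[inf])
        assert abs(r - 0.5) < 0.04

    def test_unsorted_map_rejected(self):
        m = [("a", "LG1", 5.0), ("b", "LG1", 1.0)]
        with pytest.raises(MappingError, match="unsorted"):
            sd.simulate_ril_population(m, 10, 7)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(MappingError):
            sd.simulate_ril_population(self.MAP3, 1, 7)
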