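"""Alignment-based SNP calling, filtering and copy-class partitioning."""

import numpy as np
import pandas as pd
import pytest

from markermine import homology, snp
from markermine.homology import HomologGroup, revcomp
from markermine.snp import VariantSite

from conftest import random_seq


def _hit(gene, contig, line="L1"):
    hits = homology.align_contigs(
        {"c": contig}, {"g": gene},
        min_identity=0.5, min_length=50, k=8, min_seeds=1, line=line,
    )
    return max(hits, key=lambda h: h.score)


class TestCallSNPs:
    def test_identical_homologs_no_sites(self, rng):
        gene = random_seq(rng, 500)
        sites, skip = snp.call_snps(gene, gene, _hit(gene, gene))
        assert sites == [] and skip is None

    def test_single_substitution_with_depth(self, rng):
        gene = random_seq(rng, 500)
        contig = list(gene)
        contig[249] = "A" if gene[249] != "A" else "G"
        contig = "".join(contig)
        depth = np.full(500, 12)
        sites, _ = snp.call_snps(gene, contig, _hit(gene, contig), depth=depth)
        (site,) = sites
        assert site.position == 250
        assert site.depth == 12
        assert site.ref_base == gene[249] and site.alt_base == contig[249]

    def test_minus_strand_depth_lookup(self, rng):
        gene = random_seq(rng, 400)
        mutant = list(gene)
        mutant[100] = "A" if gene[100] != "A" else "G"
        contig = revcomp("".join(mutant))
        depth = np.zeros(400, dtype=int)
        depth[400 - 1 - 100] = 9  # depth indexed in contig orientation
        sites, _ = snp.call_snps(gene, contig, _hit(gene, contig), depth=depth)
        (site,) = sites
        assert site.position == 101 and site.depth == 9

    def test_planted_snps_recovered_exactly(self, small_bundle, small_groups):
        bundle, _, contigs, depths = small_bundle
        _, groups, _ = small_groups
        planted = {
            (s.gene_id, s.position + 1) for s in bundle.truth.snp_sites
        }
        called = set()
        for g in groups:
            for hit in g.members["L1"]:
                sites, skip = snp.call_snps(
                    bundle.gene_models[g.gene_id],
                    contigs[hit.query_id], hit,
                    depth=depths[hit.query_id],
                )
                assert skip is None
                called |= {(s.gene_id, s.position) for s in sites}
        assert called == planted

    def test_symmetry_under_role_swap(self, rng):
        a = random_seq(rng, 400)
        b = list(a)
        for p in (100, 200, 300):
            b[p] = "A" if a[p] != "A" else "G"
        b = "".join(b)
        ab, _ = snp.call_snps(a, b, _hit(a, b))
        ba, _ = snp.call_snps(b, a, _hit(b, a))
        assert {(s.position, s.ref_base, s.alt_base) for s in ab} == {
            (s.position, s.alt_base, s.ref_base) for s in ba
        }

    def test_low_identity_pair_skipped(self, rng):
        gene = random_seq(rng, 300)
        contig = list(gene)
        for p in range(0, 300, 9):  # ~11% divergence, below the 90% floor
            contig[p] = "A" if gene[p] != "A" else "G"
        contig = "".join(contig)
        sites, skip = snp.call_snps(
            gene, contig, _hit(gene, contig), min_identity=0.90
        )
        assert sites == [] and skip is not None and "identity" in skip

    def test_gap_guard_excludes_indel_neighbourhood(self, rng):
        gene = random_seq(rng, 400)
        # deletion at 200 plus a substitution 3 bp away (inside guard band)
        contig = list(gene)
        contig[196] = "A" if gene[196] != "A" else "G"
        contig = "".join(contig[:200] + contig[201:])
        sites, _ = snp.call_snps(gene, contig, _hit(gene, contig), gap_guard=5)
        assert all(abs(s.position - 197) > 0 for s in sites)
        assert not any(195 <= s.position <= 205 for s in sites)


class TestFilterSNPs:
    @staticmethod
    def _site(depth, quality):
        return VariantSite("g", 100, "A", "G", depth=depth, quality=quality)

    @pytest.mark.parametrize(
        "depth,quality,kept",
        [(7, 40, True), (6, 40, False), (7, 39, False), (6, 39, False),
         (100, 60, True)],
    )
    def test_inclusive_boundaries(self, depth, quality, kept):
        retained, _ = snp.filter_snps([self._site(depth, quality)])
        assert bool(retained) is kept

    def test_empty_input(self):
        retained, report = snp.filter_snps([])
        assert retained == [] and report.n_input == 0

    def test_raising_min_depth_monotone(self):
        sites = [self._site(d, 60) for d in range(1, 20)]
        kept = [len(snp.filter_snps(sites, min_depth=d)[0]) for d in (5, 7, 10, 15)]
        assert kept == sorted(kept, reverse=True)

    def test_report_counts(self):
        sites = [self._site(6, 60), self._site(10, 30), self._site(10, 60)]
        retained, report = snp.filter_snps(sites)
        assert report.n_depth_fail == 1
        assert report.n_quality_fail == 1
        assert report.n_retained == len(retained) == 1


class TestPartitionAndPresence:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "gene_id": ["s1", "s2", "d1", "t1"],
                "family_id": ["fs1", "fs2", "fd", "ft"],
                "copy_class": [1, 1, 2, 3],
                "paralog_index": [1, 1, 1, 1],
            }
        )

    def test_partition_counts(self, table):
        sites = [
            VariantSite("s1", 1, "A", "G"),
            VariantSite("s1", 5, "A", "G"),
            VariantSite("d1", 2, "A", "G"),
            VariantSite("t1", 3, "A", "G"),
            VariantSite("unknown", 4, "A", "G"),
        ]
        counts = snp.partition_by_copy_class(sites, table)
        assert counts == {
            "total": 5, "single": 2, "two": 1, "three": 1, "unclassified": 1
        }
        shuffled = snp.partition_by_copy_class(sites[::-1], table)
        assert shuffled == counts

    def test_presence_counts_genes_not_sites(self):
        groups = [HomologGroup("s1", 1), HomologGroup("s2", 1)]
        sites = [VariantSite("s1", 1, "A", "G"), VariantSite("s1", 200, "C", "T")]
        out = snp.per_gene_snp_presence(sites, groups)
        assert out[1] == 0.5
        assert out[2] is None and out[3] is None

    def test_presence_extremes(self):
        groups = [HomologGroup("s1", 1)]
        assert snp.per_gene_snp_presence([], groups)[1] == 0.0
        assert snp.per_gene_snp_presence(
            [VariantSite("s1", 1, "A", "G")], groups
        )[1] == 1.0
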