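"""Window geometry, the three criteria, PSV classification and assay design."""

from itertools import product

import numpy as np
import pytest

from markermine import homology, marker
from markermine.marker import MarkerCandidate
from markermine.snp import VariantSite

from conftest import random_seq
from oracles import build_funnel_fixture


class TestExtractWindow:
    def test_exact_fit_window_equals_sequence(self, rng):
        seq = random_seq(rng, 101)
        window, reason = marker.extract_window(seq, 51)
        assert window == seq and reason is None

    def test_insufficient_left_flank(self, rng):
        window, reason = marker.extract_window(random_seq(rng, 300), 30)
        assert window is None and reason == "insufficient_flank"

    def test_interior_window_coordinates(self, rng):
        seq = random_seq(rng, 300)
        window, _ = marker.extract_window(seq, 150)
        assert window == seq[99:200]  # 1-based 100..200
        assert len(window) == 101

    def test_out_of_bounds_position(self, rng):
        with pytest.raises(ValueError):
            marker.extract_window(random_seq(rng, 100), 101)


def _aligned(gene, contig):
    hits = homology.align_contigs(
        {"c": contig}, {"g": gene},
        min_identity=0.5, min_length=50, k=8, min_seeds=1, line="L1",
    )
    return max(hits, key=lambda h: h.score)


class TestFlankConservation:
    def test_identical_flanks_conserved(self, rng):
        gene = random_seq(rng, 400)
        contig = gene[:199] + ("A" if gene[199] != "A" else "G") + gene[200:]
        ok, reason, window, ref = marker.check_flank_conservation(
            gene, contig, _aligned(gene, contig), 200
        )
        assert ok and reason is None
        assert len(window) == len(ref) == 101

    def test_substitution_in_flank_breaks(self, rng):
        gene = random_seq(rng, 400)
        chars = list(gene)
        chars[199] = "A" if gene[199] != "A" else "G"       # the SNP
        chars[187] = "A" if gene[187] != "A" else "G"       # offset -12
        contig = "".join(chars)
        ok, _, _, _ = marker.check_flank_conservation(
            gene, contig, _aligned(gene, contig), 200
        )
        assert not ok

    def test_gap_in_flank_breaks(self, rng):
        gene = random_seq(rng, 400)
        chars = list(gene)
        chars[199] = "A" if gene[199] != "A" else "G"
        contig = "".join(chars[:230] + chars[231:])         # deletion at +30
        ok, reason, _, _ = marker.check_flank_conservation(
            gene, contig, _aligned(gene, contig), 200
        )
        assert not ok and reason is None

    def test_uncovered_window_reported(self, rng):
        gene = random_seq(rng, 400)
        contig = gene[180:400]  # alignment cannot reach 50 bp left of 200
        ok, reason, _, _ = marker.check_flank_conservation(
            gene, contig, _aligned(gene, contig), 200
        )
        assert not ok and reason == "uncovered_window"


class TestJunctions:
    def test_intronless_gene_always_true(self, rng):
        gene = random_seq(rng, 400)
        window, _ = marker.extract_window(gene, 200)
        ok, reason = marker.check_junctions(window, gene)
        assert ok and reason is None

    def test_intron_inside_window_rejects(self, rng):
        gene = random_seq(rng, 400)
        window, _ = marker.extract_window(gene, 200)
        # intron at window offset 70 = coding offset 199 - 50 + 70 = 219
        genomic = gene[:219] + random_seq(rng, 90) + gene[219:]
        ok, _ = marker.check_junctions(window, genomic)
        assert ok is False

    def test_intron_outside_window_accepts(self, rng):
        gene = random_seq(rng, 400)
        window, _ = marker.extract_window(gene, 200)
        # window covers 0-based 149..249; junction 10 bp beyond the edge
        genomic = gene[:260] + random_seq(rng, 90) + gene[260:]
        ok, _ = marker.check_junctions(window, genomic)
        assert ok is True

    # window covers 0-based 149..249; a junction *before* base j splits it
    # iff both neighbouring bases lie inside, i.e. j in [150, 249]
    @pytest.mark.parametrize("offset,inside", [(149, False), (150, True),
                                               (249, True), (250, False)])
    def test_junction_boundary_offsets(self, rng, offset, inside):
        gene = random_seq(rng, 400)
        window, _ = marker.extract_window(gene, 200)
        genomic = gene[:offset] + random_seq(rng, 90) + gene[offset:]
        ok, _ = marker.check_junctions(window, genomic)
        assert ok is (not inside)

    def test_no_genomic_hit_rejection(self, rng):
        window, _ = marker.extract_window(random_seq(rng, 400), 200)
        ok, reason = marker.check_junctions(window, random_seq(rng, 600))
        assert ok is None and reason == "no_genomic_hit"


class TestClassification:
    @staticmethod
    def _truth(p1x, p1y, p2x, p2y):
        """Hand-coded truth table for 2 paralogs x 2 lines at one column."""
        seg1, seg2 = p1x != p1y, p2x != p2y
        if seg1 and seg2:
            return "conflict"
        if seg1 or seg2:
            return "allelic_snp"
        if p1x != p2x:
            return "psv"
        return "invariant"

    def test_exhaustive_256_patterns(self):
        for p1x, p1y, p2x, p2y in product("ACGT", repeat=4):
            column = {"P1": {"X": p1x, "Y": p1y}, "P2": {"X": p2x, "Y": p2y}}
            assert marker.classify_column(column) == self._truth(
                p1x, p1y, p2x, p2y
            ), (p1x, p1y, p2x, p2y)

    def test_sequence_level_classification(self):
        seqs = {
            ("P1", "X"): "AACGA",
            ("P1", "Y"): "ACCGA",   # position 2 segregates on P1
            ("P2", "X"): "AACTA",   # position 4 is a fixed PSV
            ("P2", "Y"): "AACTA",
        }
        labels = dict(marker.classify_paralog_sites(seqs))
        assert labels == {2: "allelic_snp", 4: "psv"}

    def test_single_line_cannot_classify(self):
        from markermine.errors import ClassificationError

        with pytest.raises(ClassificationError, match="single line"):
            marker.classify_paralog_sites({("P1", "X"): "ACGT", ("P2", "X"): "ACGA"})

    def test_missing_member_tolerated(self):
        # P2 present in one line only: cannot segregate, treated invariant
        seqs = {
            ("P1", "X"): "AAC",
            ("P1", "Y"): "ATC",
            ("P2", "X"): "AAC",
        }
        labels = dict(marker.classify_paralog_sites(seqs))
        assert labels == {2: "allelic_snp"}


def _candidate(rng, ref_window=None):
    ref_window = ref_window or random_seq(rng, 101)
    site = VariantSite("g", 200, ref_window[50], "T" if ref_window[50] != "T" else "A",
                       line="L1", contig_id="c", contig_position=200, depth=12)
    return MarkerCandidate(variant=site, ref_window=ref_window, window=ref_window)


class TestParalogDesign:
    def test_psv_at_offset_20_accepted(self, rng):
        cand = _candidate(rng)
        design, reason = marker.design_paralog_specific_marker(
            cand, {"g.2": [20]}
        )
        assert reason is None and design.psv_annotation == [20]
        assert design.paralog_specific

    def test_nearest_psv_outside_flank_rejected(self, rng):
        design, reason = marker.design_paralog_specific_marker(
            _candidate(rng), {"g.2": [80]}
        )
        assert design is None and reason == "no_discriminating_psv"

    def test_every_sibling_needs_a_psv(self, rng):
        design, reason = marker.design_paralog_specific_marker(
            _candidate(rng), {"g.2": [20], "g.3": []}
        )
        assert design is None and reason == "no_discriminating_psv"

    def test_both_flank_mode_stricter(self, rng):
        cand = _candidate(rng)
        one_side = {"g.2": [20, 30]}
        assert marker.design_paralog_specific_marker(cand, one_side)[0]
        design, _ = marker.design_paralog_specific_marker(
            cand, one_side, require_both_flanks=True
        )
        assert design is None

    def test_residual_variant_rendered_as_iupac(self, rng):
        window = list(random_seq(rng, 101))
        window[20] = "C"  # offset -30 from the SNP
        cand = _candidate(rng, "".join(window))
        design, _ = marker.design_paralog_specific_marker(
            cand, {"g.2": [20]}, residual_variants={-30: {"T"}}
        )
        assert design.target_sequence[20] == "Y"  # C/T

    def test_bracket_geometry(self, rng):
        cand = _candidate(rng)
        design, _ = marker.design_paralog_specific_marker(cand, {"g.2": [20]})
        seq = design.target_sequence
        assert len(seq) == 105
        assert seq[50] == "[" and seq[52] == "/" and seq[54] == "]"
        assert seq[51] == cand.variant.ref_base and seq[53] == cand.variant.alt_base


@pytest.fixture(scope="module")
def funnel_fixture():
    return build_funnel_fixture(seed=5)


@pytest.fixture(scope="module")
def cascade(funnel_fixture):
    gene_models, genomic, table, contigs, depths, funnel = funnel_fixture
    hits = homology.align_contigs(contigs, gene_models, k=15, line="L1")
    groups, _ = homology.assign_homologs(hits, table)
    result = marker.run_cascade(
        gene_models, genomic, table, contigs, depths, groups, "L1"
    )
    return result, funnel


class TestCascade:
    def test_funnel_matches_constructed_counts(self, cascade):
        result, funnel = cascade
        assert result.funnel.as_tuple() == funnel

    def test_funnel_counts_non_increasing(self, cascade):
        result, _ = cascade
        t = result.funnel.as_tuple()
        assert t[0] >= t[1] >= t[2] >= t[3]

    def test_accepted_set_is_criteria_order_free(self, cascade):
        # all three booleans are evaluated for every candidate, so any
        # conjunction order yields the same accepted set
        result, _ = cascade
        from_booleans = {
            c.marker_id
            for c in result.candidates
            if c.depth_ok and c.junction_free and c.flank_conserved
        }
        assert from_booleans == result.accepted_ids

    def test_shuffled_input_order_same_funnel(self, funnel_fixture):
        gene_models, genomic, table, contigs, depths, funnel = funnel_fixture
        rng = np.random.default_rng(0)
        keys = list(contigs)
        rng.shuffle(keys)
        shuffled = {k: contigs[k] for k in keys}
        hits = homology.align_contigs(shuffled, gene_models, k=15, line="L1")
        groups, _ = homology.assign_homologs(hits, table)
        result = marker.run_cascade(
            gene_models, genomic, table, shuffled, depths, groups, "L1"
        )
        assert result.funnel.as_tuple() == funnel

    def test_all_pass_construction_all_counts_equal(self):
        gene_models, genomic, table, contigs, depths, funnel = (
            build_funnel_fixture(n_pass=10, n_flank_fail=0,
                                 n_junction_fail=0, n_depth_fail=0, seed=6)
        )
        hits = homology.align_contigs(contigs, gene_models, k=15, line="L1")
        groups, _ = homology.assign_homologs(hits, table)
        result = marker.run_cascade(
            gene_models, genomic, table, contigs, depths, groups, "L1"
        )
        assert result.funnel.as_tuple() == (10, 10, 10, 10)
        assert len(result.accepted) == 10


class TestAssayTable:
    def test_round_trip(self, rng):
        cand = _candidate(rng)
        design, _ = marker.design_paralog_specific_marker(cand, {"g.2": [20, -7]})
        table = marker.emit_assay_table([design])
        (back,) = marker.parse_assay_table(table)
        assert back.target_sequence == design.target_sequence
        assert back.psv_annotation == design.psv_annotation
        assert back.depth_acgt == design.depth_acgt

    def test_depth_decomposition_tags_alt_base(self, rng):
        cand = _candidate(rng)
        design, _ = marker.design_paralog_specific_marker(cand, {"g.2": [20]})
        assert design.depth_acgt[cand.variant.alt_base] == 12
        assert sum(design.depth_acgt.values()) == 12
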