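"""End-to-end orchestration: simulate → assign → detect → call → design → map.

The pipeline compares a reference line ("REF", the gene models) against
each simulated (or loaded) line: contigs are assigned to gene models,
SSRs and SNPs are detected, the three-criteria marker cascade is run, and
the accepted markers are validated on a simulated RIL population with
two-point linkage utilities.  A run manifest (config echo, seed, per-stage
counts, funnel, output paths) makes every run reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genmap, homology, marker, snp, ssr
from . import synthetic_data as sd
from .errors import PipelineInputError
from .seqio import (
    SCHEMA_VERSION,
    read_depth_table,
    read_fasta,
    read_paralog_table,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "homology", "ssr", "snp", "marker", "genmap")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, with the study's default thresholds."""

    out_dir: str = "markermine_out"
    seed: int = 0
    lines: tuple = ("L1", "L2")
    simulation: dict = field(default_factory=dict)
    input_dir: str | None = None          # used when simulate is disabled
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # homology
    min_identity: float = 0.80
    min_length: int = 100
    kmer: int = 15
    # SSR
    ssr_minima: dict = field(default_factory=lambda: dict(ssr.DEFAULT_MINIMA))
    ssr_flank: int = 50
    # SNP / marker
    min_pair_identity: float = 0.90
    flank: int = 50
    min_depth: int = 7
    min_quality: int = 40
    gap_guard: int = 5
    # genmap
    lod_threshold: float = 6.0
    alpha: float = 0.01
    ril_individuals: int = 93
    ril_generation: int = 7
    ril_groups: int = 3
    ril_spacing_cm: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("schema_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineInputError(f"unknown config keys: {sorted(unknown)}")
        if "lines" in data:
            data["lines"] = tuple(data["lines"])
        return cls(**data)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["lines"] = list(self.lines)
        out["schema_version"] = SCHEMA_VERSION
        return out


def _validate(config: PipelineConfig) -> None:
    """Dry-run validation: every enabled stage must have producible inputs."""
    on = config.stages
    needs_sim = [s for s in STAGES[1:] if on.get(s)]
    if needs_sim and not on.get("simulate"):
        if config.input_dir is None:
            raise PipelineInputError(
                "simulate disabled but no input_dir with pre-existing data"
            )
        root = Path(config.input_dir)
        required = ["gene_models.fasta", "genomic.fasta", "paralog_table.tsv"]
        for line in config.lines:
            required += [f"{line}.contigs.fasta", f"{line}.depth.tsv"]
        missing = [f for f in required if not (root / f).exists()]
        if missing:
            raise PipelineInputError(f"missing inputs: {missing}")
    for stage, prereq in [("snp", "homology"), ("marker", "homology"),
                          ("genmap", "marker")]:
        if on.get(stage) and not on.get(prereq):
            raise PipelineInputError(
                f"stage {stage!r} enabled but prerequisite {prereq!r} disabled"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    _validate(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.echo(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()
    on = config.stages

    # --- inputs: simulate or load -----------------------------------------
    if on.get("simulate"):
        sim_kwargs = dict(config.simulation)
        sim_kwargs["seed"] = config.seed
        sim_config = sd.SimulationConfig(**sim_kwargs)
        bundle = sd.simulate_reference(sim_config)
        contigs_by_line: dict[str, dict] = {}
        depths_by_line: dict[str, dict] = {}
        for line in config.lines:
            alleles = sd.simulate_line(bundle, line)
            contigs, depths = sd.fragment_to_contigs(bundle, alleles)
            contigs_by_line[line] = contigs
            depths_by_line[line] = depths
        sd.compute_expected_markers(
            bundle, flank=config.flank, min_depth=config.min_depth
        )
        manifest["outputs"].update(sd.write_reference_bundle(bundle, out_dir))
        for line in config.lines:
            manifest["outputs"].update(
                sd.write_line_data(
                    line, contigs_by_line[line], depths_by_line[line], out_dir
                )
            )
        manifest["outputs"]["ground_truth"] = sd.write_ground_truth(
            bundle.truth, out_dir / "truth"
        )
        gene_models = bundle.gene_models
        genomic = bundle.genomic
        paralog_table = bundle.paralog_table
        manifest["stages"]["simulate"] = {
            "n_genes": len(gene_models),
            "n_planted_snps": len(bundle.truth.snp_sites),
            "n_planted_psvs": len(bundle.truth.psv_sites),
            "n_expected_markers": len(bundle.truth.expected_marker_ids),
        }
    else:
        bundle = None
        root = Path(config.input_dir)
        gene_models = {r.id: r.sequence for r in read_fasta(root / "gene_models.fasta")}
        genomic = {r.id: r.sequence for r in read_fasta(root / "genomic.fasta")}
        paralog_table = read_paralog_table(root / "paralog_table.tsv")
        contigs_by_line = {}
        depths_by_line = {}
        for line in config.lines:
            contigs_by_line[line] = {
                r.id: r.sequence for r in read_fasta(root / f"{line}.contigs.fasta")
            }
            depths_by_line[line] = read_depth_table(root / f"{line}.depth.tsv")

    # --- homology ----------------------------------------------------------
    groups_by_line: dict[str, list] = {}
    if on.get("homology"):
        hits_all = []
        for line in config.lines:
            hits = homology.align_contigs(
                contigs_by_line[line], gene_models,
                min_identity=config.min_identity,
                min_length=config.min_length,
                k=config.kmer, line=line,
            )
            hits_all.extend(hits)
        groups, unassigned = homology.assign_homologs(
            hits_all, paralog_table,
            min_identity=config.min_identity, min_length=config.min_length,
        )
        for line in config.lines:
            groups_by_line[line] = [g for g in groups if line in g.members]
        summary = homology.summarize_copy_classes(groups, paralog_table)
        summary_path = out_dir / "copy_class_summary.tsv"
        summary.to_csv(summary_path, sep="\t")
        manifest["outputs"]["copy_class_summary"] = str(summary_path)
        manifest["stages"]["homology"] = {
            "n_hits": len(hits_all),
            "n_groups": len(groups),
            "n_unassigned": len(unassigned),
            "copy_class_counts": {
                str(line): {str(k): int(v) for k, v in summary.loc[line].items()}
                for line in summary.index
            },
        }

    # --- SSR ---------------------------------------------------------------
    if on.get("ssr"):
        ref_loci = []
        for gene_id in sorted(gene_models):
            ref_loci.extend(
                ssr.detect_ssrs(gene_models[gene_id], gene_id,
                                minima=config.ssr_minima)
            )
        ssr_stats = {"n_reference_loci": len(ref_loci), "polymorphic": {}}
        poly_by_pair = {}
        for line in config.lines:
            line_loci = []
            for contig_id in sorted(contigs_by_line[line]):
                line_loci.extend(
                    ssr.detect_ssrs(contigs_by_line[line][contig_id], contig_id,
                                    minima=config.ssr_minima)
                )
            cmp = ssr.compare_ssrs(ref_loci, line_loci, flank_len=config.ssr_flank)
            poly_by_pair[frozenset({"REF", line})] = {
                (a.sequence_id, a.start, a.motif) for a, _ in cmp.polymorphic
            }
            ssr_stats["polymorphic"][line] = len(cmp.polymorphic)
        sharing = ssr.summarize_ssr_sharing(poly_by_pair)
        sharing_path = out_dir / "ssr_sharing.tsv"
        sharing.to_csv(sharing_path, sep="\t", index=False)
        manifest["outputs"]["ssr_sharing"] = str(sharing_path)
        manifest["stages"]["ssr"] = ssr_stats

    # --- SNP + marker cascade ---------------------------------------------
    cascade_by_line: dict[str, marker.CascadeResult] = {}
    if on.get("marker") or on.get("snp"):
        snp_stats = {}
        marker_stats = {}
        all_designs = []
        for line in config.lines:
            result = marker.run_cascade(
                gene_models, genomic, paralog_table,
                contigs_by_line[line], depths_by_line[line],
                groups_by_line.get(line, []), line,
                min_pair_identity=config.min_pair_identity,
                flank=config.flank,
                min_depth=config.min_depth,
                min_quality=config.min_quality,
                gap_guard=config.gap_guard,
            )
            cascade_by_line[line] = result
            snp_stats[line] = {
                "funnel": result.funnel.as_tuple(),
                "partition": snp.partition_by_copy_class(
                    [c.variant for c in result.candidates], paralog_table
                ),
            }
            marker_stats[line] = {
                "accepted": len(result.accepted),
                "conflict": result.funnel.n_conflict,
                "psv_rejected": result.funnel.n_psv_rejected,
            }
            all_designs.extend(result.accepted)
        table = marker.emit_assay_table(all_designs)
        table_path = out_dir / "markers.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        manifest["outputs"]["markers"] = str(table_path)
        if on.get("snp"):
            manifest["stages"]["snp"] = snp_stats
        if on.get("marker"):
            manifest["stages"]["marker"] = marker_stats
            if bundle is not None:
                accepted = {d.marker_id for d in all_designs}
                expected = bundle.truth.expected_marker_ids
                manifest["stages"]["marker"]["recovery"] = {
                    "n_expected": len(expected),
                    "n_accepted": len(accepted),
                    "precision": (
                        len(accepted & expected) / len(accepted) if accepted else None
                    ),
                    "recall": (
                        len(accepted & expected) / len(expected) if expected else None
                    ),
                }

    # --- linkage validation -------------------------------------------------
    if on.get("genmap"):
        marker_ids = sorted(
            {d.marker_id for r in cascade_by_line.values() for d in r.accepted}
        )
        if marker_ids:
            per_group = max(1, int(np.ceil(len(marker_ids) / config.ril_groups)))
            records = []
            for i, mid in enumerate(marker_ids):
                grp, slot = divmod(i, per_group)
                records.append((mid, f"LG{grp + 1}", slot * config.ril_spacing_cm))
            matrix, true_map = sd.simulate_ril_population(
                records, config.ril_individuals, config.ril_generation,
                seed=config.seed,
            )
            geno_path = out_dir / "ril_genotypes.tsv"
            matrix.to_dataframe().to_csv(geno_path, sep="\t")
            manifest["outputs"]["ril_genotypes"] = str(geno_path)
            results = genmap.all_pairs(matrix)
            groups_found = genmap.group_markers(
                results, matrix.marker_ids, lod_threshold=config.lod_threshold
            )
            distorted = [
                genmap.test_segregation_distortion(
                    matrix.calls[i], matrix.marker_ids[i],
                    alpha=config.alpha, n_tests=len(matrix.marker_ids),
                ).distorted
                for i in range(len(matrix.marker_ids))
            ]
            two_point_path = out_dir / "two_point.tsv"
            genmap.results_to_table(results).to_csv(
                two_point_path, sep="\t", index=False
            )
            manifest["outputs"]["two_point"] = str(two_point_path)
            manifest["stages"]["genmap"] = {
                "n_markers": len(marker_ids),
                "n_linkage_groups": len(groups_found),
                "n_true_groups": int(true_map["group"].nunique()),
                "n_distorted": int(sum(distorted)),
                "heterozygote_fraction": matrix.heterozygote_fraction(),
            }
        else:
            manifest["stages"]["genmap"] = {"n_markers": 0}

    manifest["runtime_s"] = round(time.time() - t0, 2)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
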