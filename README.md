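# markermine

Transcriptome SNP and SSR marker mining for paleopolyploid crops, with
paralog-aware assay design and two-point linkage validation.

## The problem

Crops descended from ancient whole-genome multiplications (the *Brassica*
species are the canonical case) carry most genes in two or three diverged
copies. Mining transcriptome contigs for markers there has a specific
failure mode: a base difference between a contig and a reference coding
sequence may be an **allelic SNP** (segregating between lines — a usable
marker) or a **paralog-specific variation** (PSV — a fixed difference
between gene copies that every line carries, and that a genotyping assay
would misread as a polymorphism). `markermine` implements the complete
desk-side workflow for this setting, for geneticists building
KASP/competitive-allele-specific-PCR marker panels:

* assign each line's contigs to reference gene models
  (≥ 80% identity over ≥ 100 bp, both strands, best-hit rule) and
  classify genes by paralog copy number;
* detect microsatellites (perfect 1–6 bp repeats at minima 10/6/5/5/5/5)
  and call cross-line polymorphic SSRs under strict 50 bp flank identity;
* call inter-line SNPs from homolog alignments at ≥ 90% pair identity and
  filter them at read depth ≥ 7 and quality ≥ 40;
* apply the three-criteria marker filter — conserved 50 bp flanks,
  junction-free 101 bp window against the intron-bearing genomic copy,
  sufficient depth — and, for multi-copy genes, separate allelic SNPs
  from PSVs and require a discriminating PSV in the flanks of every
  sibling copy before designing a locus-specific target;
* emit bracketed assay targets `50 bp [X/Y] 50 bp` with IUPAC degeneracy
  at residual variable positions;
* validate markers on simulated F7 RIL populations with two-point
  utilities: segregation-distortion screening, recombination fractions
  corrected through the selfed-RIL recursion (F∞ limit R = 2r/(1+2r)),
  Kosambi distances d = 25·ln((1+2r)/(1−2r)) cM, and LOD > 6.0 linkage
  grouping.

A synthetic-data module generates the whole input regime — paralog
families with planted PSVs, line alleles with planted SNPs and SSR
length variants, genomic copies with introns, partial contigs with
per-base depth, RIL genotypes — together with machine-readable ground
truth, so every stage is testable end to end without any downloads.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from markermine import synthetic_data as sd, homology, marker

config = sd.SimulationConfig(n_single=30, n_two=8, n_three=4,
                             clean_flanks=True, contig_coverage=1.0, seed=42)
bundle = sd.simulate_reference(config)
alleles = sd.simulate_line(bundle, "TETRA")
contigs, depths = sd.fragment_to_contigs(bundle, alleles)
expected = sd.compute_expected_markers(bundle)

hits = homology.align_contigs(contigs, bundle.gene_models, line="TETRA")
groups, unassigned = homology.assign_homologs(hits, bundle.paralog_table)
result = marker.run_cascade(bundle.gene_models, bundle.genomic,
                            bundle.paralog_table, contigs, depths,
                            groups, "TETRA")

print("genes:", len(bundle.gene_models), " planted SNPs:", len(bundle.truth.snp_sites))
print("funnel (eligible, flank, junction, depth):", result.funnel.as_tuple())
print("accepted markers:", len(result.accepted),
      " == planted expectation:", result.accepted_ids == expected)
d = result.accepted[0]
print(d.marker_id, d.target_sequence[40:65], "...")
```

prints

```
genes: 58  planted SNPs: 164
funnel (eligible, flank, junction, depth): (164, 164, 146, 146)
accepted markers: 117  == planted expectation: True
TETRA:F0001.1:157 TAACGGTTGT[G/T]TCGGATAACG ...
```

Reading the numbers: 58 gene sequences (30 single-copy plus 8 two-copy
and 4 three-copy families) received 164 planted allelic SNPs. All 164
had windows with conserved flanks (clean-flank simulation mode), 18 fell
on an exon–intron junction, none failed the depth filter, and of the 146
surviving candidates the multi-copy ones without a discriminating PSV in
their flanks were dropped, leaving 117 accepted markers — exactly the
set the generator's ground truth predicts. The last line is one marker's
assay target around the bracketed SNP.

The same flow is available from the shell:

```bash
markermine run-all --seed 42 --out-dir demo_run       # full pipeline + manifest
markermine simulate --seed 1 --out-dir sim            # data only
markermine detect-ssrs sim/gene_models.fasta
markermine qc-reads reads.fastq filtered.fastq
markermine map-twopoint demo_run/ril_genotypes.tsv --lod 6.0
```

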