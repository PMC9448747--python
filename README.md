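# svlink

Link population-differentiated structural variants (SVs) to cell types.
`svlink` is a tested re-implementation of an integrative analysis chain:

1. **SV I/O + merge/filter** (`svlink.sv_io`) — read/write cuteSV-style
   VCFs (SVTYPE/SVLEN/END, GT), merge per-sample call sets by breakpoint
   proximity (50 bp, type-matched, transitive), and filter the
   multi-sample genotype matrix vcftools-style (call rate ≥ 0.5, minor
   allele count ≥ 3, site quality ≥ 30).
2. **Population differentiation** (`svlink.popgen`) — per-SV two-population
   FST (Weir–Cockerham 1984 by default, Hudson optional) and selection of
   the top 0.5% ("high-FST") candidate SVs with inclusive tie handling.
3. **Region annotation** (`svlink.annotate`) — one category per SV
   (exonic > UTR > intronic > promoter > upstream > downstream >
   intergenic, with 2 kb promoters and 150 bp flanks), frameshift calls
   for coding deletions, and the derived gene lists.
4. **Bulk differential expression** (`svlink.bulk_de`) — median-of-ratios
   normalization, Welch t-test on log2(normalized+1), DEG rule
   p < 0.05 and |log2FC| ≥ 1 (inclusive).
5. **Single-cell pipeline** (`svlink.sc`) — QC (min detected genes, ≤ 20%
   mitochondrial), LogNormalize, PCA + SNN + Louvain clustering
   (resolution 0.5), Wilcoxon marker detection (p_adj < 0.05,
   avg_logFC > 1), cross-species cluster correlation with novel-cluster
   flagging (max r < 0.31), and simplified joint clustering
   (resolution 0.1) with species composition.
6. **Integration statistics** (`svlink.integrate`) — chi-square DEG/SV-gene
   association, three-list Venn counts, per-cluster marker enrichment
   (ratios, within-list z-scores, two-sided Fisher's exact) and
   one-vs-rest ratio t-tests.
7. **Synthetic data** (`svlink.simulate`) — generates every input the
   pipeline consumes (gene models, two-population SV cohorts with
   divergent sites, bulk counts with seeded fold changes, clustered
   single-cell counts with seeded markers/mito fractions and an optional
   species-specific cluster, ortholog tables) together with truth tables.

## CLI

One subcommand per stage, plus an end-to-end runner:

```bash
# full synthetic run (inputs generated under OUT/inputs, outputs + report.json in OUT)
svlink all --synthetic --seed 1 --outdir out/run1

# individual stages on files
svlink simulate --seed 1 --out out/sim
svlink merge out/sim/inputs/*.vcf --out out/merged.vcf
svlink filter out/merged.vcf --out out/filtered.vcf
svlink fst out/filtered.vcf --popmap out/sim/inputs/popmap.tsv --out out/fst.tsv
svlink annotate out/filtered.vcf --gff3 out/sim/inputs/genes_a.gff3 --out out/ann.tsv
svlink de out/sim/inputs/bulk_counts.tsv --groups out/sim/inputs/bulk_groups.tsv --out out/de.tsv
svlink sc --matrix-a out/sim/inputs/sc_a --matrix-b out/sim/inputs/sc_b \
          --orthologs out/sim/inputs/orthologs.tsv --outdir out/sc
```

Configuration is a YAML file mirroring `svlink.config.PipelineConfig`;
every numeric default matches the published parameter values. Runs are
bit-reproducible from the config + seed (echoed into `report.json`).

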