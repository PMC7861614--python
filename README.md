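# te-insite

Transposon-insertion-centric epigenomic analysis toolkit. Re-implements, as
a tested and reusable pipeline, the computational analyses of a
TE-silencing study in *Drosophila* ovarian somatic cells:

- **k-mer genome mappability tracks** from exhaustive self-matching over
  both strands, including a paired-fragment approximation (mean of the
  2n-mer track and an n-mer pair track with a fixed mate separation);
- **dual gene / TE-consensus expression quantification**: strand-aware
  unique-read counting with largest-overlap assignment, median-of-ratios
  size factors, RPKM/CPM on the robust library size, fold changes with a
  pluggable significance test, and the >4-fold / padj<0.05 / >1 RPKM
  de-repression classifier (plus the qPCR ΔΔCT fold change);
- **promoter–insertion proximity**: cluster-filtering of insertion sites,
  TSS windows (10 kb upstream / 15 kb downstream of the insertion center)
  and fold-change-stratified proximity fractions;
- **mappability-filtered 1-kb bin analysis**: bin categories (near
  upregulated-TE insertions, near other insertions, distal heterochromatic
  control), mappability/library-size-normalized signal, replicate averaging
  and category-wise Wilcoxon rank-sum comparison with the >2-fold &
  p<0.001 significance flag;
- **insertion-anchored meta-profiles**: reference-point matrices
  (−10 kb/+15 kb, missing data as zero), percentile-bootstrap confidence
  bands (200 resamples) and 99th-percentile-capped, control-sorted heatmap
  matrices;
- **a synthetic-data generator** (`sim_data`) producing genomes with
  planted TE-consensus insertions, H3K9me3/H3K4me2 enrichment domains with
  knockdown effects, negative-binomial RNA-seq counts with planted TE
  de-repression and insertion-proximal gene upregulation, multimappers,
  PCR duplicates, a mitochondrial contig — and a machine-readable truth
  table, so every stage is verifiable without downloads.

All coordinates are 0-based half-open (BED convention). The native
alignment interchange format is a plain TSV
(`chrom start end strand mapq sample`); text SAM is also accepted.

## CLI

```bash
te-insite simulate    --config sim.yaml --out simdir/ --seed 1
te-insite mappability --genome genome.fa --n 50 [--paired --shift 146] --out map.bedGraph
te-insite counts      --alignments aln.tsv --features genes.bed --strandedness reverse --out counts.tsv
te-insite de          --counts counts.tsv --out de.tsv
te-insite proximity   --genes genes.tsv --insertions insertions.bed --out prox.tsv
te-insite bins        --genome genome.fa --alignments chip.tsv --insertions insertions.bed \
                      --het-region chr3:200000-300000 --conditions s1=control,s2=knockdown \
                      --out-bins bins.tsv --out-stats stats.tsv
te-insite metaprofile --genome genome.fa --alignments chip.tsv --insertions insertions.bed \
                      --out-profile profile.tsv --out-heatmap heatmap.tsv
te-insite coverage    --genome genome.fa --alignments chip.tsv --mode chip --out-prefix cov_
te-insite run-all     --config config.yaml --out outdir/ --seed 1
```

`run-all` executes simulate → mappability → counts → de → proximity →
bins → metaprofile → coverage from one YAML config and writes a
`manifest.json` with config snapshot, stage statuses and output checksums.
Identical config + seed gives byte-identical result tables. Example
config:

```yaml
seed: 11
simulate: true
sim:
  n_chrom: 3
  chrom_length: 100000
  n_genes: 80
  insertions_per_family: 1
chip: {depth: 20000, replicates: 2, marks: [H3K9me3]}
rna: {replicates: 4, depth: 300000}
pipeline:
  kmer_length: 50
```

With `simulate: false`, provide an `inputs:` section (genome FASTA,
insertions BED, gene TSV, alignment TSV/SAM paths, optional counts TSV)
and set `pipeline.het_region` (`chrom:start-end`).

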