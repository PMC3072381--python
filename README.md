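# nucret

Analysis toolkit for studying how fine-scale base composition predicts
nucleosome retention in sperm MNase-seq data.  It builds windowed GC/CpG
tracks from a genome, converts 5′-end read records into fragment-center
retention scores against a genomic input control, calls enrichment
regions, classifies genes by expression breadth, and evaluates base
composition as a retention predictor with ROC, contingency, and
trend-in-proportions statistics.  A synthetic-data generator plants the
relevant structure (class-specific promoter GC architecture, GC-coupled
read sampling, methylation labels correlated with retention) so the
entire pipeline runs and is testable without any external downloads.

## Modules

| module               | contents |
|----------------------|----------|
| `nucret.seqcomp`     | genome / window grid types, per-window GC, CpG and N counts, 20-mer uniqueness mask, CpG-island detection (≥200 bp, GC ≥ 0.5, obs/exp CpG ≥ 0.6) |
| `nucret.retention`   | 75-bp read shifting, fragment-center window counts, read subsampling, normalized retention score `(n − i)/√(n + i)`, ≥5-read coverage filter, sliding-window binomial region caller, binomial enrichment score |
| `nucret.genes`       | gene models, expression breadth / housekeeping / tissue-specific / developmental-TF classes, retained-at-TSS calls (50-bp rule), region location labels, 13-donor presence rule, distal-site filter |
| `nucret.evaluate`    | ROC/AUC with grouped ties, sensitivity/specificity points, methylation×retention contingency, Cochran–Armitage trend test, χ² independence, (stratified) track correlations |
| `nucret.profiles`    | TSS-anchored meta-profiles (27 × 150-bp bins ≈ ±2 kb) and clustered per-gene heatmap matrices |
| `nucret.synthdata`   | synthetic genomes, read libraries, expression / presence / methylation labels |
| `nucret.pipeline`    | end-to-end orchestration with an auditable run report |
| `nucret.published`   | the published summary tables used for desk-scale validation |

## CLI

```sh
# full synthetic pipeline: simulate → compose → score → regions →
# classify → evaluate → profile, with report.json beside the outputs
nucret run-all --seed 1 --outdir out/

# or stage by stage
nucret simulate --seed 1 --outdir out/
nucret compose --fasta out/genome.fa --out out/windows.tsv --islands-out out/islands.tsv
nucret score --fasta out/genome.fa --nuc out/nuc_reads.tsv --input out/input_reads.tsv \
             --shift 75 --window 150 --min-reads 5 --out out/retention.tsv
nucret regions --fasta out/genome.fa --nuc out/nuc_reads.tsv --input out/input_reads.tsv \
               --out out/regions.bed
nucret roc --windows out/windows.tsv --retention out/retention.tsv \
           --regions out/regions.bed --predictor gc --out out/roc.tsv
nucret methyl-eval --islands out/cpg_islands.tsv --regions out/regions.bed
nucret trend --table bins.tsv
```

Reads are 3-column TSVs (`chrom`, `five_prime`, `strand`); BED6
alignments can be converted with `nucret.retention.reads_from_bed6`.
All coordinates are 0-based, half-open.

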