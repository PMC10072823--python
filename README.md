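# mitoevo

Analysis toolkit for highly replicated mitonuclear-hybrid evolution
experiments in yeast: depth-based calling of genomic changes, mutational
profile convergence statistics, growth-curve phenotyping and
competition-based fitness estimation — plus a synthetic-data module that
emulates a 7-genotype × 2-medium × 96-replicate design with full ground
truth for parameter-recovery testing.

## What's inside

| module | purpose |
| --- | --- |
| `mitoevo.simulate` | synthetic cohorts (planted SNV/CNV/aneuploidy calls with per-circumstance locus rates), depth/pileup profiles, Gompertz growth curves, competition count series |
| `mitoevo.calls` | mtDNA coding fraction, depth-based aneuploidy and CNV callers, cross-sample CNV artifact resolution, ancestor-subtracted pileup SNV calling, feature annotation |
| `mitoevo.growth` | Zwietering modified-Gompertz fitting (multi-start least squares), per-clone replicate aggregation, Type II factorial ANOVA, Tukey HSD |
| `mitoevo.convergence` | circumstance × annotation mutation profiles, Bray–Curtis dissimilarity, nonmetric MDS (SMACOF, Kruskal stress-1), match/mismatch partitioning, joint χ²/mutual-information locus specificity with BH FDR, substitution-spectrum tests, phenotype association |
| `mitoevo.competition` | per-generation selection coefficients from log-ratio regression, locus × genotype fitness matrices with interaction ANOVA, rank concordance |
| `mitoevo.io` / `mitoevo.pipeline` / `mitoevo.cli` | BED/GFF3/depth/pileup/VCF readers and writers, YAML config, end-to-end driver with provenance manifest |

Coordinates are 1-based inclusive internally; BED input is converted from
0-based half-open at the boundary.

## CLI

One executable with a subcommand per operation:

```sh
mitoevo simulate --seed 1 --replicates 96 --out-prefix cohort
mitoevo mtfrac --depth clone.depth.tsv --mito-coding mito_cds.bed
mitoevo aneuploidy --depth clone.depth.tsv --out aneu.tsv
mitoevo cnv --depth clone.depth.tsv --out cnv.tsv
mitoevo snv --sample clone.pileup.tsv --ancestor anc.pileup.tsv --out snv.tsv
mitoevo annotate --calls snv.tsv --features genes.gff3 --out calls.tsv
mitoevo profiles --calls calls.tsv --metadata cohort.metadata.tsv --out prof.tsv
mitoevo dissim --profiles prof.tsv --out bc.tsv
mitoevo nmds --dissim bc.tsv --n-init 10000 --seed 1 --out coords.tsv
mitoevo partition --dissim bc.tsv --out-pairs pairs.tsv --out-anova anova.tsv
mitoevo specificity --calls calls.tsv --metadata cohort.metadata.tsv --out spec.tsv
mitoevo competition --series counts.csv --generations-per-day 5.2 --out s.tsv
mitoevo run --config pipeline.yaml --outdir out/
```

`mitoevo run` drives the full synthetic (or user-data) pipeline:
generation → calling → profiles → dissimilarity/NMDS/partition →
specificity, writing every table plus a `manifest.json` recording
parameters, seeds and SHA-256 digests of all outputs.

## Notes on defaults

- Aneuploidy calling: copy ratio ≥ 1.35 (gain) / ≤ 0.65 (loss) plus a
  Bonferroni-corrected rank-sum test on 1-kb window medians.
- CNV calling: 50-bp windows, 1.5×/0.5× thresholds, 150-bp minimum length;
  windows are normalized by the enclosing chromosome's median depth.
- SNV calling: depth ≥ 10, alt fraction ≥ 0.8 (clonal haploid isolates),
  ancestor alt fraction ≤ 0.05.
- Mutual information is reported in dits (log base 10); a locus is
  "specific" when its BH-adjusted χ² q ≤ 0.05 **and** its MI exceeds the
  across-locus mean by ≥ 2 SDs.
- Selection coefficients are per generation (default 5.2 generations/day).
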