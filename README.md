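# polycap

Analysis toolkit for polyploid target-capture (hybridization enrichment)
sequencing data. It implements the downstream computations needed to go
from multi-caller variant sets and per-gene/per-probe read-count tables to:

- **Variant hard-filtering** — a six-rule conjunctive cascade (mapping
  quality > 30, base quality > 20, per-accession alternate reads > 2,
  summed depth < 3000 and > 600, QUAL > 80) with a first-failing-rule
  rejection tally, caller concordance/union sets, and Ts/Tv summaries.
- **Allele-dosage genotyping** — maximum-likelihood dosage assignment under
  each accession's ploidy (6/8/12 supported, any even ploidy 2–12), for
  bi-allelic (binomial) and up to tetra-allelic (multinomial) sites;
  single-dose-marker (SDM) identification and heterozygosity rates.
- **CNV/PAV detection** — per-gene depth normalization
  `1e9 · reads / (total_mapped · length)`, log2-ratio percentile-outlier
  CNV calls (99th percentile by default), and deterministic
  presence/absence criteria (zero reads one side, ≥ 10 reads and
  normalized depth ≥ 0.1 the other).
- **Functional annotation** — mutually exclusive region classes
  (CDS exon > UTR > splice site > intron > intergenic, 2-bp splice
  windows), codon-level coding effects honoring strand and phase, and
  InDel frame classification (length mod 3).
- **Probe capture-efficiency modelling** — GC, RNA/DNA-hybrid
  nearest-neighbor Tm, hybridization free energy at 65 °C, a weighted
  minimum-folding-energy recursion (PMFE), hairpin and dimer scores;
  successful-probe selection (10 % of mean … 99th percentile), |r| > 0.95
  correlation pruning, OLS with backward significance pruning, and exact
  LMG relative-importance decomposition.
- **Divergence and phylogeny** — Nei–Gojobori-style counting Ka/Ks with
  Jukes–Cantor correction, divergence dating `T = Ks / (2 · 6.9e-9)`, SNP
  mismatch distance matrices, and bootstrap neighbor-joining trees.
- **Synthetic data** — generators for every input above with known ground
  truth (planted dosages, copy-number multipliers, absence events, probe
  structure, target Ks, tree topology), byte-deterministic under a seed.

## Command line

All stages are subcommands of `polycap`:

```sh
polycap simulate --config config.json --seed 1 --out simdir/
polycap filter --vcf simdir/variants.vcf --out passed.vcf --report tally.tsv
polycap concord --sets samtools=a.vcf --sets gatk=b.vcf --sets freebayes=c.vcf
polycap dosage --counts simdir/locus_counts.tsv --ploidy-map ploidy.tsv \
    --out genotypes.tsv --summary sdm.tsv
polycap cnv --depths simdir/gene_depths.tsv --query q --subject s --out cnv.tsv
polycap pav --depths simdir/gene_depths.tsv --query q --subject s --out pav.tsv
polycap annotate --vcf passed.vcf --gff simdir/genes.gff3 \
    --fasta simdir/genome.fasta --out annotated.tsv
polycap probe-features --fasta simdir/probes.fasta \
    --counts simdir/probe_counts.tsv --out features.tsv
polycap fit-capture --features features.tsv --out model.json
polycap coverage --depth depth.tsv --probes probes.bed --flank 100 --out msd.tsv
polycap divergence --pairs simdir/cds_pairs/ --out kaks.tsv
polycap tree --genotypes matrix.tsv --boot 1000 --seed 1 --out tree.nwk
```

## Formats

Internal coordinates are 0-based half-open; VCF stays 1-based at the
parse/emit boundary and GFF3 is converted on read. The VCF dialect
requires per-sample `AD` and site `INFO/MQ`; base quality is read from
`INFO/BQ` or `INFO/BaseQRankSum` (auto-detected, selectable via
`bq_key`). Records missing a required key are retained and routed to an
*unfilterable* bucket rather than dropped. Depth tables, count tables and
genotype matrices are plain TSV with a header row and `#` comments.

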