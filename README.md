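# ldpanel

Low-density SNP panel design and genotype-imputation accuracy evaluation
for pedigreed breeding populations.

Medium- and high-density SNP arrays are often too expensive for routine
genotyping in small-scale breeding programs (the motivating case is
aquaculture broodstock management). A cost-effective alternative genotypes
most animals on a small panel — a few hundred to a few thousand markers —
and imputes the remaining genotypes from a reference population typed at
full density, exploiting pedigree relationships and shared haplotypes.
Whether that works hinges on one question: **how much accuracy is lost at
each panel density?**

`ldpanel` implements the full evaluation pipeline as a Python library:

* **`simdata`** — pedigreed, LD-structured synthetic genotype data
  (ancestral-haplotype mosaic founders, Balding–Nichols population
  divergence, gene dropping with Haldane recombination, controlled
  missingness and genotyping error). Every downstream stage is testable
  against known ground truth without any external data.
* **`qc`** — marker/sample quality control: MAF, call rate, the exact
  Hardy–Weinberg test (Bonferroni-corrected), Mendelian-error exclusion
  with `--me`-style trio/marker bounds.
* **`panels`** — low-density panel construction: sliding-window LD pruning
  over an r² threshold ladder, per-population panel intersection, nested
  density tiers, per-chromosome coverage reports.
* **`imputer`** — family-based imputation: Mendelian trio phasing plus
  surrogate-haplotype refinement builds a phased reference library; masked
  genotypes are filled by pedigree-forced transmission, shrinking-window
  haplotype matching, and an allele-frequency fallback.
* **`evaluation`** — masking cross-validation: individuals are partitioned
  into folds, each fold's genotypes are hidden down to a panel, imputed
  back, and scored per SNP and per individual.
* **`popgen`** — panel validation on field populations: MAF spectrum,
  heterozygosity, IBS matrix with classical (Torgerson) MDS, admixture
  clustering by EM, and Evanno ΔK choice of the cluster number K.
* **`io` / `pipeline`** — PLINK PED/MAP and VCF round trips (minor-allele
  dosage polarity), and a one-call `run_pipeline` driving every stage from
  a YAML config into an artifacts directory with a hashed manifest.

## The accuracy statistic

Genotypes are coded as minor-allele dosage g ∈ {0, 1, 2}. For each masked
SNP (and symmetrically for each validation individual), accuracy is the
Pearson correlation between imputed and true genotypes,

```
R = Σᵢ (xᵢ − x̄)(gᵢ − ḡ) / sqrt( Σᵢ (xᵢ − x̄)² · Σᵢ (gᵢ − ḡ)² )
```

where xᵢ is the imputed genotype (real-valued expected dosage by default,
hard calls optionally) and gᵢ the true genotype of individual i, with the
sum over the n validation genotypes compared. Summaries report mean, SD,
min, max and the percentage of SNPs with R > 0.8, plus accuracy profiles
by MAF bin and by position along each chromosome (chromosome ends are
known to impute worse).

## Worked example

`examples/04_impute_and_evaluate.py` simulates the default breeding design
(34 parents + 238 offspring in 18 half/full-sib families) at 4 × 150
markers, applies QC, builds a nested panel ladder and runs a 5-replicate
masking cross-validation:

```
  tier  panel_snps  imputed_snps  snp_mean  snp_sd  snp_pct_gt_0.8  ind_mean  baseline_snp_mean
0.1K.1          38           333     0.495   0.147           1.502     0.566             -0.107
  0.1K          76           296     0.666   0.128          13.514     0.716             -0.107
  0.2K         152           221     0.793   0.101          53.846     0.821             -0.110
  0.3K         303            70     0.893   0.045          97.143     0.904             -0.108
  0.4K         369             4     0.913   0.034         100.000     0.938             -0.101
```

Each row is one panel density tier: `panel_snps` markers stay visible,
`imputed_snps` are hidden and imputed, `snp_mean` is the mean per-SNP R
over those markers and `snp_pct_gt_0.8` the share imputed accurately
(R > 0.8). Accuracy falls smoothly as the panel shrinks, while the
allele-frequency baseline (`baseline_snp_mean`, near zero) shows that all
of the signal comes from pedigree and haplotype information. The other
examples cover simulation, QC accounting, panel coverage and population
structure (`examples/01…05`).

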