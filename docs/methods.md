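# Methods

This note documents the models, algorithms and design choices behind
`ldpanel`: what the synthetic data emulate, how the imputer works, how
accuracy is scored, and where the genuinely open decisions were made.

## Synthetic study populations

The generator produces three scenario presets mirroring the study designs
the pipeline is meant for:

* **`breeding_population`** — a hatchery population of 272 genotyped
  animals: 238 offspring in 18 half/full-sib families plus 34 genotyped
  parents. The mating design is four sires with two dams each (8
  families), three sires sharing one dam (3), two sires sharing one dam
  (2), and five single pairs (5). That design uses 29 distinct breeding
  parents; five additional genotyped broodstock founders carry no
  offspring, bringing the genotyped parents to 34. Offspring counts are
  near-equal across families (238 = 4×14 + 14×13, remainder to the
  earliest families) because per-family counts are not otherwise
  constrained.
* **`five_broodstocks`** — five unrelated farm samples of sizes
  20/33/9/9/10, each drawn from its own diverged population.
* **`two_regions`** — two regional populations of 96 individuals each at
  a configurable Fst (default 0.15).

**Linkage disequilibrium.** Founder haplotypes are mosaics over a small
pool of ancestral haplotypes (a Li–Stephens-style model): the source
ancestor switches along the chromosome as a Poisson process in genetic
distance. Defaults — 5 ancestral haplotypes, 0.05 switches/cM on 100 cM
chromosomes of 200 markers — give strong, block-like local LD (adjacent
r² ≈ 0.3, with frequent near-duplicate marker pairs) that decays with
distance, resembling a commercial array on a recently-bottlenecked farmed
population. A small pool is deliberate: it also makes roughly 40% of
generated markers rare or monomorphic, so the QC stage has realistic work
to do (roughly the survival fraction seen on real arrays).

**Population divergence** follows the Balding–Nichols model: given the
ancestral frequency p and divergence F, each population's frequency is
drawn from Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and variance
F·p(1−p). Frequencies at exactly 0 or 1 are clamped into
[10⁻⁴, 1−10⁻⁴] with a warning.

**Transmission** is gene dropping: founders draw two pool haplotypes
without replacement; each offspring gamete recombines the parent's pair
with Poisson(L/100) crossovers placed uniformly in cM (Haldane, no
interference). Physical positions map 1 cM ≈ 1 Mb; only marker order and
cM distances matter to any stage.

**Noise.** Each genotype is independently dropped to missing
(default 2%) or replaced by a uniformly random different genotype
(default 0.5%), giving call rates in the high-90s. Array vendors publish
no usable per-genotype error model, so the symmetric-replacement model is
a package choice.

What the simulator does **not** emulate: ascertainment bias of array SNP
selection, long-range admixture LD, genotype-error structure correlated
with probe chemistry, sex chromosomes, mutation and selection. Passing
tests therefore demonstrate correctness of the pipeline's logic and the
qualitative density/accuracy phenomena, not the numeric accuracy values
any particular real array would achieve.

## Quality control

Filters are applied in a configurable order (default: HWE → call rate →
MAF; Mendelian exclusion available as a step when a pedigree is present).

* **HWE** uses the exact conditional test (Wigginton-style enumeration of
  heterozygote counts, plain rather than mid-p), chosen for correct
  behavior at the tiny sample sizes of broodstock panels (N = 9–10).
  The Bonferroni divisor is the number of markers in the current dataset.
  Because that divisor shrinks as markers are removed, the whole filter
  sequence is iterated to a fixed point; re-applying QC with the same
  thresholds is then exactly the identity. Pass-1 rows of the report give
  the familiar per-step accounting; later passes are tagged.
* **Mendelian errors** follow PLINK `--me a b` semantics: a trio-marker
  cell is an error when the offspring dosage is impossible given observed
  parental dosages (duos use the one-parent rule); offspring above the
  trio bound are dropped, markers above the marker bound removed.
* **MAF** is computed over the whole population (not within families),
  on non-missing calls only.

## Panel construction

Pairwise LD is the squared Pearson correlation of dosage vectors over
individuals non-missing at both markers (composite LD on genotypes, not
EM-phased haplotype r² — simpler, deterministic, and what genotype-level
pruning tools act on). Pruning slides a window (default 50 markers, step
5 — the conventional window geometry, config-exposed) and repeatedly
resolves the currently worst offending pair by removing its lower-MAF
member (ties: the later map position), so at least one member of every
pair survives and no retained within-window pair exceeds the threshold.
Undefined (zero-variance) pairs count as r² = 0.

Per-population panels can be intersected in map order (an empty
intersection is an explicit error with diagnostics). Panel labels derive
from rounded marker counts ("1K", "0.5K", …).

**The experiment ladder.** The default five-tier ladder
(`nested_density_ladder`) takes the 0.9-pruned panel, the successive
0.6-pruned panel, and uniform thinnings of the latter by factors 2/4/8
(divisible factors keep the ladder nested) — about 94/70/35/17.5/8.7% of
QC'd markers. The tiers were placed so that, on the default simulated
population, mean accuracy spans the range reported for commercial
low-density arrays (R ≈ 0.6–0.95) and the lowest tier sits in the regime
where chromosome-end degradation is the dominant failure mode; at far
lower densities the simulator's shorter-range LD degrades interiors and
ends alike, which is a property of the generator rather than of real
array data.

## Imputation

The imputer is an in-package, deterministic family-based method (the
external tools it stands in for are cited in the literature but their
algorithms are not public contracts). Three passes:

1. **Reference phasing / haplotype library.** Missing reference genotypes
   are completed with the frequency hard call. Homozygous sites phase
   trivially; heterozygous sites of trio members resolve by Mendelian
   rules whenever a parent is homozygous. Remaining heterozygous sites are
   oriented by the sign of local LD, chained along the chromosome from the
   nearest anchored site (the covariance sign of adjacent dosage columns,
   composed transitively). Four surrogate-refinement rounds follow: in
   half-overlapping 100-marker windows, each individual's genotype is
   explained by the best pair of other individuals' haplotypes
   (homozygous sites must agree; heterozygous sites need complementary
   donor alleles; 12 candidate first haplotypes with conditional second),
   and the winning pair re-phases the heterozygous sites, oriented by
   trio-anchored sites or, failing that, by the standing assignment.
   On the default population this phases ≥95% of trio-offspring
   heterozygous sites to the correct parental origin.
2. **Pedigree pass.** Entries forced by transmission — both parents in
   the reference and homozygous — are filled directly.
3. **Haplotype matching.** Each target chromosome is matched against the
   library on its observed panel alleles in shrinking windows (whole
   chromosome, halves, quarters, …): the first haplotype maximizes
   agreement−mismatch over homozygous observed sites (ties prefer more
   frequent, then earlier library rows; tied-top candidates are searched
   up to a cap, plus the target's parental haplotypes when known), the
   second maximizes the complementary score. A window with a
   mismatch-free pair is filled and the recursion stops; otherwise it
   splits, but never below 32 markers or below 8 observed markers per
   half — windows with too few observations cannot discriminate
   haplotypes. Anything left (e.g., chromosomes with no observed markers)
   is filled with expected dosage 2f from reference frequencies.

Outputs carry per-entry provenance (observed / pedigree / haplotype /
frequency) and real-valued expected dosage next to the hard call
(rounding ties go to the heterozygote). Accuracy is computed on expected
dosages by default, hard calls optionally — the correlation statistic
admits both. `baseline_impute` (frequency fill only) provides the
accuracy floor every report can be compared against.

## Cross-validation and accuracy analytics

Folds are a strict random partition into near-equal validation sets
(272 animals in 10 folds → sizes 27/28; a "27 to 29" spread would imply
resampling rather than a partition, and the partition guarantees every
individual is validated exactly once). The reference library is rebuilt
once per replicate and shared across panel tiers.

Per-SNP R pools (imputed, true) pairs over all validation individuals
across replicates — each marker is scored on the whole population rather
than on ~27 animals per replicate; per-individual R is computed over that
individual's masked markers. Zero-variance vectors give undefined R,
excluded from summaries with their count reported. Summaries use the
population SD (n divisor) and a strict R > 0.8 threshold. Profiles:
mean R per MAF bin (half-open bins, default edges 0.01/0.05/0.1/0.2/0.3/
0.4/0.5) and per chromosome end versus interior (first/last n_end scored
markers per chromosome in map order; short chromosomes contribute
everything and are flagged).

## Population analytics

IBS similarity between two individuals is the mean allele-sharing
proportion (2 − |dᵢ − dⱼ|)/2 over markers observed in both. Classical
MDS double-centers squared distances, eigendecomposes, truncates negative
eigenvalues to zero, and fixes each axis's sign so its largest-magnitude
coordinate is positive (reproducibility of plots and tests).

Admixture clustering maximizes the binomial admixture likelihood
Π Binom(d | 2, Σₖ qᵢₖ pₖₘ) with the standard multiplicative EM updates
from random Dirichlet initialization — a deterministic-given-seed,
desk-scale counterpart of Bayesian MCMC clustering, sufficient for the
label-recovery and K-selection claims the package validates. The
log-likelihood is non-decreasing per iteration (clipping of P at
[10⁻¹², 1−10⁻¹²] can perturb it below 10⁻⁸). K = 1 is closed-form.
Evanno's ΔK is the mean absolute second difference of log-likelihood
across K divided by the replicate SD (sample SD), undefined at grid ends,
infinite (flagged) at zero SD; the default grid is K = 1–3 with 5
replicate seeds.

## Interfaces

Genotypes round-trip through PLINK text PED/MAP and VCF v4.2 (GT only;
genetic positions in INFO/CM). Internal polarity is always minor-allele
dosage: readers re-polarize (frequency ties break toward the
alphabetically first allele) and record flips. The pipeline driver runs
every stage from one YAML config and writes a manifest with SHA-256
hashes of all outputs; identical configs give identical manifests.

The package is import-first: the `examples/` scripts are the narrative
interface, and `run_pipeline` plus the acceptance script cover batch use,
so no console-script CLI is shipped.

## Numerical and testing choices

* Exact-test agreement between the Wigginton recurrence and the
  independent log-factorial enumeration oracle is asserted to 10⁻¹²;
  both use a 10⁻⁷ relative slack when comparing table probabilities so
  borderline equal-probability tables are treated consistently.
* Scale: tests and the acceptance script run the study at 27 × 200
  markers — the package's default desk-scale study size — with the full
  272-animal pedigree and 10-replicate CV.
* Determinism: every stochastic step takes an explicit seed; matching and
  pruning tie-breaks are fully specified; repeated runs are bit-identical.

## Known limitations

* The imputer is a deterministic matcher, not a probabilistic HMM; its
  expected dosages are integer-valued except in the frequency fallback,
  so dosage-vs-hard-call accuracy differences are small by construction.
* Unregularized ML admixture absorbs sampling noise into Q at K above the
  true cluster number (null runs at K=2 sit near mean |q−0.5| ≈ 0.25,
  far from polarization but not at 0).
* Reference phasing quality bounds sparse-panel accuracy; founders with
  few relatives phase worst.
* No support for sex chromosomes, multiallelic markers, or binary
  PLINK/BCF containers.
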