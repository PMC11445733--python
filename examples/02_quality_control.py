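"""Run the marker QC stack and print the per-step accounting.

Filters follow the usual pre-imputation order: Hardy-Weinberg exact test
(Bonferroni-corrected), marker call rate, then minor allele frequency.
"""

import ldpanel as lp

cfg = lp.SimConfig(n_chromosomes=4, markers_per_chromosome=150, seed=1)
study = lp.simulate_study(cfg, "breeding_population")

thresholds = lp.QcThresholds(maf_min=0.01, marker_call_rate_min=0.90,
                             hwe_alpha=0.05, hwe_bonferroni=True)
g_qc, report = lp.apply_qc(study.bundle.genotypes, study.bundle.pedigree, thresholds)

print(report.to_frame()[["step", "markers_before", "markers_removed",
                         "markers_after", "detail"]].to_string(index=False))
print(f"\nsurviving markers: {g_qc.n_markers} of {study.bundle.genotypes.n_markers}")
# Each row consumes the previous one's survivors; removed markers are
# mostly monomorphic or rare variants plus family-structure HWE outliers.
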