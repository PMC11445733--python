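"""Simulate a pedigreed breeding population and inspect its structure.

Generates the default hatchery design — 34 genotyped parents and 238
offspring in 18 half/full-sib families — at a reduced marker count, and
prints the basic shape of the dataset.
"""

import ldpanel as lp

cfg = lp.SimConfig(n_chromosomes=4, markers_per_chromosome=150, seed=1)
study = lp.simulate_study(cfg, "breeding_population")
g = study.bundle.genotypes
ped = study.bundle.pedigree

print(f"individuals: {g.n_individuals} ({len(ped.founders)} parents, "
      f"{g.n_individuals - len(ped.founders)} offspring)")
print(f"families:    {len(ped.families)}")
print(f"markers:     {g.n_markers} on {len(study.bundle.marker_map.chromosomes)} chromosomes")
print(f"missing:     {100 * g.missing_mask().mean():.2f}% of calls")

scan = lp.mendel_error_scan(study.clean_genotypes, ped)
print(f"Mendelian errors before noise injection: {scan.per_trio['errors'].sum()}")
# The pre-noise transmission is exactly Mendelian; the observed matrix adds
# the configured missingness and genotyping-error rates on top.
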