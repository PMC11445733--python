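"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities from first principles
(log-factorial enumeration, textbook formulas, brute-force scans) so the
implementation under test is never checked against itself.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import ldpanel as lp
from ldpanel.core import MISSING, GenotypeMatrix, MarkerMap


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact HWE p-value by direct log-factorial enumeration of every table
    with the observed allele counts and sample size."""
    n = n_hom_a + n_het + n_hom_b
    rare = 2 * min(n_hom_a, n_hom_b) + n_het
    common = 2 * n - rare
    if rare == 0:
        return 1.0

    def log_prob(h: int) -> float:
        hr = (rare - h) // 2
        hc = (common - h) // 2
        return (math.lgamma(n + 1) - math.lgamma(hr + 1) - math.lgamma(h + 1)
                - math.lgamma(hc + 1) + h * math.log(2)
                + math.lgamma(rare + 1) + math.lgamma(common + 1)
                - math.lgamma(2 * n + 1))

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1.0 + 1e-7)))


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation: sum of cross-deviations over the root
    product of squared deviations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    num = ((x - xm) * (y - ym)).sum()
    den = math.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum())
    return num / den if den > 0 else float("nan")


def brute_force_window_violations(g: GenotypeMatrix, mmap: MarkerMap,
                                  retained: list[str], r2_threshold: float,
                                  window_size: int, step: int) -> int:
    """Count retained within-window pairs exceeding the threshold, by
    exhaustive pairwise scan of every window position."""
    kept = set(retained)
    order = [mk for mk in g.markers if mk in kept]
    pos = {mk: j for j, mk in enumerate(g.markers)}
    chroms = mmap.table.set_index("marker")["chrom"]
    violations = 0
    for c in mmap.chromosomes:
        on_c = [mk for mk in g.markers if chroms[mk] == c]
        kept_c = [mk for mk in on_c if mk in kept]
        for start in range(0, max(len(on_c) - 1, 1), step):
            win = set(on_c[start:start + window_size])
            inside = [mk for mk in kept_c if mk in win]
            for a in range(len(inside)):
                for b in range(a + 1, len(inside)):
                    r2 = lp.pairwise_r2(g, inside[a], inside[b])
                    if not np.isnan(r2) and r2 > r2_threshold + 1e-9:
                        violations += 1
            if start + window_size >= len(on_c):
                break
    return violations


def make_matrix(dosages, individuals=None, markers=None) -> GenotypeMatrix:
    d = np.asarray(dosages, dtype=np.int8)
    individuals = individuals or [f"i{k}" for k in range(d.shape[0])]
    markers = markers or [f"m{k}" for k in range(d.shape[1])]
    return GenotypeMatrix(d, individuals, markers)


def make_map(n_markers: int, n_chrom: int = 1, markers=None) -> MarkerMap:
    per = n_markers // n_chrom
    rows = []
    k = 0
    for c in range(1, n_chrom + 1):
        for j in range(per):
            mk = markers[k] if markers else f"m{k}"
            rows.append((mk, c, j * 1000 + 1, float(j), "A", "B"))
            k += 1
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


# --------------------------------------------------------------------------
# shared simulated datasets (session-scoped: several tests reuse them)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_study():
    """The full default study population: 272 individuals, 27 x 200 markers."""
    return lp.simulate_study(lp.SimConfig(seed=1), "breeding_population")


@pytest.fixture(scope="session")
def default_qc(default_study):
    g, rep = lp.apply_qc(default_study.bundle.genotypes,
                         default_study.bundle.pedigree, lp.QcThresholds())
    mmap = default_study.bundle.marker_map.subset(g.markers)
    return g, mmap, rep


@pytest.fixture(scope="session")
def small_study():
    """A light pedigreed dataset for fast unit tests (4 chromosomes)."""
    cfg = lp.SimConfig(n_chromosomes=4, markers_per_chromosome=120, seed=9)
    return lp.simulate_study(cfg, "breeding_population")


@pytest.fixture(scope="session")
def small_qc(small_study):
    g, _ = lp.apply_qc(small_study.bundle.genotypes,
                       small_study.bundle.pedigree, lp.QcThresholds())
    mmap = small_study.bundle.marker_map.subset(g.markers)
    return g, mmap
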