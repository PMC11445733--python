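"""Pedigreed, LD-structured synthetic genotype data.

The generator emulates the study designs every downstream stage needs:

* ``breeding_population`` — a hatchery population of 34 genotyped parents
  and 238 offspring in 18 half/full-sib families;
* ``five_broodstocks`` — five small unrelated broodstock samples
  (N = 20, 33, 9, 9, 10) from diverged farm populations;
* ``two_regions`` — two regional populations of 96 individuals each at a
  configurable Fst.

Linkage disequilibrium comes from a Li–Stephens-style mosaic: every founder
haplotype is a patchwork of a small pool of ancestral haplotypes, with the
source ancestor switching along the chromosome as a Poisson process.
Population divergence follows the Balding–Nichols model: per-population
allele frequencies are Beta-distributed around the ancestral frequency with
variance ``F * p * (1 - p)``.  Transmission down the pedigree is simulated
by gene dropping with Haldane recombination (Poisson crossovers, no
interference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import MISSING, DatasetBundle, GenotypeMatrix, MarkerMap, Pedigree

SCENARIOS = ("breeding_population", "five_broodstocks", "two_regions")

# RNG stream tags so every stage draws from an independent, named substream.
_STREAM_ANCESTRAL_FREQ = 1
_STREAM_POP_FREQ = 2
_STREAM_ANCESTRAL_HAP = 3
_STREAM_MOSAIC = 4
_STREAM_GENE_DROP = 5
_STREAM_NOISE = 6


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generator.

    Defaults give a desk-scale analogue of the study populations: 27
    chromosomes of 200 markers (5,400 SNPs) on 100 cM maps, array-like
    flat founder frequencies, strong block-like local LD from a small
    (5-ancestor) mosaic with ~20 cM mean segment length, and call rates
    in the high-90s as on a commercial array.
    """

    n_chromosomes: int = 27
    markers_per_chromosome: int = 200
    map_length_cm: float = 100.0
    founder_maf_dist: tuple[float, float] = (1.0, 1.0)  # Beta(a, b)
    n_ancestral_haplotypes: int = 5
    switch_rate_per_cm: float = 0.05
    fst: float = 0.15
    missing_rate: float = 0.02
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one marker")
        if self.map_length_cm < 0:
            raise ValueError("map length must be non-negative")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        for name in ("missing_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        a, b = self.founder_maf_dist
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.n_ancestral_haplotypes < 1:
            raise ValueError("need at least one ancestral haplotype")
        if self.switch_rate_per_cm < 0:
            raise ValueError("switch rate must be non-negative")


def _rng(cfg: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *tags])


def build_marker_map(cfg: SimConfig) -> MarkerMap:
    """Evenly spaced markers; 1 cM is mapped to 1 Mb of physical position."""
    rows = []
    m = cfg.markers_per_chromosome
    for c in range(1, cfg.n_chromosomes + 1):
        if m == 1:
            cm = np.array([cfg.map_length_cm / 2.0])
        else:
            cm = np.linspace(0.0, cfg.map_length_cm, m)
        bp = np.round(cm * 1_000_000).astype(int) + np.arange(m) + 1
        for j in range(m):
            rows.append((f"c{c:02d}_{j + 1:05d}", c, int(bp[j]), float(cm[j]), "A", "B"))
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


@dataclass
class FounderPool:
    """Binary founder haplotypes per chromosome plus the frequencies used."""

    haplotypes: list[np.ndarray]          # per chromosome: (n_hap, m) uint8
    frequencies: list[np.ndarray]         # per chromosome: (m,) population freqs
    ancestral: list[np.ndarray]           # per chromosome: (n_anc, m) uint8
    population_index: int

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes[0].shape[0]


def _population_frequencies(cfg: SimConfig, population_index: int) -> list[np.ndarray]:
    rng = _rng(cfg, _STREAM_ANCESTRAL_FREQ)
    a, b = cfg.founder_maf_dist
    m = cfg.markers_per_chromosome
    ancestral = [rng.beta(a, b, size=m) for _ in range(cfg.n_chromosomes)]
    if population_index == 0:
        return ancestral
    prng = _rng(cfg, _STREAM_POP_FREQ, population_index)
    F = cfg.fst
    out = []
    for p in ancestral:
        clipped = np.clip(p, 1e-4, 1 - 1e-4)
        if np.any(p != clipped):
            warnings.warn("ancestral frequency at 0 or 1 clamped for Balding-Nichols draw")
        scale = (1.0 - F) / F
        out.append(prng.beta(clipped * scale, (1.0 - clipped) * scale))
    return out


def generate_founder_haplotypes(cfg: SimConfig, population_index: int = 0,
                                n_haplotypes: int = 100) -> FounderPool:
    """Draw a pool of mosaic founder haplotypes for one population.

    Ancestral haplotypes are Bernoulli draws at the population's allele
    frequencies (Balding–Nichols-diverged for ``population_index > 0``);
    each founder haplotype then copies from a random ancestor, switching
    ancestor along the chromosome as a Poisson(``switch_rate_per_cm``)
    process in genetic distance.
    """
    freqs = _population_frequencies(cfg, population_index)
    hrng = _rng(cfg, _STREAM_ANCESTRAL_HAP, population_index)
    mrng = _rng(cfg, _STREAM_MOSAIC, population_index)
    n_anc = cfg.n_ancestral_haplotypes
    m = cfg.markers_per_chromosome
    L = cfg.map_length_cm
    cm = (np.array([L / 2.0]) if m == 1 else np.linspace(0.0, L, m))

    ancestral, pool = [], []
    for p in freqs:
        anc = (hrng.random((n_anc, m)) < p[None, :]).astype(np.uint8)
        ancestral.append(anc)
        haps = np.empty((n_haplotypes, m), dtype=np.uint8)
        for h in range(n_haplotypes):
            n_switch = mrng.poisson(cfg.switch_rate_per_cm * L)
            cuts = np.sort(mrng.uniform(0.0, L, size=n_switch))
            sources = mrng.integers(0, n_anc, size=n_switch + 1)
            seg = np.searchsorted(cuts, cm, side="right")
            haps[h] = anc[sources[seg], np.arange(m)]
        pool.append(haps)
    return FounderPool(pool, freqs, ancestral, population_index)


@dataclass
class PhasedGenotypes:
    """Phased diplotypes: (n_individuals, 2, n_markers); axis 1 = (paternal, maternal)."""

    haplotypes: np.ndarray
    individuals: np.ndarray
    marker_map: MarkerMap

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.haplotypes.sum(axis=1).astype(np.int8),
                              self.individuals, self.marker_map.markers)


def _recombine(hap_a: np.ndarray, hap_b: np.ndarray, cm: np.ndarray,
               length_cm: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two chromosome haplotypes (Haldane)."""
    n_xo = rng.poisson(length_cm / 100.0)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return (hap_a if start == 0 else hap_b).copy()
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    phase = (start + np.searchsorted(cuts, cm, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8)


def gene_drop(cfg: SimConfig, pedigree: Pedigree, pool: FounderPool,
              founder_assignment: dict[str, tuple[int, int]] | None = None) -> PhasedGenotypes:
    """Drop founder haplotypes through the pedigree with Haldane recombination.

    Founders receive two pool haplotypes sampled without replacement;
    every offspring gamete is a recombinant of the parent's two haplotypes
    with Poisson(``map_length_cm / 100``) crossovers per chromosome.
    """
    founders = pedigree.founders
    if founder_assignment is None:
        if 2 * len(founders) > pool.n_haplotypes:
            raise ValueError(
                f"pool of {pool.n_haplotypes} haplotypes cannot supply "
                f"{len(founders)} founders without replacement")
        arng = _rng(cfg, _STREAM_GENE_DROP, 0, pool.population_index)
        picks = arng.permutation(pool.n_haplotypes)[: 2 * len(founders)]
        founder_assignment = {f: (int(picks[2 * i]), int(picks[2 * i + 1]))
                              for i, f in enumerate(founders)}

    mmap = build_marker_map(cfg)
    chrom_slices = [mmap.chrom_slice(c) for c in range(1, cfg.n_chromosomes + 1)]
    m = cfg.markers_per_chromosome
    L = cfg.map_length_cm
    cm = (np.array([L / 2.0]) if m == 1 else np.linspace(0.0, L, m))
    rng = _rng(cfg, _STREAM_GENE_DROP, 1, pool.population_index)

    order = pedigree.topological_order()
    haps: dict[str, np.ndarray] = {}
    total = len(mmap)
    for ind in order:
        sire, dam = pedigree.parents_of(ind)
        out = np.empty((2, total), dtype=np.uint8)
        if sire is None and dam is None:
            i0, i1 = founder_assignment[ind]
            for c, sl in enumerate(chrom_slices):
                out[0, sl] = pool.haplotypes[c][i0]
                out[1, sl] = pool.haplotypes[c][i1]
        else:
            if sire is None or dam is None:
                raise ValueError(f"{ind!r} has exactly one known parent")
            for parent, row in ((sire, 0), (dam, 1)):
                ph = haps[parent]
                for c, sl in enumerate(chrom_slices):
                    out[row, sl] = _recombine(ph[0, sl], ph[1, sl], cm, L, rng)
        haps[ind] = out

    ids = list(pedigree.individuals)
    stacked = np.stack([haps[i] for i in ids], axis=0)
    return PhasedGenotypes(stacked, np.asarray(ids, dtype=object), mmap)


def apply_genotyping_noise(g: GenotypeMatrix, cfg: SimConfig,
                           rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Independently drop calls to MISSING and corrupt calls to a random
    different genotype; the input matrix is left unmodified."""
    if rng is None:
        rng = _rng(cfg, _STREAM_NOISE)
    d = g.dosages.copy()
    u = rng.random(d.shape)
    err_u = rng.random(d.shape)
    err_pick = rng.integers(0, 2, size=d.shape)
    observed = d != MISSING
    make_missing = observed & (u < cfg.missing_rate)
    make_error = observed & ~make_missing & (err_u < cfg.error_rate)
    # replacement: uniform over the two genotypes other than the current one
    alt = np.array([[1, 2], [0, 2], [0, 1]], dtype=np.int8)
    safe = np.clip(d, 0, 2).astype(np.intp)
    replacement = alt[safe, err_pick]
    d = np.where(make_error, replacement, d)
    d[make_missing] = MISSING
    return GenotypeMatrix(d.astype(np.int8), g.individuals, g.markers)


def breeding_pedigree(offspring_total: int = 238) -> Pedigree:
    """The hatchery mating design: 18 half/full-sib families.

    Four sires with two dams each (8 families), three sires sharing one dam
    (3 families), two sires sharing one dam (2 families), and five single
    pairs (5 families); five additional genotyped broodstock founders carry
    no offspring, giving 34 genotyped parents in total.  Offspring counts
    are near-equal across families, with the remainder assigned to the
    earliest families.
    """
    sires = [f"S{i:02d}" for i in range(1, 15)]
    dams = [f"D{i:02d}" for i in range(1, 16)]
    extras = [f"X{i:02d}" for i in range(1, 6)]
    matings: list[tuple[str, str]] = []
    matings += [(sires[i], dams[2 * i + j]) for i in range(4) for j in range(2)]  # 8
    matings += [(sires[4 + i], dams[8]) for i in range(3)]                        # 3
    matings += [(sires[7 + i], dams[9]) for i in range(2)]                        # 2
    matings += [(sires[9 + i], dams[10 + i]) for i in range(5)]                   # 5
    assert len(matings) == 18

    base, rem = divmod(offspring_total, len(matings))
    records = [(p, None, None, None) for p in sires + dams + extras]
    child = 0
    for fam_idx, (s, d) in enumerate(matings, start=1):
        fam = f"F{fam_idx:02d}"
        n_off = base + (1 if fam_idx <= rem else 0)
        for _ in range(n_off):
            child += 1
            records.append((f"O{child:03d}", s, d, fam))
    return Pedigree.from_records(records)


@dataclass
class SimulatedStudy:
    """A simulated dataset plus the ground truth the generator knows."""

    bundle: DatasetBundle                      # observed (noisy) genotypes
    clean_genotypes: GenotypeMatrix            # pre-noise dosages
    haplotypes: np.ndarray | None              # (n, 2, m) true phase, minor-allele coded
    labels: pd.Series                          # individual -> population label
    config: SimConfig = field(repr=False, default=None)


def _polarize_to_minor(geno: np.ndarray, haps: np.ndarray | None,
                       mmap: MarkerMap) -> tuple[np.ndarray, np.ndarray | None, MarkerMap]:
    """Flip columns whose counted-allele frequency exceeds 0.5 and swap
    allele labels so dosage is always the minor-allele count."""
    freq = geno.mean(axis=0) / 2.0
    flip = freq > 0.5
    geno = np.where(flip[None, :], 2 - geno, geno).astype(np.int8)
    if haps is not None:
        haps = np.where(flip[None, None, :], 1 - haps, haps).astype(np.uint8)
    tab = mmap.table.copy()
    a = tab["allele_a"].to_numpy().copy()
    b = tab["allele_b"].to_numpy().copy()
    tab["allele_a"] = np.where(flip, b, a)
    tab["allele_b"] = np.where(flip, a, b)
    return geno, haps, MarkerMap(tab)


def _founder_only_population(cfg: SimConfig, ids: list[str], population_index: int,
                             family: str | None) -> tuple[np.ndarray, list[tuple]]:
    pool = generate_founder_haplotypes(cfg, population_index, n_haplotypes=2 * len(ids))
    ped = Pedigree.from_records([(i, None, None, family) for i in ids])
    phased = gene_drop(cfg, ped, pool)
    return phased.haplotypes, [(i, None, None, family) for i in ids]


def simulate_study(cfg: SimConfig, design: str) -> SimulatedStudy:
    """Generate one of the named study scenarios, reproducibly from the seed."""
    if design not in SCENARIOS:
        raise ValueError(f"unknown scenario {design!r}; choose from {SCENARIOS}")
    mmap = build_marker_map(cfg)

    if design == "breeding_population":
        ped = breeding_pedigree()
        pool = generate_founder_haplotypes(cfg, 0, n_haplotypes=2 * len(ped.founders))
        phased = gene_drop(cfg, ped, pool)
        haps = phased.haplotypes
        ids = list(phased.individuals)
        labels = pd.Series("breeding", index=ids, name="population")
    elif design == "five_broodstocks":
        sizes = (20, 33, 9, 9, 10)
        hap_parts, records, lab = [], [], []
        for b, n in enumerate(sizes, start=1):
            ids_b = [f"B{b}_{i:02d}" for i in range(1, n + 1)]
            h, rec = _founder_only_population(cfg, ids_b, b, f"broodstock{b}")
            hap_parts.append(h)
            records += rec
            lab += [(i, f"broodstock{b}") for i in ids_b]
        haps = np.concatenate(hap_parts, axis=0)
        ped = Pedigree.from_records(records)
        ids = [i for i, _ in lab]
        labels = pd.Series({i: p for i, p in lab}, name="population").loc[ids]
    else:  # two_regions
        hap_parts, records, lab = [], [], []
        for r, (name, tag) in enumerate((("north", "N"), ("southeast", "S")), start=1):
            ids_r = [f"{tag}{i:03d}" for i in range(1, 97)]
            h, rec = _founder_only_population(cfg, ids_r, r, name)
            hap_parts.append(h)
            records += rec
            lab += [(i, name) for i in ids_r]
        haps = np.concatenate(hap_parts, axis=0)
        ped = Pedigree.from_records(records)
        ids = [i for i, _ in lab]
        labels = pd.Series({i: p for i, p in lab}, name="population").loc[ids]

    geno = haps.sum(axis=1).astype(np.int8)
    geno, haps, mmap = _polarize_to_minor(geno, haps, mmap)
    clean = GenotypeMatrix(geno, ids, mmap.markers)
    noisy = apply_genotyping_noise(clean, cfg)
    bundle = DatasetBundle(noisy, mmap, ped, labels,
                           metadata={"scenario": design, "seed": cfg.seed})
    return SimulatedStudy(bundle, clean, haps, labels, cfg)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """A copy of ``cfg`` with a different RNG seed."""
    return replace(cfg, seed=seed)
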