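"""Pedigree- and haplotype-library-based genotype imputation.

Fills masked genotypes of low-density-typed individuals from a
medium-density reference population in three passes:

1. **pedigree** — entries forced by Mendelian transmission (both parents
   homozygous in the reference) are filled directly;
2. **haplotype** — each target haplotype pair is matched against a library
   of phased reference haplotypes on the observed panel alleles, in
   shrinking windows (whole chromosome, halves, quarters, ... down to a
   minimum window); missing alleles are copied from the best-matching
   library haplotypes;
3. **frequency** — anything still unfilled gets the expected dosage
   ``2 f`` from reference allele frequencies.

Reference phasing combines Mendelian trio rules with a deterministic
population step: the relative phase of two nearby heterozygous sites is
oriented by the sign of the local linkage disequilibrium, chained along
the chromosome from the nearest trio-anchored site.  Every tie-break is
deterministic, so identical inputs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, MarkerMap, Pedigree

PROVENANCE_CODES = {"observed": 0, "pedigree": 1, "haplotype": 2, "frequency": 3}

# cap on extra tied-top candidates examined per matching window
_TIE_CAP = 32


def hard_call(expected: np.ndarray) -> np.ndarray:
    """Round expected dosage to the nearest genotype, ties toward the
    heterozygote (0.5 -> 1, 1.5 -> 1)."""
    e = np.asarray(expected, dtype=float)
    return np.where(e < 0.5, 0, np.where(e <= 1.5, 1, 2)).astype(np.int8)


@dataclass
class HaplotypeLibrary:
    """Phased reference haplotypes over the full marker set."""

    haplotypes: np.ndarray          # (2 * n_ref, n_markers) uint8
    allele_freq: np.ndarray         # (n_markers,) counted-allele frequency
    marker_map: MarkerMap
    source_individuals: np.ndarray  # (n_ref,) ids, haplotype rows 2i / 2i+1
    chrom_counts: dict              # chrom -> (n_hap,) multiplicity of each row

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def _fill_missing_by_frequency(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace MISSING with the frequency hard call; returns (filled, freq)."""
    obs = d != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs.sum(0) > 0,
                        np.where(obs, d, 0).sum(0) / (2.0 * np.maximum(obs.sum(0), 1)),
                        0.0)
    filled = np.where(obs, d, hard_call(2.0 * freq)[None, :]).astype(np.int8)
    return filled, freq


def _adjacent_ld_signs(d: np.ndarray) -> np.ndarray:
    """Sign (+1/-1) of the dosage covariance of each adjacent marker pair;
    zero covariance counts as +1."""
    x = d - d.mean(axis=0, keepdims=True)
    cov = (x[:, :-1] * x[:, 1:]).sum(axis=0)
    return np.where(cov < 0, -1, 1).astype(np.int8)


def _phase_chromosome(d: np.ndarray, trio_idx: list[tuple[int, int | None, int | None]]
                      ) -> np.ndarray:
    """Phase one chromosome of reference genotypes.

    ``d`` is (n, m) with no missing values; ``trio_idx`` lists
    (individual_row, sire_row or None, dam_row or None).  Returns
    (n, 2, m) haplotypes, axis 1 = (paternal, maternal) where trio
    information anchors the orientation, plus the (n, m) mask of sites
    whose phase is anchored (homozygous or trio-resolved).
    """
    n, m = d.shape
    hapA = np.full((n, m), -1, dtype=np.int8)
    hapB = np.full((n, m), -1, dtype=np.int8)
    hom = d != 1
    half = (d // 2).astype(np.int8)
    hapA[hom] = half[hom]
    hapB[hom] = half[hom]

    # Mendelian resolution at heterozygous sites of non-founders
    for i, si, di in trio_idx:
        het = d[i] == 1
        if si is not None:
            s_hom = het & (d[si] != 1)
            hapA[i, s_hom] = d[si, s_hom] // 2
            hapB[i, s_hom] = 1 - hapA[i, s_hom]
        if di is not None:
            d_hom = het & (d[di] != 1) & (hapA[i] == -1)
            hapB[i, d_hom] = d[di, d_hom] // 2
            hapA[i, d_hom] = 1 - hapB[i, d_hom]

    anchored = hapA != -1

    # population resolution: chain the remaining het sites to the nearest
    # anchored het via cumulative adjacent-LD signs
    if m > 1:
        signs = _adjacent_ld_signs(d)
        cum = np.concatenate([[1], np.cumprod(signs)]).astype(np.int8)
    else:
        cum = np.ones(1, dtype=np.int8)
    for i in range(n):
        het_pos = np.flatnonzero(d[i] == 1)
        if het_pos.size == 0:
            continue
        unresolved = het_pos[hapA[i, het_pos] == -1]
        if unresolved.size == 0:
            continue
        anchors = het_pos[hapA[i, het_pos] != -1]
        if anchors.size == 0:
            j0 = het_pos[0]
            hapA[i, j0], hapB[i, j0] = 1, 0
            anchors = het_pos[:1]
            unresolved = unresolved[unresolved != j0]
            if unresolved.size == 0:
                continue
        ins = np.searchsorted(anchors, unresolved)
        left = anchors[np.clip(ins - 1, 0, anchors.size - 1)]
        right = anchors[np.clip(ins, 0, anchors.size - 1)]
        nearest = np.where(
            (ins == 0), right,
            np.where(ins == anchors.size, left,
                     np.where(unresolved - left <= right - unresolved, left, right)))
        rel = cum[unresolved] * cum[nearest]
        a = np.where(rel > 0, hapA[i, nearest], 1 - hapA[i, nearest]).astype(np.int8)
        hapA[i, unresolved] = a
        hapB[i, unresolved] = 1 - a
    return np.stack([hapA, hapB], axis=1), anchored


def _refine_phase(haps: np.ndarray, d: np.ndarray, anchored: np.ndarray,
                  window: int = 100, n_candidates: int = 12) -> np.ndarray:
    """One surrogate-matching refinement round for one chromosome.

    For each individual, half-overlapping windows of its genotype are
    explained by the best pair of other individuals' haplotypes (homozygous
    sites must agree, heterozygous sites need complementary donor alleles);
    the donor pair then re-phases the heterozygous sites.  The pair's
    orientation is chained: trio-anchored sites vote first, otherwise the
    already-refined left overlap.  Exploits the surrogate-haplotype
    structure of a pedigreed population, where near-identical haplotypes
    recur across relatives.
    """
    n, _, m = haps.shape
    flat = np.vstack([haps[:, 0, :], haps[:, 1, :]]).astype(np.float32)
    B = 2.0 * flat - 1.0                       # (2n, m) in +/-1 coding
    out = haps.copy()
    step = max(window // 2, 1)
    for i in range(n):
        het = d[i] == 1
        if het.sum() < 2:
            continue
        own = np.array([i, n + i])
        c_full = np.where(d[i] == 2, 1.0, np.where(d[i] == 0, -1.0, 0.0)).astype(np.float32)
        for lo in range(0, m, step):
            hi = min(lo + window, m)
            hw = np.flatnonzero(het[lo:hi]) + lo
            if hw.size < 2:
                if hi >= m:
                    break
                continue
            Bw = B[:, lo:hi]
            s1 = Bw @ c_full[lo:hi]
            s1[own] = -np.inf
            cand = np.argsort(s1)[::-1][:n_candidates]
            best = None
            for ha in cand:
                c2 = c_full[lo:hi].copy()
                c2[hw - lo] = 1.0 - 2.0 * flat[ha, hw]   # complement at het sites
                s2 = Bw @ c2
                s2[own] = -np.inf
                hb = int(s2.argmax())
                key = float(s1[ha] + s2[hb])
                if best is None or key > best[0]:
                    best = (key, int(ha), hb)
            _, ha, hb = best
            don_a = flat[ha, hw]
            don_b = flat[hb, hw]
            ok = don_a + don_b == 1.0            # donor pair heterozygous too
            if not ok.any():
                if hi >= m:
                    break
                continue
            votes = hw[ok]
            don_ok = don_a[ok]
            is_anchor = anchored[i, votes]
            if is_anchor.any():
                agree = (out[i, 0, votes[is_anchor]] == don_ok[is_anchor]).mean()
            else:
                agree = (out[i, 0, votes] == don_ok).mean()
            if agree < 0.5:                      # swap donors to keep orientation
                don_ok = 1.0 - don_ok
            out[i, 0, votes] = don_ok.astype(np.int8)
            out[i, 1, votes] = (1.0 - don_ok).astype(np.int8)
            if hi >= m:
                break
    return out


def build_haplotype_library(g_ref: GenotypeMatrix, ped: Pedigree | None,
                            mmap: MarkerMap, refine_rounds: int = 4) -> HaplotypeLibrary:
    """Phase the reference population and collect its haplotypes.

    Missing reference genotypes are first completed with the frequency
    hard call (they are a small minority after QC); phasing then applies
    Mendelian trio rules and the LD-sign chain described in the module
    docstring, followed by ``refine_rounds`` surrogate-matching passes.
    """
    if not np.array_equal(g_ref.markers, mmap.markers):
        raise ValueError("reference markers must match the marker map")
    filled, freq = _fill_missing_by_frequency(g_ref.dosages)
    ind_pos = {ind: i for i, ind in enumerate(g_ref.individuals)}
    trio_idx: list[tuple[int, int | None, int | None]] = []
    if ped is not None:
        for ind, i in ind_pos.items():
            sire, dam = ped.parents_of(ind)
            si = ind_pos.get(sire) if sire is not None else None
            di = ind_pos.get(dam) if dam is not None else None
            if si is not None or di is not None:
                trio_idx.append((i, si, di))

    n = g_ref.n_individuals
    total = len(mmap)
    haps = np.empty((n, 2, total), dtype=np.int8)
    chrom_counts: dict = {}
    for chrom in mmap.chromosomes:
        sl = mmap.chrom_slice(chrom)
        phased, anchored = _phase_chromosome(filled[:, sl], trio_idx)
        for _ in range(refine_rounds):
            phased = _refine_phase(phased, filled[:, sl], anchored)
        haps[:, :, sl] = phased
        flat = phased.reshape(2 * n, sl.size)
        _, inverse, counts = np.unique(flat, axis=0, return_inverse=True, return_counts=True)
        chrom_counts[chrom] = counts[inverse]
    # interleave rows as (ind0 pat, ind0 mat, ind1 pat, ...)
    lib = np.empty((2 * n, total), dtype=np.uint8)
    lib[0::2] = haps[:, 0, :]
    lib[1::2] = haps[:, 1, :]
    counts_interleaved = {}
    for chrom, c in chrom_counts.items():
        cc = np.empty(2 * n, dtype=np.int64)
        cc[0::2] = c.reshape(n, 2)[:, 0]
        cc[1::2] = c.reshape(n, 2)[:, 1]
        counts_interleaved[chrom] = cc
    return HaplotypeLibrary(lib, freq, mmap, g_ref.individuals.copy(), counts_interleaved)


@dataclass
class ImputationResult:
    """Completed genotypes with per-entry provenance and expected dosage."""

    genotypes: GenotypeMatrix          # hard calls, no MISSING
    expected: np.ndarray               # (n, m) real-valued expected dosage
    provenance: np.ndarray             # (n, m) uint8, see PROVENANCE_CODES

    def provenance_counts(self) -> dict:
        names = {v: k for k, v in PROVENANCE_CODES.items()}
        vals, counts = np.unique(self.provenance, return_counts=True)
        return {names[int(v)]: int(c) for v, c in zip(vals, counts)}


def _match_window(B: np.ndarray, counts: np.ndarray, c_vec: np.ndarray,
                  het: np.ndarray, lo: int, hi: int,
                  n_candidates: int = 8,
                  extra_candidates: np.ndarray | None = None) -> tuple[int, int, int]:
    """Best haplotype pair for window [lo, hi); returns (h1, h2, mismatches).

    The first haplotype is searched among the ``n_candidates`` best rows by
    homozygous-site agreement; for each, the complementary second haplotype
    is chosen conditionally, and the pair with the highest joint score wins
    (score = agreements - mismatches over observed sites; ties prefer the
    more frequent haplotype, then library order).
    """
    Bw = B[:, lo:hi]
    cw = c_vec[lo:hi]
    s1 = Bw @ cw
    # at a homozygous observed site the per-site score is +/-1, so
    # mismatches = (n_hom_sites - score) / 2
    n_hom = int(np.abs(cw).sum())
    hetw = het[lo:hi]
    n_het = int(hetw.sum())
    order = np.lexsort((np.arange(s1.shape[0]), -counts, -s1))
    cand = order[:n_candidates]
    # a haplotype from a perfectly matching pair always ties the top
    # homozygous-site score, so widen the search to top-score ties (capped)
    tied = order[s1[order] >= s1[order[0]] - 1e-6][:_TIE_CAP]
    cand = np.concatenate([cand, tied])
    if extra_candidates is not None and extra_candidates.size:
        cand = np.concatenate([cand, extra_candidates])
    seen: set[int] = set()
    best = None
    for h1 in cand:
        h1 = int(h1)
        if h1 in seen:
            continue
        seen.add(h1)
        if n_het:
            target = (1 - (Bw[h1] + 1) // 2)[hetw].astype(np.float32)
            c2 = cw.copy()
            c2[hetw] = 2.0 * target - 1.0
            s2 = Bw @ c2
        else:
            s2 = s1
        o2 = np.lexsort((np.arange(s2.shape[0]), -counts, -s2))
        h2 = int(o2[0])
        total = float(s1[h1] + s2[h2])
        key = (total, float(counts[h1] + counts[h2]), -int(h1), -int(h2))
        if best is None or key > best[0]:
            mism = (n_hom - int(s1[h1])) // 2 + (n_hom + n_het - int(s2[h2])) // 2
            best = (key, int(h1), h2, mism)
            if mism == 0:
                break
    return best[1], best[2], best[3]


def _impute_chromosome(t: np.ndarray, filled: np.ndarray, exp: np.ndarray,
                       prov: np.ndarray, L: np.ndarray, B: np.ndarray,
                       counts: np.ndarray, freq: np.ndarray, min_window: int,
                       min_observed: int = 8,
                       family_rows: np.ndarray | None = None) -> None:
    """Shrinking-window haplotype matching for one target chromosome.

    Windows halve while a perfect pair match is not found, but never below
    ``min_window`` markers or ``min_observed`` observed panel markers — a
    window with too few observed sites cannot discriminate haplotypes.
    Arrays are chromosome-local views; ``filled`` marks entries already set
    (observed or pedigree).  Mutates ``exp``/``prov``/``filled`` in place.
    """
    m = t.shape[0]
    obs = t != MISSING
    if not obs.any():
        todo = ~filled
        exp[todo] = 2.0 * freq[todo]
        prov[todo] = PROVENANCE_CODES["frequency"]
        filled[todo] = True
        return
    c_vec = np.zeros(m, dtype=np.float32)
    c_vec[obs & (t == 2)] = 1.0
    c_vec[obs & (t == 0)] = -1.0
    het = obs & (t == 1)
    n_obs_cum = np.concatenate([[0], np.cumsum(obs)])

    stack = [(0, m)]
    while stack:
        lo, hi = stack.pop()
        if filled[lo:hi].all():
            continue
        h1, h2, mism = _match_window(B, counts, c_vec, het, lo, hi,
                                     extra_candidates=family_rows)
        half_obs = min(n_obs_cum[(lo + hi) // 2] - n_obs_cum[lo],
                       n_obs_cum[hi] - n_obs_cum[(lo + hi) // 2])
        if mism == 0 or (hi - lo) <= min_window or half_obs < min_observed:
            todo = ~filled[lo:hi]
            seg = (L[h1, lo:hi] + L[h2, lo:hi]).astype(float)
            exp[lo:hi][todo] = seg[todo]
            prov[lo:hi][todo] = PROVENANCE_CODES["haplotype"]
            filled[lo:hi][todo] = True
        else:
            mid = (lo + hi) // 2
            stack.append((mid, hi))
            stack.append((lo, mid))


def impute(g_low: GenotypeMatrix, g_ref: GenotypeMatrix, ped: Pedigree | None,
           mmap: MarkerMap, lib: HaplotypeLibrary | None = None,
           min_window: int = 32, seed: int | None = None) -> ImputationResult:
    """Impute every missing entry of ``g_low`` from the reference.

    ``g_low`` may carry any subset of the reference markers (others are
    treated as fully masked); its observed entries are passed through
    unchanged.  The algorithm is deterministic; ``seed`` is accepted for
    interface symmetry but no step draws randomness.
    """
    ref_markers = set(g_ref.markers.tolist())
    extra = [mk for mk in g_low.markers if mk not in ref_markers]
    if extra:
        raise ValueError(f"markers absent from reference: {extra[:5]}")
    if lib is None:
        lib = build_haplotype_library(g_ref, ped, mmap)

    n = g_low.n_individuals
    total = len(mmap)
    # expand target matrix onto the full marker set
    t_full = np.full((n, total), MISSING, dtype=np.int8)
    cols = mmap.positions(g_low.markers)
    t_full[:, cols] = g_low.dosages

    exp = np.zeros((n, total), dtype=float)
    prov = np.full((n, total), PROVENANCE_CODES["frequency"], dtype=np.uint8)
    filled = np.zeros((n, total), dtype=bool)
    observed = t_full != MISSING
    exp[observed] = t_full[observed]
    prov[observed] = PROVENANCE_CODES["observed"]
    filled[observed] = True

    # pedigree pass: entries forced by two homozygous reference parents
    if ped is not None:
        ref_pos = {ind: i for i, ind in enumerate(g_ref.individuals)}
        for i, ind in enumerate(g_low.individuals):
            sire, dam = ped.parents_of(ind)
            if sire in ref_pos and dam in ref_pos:
                s = g_ref.dosages[ref_pos[sire]]
                d = g_ref.dosages[ref_pos[dam]]
                forced = (~filled[i]) & (s != MISSING) & (d != MISSING) & (s != 1) & (d != 1)
                exp[i, forced] = (s[forced] // 2 + d[forced] // 2).astype(float)
                prov[i, forced] = PROVENANCE_CODES["pedigree"]
                filled[i, forced] = True

    # haplotype pass, chromosome by chromosome
    chrom_slices = {c: mmap.chrom_slice(c) for c in mmap.chromosomes}
    B_by_chrom = {}
    for c, sl in chrom_slices.items():
        B_by_chrom[c] = (2.0 * lib.haplotypes[:, sl] - 1.0).astype(np.float32)
    lib_pos = {ind: k for k, ind in enumerate(lib.source_individuals)}
    for i, ind in enumerate(g_low.individuals):
        fam_rows: list[int] = []
        if ped is not None:
            for parent in ped.parents_of(ind):
                if parent is not None and parent in lib_pos:
                    k = lib_pos[parent]
                    fam_rows += [2 * k, 2 * k + 1]
        fam = np.asarray(fam_rows, dtype=int)
        for c, sl in chrom_slices.items():
            lo, hi = sl[0], sl[-1] + 1
            _impute_chromosome(t_full[i, lo:hi], filled[i, lo:hi], exp[i, lo:hi],
                               prov[i, lo:hi], lib.haplotypes[:, lo:hi],
                               B_by_chrom[c], lib.chrom_counts[c],
                               lib.allele_freq[lo:hi], min_window,
                               family_rows=fam)

    # frequency pass mops up anything the other passes left
    todo = ~filled
    if todo.any():
        exp[todo] = (2.0 * lib.allele_freq[None, :] * np.ones((n, 1)))[todo]
        prov[todo] = PROVENANCE_CODES["frequency"]

    hard = np.where(observed, t_full, hard_call(exp)).astype(np.int8)
    out = GenotypeMatrix(hard, g_low.individuals, mmap.markers)
    return ImputationResult(out, exp, prov)


def baseline_impute(g_low: GenotypeMatrix, g_ref: GenotypeMatrix,
                    mmap: MarkerMap | None = None) -> ImputationResult:
    """Naive comparator: every missing entry gets expected dosage ``2 f``
    from reference allele frequencies (no pedigree, no haplotypes)."""
    markers = mmap.markers if mmap is not None else g_ref.markers
    ref_index = {mk: j for j, mk in enumerate(g_ref.markers)}
    extra = [mk for mk in g_low.markers if mk not in ref_index]
    if extra:
        raise ValueError(f"markers absent from reference: {extra[:5]}")
    _, freq = _fill_missing_by_frequency(g_ref.dosages)
    freq_full = np.array([freq[ref_index[mk]] for mk in markers])

    n, total = g_low.n_individuals, len(markers)
    t_full = np.full((n, total), MISSING, dtype=np.int8)
    col_of = {mk: j for j, mk in enumerate(markers)}
    t_full[:, [col_of[mk] for mk in g_low.markers]] = g_low.dosages
    observed = t_full != MISSING

    exp = np.where(observed, t_full, 2.0 * freq_full[None, :]).astype(float)
    prov = np.where(observed, PROVENANCE_CODES["observed"],
                    PROVENANCE_CODES["frequency"]).astype(np.uint8)
    hard = np.where(observed, t_full, hard_call(2.0 * freq_full)[None, :]).astype(np.int8)
    out = GenotypeMatrix(hard, g_low.individuals, markers)
    return ImputationResult(out, exp, prov)
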