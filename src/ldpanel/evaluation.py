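"""Masking cross-validation and imputation-accuracy analytics.

The harness hides the genotypes of a validation fold down to a low-density
panel, imputes them back from the remaining reference individuals, and
scores the result with the Pearson correlation R between imputed and true
genotypes — per SNP (across individuals, pooled over all replicates so
each marker is scored on the whole population) and per individual (across
that individual's masked markers).  Folds form a strict partition, so
every individual is validated exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap, Pedigree
from .imputer import HaplotypeLibrary, baseline_impute, build_haplotype_library, impute
from .panels import PanelDefinition
from .qc import minor_allele_frequency

DEFAULT_MAF_EDGES = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class MaskingScheme:
    """One cross-validation replicate: who is validated, what stays visible."""

    replicate_id: int
    validation: list[str]
    panel: list[str] | None = None  # markers kept visible; None = not yet set

    def with_panel(self, panel: list[str]) -> "MaskingScheme":
        return MaskingScheme(self.replicate_id, list(self.validation), list(panel))


def make_masking_scheme(individual_ids, n_replicates: int,
                        validation_fraction: float = 0.1,
                        seed: int = 0) -> list[MaskingScheme]:
    """Randomly partition individuals into near-equal validation folds.

    Fold sizes differ by at most one; together the folds cover every
    individual exactly once.  ``validation_fraction`` is checked for
    consistency with the fold count (a strict partition implies
    ``n_replicates * fraction ~ 1``).
    """
    ids = list(individual_ids)
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if not (0.0 < validation_fraction <= 1.0):
        raise ValueError("validation fraction must lie in (0, 1]")
    if len(ids) < n_replicates:
        raise ValueError(f"{len(ids)} individuals cannot fill {n_replicates} folds")
    if abs(n_replicates * validation_fraction - 1.0) > 0.5:
        raise ValueError("n_replicates x validation_fraction must be close to 1 "
                         "for a strict partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, n_replicates)
    return [MaskingScheme(r + 1, [ids[i] for i in fold])
            for r, fold in enumerate(folds)]


def mask_genotypes(g: GenotypeMatrix, scheme: MaskingScheme) -> GenotypeMatrix:
    """Set validation individuals' genotypes at masked markers to MISSING;
    panel markers and reference individuals are untouched."""
    if scheme.panel is None:
        raise ValueError("scheme has no panel set")
    out = g.dosages.copy()
    rows = g.individual_positions(scheme.validation)
    panel_cols = set(g.marker_positions(scheme.panel).tolist())
    masked_cols = np.array([j for j in range(g.n_markers) if j not in panel_cols],
                           dtype=int)
    if masked_cols.size:
        out[np.ix_(rows, masked_cols)] = MISSING
    return GenotypeMatrix(out, g.individuals, g.markers)


def _columnwise_pearson(x: np.ndarray, y: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Pearson r per column of two (n, m) arrays over rows where ``valid``;
    zero-variance columns give nan."""
    w = valid.astype(float)
    n = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = (x * w).sum(axis=0) / n
        my = (y * w).sum(axis=0) / n
        dx = (x - mx) * w
        dy = (y - my) * w
        cov = (dx * dy).sum(axis=0)
        vx = (dx * dx).sum(axis=0)
        vy = (dy * dy).sum(axis=0)
        r = cov / np.sqrt(vx * vy)
    r[(n < 2) | (vx <= 0) | (vy <= 0)] = np.nan
    return r


def accuracy_per_snp(imputed: np.ndarray, truth: GenotypeMatrix,
                     masked_markers) -> pd.Series:
    """Eq.-style Pearson R per masked marker, pooling (imputed, true) pairs
    over every validated individual.  Markers where either vector has zero
    variance are reported as nan."""
    cols = truth.marker_positions(list(masked_markers))
    t = truth.dosages[:, cols].astype(float)
    x = np.asarray(imputed, dtype=float)[:, cols]
    valid = truth.dosages[:, cols] != MISSING
    r = _columnwise_pearson(x, t, valid)
    return pd.Series(r, index=list(masked_markers), name="R")


def accuracy_per_individual(imputed: np.ndarray, truth: GenotypeMatrix,
                            masked_markers) -> pd.Series:
    """Pearson R per individual over that individual's masked markers."""
    cols = truth.marker_positions(list(masked_markers))
    t = truth.dosages[:, cols].astype(float).T
    x = np.asarray(imputed, dtype=float)[:, cols].T
    valid = (truth.dosages[:, cols] != MISSING).T
    r = _columnwise_pearson(x, t, valid)
    return pd.Series(r, index=list(truth.individuals), name="R")


def summarize_accuracy(r_values, threshold: float = 0.8) -> dict:
    """Mean, population SD, min, max and % strictly above the threshold."""
    r = pd.Series(r_values).astype(float)
    defined = r.dropna()
    if defined.empty:
        raise ValueError("no defined accuracy values to summarize")
    arr = defined.to_numpy()
    return {
        "n": int(arr.size),
        "n_undefined": int(r.isna().sum()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=0)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "pct_gt_threshold": float(100.0 * (arr > threshold).mean()),
        "threshold": threshold,
    }


def accuracy_by_maf_bin(r_per_snp: pd.Series, maf_per_snp: pd.Series,
                        edges=DEFAULT_MAF_EDGES) -> pd.DataFrame:
    """Mean/SD/count of per-SNP accuracy in half-open MAF bins
    [e_i, e_{i+1}); the last bin includes its right edge."""
    edges = np.asarray(edges, dtype=float)
    maf = maf_per_snp.reindex(r_per_snp.index)
    rows = []
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        last = i == edges.size - 2
        sel = (maf >= lo) & ((maf <= hi) if last else (maf < hi))
        vals = r_per_snp[sel].dropna().to_numpy()
        rows.append({
            "maf_lo": lo, "maf_hi": hi, "n": int(vals.size),
            "mean_r": float(vals.mean()) if vals.size else np.nan,
            "sd_r": float(vals.std(ddof=0)) if vals.size else np.nan,
        })
    return pd.DataFrame(rows)


def chromosome_end_accuracy(r_per_snp: pd.Series, mmap: MarkerMap,
                            n_end: int = 100) -> tuple[pd.DataFrame, list[str]]:
    """Accuracy at chromosome ends versus interiors.

    For each chromosome, the first and last ``n_end`` scored markers in map
    order form the end set; a chromosome with fewer than ``2 * n_end``
    scored markers contributes all of them and is flagged.  Returns the
    per-chromosome table and the selected end-marker ids.
    """
    scored = list(r_per_snp.index)
    pos = mmap.positions(scored)
    chrom = mmap.table["chrom"].to_numpy()[pos]
    order = np.argsort(pos, kind="stable")
    rows, selected = [], []
    for c in mmap.chromosomes:
        on_c = order[chrom[order] == c]
        ids_c = [scored[i] for i in on_c]
        if len(ids_c) == 0:
            continue
        if len(ids_c) < 2 * n_end:
            end_ids, interior_ids, overlap = ids_c, [], True
        else:
            end_ids = ids_c[:n_end] + ids_c[-n_end:]
            interior_ids = ids_c[n_end:-n_end]
            overlap = False
        selected += end_ids
        e = r_per_snp[end_ids].dropna().to_numpy()
        it = r_per_snp[interior_ids].dropna().to_numpy() if interior_ids else np.array([])
        rows.append({
            "chrom": c, "n_end_markers": len(end_ids), "overlap": overlap,
            "end_mean": float(e.mean()) if e.size else np.nan,
            "end_sd": float(e.std(ddof=0)) if e.size else np.nan,
            "interior_mean": float(it.mean()) if it.size else np.nan,
            "interior_sd": float(it.std(ddof=0)) if it.size else np.nan,
        })
    return pd.DataFrame(rows), selected


@dataclass
class AccuracyReport:
    """The full per-tier accuracy surface."""

    label: str
    panel_size: int
    masked_markers: list[str]
    per_snp: pd.Series
    per_individual: pd.Series
    summary_snp: dict
    summary_individual: dict
    maf_bins: pd.DataFrame
    chrom_end: pd.DataFrame
    baseline_summary_snp: dict | None = None
    extras: dict = field(default_factory=dict)


def run_cv_experiment(g: GenotypeMatrix, ped: Pedigree | None, mmap: MarkerMap,
                      panels: list[PanelDefinition], n_replicates: int = 10,
                      validation_fraction: float = 0.1, seed: int = 0,
                      min_window: int = 32, accuracy_on: str = "dosage",
                      n_end: int = 100, with_baseline: bool = True,
                      maf_edges=DEFAULT_MAF_EDGES
                      ) -> tuple[dict[str, AccuracyReport], pd.DataFrame]:
    """Mask -> impute -> score for every panel tier and replicate.

    The reference haplotype library is rebuilt once per replicate (it
    depends only on the fold, not the tier) and reused across tiers.
    Returns one report per tier plus a cross-tier comparison table.
    """
    if accuracy_on not in ("dosage", "hard"):
        raise ValueError("accuracy_on must be 'dosage' or 'hard'")
    schemes = make_masking_scheme(g.individuals, n_replicates, validation_fraction, seed)

    n, m = g.shape
    pooled = {p.label: np.zeros((n, m)) for p in panels}
    pooled_base = {p.label: np.zeros((n, m)) for p in panels} if with_baseline else None
    row_of = {ind: i for i, ind in enumerate(g.individuals)}

    for scheme in schemes:
        val = scheme.validation
        ref_ids = [i for i in g.individuals if i not in set(val)]
        g_ref = g.subset(ref_ids)
        lib = build_haplotype_library(g_ref, ped, mmap)
        rows = [row_of[i] for i in val]
        for panel in panels:
            g_low = g.subset(val, panel.markers)
            res = impute(g_low, g_ref, ped, mmap, lib, min_window=min_window)
            vals = res.expected if accuracy_on == "dosage" else res.genotypes.dosages
            pooled[panel.label][rows] = vals
            if with_baseline:
                bres = baseline_impute(g_low, g_ref, mmap)
                pooled_base[panel.label][rows] = bres.expected

    maf = pd.Series(minor_allele_frequency(g), index=g.markers)
    reports: dict[str, AccuracyReport] = {}
    table_rows = []
    for panel in panels:
        panel_set = set(panel.markers)
        masked = [mk for mk in g.markers if mk not in panel_set]
        evaluated = masked if masked else list(g.markers)
        per_snp = accuracy_per_snp(pooled[panel.label], g, evaluated)
        per_ind = accuracy_per_individual(pooled[panel.label], g, evaluated)
        s_snp = summarize_accuracy(per_snp)
        s_ind = summarize_accuracy(per_ind)
        base_s = None
        if with_baseline:
            base_r = accuracy_per_snp(pooled_base[panel.label], g, evaluated)
            base_s = summarize_accuracy(base_r)
        bins = accuracy_by_maf_bin(per_snp, maf, maf_edges)
        ends, _sel = chromosome_end_accuracy(per_snp, mmap, n_end=n_end)
        reports[panel.label] = AccuracyReport(
            panel.label, len(panel), masked, per_snp, per_ind, s_snp, s_ind,
            bins, ends, base_s, extras={"imputed_pooled": pooled[panel.label]})
        table_rows.append({
            "tier": panel.label, "panel_snps": len(panel), "imputed_snps": s_snp["n"],
            "snp_mean": s_snp["mean"], "snp_sd": s_snp["sd"],
            "snp_pct_gt_0.8": s_snp["pct_gt_threshold"],
            "ind_mean": s_ind["mean"], "ind_sd": s_ind["sd"],
            "ind_min": s_ind["min"], "ind_max": s_ind["max"],
            "ind_pct_gt_0.8": s_ind["pct_gt_threshold"],
            "baseline_snp_mean": base_s["mean"] if base_s else np.nan,
        })
    comparison = pd.DataFrame(table_rows).sort_values("panel_snps").reset_index(drop=True)
    return reports, comparison
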