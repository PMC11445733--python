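"""Marker and sample quality control.

Implements the standard pre-imputation filter stack: minor allele
frequency, call rate (marker and sample), the Hardy-Weinberg exact test
with optional Bonferroni correction, and trio/marker Mendelian-error
exclusion with PLINK ``--me a b`` semantics (first bound per trio, second
per marker; the offspring — not the whole family — is dropped when a trio
fails).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Pedigree

DEFAULT_FILTER_ORDER = ("hwe", "call_rate", "maf")


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; ``None`` disables the corresponding filter."""

    maf_min: float | None = 0.01
    marker_call_rate_min: float | None = 0.90
    sample_call_rate_min: float | None = None
    hwe_alpha: float | None = 0.05
    hwe_bonferroni: bool = True
    mendel_trio_max: float | None = 0.05
    mendel_marker_max: float | None = 0.10

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_call_rate_min", "sample_call_rate_min",
                     "hwe_alpha", "mendel_trio_max", "mendel_marker_max"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.maf_min is not None and self.maf_min > 0.5:
            raise ValueError("maf_min cannot exceed 0.5")


@dataclass
class QcReport:
    """Per-step marker/sample accounting, Table-1 style."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, markers_before: int, markers_removed: int,
            samples_removed: int = 0, detail: str = "") -> None:
        self.steps.append({
            "step": name,
            "markers_before": markers_before,
            "markers_removed": markers_removed,
            "markers_after": markers_before - markers_removed,
            "samples_removed": samples_removed,
            "detail": detail,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    @property
    def markers_after(self) -> int:
        return self.steps[-1]["markers_after"] if self.steps else 0


def minor_allele_frequency(g: GenotypeMatrix, marker: str | None = None):
    """MAF per marker (or one marker), over non-missing calls only."""
    freq = g.allele_frequencies()
    maf = np.where(np.isnan(freq), np.nan, np.minimum(freq, 1.0 - freq))
    if marker is None:
        return maf
    return float(maf[g.marker_positions([marker])[0]])


def call_rate(g: GenotypeMatrix, axis: str = "marker") -> np.ndarray:
    """Fraction of non-missing entries per marker or per sample."""
    obs = g.dosages != MISSING
    if axis == "marker":
        return obs.mean(axis=0)
    if axis == "sample":
        return obs.mean(axis=1)
    raise ValueError("axis must be 'marker' or 'sample'")


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton-style, plain p).

    Given genotype counts, sums the conditional probabilities of every
    heterozygote count (with the observed allele counts and sample size)
    whose probability does not exceed that of the observed table.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * min(n_aa_hom, n_bb_hom) + n_het
    if rare == 0:
        return 1.0

    # unnormalized probabilities over all feasible het counts, built by the
    # standard recurrence from the modal het count
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(hets.shape[0])
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    mid_idx = int(np.searchsorted(hets, mid))
    probs[mid_idx] = 1.0
    # going down in het count: P(h-2) = P(h) * h*(h-1) / ((r-h+2)*(c-h+2))
    for i in range(mid_idx, 0, -1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    # going up: P(h+2) = P(h) * 4*hom_r*hom_c / ((h+2)*(h+1))
    for i in range(mid_idx, probs.shape[0] - 1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(hets, n_het))]
    # relative slack so borderline equal-probability tables are treated
    # consistently across floating-point evaluation orders
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-7)].sum()))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per marker; all-missing markers get p = 1."""
    d = g.dosages
    obs = d != MISSING
    n_hom0 = ((d == 0) & obs).sum(axis=0)
    n_het = ((d == 1) & obs).sum(axis=0)
    n_hom2 = ((d == 2) & obs).sum(axis=0)
    out = np.ones(g.n_markers)
    for j in range(g.n_markers):
        if n_hom0[j] + n_het[j] + n_hom2[j] >= 1:
            out[j] = hwe_exact_test(int(n_hom0[j]), int(n_het[j]), int(n_hom2[j]))
    return out


# Offspring dosages impossible given two observed parental dosages.
# _TRIO_FORBIDDEN[s, d, o] is True when (sire=s, dam=d, offspring=o) is an error.
_TRIO_FORBIDDEN = np.zeros((3, 3, 3), dtype=bool)
for _s in range(3):
    for _d in range(3):
        s_gametes = {0} if _s == 0 else {1} if _s == 2 else {0, 1}
        d_gametes = {0} if _d == 0 else {1} if _d == 2 else {0, 1}
        possible = {a + b for a in s_gametes for b in d_gametes}
        for _o in range(3):
            _TRIO_FORBIDDEN[_s, _d, _o] = _o not in possible


@dataclass
class MendelScan:
    per_trio: pd.DataFrame      # offspring, checked, errors, rate
    per_marker: pd.DataFrame    # marker, checked, errors, rate


def mendel_error_scan(g: GenotypeMatrix, ped: Pedigree) -> MendelScan:
    """Count offspring genotypes impossible under Mendelian transmission.

    Trios (both parents genotyped) use the full transmission table; duos
    use the one-parent rule (a homozygous parent forbids the opposite
    homozygote in the offspring).
    """
    d = g.dosages
    n_markers = g.n_markers
    marker_err = np.zeros(n_markers, dtype=np.int64)
    marker_chk = np.zeros(n_markers, dtype=np.int64)
    trio_rows = []
    for ind in ped.individuals:
        sire, dam = ped.parents_of(ind)
        if (sire is None and dam is None) or not g.has_individual(ind):
            continue
        o = g.row(ind)
        s = g.row(sire) if sire is not None and g.has_individual(sire) else None
        m = g.row(dam) if dam is not None and g.has_individual(dam) else None
        if s is None and m is None:
            continue
        o_obs = o != MISSING
        if s is not None and m is not None:
            both = o_obs & (s != MISSING) & (m != MISSING)
            err = np.zeros(n_markers, dtype=bool)
            err[both] = _TRIO_FORBIDDEN[s[both], m[both], o[both]]
            # fall back to duo rules where exactly one parent is missing
            for p in (s, m):
                only = o_obs & (p != MISSING) & ~both
                err[only] |= ((p[only] == 0) & (o[only] == 2)) | ((p[only] == 2) & (o[only] == 0))
            checked = o_obs & ((s != MISSING) | (m != MISSING))
        else:
            p = s if s is not None else m
            checked = o_obs & (p != MISSING)
            err = np.zeros(n_markers, dtype=bool)
            err[checked] = ((p[checked] == 0) & (o[checked] == 2)) | \
                           ((p[checked] == 2) & (o[checked] == 0))
        n_chk = int(checked.sum())
        n_err = int(err.sum())
        trio_rows.append((ind, n_chk, n_err, n_err / n_chk if n_chk else np.nan))
        marker_err += err
        marker_chk += checked
    per_trio = pd.DataFrame(trio_rows, columns=["offspring", "checked", "errors", "rate"])
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(marker_chk > 0, marker_err / np.maximum(marker_chk, 1), np.nan)
    per_marker = pd.DataFrame({"marker": g.markers, "checked": marker_chk,
                               "errors": marker_err, "rate": rate})
    return MendelScan(per_trio, per_marker)


def apply_qc(g: GenotypeMatrix, ped: Pedigree | None, thresholds: QcThresholds,
             order: Sequence[str] = DEFAULT_FILTER_ORDER) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the filters in ``order``; each step consumes the previous output.

    Step names: ``mendel`` (needs a pedigree), ``hwe``, ``call_rate``
    (markers, then samples if a sample threshold is set), ``maf``.

    Because the Bonferroni divisor of the HWE step tracks the current
    marker count, the ordered sequence is repeated until no filter removes
    anything, so the returned matrix is a fixed point: re-applying the
    same thresholds is the identity.  The first pass carries the familiar
    per-step accounting; later passes (usually empty or near-empty) are
    tagged with their pass number.
    """
    report = QcReport()
    current = g
    for qc_pass in range(1, 100):
        size_before = current.shape
        current = _apply_qc_pass(current, ped, thresholds, order, report,
                                 qc_pass if qc_pass > 1 else None)
        if current.shape == size_before:
            break
    return current, report


def _apply_qc_pass(g: GenotypeMatrix, ped: Pedigree | None, thresholds: QcThresholds,
                   order: Sequence[str], report: QcReport,
                   pass_tag: int | None) -> GenotypeMatrix:
    def name(step: str) -> str:
        return step if pass_tag is None else f"{step} (pass {pass_tag})"

    current = g
    for step in order:
        n_before = current.n_markers
        if step == "mendel":
            if ped is None or (thresholds.mendel_trio_max is None
                               and thresholds.mendel_marker_max is None):
                report.add(name("mendel"), n_before, 0, detail="disabled")
                continue
            scan = mendel_error_scan(current, ped)
            drop_inds: list[str] = []
            if thresholds.mendel_trio_max is not None and len(scan.per_trio):
                bad = scan.per_trio["rate"] > thresholds.mendel_trio_max
                drop_inds = scan.per_trio.loc[bad.fillna(False), "offspring"].tolist()
            keep_markers = np.ones(n_before, dtype=bool)
            if thresholds.mendel_marker_max is not None:
                rate = scan.per_marker["rate"].to_numpy()
                keep_markers = ~(rate > thresholds.mendel_marker_max)
            keep_inds = [i for i in current.individuals if i not in set(drop_inds)]
            current = current.subset(keep_inds, current.markers[keep_markers])
            report.add(name("mendel"), n_before, int((~keep_markers).sum()),
                       samples_removed=len(drop_inds),
                       detail=f"--me {thresholds.mendel_trio_max} {thresholds.mendel_marker_max}")
        elif step == "hwe":
            if thresholds.hwe_alpha is None:
                report.add(name("hwe"), n_before, 0, detail="disabled")
                continue
            # with a Bonferroni divisor tied to the current marker count the
            # threshold loosens as markers drop, so re-test to a fixed point;
            # this makes the whole filter stack idempotent
            pvals = hwe_pvalues(current)
            while True:
                alpha = thresholds.hwe_alpha
                if thresholds.hwe_bonferroni and current.n_markers > 0:
                    alpha = alpha / current.n_markers
                keep = pvals >= alpha
                if keep.all():
                    break
                current = current.subset(markers=current.markers[keep])
                pvals = pvals[keep]
            report.add(name("hwe"), n_before, n_before - current.n_markers,
                       detail=f"p < {alpha:.3g}{' (Bonferroni)' if thresholds.hwe_bonferroni else ''}")
        elif step == "call_rate":
            removed_samples = 0
            keep = np.ones(n_before, dtype=bool)
            if thresholds.marker_call_rate_min is not None:
                keep = call_rate(current, "marker") >= thresholds.marker_call_rate_min
            current = current.subset(markers=current.markers[keep])
            if thresholds.sample_call_rate_min is not None:
                keep_s = call_rate(current, "sample") >= thresholds.sample_call_rate_min
                removed_samples = int((~keep_s).sum())
                current = current.subset(individuals=current.individuals[keep_s])
            report.add(name("call_rate"), n_before, int((~keep).sum()),
                       samples_removed=removed_samples,
                       detail=f"marker >= {thresholds.marker_call_rate_min}")
        elif step == "maf":
            if thresholds.maf_min is None:
                report.add(name("maf"), n_before, 0, detail="disabled")
                continue
            maf = minor_allele_frequency(current)
            keep = ~(np.isnan(maf) | (maf < thresholds.maf_min))
            current = current.subset(markers=current.markers[keep])
            report.add(name("maf"), n_before, int((~keep).sum()),
                       detail=f"MAF >= {thresholds.maf_min}")
        else:
            raise ValueError(f"unknown QC step {step!r}")
    return current
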