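"""Low-density panel construction by LD pruning.

A panel ladder is produced by sliding-window greedy pruning of markers in
high linkage disequilibrium (squared Pearson correlation of dosage
vectors), at a ladder of r-squared thresholds; per-population panels are
intersected to keep only markers informative everywhere, and genome
coverage is reported per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap
from .qc import minor_allele_frequency


@dataclass
class PanelDefinition:
    """An ordered marker subset with the parameters that produced it."""

    label: str
    r2_threshold: float | None
    markers: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError("a panel must contain at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("panel markers must be unique")

    def __len__(self) -> int:
        return len(self.markers)

    def write(self, path) -> None:
        """One marker id per line (PLINK ``--extract`` compatible)."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.markers) + "\n")


def density_label(n_markers: int) -> str:
    """A size tier label like '9K', '1K' or '0.5K' from a marker count."""
    if n_markers >= 950:
        return f"{round(n_markers / 1000):d}K"
    return f"{max(round(n_markers / 100) / 10, 0.1):g}K"


def _pairwise_complete_r2(x: np.ndarray) -> np.ndarray:
    """r² between all column pairs of a dosage block, using for each pair
    only the individuals observed at both markers.  Zero-variance pairs
    yield nan."""
    obs = (x != MISSING)
    x0 = np.where(obs, x, 0).astype(float)
    m = obs.astype(float)
    n = m.T @ m
    sx = x0.T @ m          # sum of column i over pair-complete rows (i, j)
    sxy = x0.T @ x0
    sxx = (x0 * x0).T @ m
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        cov = sxy / n - mean_x * mean_x.T
        var_x = sxx / n - mean_x ** 2
        denom = var_x * var_x.T
        r2 = np.where(denom > 0, cov * cov / denom, np.nan)
    r2[n < 2] = np.nan
    return r2


def pairwise_r2(g: GenotypeMatrix, marker_i: str, marker_j: str) -> float:
    """Squared Pearson correlation between two markers' dosage vectors.

    Computed over individuals non-missing at both; nan when either marker
    has zero variance among the shared individuals.
    """
    cols = g.marker_positions([marker_i, marker_j])
    block = g.dosages[:, cols]
    return float(_pairwise_complete_r2(block)[0, 1])


def ld_prune(g: GenotypeMatrix, mmap: MarkerMap, r2_threshold: float,
             window_size: int = 50, step: int = 5) -> list[str]:
    """Sliding-window greedy pruning.

    Within each window the most correlated offending pair is resolved by
    removing its lower-MAF member (ties go to the later map position) until
    no retained pair exceeds the threshold; the window then advances by
    ``step`` markers.  Undefined (zero-variance) pairs are treated as
    r² = 0 — an invariant marker cannot be redundant with anything.
    """
    if window_size < 2:
        raise ValueError("window_size must be at least 2")
    if step < 1:
        raise ValueError("step must be at least 1")
    order = mmap.positions(g.markers)
    if np.any(np.diff(order) < 0):
        raise ValueError("genotype markers must be in map order")
    maf = minor_allele_frequency(g)
    keep = np.ones(g.n_markers, dtype=bool)
    chroms = mmap.table["chrom"].to_numpy()[order]

    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = idx.shape[0]
        for start in range(0, max(m - 1, 1), step):
            win = idx[start:start + window_size]
            win = win[keep[win]]
            if win.shape[0] < 2:
                continue
            r2 = _pairwise_complete_r2(g.dosages[:, win])
            r2 = np.nan_to_num(r2, nan=0.0)
            np.fill_diagonal(r2, 0.0)
            active = np.ones(win.shape[0], dtype=bool)
            while True:
                sub = np.where(np.outer(active, active), r2, 0.0)
                worst = sub.max()
                if worst <= r2_threshold:
                    break
                i, j = np.unravel_index(int(sub.argmax()), sub.shape)
                mi, mj = win[i], win[j]
                # remove the less informative (lower-MAF) member;
                # ties remove the later map position
                if maf[mi] < maf[mj] or (maf[mi] == maf[mj] and mi > mj):
                    victim = i
                else:
                    victim = j
                active[victim] = False
                keep[win[victim]] = False
            if start + window_size >= m:
                break
    return [str(mk) for mk in g.markers[keep]]


def prune_ladder(g: GenotypeMatrix, mmap: MarkerMap, thresholds=(0.9, 0.8, 0.7, 0.6),
                 window_size: int = 50, step: int = 5,
                 successive: bool = True) -> list[PanelDefinition]:
    """Panels at a descending r² ladder.

    With ``successive=True`` each threshold prunes the previous panel's
    markers, so the ladder is nested (each lower-density panel is a subset
    of the denser one above it).
    """
    panels = []
    current = g
    for thr in sorted(thresholds, reverse=True):
        source = current if successive else g
        retained = ld_prune(source, mmap, thr, window_size, step)
        panels.append(PanelDefinition(density_label(len(retained)), thr, retained,
                                      provenance={"window": window_size, "step": step,
                                                  "successive": successive}))
        if successive:
            current = g.subset(markers=retained)
    return panels


def thin_panel(panel: PanelDefinition, mmap: MarkerMap, factor: int = 2) -> PanelDefinition:
    """Uniformly thin a panel in map order (every ``factor``-th marker),
    producing a lower tier below the pruning ladder."""
    pos = np.sort(mmap.positions(panel.markers))
    kept = [str(mmap.markers[p]) for p in pos[::factor]]
    return PanelDefinition(density_label(len(kept)), panel.r2_threshold, kept,
                           provenance={**panel.provenance, "thinned_by": factor})


def nested_density_ladder(g: GenotypeMatrix, mmap: MarkerMap,
                          thresholds=(0.9, 0.8, 0.7, 0.6),
                          thin_factors=(2, 4, 8), window_size: int = 50,
                          step: int = 5) -> list[PanelDefinition]:
    """Five nested density tiers for the imputation-accuracy experiment.

    The top tiers come from the successive r² pruning ladder (its first and
    last thresholds); the lower tiers thin the lowest pruned panel
    uniformly in map order, spanning the accuracy range reported for
    commercial low-density arrays (mean R roughly 0.6 to 0.95 on the
    default simulated population).  Using thin factors that divide each
    other keeps the whole ladder nested.  Returned densest first.
    """
    ladder = prune_ladder(g, mmap, thresholds, window_size, step, successive=True)
    tiers = [ladder[0], ladder[-1]]
    for f in thin_factors:
        tiers.append(thin_panel(ladder[-1], mmap, factor=f))
    # relabel duplicates so tier labels stay unique
    seen: dict[str, int] = {}
    for t in tiers:
        if t.label in seen:
            seen[t.label] += 1
            t.label = f"{t.label}.{seen[t.label]}"
        else:
            seen[t.label] = 0
    return tiers


class EmptyPanelError(ValueError):
    pass


def intersect_panels(retained_lists: list[list[str]], mmap: MarkerMap) -> list[str]:
    """Markers common to every per-population retained list, in map order."""
    if not retained_lists:
        raise ValueError("need at least one retained list")
    common = set(retained_lists[0])
    for lst in retained_lists[1:]:
        common &= set(lst)
    if not common:
        sizes = [len(lst) for lst in retained_lists]
        raise EmptyPanelError(f"no common markers across {len(retained_lists)} "
                              f"populations (list sizes {sizes})")
    pos = np.sort(mmap.positions(sorted(common)))
    return [str(mmap.markers[p]) for p in pos]


def coverage_report(panel: "PanelDefinition | list[str]", mmap: MarkerMap) -> pd.DataFrame:
    """Per-chromosome panel coverage: total mapped markers, panel markers,
    percentage; final row totals the genome."""
    markers = panel.markers if isinstance(panel, PanelDefinition) else list(panel)
    if markers:
        pos = mmap.positions(markers)
        panel_chrom = mmap.table["chrom"].to_numpy()[pos]
    else:
        panel_chrom = np.array([], dtype=int)
    rows = []
    for c in mmap.chromosomes:
        total = int((mmap.table["chrom"] == c).sum())
        in_panel = int((panel_chrom == c).sum())
        rows.append((str(c), total, in_panel, 100.0 * in_panel / total))
    tot_map, tot_panel = len(mmap), len(markers)
    rows.append(("total", tot_map, tot_panel, 100.0 * tot_panel / tot_map))
    return pd.DataFrame(rows, columns=["chrom", "map_markers", "panel_markers", "pct"])
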