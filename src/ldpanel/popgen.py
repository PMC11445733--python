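"""Population-level validation analytics.

Covers the descriptive and structure analyses used to validate a panel on
field populations: the MAF spectrum, per-individual heterozygosity, the
genomic identity-by-state (IBS) matrix with classical (Torgerson) MDS, a
maximum-likelihood admixture model fitted by EM (a deterministic,
desk-scale counterpart of Bayesian MCMC clustering), and the Evanno
second-difference statistic for choosing the number of clusters K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .qc import minor_allele_frequency


def maf_spectrum(g: GenotypeMatrix, edges=None) -> pd.DataFrame:
    """Histogram of per-marker MAF over (0, 0.5]; default bin width 0.05."""
    if g.n_markers == 0:
        raise ValueError("no markers")
    if edges is None:
        edges = np.round(np.arange(0.0, 0.5001, 0.05), 10)
    edges = np.asarray(edges, dtype=float)
    maf = minor_allele_frequency(g)
    maf = maf[~np.isnan(maf)]
    rows = []
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        last = i == edges.size - 2
        sel = (maf >= lo) & ((maf <= hi) if last else (maf < hi))
        rows.append({"maf_lo": lo, "maf_hi": hi, "count": int(sel.sum()),
                     "fraction": float(sel.mean()) if maf.size else np.nan})
    return pd.DataFrame(rows)


def individual_heterozygosity(g: GenotypeMatrix) -> pd.Series:
    """Fraction of non-missing genotypes that are heterozygous, per
    individual; all-missing individuals get nan."""
    obs = g.dosages != MISSING
    het = g.dosages == 1
    n = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n > 0, het.sum(axis=1) / np.maximum(n, 1), np.nan)
    return pd.Series(h, index=g.individuals, name="heterozygosity")


@dataclass
class IbsMatrix:
    """Pairwise allele-sharing similarity and its complement distance."""

    similarity: np.ndarray
    individuals: np.ndarray

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.similarity


def ibs_matrix(g: GenotypeMatrix) -> IbsMatrix:
    """IBS similarity: mean over markers observed in both individuals of
    ``(2 - |d_i - d_j|) / 2``."""
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    d = g.dosages.astype(np.float64)
    obs = (g.dosages != MISSING).astype(np.float64)
    d0 = np.where(g.dosages == MISSING, 0.0, d)
    n_shared = obs @ obs.T
    if np.any(n_shared == 0):
        i, j = np.argwhere(n_shared == 0)[0]
        raise ValueError(f"individuals {g.individuals[i]!r} and {g.individuals[j]!r} "
                         "share no genotyped marker")
    # sum over shared markers of |d_i - d_j|, via the 0/1/2 indicator trick:
    # |a-b| = a + b - 2*min(a,b); with dosages, min(a,b) decomposes over
    # the indicators (d>=1) and (d>=2)
    ge1 = (g.dosages >= 1).astype(np.float64)
    ge2 = (g.dosages >= 2).astype(np.float64)
    sum_min = ge1 @ ge1.T + ge2 @ ge2.T
    sum_a = d0 @ obs.T
    abs_diff = sum_a + sum_a.T - 2.0 * sum_min
    sim = (2.0 * n_shared - abs_diff) / (2.0 * n_shared)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return IbsMatrix(sim, g.individuals.copy())


def classical_mds(distance: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix to k coordinates.

    Double-centers the squared distances, eigendecomposes, and scales the
    top-k eigenvectors by root eigenvalues.  Negative eigenvalues are
    truncated to zero; each axis is oriented so its largest-magnitude
    coordinate is positive.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-10).sum())
    if k > n_pos and not np.allclose(D, 0.0):
        raise ValueError(f"only {n_pos} positive eigenvalues; cannot embed in {k} dimensions")
    vals_k = np.clip(vals[:k], 0.0, None)
    coords = vecs[:, :k] * np.sqrt(vals_k)[None, :]
    for ax in range(k):
        col = coords[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    return coords


@dataclass
class AdmixtureFit:
    """An admixture-model fit: memberships Q, cluster frequencies P."""

    K: int
    Q: np.ndarray                # (n, K), rows sum to 1
    P: np.ndarray                # (K, m) cluster allele frequencies
    log_likelihood: float
    log_likelihood_path: np.ndarray
    seed: int
    converged: bool
    individuals: np.ndarray


def _admixture_loglik(d: np.ndarray, obs: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    mu = np.clip(Q @ P, 1e-12, 1 - 1e-12)
    d0 = np.where(obs, d, 0.0)
    ll = d0 * np.log(mu) + np.where(obs, 2.0 - d0, 0.0) * np.log(1.0 - mu)
    # binomial coefficient term: log C(2, d), constant in (Q, P)
    coef = np.where(obs & (d == 1), np.log(2.0), 0.0)
    return float((ll + coef).sum())


def admixture_em(g: GenotypeMatrix, K: int, seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-4) -> AdmixtureFit:
    """Maximum-likelihood admixture clustering by EM.

    Models each dosage as Binomial(2, sum_k q_ik p_km) and alternates the
    standard multiplicative EM updates of Q and P from a random Dirichlet
    initialization; the log-likelihood is non-decreasing every iteration.
    Deterministic given the seed.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > g.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    d = g.dosages.astype(np.float64)
    obs = g.dosages != MISSING
    d0 = np.where(obs, d, 0.0)
    c0 = np.where(obs, 2.0 - d, 0.0)         # copies of the other allele
    n, m = d.shape
    two_m = 2.0 * obs.sum(axis=1, keepdims=True)

    freq = np.clip(np.nan_to_num(g.allele_frequencies(), nan=0.5), 1e-3, 1 - 1e-3)
    if K == 1:
        Q = np.ones((n, 1))
        P = freq[None, :].copy()
        ll = _admixture_loglik(d, obs, Q, P)
        return AdmixtureFit(1, Q, P, ll, np.array([ll]), seed, True, g.individuals.copy())

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(freq[None, :] + rng.uniform(-0.05, 0.05, size=(K, m)), 1e-3, 1 - 1e-3)

    path = []
    ll_prev = -np.inf
    converged = False
    eps = 1e-12
    for _ in range(max_iter):
        mu = np.clip(Q @ P, eps, 1 - eps)          # (n, m)
        # responsibilities for the counted and the other allele
        #   a_imk = d_im * q_ik p_km / mu_im ; b_imk analogous with 1 - p
        A = d0 / mu                                 # (n, m)
        Bm = c0 / (1.0 - mu)
        # P update: sum_i a_imk / sum_i (a_imk + b_imk)
        num = P * (Q.T @ A)
        den = num + (1.0 - P) * (Q.T @ Bm)
        P_new = np.where(den > 0, num / np.maximum(den, eps), P)
        # Q update: sum_m (a_imk + b_imk) / (2 M_i)
        Qn = Q * ((A @ P.T) + (Bm @ (1.0 - P).T))
        Q_new = Qn / two_m
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        P = np.clip(P_new, eps, 1 - eps)
        Q = Q_new
        ll = _admixture_loglik(d, obs, Q, P)
        path.append(ll)
        if np.isfinite(ll_prev) and (ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    return AdmixtureFit(K, Q, P, path[-1], np.asarray(path), seed, converged,
                        g.individuals.copy())


def assign_clusters(fit: AdmixtureFit) -> np.ndarray:
    """Hard cluster labels: argmax of each Q row."""
    return fit.Q.argmax(axis=1)


def label_recovery(fit: AdmixtureFit, true_labels) -> float:
    """Fraction of individuals whose argmax-Q cluster matches the true
    population, maximized over cluster-label permutations."""
    from itertools import permutations

    truth = pd.Series(list(true_labels))
    codes = truth.astype("category").cat.codes.to_numpy()
    pred = assign_clusters(fit)
    best = 0.0
    for perm in permutations(range(fit.K)):
        mapped = np.array([perm[p] for p in pred])
        best = max(best, float((mapped == codes).mean()))
    return best


def evanno_delta_k(loglik_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno second-difference statistic over a replicate-by-K table.

    ``loglik_table`` has one row per replicate run and one column per K
    (contiguous grid, at least three values).  Returns per interior K:
    Delta K = mean_r |L(K-1) - 2 L(K) + L(K+1)| / SD_r(L(K)); a zero SD
    yields an infinite Delta K, flagged in the output.
    """
    ks = sorted(int(k) for k in loglik_table.columns)
    if len(ks) < 3:
        raise ValueError("need at least three K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K grid must be contiguous")
    if len(loglik_table) < 2:
        raise ValueError("need at least two replicates per K")
    L = loglik_table.loc[:, ks].to_numpy(dtype=float)
    rows = []
    for j in range(1, len(ks) - 1):
        second = np.abs(L[:, j - 1] - 2.0 * L[:, j] + L[:, j + 1])
        sd = float(L[:, j].std(ddof=1))
        dk = float(second.mean() / sd) if sd > 0 else np.inf
        rows.append({"K": ks[j], "mean_abs_second_diff": float(second.mean()),
                     "sd_loglik": sd, "delta_k": dk, "zero_sd": sd == 0})
    out = pd.DataFrame(rows)
    best = out.loc[out["delta_k"].idxmax(), "K"] if len(out) else None
    out.attrs["optimal_k"] = int(best) if best is not None else None
    return out
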