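"""Ancestry inference and clustering.

The Bayesian admixture sampler traditionally used for this analysis is
replaced by maximum-likelihood admixture estimation under the same
generative model: individual i carries ancestry proportions q_i over K
clusters with cluster allele frequencies p_k, so the expected ALT dose
at locus l is pi_il = sum_k q_ik p_kl and the log-likelihood is
binomial, sum_il [g log pi + (2-g) log(1-pi)] over non-missing
genotypes.  Block EM maximizes it deterministically given a seed, and
the quantities consumed downstream — the membership matrix Q and the
model log-likelihood L(K) for the Evanno Delta-K choice of K — are the
same ones the sampler would provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import MISSING, Genotypes

_EPS = 1e-6


class AdmixtureModel:
    """Maximum-likelihood admixture model for a genotype matrix.

    Parameters
    ----------
    gt
        Genotype container; missing calls are skipped in the likelihood.
    K
        Number of ancestral clusters.
    """

    def __init__(self, gt: Genotypes, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > gt.n_samples:
            raise ValueError("K cannot exceed the number of samples")
        self.gt = gt
        self.K = int(K)
        # dense copies with missing zeroed, plus mask
        self._obs = (gt.g != MISSING)
        self._A = np.where(self._obs, gt.g, 0).astype(float)  # ALT counts
        self._B = np.where(self._obs, 2 - gt.g, 0).astype(float)  # REF counts
        self._L_i = 2.0 * self._obs.sum(axis=1)  # alleles observed per sample

    def loglik(self, Q: np.ndarray, P: np.ndarray) -> float:
        pi = np.clip(Q @ P, _EPS, 1 - _EPS)
        return float(np.sum(self._A * np.log(pi) + self._B * np.log1p(-pi)))

    def fit(self, seed: int = 0, max_iter: int = 300, tol: float = 1e-2) -> "AncestryFit":
        """Run EM to convergence (Delta loglik < tol or max_iter)."""
        rng = np.random.default_rng(seed)
        n, L, K = self.gt.n_samples, self.gt.n_sites, self.K
        with np.errstate(invalid="ignore"):
            pooled = np.where(
                self._obs.sum(axis=0) > 0,
                self._A.sum(axis=0) / np.maximum(2.0 * self._obs.sum(axis=0), 1.0),
                0.5,
            )
        P = np.clip(pooled[None, :] + rng.normal(0, 0.05, (K, L)), _EPS, 1 - _EPS)
        Q = rng.dirichlet(np.full(K, 5.0), size=n)
        path = [self.loglik(Q, P)]
        for _ in range(max_iter):
            pi = np.clip(Q @ P, _EPS, 1 - _EPS)
            U = self._A / pi          # zero where missing (A is zero there)
            V = self._B / (1.0 - pi)
            # E-step responsibilities folded into the multiplicative updates
            num_p = P * (Q.T @ U)
            den_p = num_p + (1.0 - P) * (Q.T @ V)
            Q = Q * (U @ P.T + V @ (1.0 - P).T) / np.maximum(self._L_i, 1.0)[:, None]
            Q = np.clip(Q, _EPS, None)
            Q /= Q.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                P = np.where(den_p > 0, num_p / den_p, P)
            P = np.clip(P, _EPS, 1 - _EPS)
            path.append(self.loglik(Q, P))
            if path[-1] - path[-2] < tol:
                break
        return AncestryFit(
            K=K, Q=Q, P=P, loglik=path[-1], loglik_path=np.asarray(path),
            seed=seed, n_iter=len(path) - 1, samples=list(self.gt.samples),
        )


@dataclass
class AncestryFit:
    """Converged admixture estimates for one K and one seed."""

    K: int
    Q: np.ndarray
    P: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    seed: int
    n_iter: int
    samples: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Per-sample membership table (sample, q1..qK, label)."""
        df = pd.DataFrame(
            self.Q, columns=[f"q{k + 1}" for k in range(self.K)]
        )
        df.insert(0, "sample", self.samples or range(len(df)))
        df["label"] = assign_membership(self)
        return df


def fit_admixture(gt: Genotypes, K: int, seed: int = 0,
                  max_iter: int = 300, tol: float = 1e-2) -> AncestryFit:
    """Convenience wrapper: ``AdmixtureModel(gt, K).fit(...)``."""
    return AdmixtureModel(gt, K).fit(seed=seed, max_iter=max_iter, tol=tol)


def evanno_delta_k(fits: dict[int, list[AncestryFit]]) -> tuple[pd.DataFrame, int]:
    """Evanno-style Delta-K table from replicated fits over contiguous K.

    Delta K = mean(|L(K+1) - 2 L(K) + L(K-1)|) / sd(L(K)), defined for
    interior K only.  A replicate sd of exactly zero leaves that K's
    Delta K undefined (NaN) rather than dividing by zero.
    Returns the table and the arg-max-Delta-K suggestion.
    """
    ks = sorted(fits)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    if len(ks) < 3:
        raise ValueError("Delta K needs at least one interior K (Kmax >= 3)")
    for k in ks:
        if len(fits[k]) < 2:
            raise ValueError(f"K={k}: need >=2 replicates for Delta K")
    mean_l = {k: float(np.mean([f.loglik for f in fits[k]])) for k in ks}
    sd_l = {k: float(np.std([f.loglik for f in fits[k]], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            second = abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1])
            dk = second / sd_l[k] if sd_l[k] > 0 else np.nan
        rows.append({"K": k, "mean_loglik": mean_l[k], "sd_loglik": sd_l[k], "delta_k": dk})
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    if interior.empty:
        raise ValueError("Delta K undefined at every interior K (zero replicate sd)")
    best_k = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return table, best_k


def assign_membership(fit: AncestryFit, threshold: float = 0.8) -> np.ndarray:
    """Label each sample ``pop_k`` if max membership strictly exceeds the
    threshold, else ``admixed``."""
    best = fit.Q.argmax(axis=1)
    maxq = fit.Q.max(axis=1)
    labels = np.array([f"pop_{b + 1}" for b in best], dtype=object)
    labels[maxq <= threshold] = "admixed"
    return labels


def rogers_distance(gt: Genotypes) -> np.ndarray:
    """Pairwise Rogers' distance on within-individual allele frequencies.

    For diallelic loci with dosages x, y in {0, 1/2, 1} the per-locus
    term sqrt(0.5 * sum_alleles (x_a - y_a)^2) reduces to |x - y|, so
    RD(i, j) is the mean absolute dosage difference over loci called in
    both individuals.
    """
    X = gt.g.astype(float) / 2.0
    obs = gt.g != MISSING
    X[~obs] = 0.0
    n = gt.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        shared = obs[i] & obs
        n_shared = shared.sum(axis=1)
        if (n_shared == 0).any():
            j = int(np.flatnonzero(n_shared == 0)[0])
            if j != i:
                raise ValueError(f"samples {i} and {j} share no called locus")
        diff = np.abs(X[i] - X) * shared
        with np.errstate(invalid="ignore"):
            D[i] = diff.sum(axis=1) / np.maximum(n_shared, 1)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def upgma(dist: np.ndarray, labels: list[str] | None = None) -> str:
    """UPGMA tree from a distance matrix, returned as a Newick string.

    Average linkage with cluster-size weights; merge ties are broken by
    the lexicographically smallest (i, j) index pair so the topology is
    deterministic.  Branch lengths place each merge at half the
    between-cluster distance (ultrametric heights).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    if n == 1:
        return labels[0] + ";"
    active = {i: (labels[i], 0.0, 1) for i in range(n)}  # newick, height, size
    d = {(min(i, j), max(i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, hi, si = active.pop(i)
        nj, hj, sj = active.pop(j)
        h = dij / 2.0
        if sj > si:  # larger subtree printed first (conventional layout)
            newick = f"({nj}:{h - hj:.10g},{ni}:{h - hi:.10g})"
        else:
            newick = f"({ni}:{h - hi:.10g},{nj}:{h - hj:.10g})"
        for k in list(active):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            sk = active[k][2]
            d[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        active[next_id] = (newick, h, si + sj)
        next_id += 1
    (newick, _, _), = active.values()
    return newick + ";"


def kmeans_elbow(
    X: np.ndarray,
    k_range=range(1, 16),
    n_repeats: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, int, np.ndarray]:
    """Within-cluster SS curve over k, repeated, with an elbow suggestion.

    Per k the mean within-cluster sum of squares over ``n_repeats``
    differently seeded runs is reported; the suggested k maximizes the
    second difference of the mean curve (a reproducible stand-in for the
    by-eye elbow).  Labels at the suggested k come from the best run.
    """
    X = np.asarray(X, dtype=float)
    ks = list(k_range)
    if max(ks) > X.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    rows, best_runs = [], {}
    for k in ks:
        inertias = []
        best = None
        for r in range(n_repeats):
            km = KMeans(n_clusters=k, n_init=1, random_state=seed * 1009 + 31 * k + r)
            km.fit(X)
            inertias.append(km.inertia_)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        rows.append({"k": k, "mean_within_ss": float(np.mean(inertias))})
        best_runs[k] = best
    curve = pd.DataFrame(rows)
    wss = curve["mean_within_ss"].to_numpy()
    if len(ks) >= 3:
        second = wss[:-2] - 2 * wss[1:-1] + wss[2:]
        chosen = ks[1 + int(np.argmax(second))]
    else:
        chosen = ks[-1]
    return curve, chosen, best_runs[chosen].labels_.copy()


def genotype_pca(gt: Genotypes, n_components: int = 4):
    """PCA of the genotype matrix after per-site mean fill of missing calls.

    Returns (scores, explained-variance fractions).
    """
    X = gt.g.astype(float)
    miss = gt.missing_mask()
    X[miss] = np.nan
    mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    X = np.where(miss, mean[None, :], X)
    X -= X.mean(axis=0)
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
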