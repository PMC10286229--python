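"""Linkage disequilibrium, differentiation and isolation by distance.

r^2 between unphased GBS genotypes uses the composite (Burrows-type)
estimator — the squared Pearson correlation of ALT dosages over samples
called at both sites — since no phasing information exists.  The decay
of r^2 with physical distance is summarized by fitting the Hill-Weir
drift-recombination expectation and solving for the distance d_0.2 at
which the fitted curve crosses 0.2.  Differentiation uses the Weir &
Cockerham (1984) theta with the ratio-of-sums combination across loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, Genotypes

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(gt: Genotypes, vt: pd.DataFrame, chrom: str, max_dist_bp: int) -> pd.DataFrame:
    """Composite r^2 for all site pairs on ``chrom`` within ``max_dist_bp``.

    Pairs involving a monomorphic site (over their shared called
    samples) are skipped.  Returns columns ``dist_bp, r2, n``.
    """
    idx = np.flatnonzero((vt["chrom"] == chrom).to_numpy())
    if len(idx) < 2:
        raise ValueError(f"need >=2 sites on {chrom}")
    pos = vt["pos"].to_numpy()[idx]
    order = np.argsort(pos, kind="stable")
    idx, pos = idx[order], pos[order]
    G = gt.g[:, idx].astype(float)
    G[gt.g[:, idx] == MISSING] = np.nan
    rows = []
    for a in range(len(idx) - 1):
        for b in range(a + 1, len(idx)):
            dist = pos[b] - pos[a]
            if dist > max_dist_bp:
                break
            x, y = G[:, a], G[:, b]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            xv, yv = x[ok], y[ok]
            sx, sy = xv.std(), yv.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(xv, yv)[0, 1]
            rows.append({"dist_bp": int(dist), "r2": float(r * r), "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["dist_bp", "r2", "n"])


def hill_weir_expectation(dist_bp: np.ndarray, rho: float, n: float) -> np.ndarray:
    """Expected r^2 at recombination scale C = rho * d for sample size n.

    E[r^2] = (10+C)/((2+C)(11+C)) * [1 + ((3+C)(12+12C+C^2)) / (n(2+C)(11+C))]
    """
    C = rho * np.asarray(dist_bp, dtype=float)
    lead = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (n * (2.0 + C) * (11.0 + C))
    return lead * (1.0 + corr)


@dataclass
class LDDecayResult:
    """Fitted decay curve for one chromosome (or pooled set of pairs)."""

    rho: float
    d02: float
    n_pairs: int
    n_samples: float
    at_bound: bool = False

    def expected_r2(self, dist_bp) -> np.ndarray:
        return hill_weir_expectation(dist_bp, self.rho, self.n_samples)


class LDDecayModel:
    """Nonlinear least-squares fit of the Hill-Weir expectation.

    ``pairs`` is a table with ``dist_bp`` and ``r2``; ``n_samples`` is
    the (mean) number of individuals behind each r^2 estimate, entering
    the sample-size correction term.
    """

    def __init__(self, pairs: pd.DataFrame, n_samples: float):
        if len(pairs) < 50:
            raise ValueError("need >=50 pairs to fit the decay curve")
        self.d = pairs["dist_bp"].to_numpy(dtype=float)
        self.r2 = pairs["r2"].to_numpy(dtype=float)
        self.n = float(n_samples)

    def fit(self, d02_bound_bp: float = 1e8) -> LDDecayResult:
        def model(d, log_rho):
            return hill_weir_expectation(d, np.exp(log_rho), self.n)

        # crude scale guess: rho ~ 1/median distance
        guess = np.log(1.0 / max(np.median(self.d), 1.0))
        try:
            popt, _ = optimize.curve_fit(model, self.d, self.r2, p0=[guess], maxfev=2000)
        except RuntimeError as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"Hill-Weir fit failed to converge ({len(self.d)} pairs, "
                f"mean r2 {self.r2.mean():.3f})"
            ) from exc
        rho = float(np.exp(popt[0]))

        def f(dist):
            return hill_weir_expectation(dist, rho, self.n) - 0.2

        at_bound = False
        if f(d02_bound_bp) > 0:
            d02, at_bound = d02_bound_bp, True
        elif f(1e-9) < 0:
            d02, at_bound = 1e-9, True
        else:
            d02 = float(optimize.brentq(f, 1e-9, d02_bound_bp))
        return LDDecayResult(rho=rho, d02=d02, n_pairs=len(self.d),
                             n_samples=self.n, at_bound=at_bound)


def fit_ld_decay(pairs: pd.DataFrame, n_samples: float) -> LDDecayResult:
    return LDDecayModel(pairs, n_samples).fit()


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _wc_components(gt: Genotypes, groups: list[np.ndarray]):
    """Per-locus Weir & Cockerham (1984) a, b, c variance components."""
    r = len(groups)
    L = gt.n_sites
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, idx in enumerate(groups):
        sub = gt.g[idx]
        called = sub != MISSING
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(called, sub, 0).sum(axis=0) / np.maximum(2.0 * n_i[k], 1)
        h_i[k] = np.where(called & (sub == 1), 1, 0).sum(axis=0) / np.maximum(n_i[k], 1)
    ok = (n_i >= 1).all(axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]
    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / nsum
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / nsum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2.0
    poly = (pbar > 0) & (pbar < 1) & (nbar > 1) & (nc > 0)
    return a[poly], b[poly], c[poly]


@dataclass
class FstResult:
    """Weir-Cockerham differentiation summary."""

    overall: float
    pairwise: pd.DataFrame  # columns pop_a, pop_b, fst
    n_loci: int


def wc_fst(gt: Genotypes, labels) -> FstResult:
    """Weir & Cockerham theta between labeled groups, ratio of sums.

    ``labels`` is one group label per sample; samples with a null label
    (None/NaN) are ignored.  The pairwise table covers every pair of
    groups with >=2 samples.
    """
    labels = np.asarray(labels, dtype=object)
    keep = np.array([lab is not None and lab == lab for lab in labels])
    names = sorted({str(lab) for lab in labels[keep]})
    groups = {g: np.flatnonzero(keep & (labels.astype(str) == g)) for g in names}
    names = [g for g in names if len(groups[g]) >= 2]
    if len(names) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")

    def theta(group_list):
        a, b, c = _wc_components(gt, group_list)
        denom = (a + b + c).sum()
        if denom == 0:
            return np.nan, 0
        return float(a.sum() / denom), len(a)

    overall, n_loci = theta([groups[g] for g in names])
    rows = []
    for x in range(len(names)):
        for y in range(x + 1, len(names)):
            est, _ = theta([groups[names[x]], groups[names[y]]])
            rows.append({"pop_a": names[x], "pop_b": names[y], "fst": est})
    return FstResult(overall=overall, pairwise=pd.DataFrame(rows), n_loci=n_loci)


def intrapop_f(gt: Genotypes, labels) -> pd.DataFrame:
    """Per-cluster drift from the pooled frequencies.

    F_k = mean over polymorphic loci of (p_k - pbar)^2 / (pbar (1 - pbar)),
    the Balding-Nichols sense of a cluster-specific drift coefficient.
    """
    labels = np.asarray(labels, dtype=object)
    names = sorted({str(lab) for lab in labels if lab is not None and lab == lab})
    pbar = gt.alt_freq()
    poly = (pbar > 0) & (pbar < 1) & ~np.isnan(pbar)
    rows = []
    for name in names:
        idx = np.flatnonzero(labels.astype(str) == name)
        if len(idx) < 2:
            continue
        sub = gt.take_samples(idx)
        p_k = sub.alt_freq()
        ok = poly & ~np.isnan(p_k)
        f = np.mean((p_k[ok] - pbar[ok]) ** 2 / (pbar[ok] * (1 - pbar[ok])))
        rows.append({"cluster": name, "f": float(f), "n_samples": len(idx)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genetic & geographic distance, Mantel
# ---------------------------------------------------------------------------

def nei_distance(gt: Genotypes) -> np.ndarray:
    """Nei's (1972) standard distance between individuals.

    Individual allele frequencies are the dosage halves x in {0, .5, 1};
    D = -ln( Jxy / sqrt(Jx Jy) ) with J the mean over shared loci of the
    allele-frequency products.
    """
    X = gt.g.astype(float) / 2.0
    obs = gt.g != MISSING
    X[~obs] = 0.0
    n = gt.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        shared = obs[i] & obs  # (n, L)
        m = shared.sum(axis=1)
        if (m == 0).any():
            j = int(np.flatnonzero(m == 0)[0])
            if j != i:
                raise ValueError(f"samples {i} and {j} share no called locus")
        xi = X[i]
        jxy = ((xi * X + (1 - xi) * (1 - X)) * shared).sum(axis=1) / np.maximum(m, 1)
        jx = ((xi**2 + (1 - xi) ** 2) * shared).sum(axis=1) / np.maximum(m, 1)
        jy = ((X**2 + (1 - X) ** 2) * shared).sum(axis=1) / np.maximum(m, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            D[i] = -np.log(jxy / np.sqrt(jx * jy))
    np.fill_diagonal(D, 0.0)
    D[D < 0] = 0.0
    return (D + D.T) / 2.0


def family_mean_distance(dist: np.ndarray, samples: list[str],
                         sample_to_mother: dict) -> tuple[np.ndarray, list[str]]:
    """Collapse a sample-level distance matrix to mother-plant level.

    Entry (m1, m2), m1 != m2, is the mean distance over all cross-family
    offspring pairs; the diagonal is zero.  Mothers with no retained
    offspring are dropped.
    """
    unmapped = [s for s in samples if s not in sample_to_mother]
    if unmapped:
        raise ValueError(f"samples without a mother mapping: {unmapped[:5]}")
    mothers = sorted({sample_to_mother[s] for s in samples})
    index = {m: i for i, m in enumerate(mothers)}
    member = {m: [] for m in mothers}
    for i, s in enumerate(samples):
        member[sample_to_mother[s]].append(i)
    M = np.zeros((len(mothers), len(mothers)))
    for a, ma in enumerate(mothers):
        for b in range(a + 1, len(mothers)):
            block = dist[np.ix_(member[ma], member[mothers[b]])]
            M[a, b] = M[b, a] = block.mean()
    return M, mothers


def geo_distance(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Great-circle (haversine) distance matrix between mother sites, km.

    ``meta`` needs columns ``mother, latitude, longitude`` (one row per
    sample is fine; the first row per mother is used).
    """
    sites = meta.drop_duplicates("mother").sort_values("mother")
    lat = np.radians(sites["latitude"].to_numpy(dtype=float))
    lon = np.radians(sites["longitude"].to_numpy(dtype=float))
    if (np.abs(sites["latitude"]) > 90).any() or (np.abs(sites["longitude"]) > 180).any():
        raise ValueError("coordinates outside decimal-degree range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    D = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(D, 0.0)
    return D, list(sites["mother"])


def mantel_test(d_gen: np.ndarray, d_geo: np.ndarray, n_perm: int = 9999,
                method: str = "spearman", seed: int = 0) -> tuple[float, float]:
    """One-sided (greater) Mantel permutation test of matrix association.

    rho is the rank (or Pearson) correlation of the upper-triangle
    entries; the p-value is (1 + #{perm rho >= observed}) / (1 + n_perm),
    so the smallest attainable p is 1/(n_perm + 1).
    """
    d_gen = np.asarray(d_gen, float)
    d_geo = np.asarray(d_geo, float)
    if d_gen.shape != d_geo.shape or d_gen.shape[0] != d_gen.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = d_gen.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d_gen[iu]
    if np.ptp(x) == 0 or np.ptp(d_geo[iu]) == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def corr(y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        return stats.pearsonr(x, y).statistic

    obs = corr(d_geo[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += corr(d_geo[np.ix_(perm, perm)][iu]) >= obs
    return float(obs), float((1 + hits) / (1 + n_perm))
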