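"""Multi-locus genome-environment association scan.

An iterative fixed-effect scheme in the FarmCPU/BLINK family,
re-implemented from its published description: each marker is tested in
a linear model ``trait ~ intercept + structure covariates + pseudo-QTNs
+ marker``; after a scan, markers are ranked by p-value, LD-pruned
greedily (a candidate joins only if its r^2 with every retained
candidate stays below a threshold), and the number of pseudo-QTNs kept
is chosen by minimum BIC of ``trait ~ covariates + top-m``.  The
pseudo-QTN set then conditions the next scan — any pseudo-QTN in LD
with the tested marker (or the marker itself) is dropped from that
marker's covariate block — and iteration stops when the set repeats.
Significance uses Bonferroni thresholds 0.05/n and 0.01/n with n the
number of tested markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Genotypes, variant_ids


@dataclass
class GEAConfig:
    """Scan hyper-parameters (all config-exposed defaults)."""

    ld_r2_threshold: float = 0.7
    max_iterations: int = 10
    alpha: tuple = (0.05, 0.01)
    m_max: int | None = None  # default n_samples // 10
    #: pseudo-QTNs engage only if the scan minimum p beats this level
    #: divided by the marker count (selection-aware entry guard)
    p_threshold: float = 0.01
    #: Bonferroni-scaled cut (alpha / n_markers) for a marker to be a
    #: pseudo-QTN candidate; keeps polygenic/family background markers
    #: out of the covariate block
    qtn_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> "GEAConfig":
        if not 0.0 < self.ld_r2_threshold < 1.0:
            raise ValueError("ld_r2_threshold must lie in (0, 1)")
        return self


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        cols.append(covariates)
    return np.hstack(cols)


def _orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of X (rank-revealing, drops collinear)."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _marker_pvals(G: np.ndarray, y: np.ndarray, Q0: np.ndarray):
    """Vectorized per-marker slope test after projecting out Q0's span."""
    n = len(y)
    ry = y - Q0 @ (Q0.T @ y)
    RG = G - Q0 @ (Q0.T @ G)
    ss_g = (RG**2).sum(axis=0)
    ss_y = float(ry @ ry)
    xy = RG.T @ ry
    df = n - Q0.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ss_g > 1e-12, xy / np.maximum(ss_g, 1e-300), 0.0)
        sse = np.maximum(ss_y - beta * xy, 0.0)
        fstat = np.where(
            (ss_g > 1e-12) & (sse > 1e-300),
            (beta**2) * ss_g / (sse / df),
            0.0,
        )
    p = stats.f.sf(fstat, 1, df)
    p = np.where(ss_g > 1e-12, p, 1.0)
    return np.clip(p, np.finfo(float).tiny, 1.0), beta


def _r2_with(G: np.ndarray, j: int, idx: np.ndarray) -> np.ndarray:
    """Squared correlation of marker j with each marker in idx."""
    x = G[:, j] - G[:, j].mean()
    Y = G[:, idx] - G[:, idx].mean(axis=0)
    sx = float(x @ x)
    sy = (Y**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((sx > 0) & (sy > 0), (x @ Y) / np.sqrt(np.maximum(sx * sy, 1e-300)), 0.0)
    return r**2


def glm_scan(
    G: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    pseudo_qtns: list[int] | None = None,
    ld_r2_threshold: float = 0.7,
):
    """Per-marker p-values and effects under pseudo-QTN conditioning.

    ``G`` is the imputed (no missing) dosage matrix, samples x markers.
    Markers whose r^2 with a pseudo-QTN reaches the threshold — and the
    pseudo-QTNs themselves — are tested in a model excluding the
    conflicting pseudo-QTNs from the covariate block.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(trait, dtype=float)
    if np.std(y) == 0:
        raise ValueError("trait has zero variance")
    n, L = G.shape
    qtns = list(pseudo_qtns or [])
    X0 = _design(covariates, n)
    base = np.hstack([X0, G[:, qtns]]) if qtns else X0
    Q0 = _orth_basis(base)
    p, beta = _marker_pvals(G, y, Q0)

    if qtns:
        qtn_arr = np.array(qtns)
        conflict: dict[int, tuple] = {}
        for j in range(L):
            r2 = _r2_with(G, j, qtn_arr)
            drop = qtn_arr[r2 >= ld_r2_threshold]
            if j in qtns:
                drop = np.union1d(drop, [j])
            if drop.size:
                conflict[j] = tuple(int(q) for q in drop)
        # markers sharing the same dropped set share a design
        by_set: dict[tuple, list[int]] = {}
        for j, dropped in conflict.items():
            by_set.setdefault(dropped, []).append(j)
        for dropped, markers in by_set.items():
            kept = [q for q in qtns if q not in dropped]
            Xk = np.hstack([X0, G[:, kept]]) if kept else X0
            Qk = _orth_basis(Xk)
            pj, bj = _marker_pvals(G[:, markers], y, Qk)
            p[markers], beta[markers] = pj, bj
    return p, beta


def select_pseudo_qtns(
    p: np.ndarray,
    G: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    cfg: GEAConfig,
) -> list[int]:
    """LD-pruned, BIC-sized pseudo-QTN set from the current scan.

    Markers are taken in ascending p order; a candidate is retained only
    if its r^2 with every already-retained candidate is below the LD
    threshold.  The retained count m is chosen by minimum BIC of
    ``trait ~ covariates + top-m candidates`` over m = 0..m_max.

    Two selection-aware guards: the set stays empty unless the minimum
    p beats ``p_threshold / L`` (naive BIC after a best-of-L search
    would otherwise always admit the top chance marker), and a
    candidate must itself clear the Bonferroni-scaled
    ``qtn_threshold / L`` — background markers carrying only polygenic
    or family-structure signal stay out of the covariate block.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = len(y)
    L = G.shape[1]
    if p.min() >= cfg.p_threshold / L:
        return []
    m_max = cfg.m_max if cfg.m_max is not None else max(n // 10, 1)
    order = np.argsort(p, kind="stable")
    cands: list[int] = []
    for j in order:
        if len(cands) >= m_max:
            break
        if p[j] >= cfg.qtn_threshold / L:
            break
        if cands and (_r2_with(G, int(j), np.array(cands)) >= cfg.ld_r2_threshold).any():
            continue
        cands.append(int(j))
    X0 = _design(covariates, n)

    def bic(m: int) -> float:
        X = np.hstack([X0, G[:, cands[:m]]]) if m else X0
        Q = _orth_basis(X)
        resid = y - Q @ (Q.T @ y)
        sse = float(resid @ resid)
        k = Q.shape[1]
        return n * np.log(max(sse, 1e-300) / n) + k * np.log(n)

    bics = [bic(m) for m in range(len(cands) + 1)]
    best_m = int(np.argmin(bics))
    return cands[:best_m]


@dataclass
class ScanResult:
    """Final association scan for one trait."""

    trait_name: str
    p: np.ndarray
    effects: np.ndarray
    maf: np.ndarray
    pseudo_qtns: list = field(default_factory=list)
    qtn_history: list = field(default_factory=list)
    n_markers: int = 0
    n_samples: int = 0
    converged: bool = True
    n_iterations: int = 0

    @property
    def threshold_05(self) -> float:
        return 0.05 / self.n_markers

    @property
    def threshold_01(self) -> float:
        return 0.01 / self.n_markers

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return np.flatnonzero(self.p < alpha / self.n_markers)

    def lambda_gc(self) -> float:
        """Genomic inflation from the median marker chi-square."""
        chi2 = stats.chi2.isf(self.p, 1)
        return float(np.median(chi2) / stats.chi2.isf(0.5, 1))

    def summary(self, vt: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"p": self.p, "effect": self.effects, "maf": self.maf})
        df["significant_05"] = df["p"] < self.threshold_05
        df["significant_01"] = df["p"] < self.threshold_01
        if vt is not None:
            df.insert(0, "chrom", vt["chrom"].to_numpy())
            df.insert(1, "pos", vt["pos"].to_numpy())
            df.insert(2, "marker", variant_ids(vt).to_numpy())
        return df


def iterate_scan(
    gt: Genotypes,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    cfg: GEAConfig | None = None,
    trait_name: str = "trait",
) -> ScanResult:
    """Run the iterative pseudo-QTN scan to convergence.

    ``gt`` must already be imputed and MAF-refiltered.  Iteration stops
    when the pseudo-QTN set repeats (including the empty set twice) or
    after ``max_iterations``, in which case the result is flagged.
    """
    cfg = (cfg or GEAConfig()).validate()
    if gt.missing_mask().any():
        raise ValueError("scan requires an imputed genotype matrix")
    G = gt.g.astype(float)
    y = np.asarray(trait, dtype=float)
    if len(y) != gt.n_samples:
        raise ValueError("trait length does not match sample count")

    seen: list[list[int]] = []
    qtns: list[int] = []
    converged = False
    p = beta = None
    history = []
    n_iter = 0
    for _ in range(cfg.max_iterations):
        p, beta = glm_scan(G, y, covariates, qtns, cfg.ld_r2_threshold)
        n_iter += 1
        new_qtns = select_pseudo_qtns(p, G, y, covariates, cfg)
        history.append(list(new_qtns))
        if sorted(new_qtns) == sorted(qtns):
            converged = True
            break
        if sorted(new_qtns) in seen:
            # cycle: adopt the repeating set and scan once more so the
            # reported p-values are conditioned on the returned set
            qtns = new_qtns
            p, beta = glm_scan(G, y, covariates, qtns, cfg.ld_r2_threshold)
            n_iter += 1
            converged = True
            break
        seen.append(sorted(qtns))
        qtns = new_qtns
    else:
        # iteration budget exhausted: rescan with the last set so the
        # result is internally consistent, flagged as unconverged
        p, beta = glm_scan(G, y, covariates, qtns, cfg.ld_r2_threshold)
        n_iter += 1
    return ScanResult(
        trait_name=trait_name,
        p=p,
        effects=beta,
        maf=gt.maf(),
        pseudo_qtns=list(qtns),
        qtn_history=history,
        n_markers=gt.n_sites,
        n_samples=gt.n_samples,
        converged=converged,
        n_iterations=n_iter,
    )


def annotate_hits(
    scan: ScanResult, vt: pd.DataFrame, annotation: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significant-marker table in publication layout.

    Columns: trait, chr, position, marker, n, p_value, maf, effect_size,
    effect, impact, gene.  ``annotation`` (chrom, pos, impact, effect,
    gene) is merged when given; unannotated hits get blanks.
    """
    if vt.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate chrom/pos in variant table")
    hits = scan.significant(alpha)
    base = pd.DataFrame(
        {
            "trait": scan.trait_name,
            "chr": vt["chrom"].to_numpy()[hits],
            "position": vt["pos"].to_numpy()[hits],
            "marker": variant_ids(vt).to_numpy()[hits],
            "n": scan.n_samples,
            "p_value": scan.p[hits],
            "maf": scan.maf[hits],
            "effect_size": scan.effects[hits],
        }
    )
    if annotation is not None and len(base):
        ann = annotation[["chrom", "pos", "impact", "effect", "gene"]]
        base = base.merge(
            ann, left_on=["chr", "position"], right_on=["chrom", "pos"], how="left"
        ).drop(columns=["chrom", "pos"])
        base[["impact", "effect", "gene"]] = base[["impact", "effect", "gene"]].fillna("")
    elif annotation is not None:
        base["effect"] = base["impact"] = base["gene"] = ""
    return base.sort_values(["chr", "position"]).reset_index(drop=True)


def qq_manhattan_export(scan: ScanResult, vt: pd.DataFrame):
    """Plot-ready Manhattan and QQ tables plus threshold lines.

    Returns (manhattan frame with cumulative genome coordinate and
    -log10 p, qq frame expected vs observed, thresholds dict).
    """
    mlog = -np.log10(scan.p)
    chroms = vt["chrom"].to_numpy()
    pos = vt["pos"].to_numpy().astype(float)
    cum = np.zeros_like(pos)
    offset = 0.0
    for c in pd.unique(chroms):
        sel = chroms == c
        cum[sel] = pos[sel] + offset
        offset = cum[sel].max() + 1.0
    man = pd.DataFrame(
        {"chrom": chroms, "pos": vt["pos"].to_numpy(), "cum_pos": cum, "minus_log10_p": mlog}
    )
    n = len(scan.p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"expected": expected, "observed": np.sort(mlog)[::-1]})
    thresholds = {
        "threshold_05": -np.log10(scan.threshold_05),
        "threshold_01": -np.log10(scan.threshold_01),
    }
    return man, qq, thresholds
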