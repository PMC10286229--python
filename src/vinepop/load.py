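"""Per-individual deleterious-allele load and subpopulation comparison.

The load statistic P_del is the proportion of minor alleles carried at
HIGH-impact SNPs relative to all alleles carried at MODERATE- or
HIGH-impact SNPs:

    P_del = (minor alleles at non-missing HIGH SNPs)
            / (2 x number of non-missing MODERATE+HIGH SNPs)

Missing genotypes are excluded per individual from both counts, and the
minor allele is fixed once from the whole retained sample so the
statistic is comparable across individuals.  An alternative parse of
the denominator ("number of alleles" already = 2 per SNP, then x2
again) is available behind ``allele_count_times_two``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import MISSING, Genotypes


def minor_allele_map(gt: Genotypes) -> np.ndarray:
    """True where ALT is the minor allele (REF is major on an exact tie)."""
    return gt.minor_is_alt()


def pdel(gt: Genotypes, impacts: pd.Series,
         allele_count_times_two: bool = False) -> pd.DataFrame:
    """P_del for every individual.

    Parameters
    ----------
    gt
        Genotypes of the retained sample (minor alleles are defined on
        this whole matrix).
    impacts
        Impact class per site, aligned to the site axis of ``gt``.
    allele_count_times_two
        Use the alternative denominator parse (x4 per SNP instead of x2).

    Returns a frame with ``sample, num, den, pdel``; individuals with an
    empty denominator get ``pdel = NaN`` and are flagged.
    """
    impacts = np.asarray(impacts, dtype=object)
    if len(impacts) != gt.n_sites:
        raise ValueError("impact vector not aligned to genotype sites")
    high = impacts == "HIGH"
    modhigh = high | (impacts == "MODERATE")
    obs = gt.g != MISSING
    alt_minor = minor_allele_map(gt)
    minor_count = np.where(alt_minor[None, :], gt.g, 2 - gt.g)
    minor_count = np.where(obs, minor_count, 0)
    num = minor_count[:, high].sum(axis=1)
    per_snp = 4 if allele_count_times_two else 2
    den = per_snp * obs[:, modhigh].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return pd.DataFrame(
        {"sample": gt.samples, "num": num.astype(int), "den": den.astype(int), "pdel": p}
    )


@dataclass
class LoadComparison:
    """Group means plus one-way ANOVA and Tukey HSD pairwise results."""

    group_summary: pd.DataFrame
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    excluded_groups: list

    def any_significant(self, alpha: float = 0.05) -> bool:
        return bool((self.tukey["p_adj"] < alpha).any())


def population_load(loads: pd.DataFrame, labels, min_group: int = 3) -> LoadComparison:
    """Compare mean P_del between labeled groups (ANOVA + Tukey HSD).

    Groups below ``min_group`` individuals are excluded (reported in
    ``excluded_groups``).  Individuals with undefined P_del are dropped.
    """
    df = loads.copy()
    df["group"] = np.asarray(labels, dtype=object)
    df = df.dropna(subset=["pdel", "group"])
    sizes = df.groupby("group").size()
    excluded = sorted(sizes.index[sizes < min_group])
    df = df[~df["group"].isin(excluded)]
    kept = sorted(df["group"].unique())
    if len(kept) < 2:
        raise ValueError("need >=2 groups above the minimum size")
    summary = (
        df.groupby("group")["pdel"]
        .agg(mean_pdel="mean", sd_pdel="std", n="size")
        .reset_index()
    )
    vectors = [df.loc[df["group"] == g, "pdel"].to_numpy() for g in kept]
    if all(np.allclose(v, vectors[0][0]) for v in vectors):
        # degenerate: identical values everywhere -> nothing to test
        pairs = [
            {"group_a": kept[a], "group_b": kept[b], "mean_diff": 0.0, "p_adj": 1.0}
            for a in range(len(kept))
            for b in range(a + 1, len(kept))
        ]
        return LoadComparison(summary, 0.0, 1.0, pd.DataFrame(pairs), excluded)
    f_stat, p_val = stats.f_oneway(*vectors)
    res = pairwise_tukeyhsd(df["pdel"].to_numpy(), df["group"].to_numpy())
    tukey = pd.DataFrame(
        {
            "group_a": res._multicomp.groupsunique[res._multicomp.pairindices[0]],
            "group_b": res._multicomp.groupsunique[res._multicomp.pairindices[1]],
            "mean_diff": res.meandiffs,
            "p_adj": res.pvalues,
        }
    )
    return LoadComparison(summary, float(f_stat), float(p_val), tukey, excluded)
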