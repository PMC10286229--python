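"""VCF input and the GBS filter cascade.

The cascade mirrors a standard GATK + VCFtools workflow: per-site
quality rules applied one by one (QD < 2, FS > 60, MQ < 40,
MQRankSum < -12.5, ReadPosRankSum < -8), removal of high-missingness
individuals, genotype-level depth masking, site missingness / MAF /
mean-depth filters, and — ahead of association scanning — major-allele
imputation followed by a fresh MAF cut.  All inequalities are strict in
the printed direction; sites lacking an annotation pass that rule by
default (rank-sum annotations are only emitted at informative sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, Genotypes, check_variant_table

QUALITY_RULES = [
    # (report name, column, op, threshold); strict inequalities remove
    ("QD<2.0", "qd", "lt", 2.0),
    ("FS>60.0", "fs", "gt", 60.0),
    ("MQ<40.0", "mq", "lt", 40.0),
    ("MQRankSum<-12.5", "mq_rank_sum", "lt", -12.5),
    ("ReadPosRankSum<-8.0", "read_pos_rank_sum", "lt", -8.0),
]

INFO_TO_COLUMN = {
    "QD": "qd",
    "FS": "fs",
    "MQ": "mq",
    "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum",
}


@dataclass
class FilterReport:
    """Ordered per-rule removal counts for one cascade stage."""

    steps: list = field(default_factory=list)  # (rule, n_removed)

    def add(self, rule: str, n_removed: int) -> None:
        self.steps.append((rule, int(n_removed)))

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_removed"])


def read_vcf(path, on_multiallelic: str = "error"):
    """Read a biallelic-SNP VCF into (Genotypes, variant table, site quality).

    Genotypes are coded as ALT-allele counts; ``./.`` becomes the
    missing sentinel.  Per-genotype DP is captured when present.
    ``on_multiallelic`` is ``"error"`` or ``"drop"``.
    """
    if on_multiallelic not in ("error", "drop"):
        raise ValueError("on_multiallelic must be 'error' or 'drop'")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    geno_cols, depth_cols, rows = [], [], []
    has_depth = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            if on_multiallelic == "error":
                raise ValueError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS}; "
                    "split it upstream or pass on_multiallelic='drop'"
                )
            continue
        # gts012: 0/1/2 = ALT count, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        geno_cols.append(g)
        dp = rec.format("DP")
        if dp is not None:
            has_depth = True
            dp = np.asarray(dp).reshape(-1).astype(np.int32)
            dp[dp < 0] = 0
            depth_cols.append(dp)
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))
        row = {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0]}
        for key, col in INFO_TO_COLUMN.items():
            val = rec.INFO.get(key)
            row[col] = float(val) if val is not None else np.nan
        rows.append(row)
    if rows:
        g = np.column_stack(geno_cols)
        depth = np.column_stack(depth_cols) if has_depth else None
        vt = pd.DataFrame(rows)
    else:
        g = np.empty((len(samples), 0), dtype=np.int8)
        depth = None
        vt = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"] + list(INFO_TO_COLUMN.values()))
    gt = Genotypes(g, samples, depth)
    sq = vt[[c for c in INFO_TO_COLUMN.values()]].copy() if len(vt) else vt
    if len(vt):
        check_variant_table(vt)
    return gt, vt.drop(columns=[c for c in INFO_TO_COLUMN.values() if c in vt.columns]), sq


def filter_sites_quality(
    gt: Genotypes, vt: pd.DataFrame, sq: pd.DataFrame, strict_missing: bool = False
):
    """Apply the five site-quality rules sequentially.

    A site lacking a given annotation passes that rule unless
    ``strict_missing`` is set, in which case it is removed by it.
    """
    if len(sq) != len(vt):
        raise ValueError("site-quality table not aligned to variant table")
    keep = np.ones(len(vt), dtype=bool)
    report = FilterReport()
    for rule, col, op, thr in QUALITY_RULES:
        vals = sq[col].to_numpy(dtype=float) if col in sq.columns else np.full(len(vt), np.nan)
        with np.errstate(invalid="ignore"):
            fails = (vals < thr) if op == "lt" else (vals > thr)
        absent = np.isnan(vals)
        fails = np.where(absent, strict_missing, fails)
        removed = keep & fails
        report.add(rule, removed.sum())
        keep &= ~fails
    idx = np.flatnonzero(keep)
    return gt.take_sites(idx), vt.iloc[idx].reset_index(drop=True), report


def filter_individuals(gt: Genotypes, max_missing: float = 0.8):
    """Drop samples whose missing fraction strictly exceeds ``max_missing``."""
    if not 0.0 < max_missing <= 1.0:
        raise ValueError("max_missing must lie in (0, 1]")
    rate = gt.sample_missing_rate()
    keep = rate <= max_missing
    if not keep.any():
        raise ValueError("individual-missingness filter would remove every sample")
    removed = [s for s, k in zip(gt.samples, keep) if not k]
    return gt.take_samples(np.flatnonzero(keep)), removed


def filter_genotype_level(
    gt: Genotypes,
    vt: pd.DataFrame,
    min_depth: int = 3,
    max_site_missing: float = 0.5,
    min_maf: float = 0.05,
    min_mean_depth: float = 5.0,
):
    """Depth-mask genotypes, then drop sites by missingness, MAF, mean depth.

    Rules run sequentially (VCFtools style) and are reported per rule.
    MAF is computed on non-missing genotypes; sites at exactly the MAF
    threshold are retained (VCFtools ``--maf`` keeps >=).
    """
    gt = gt.copy()
    report = FilterReport()
    if gt.depth is not None:
        mask = (gt.depth < min_depth) & (gt.g != MISSING)
        gt.g[mask] = MISSING
        report.add(f"genotype DP<{min_depth} masked", mask.sum())
    else:
        report.add(f"genotype DP<{min_depth} masked", 0)

    keep = np.ones(gt.n_sites, dtype=bool)
    miss = gt.site_missing_rate()
    fails = miss > max_site_missing
    report.add(f"site missing>{max_site_missing}", (keep & fails).sum())
    keep &= ~fails

    maf = gt.maf()
    with np.errstate(invalid="ignore"):
        fails = ~(maf >= min_maf)  # NaN (all-missing) also fails
    report.add(f"MAF<{min_maf}", (keep & fails).sum())
    keep &= ~fails

    if gt.depth is not None:
        called = gt.g != MISSING
        with np.errstate(invalid="ignore"):
            mean_dp = np.where(
                called.sum(axis=0) > 0,
                np.where(called, gt.depth, 0).sum(axis=0) / called.sum(axis=0),
                0.0,
            )
        fails = mean_dp < min_mean_depth
    else:
        fails = np.zeros(gt.n_sites, dtype=bool)
    report.add(f"mean depth<{min_mean_depth}", (keep & fails).sum())
    keep &= ~fails

    idx = np.flatnonzero(keep)
    return gt.take_sites(idx), vt.iloc[idx].reset_index(drop=True), report


def impute_major(gt: Genotypes) -> Genotypes:
    """Replace missing genotypes by the homozygous major-allele code.

    The major allele is REF on an exact 0.5 frequency tie.
    """
    out = gt.copy()
    p = out.alt_freq()
    if np.isnan(p).any():
        bad = int(np.flatnonzero(np.isnan(p))[0])
        raise ValueError(f"site {bad} has no called genotype; cannot impute")
    fill = np.where(p > 0.5, 2, 0).astype(np.int8)
    miss = out.missing_mask()
    out.g = np.where(miss, fill[None, :], out.g).astype(np.int8)
    if out.depth is not None:
        out.depth = out.depth.copy()
    return out


def refilter_maf(gt: Genotypes, vt: pd.DataFrame, min_maf: float = 0.05):
    """Drop sites whose post-imputation MAF fell below the threshold."""
    maf = gt.maf()
    keep = maf >= min_maf
    idx = np.flatnonzero(keep)
    n_removed = int((~keep).sum())
    return gt.take_sites(idx), vt.iloc[idx].reset_index(drop=True), n_removed
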