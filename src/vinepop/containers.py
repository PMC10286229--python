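"""Core in-memory containers shared by every analysis stage.

Genotypes are held as a dense ``int8`` matrix of ALT-allele counts
(samples x sites) with ``-1`` marking a missing call, the natural coding
for diallelic SNPs from reduced-representation sequencing.  Variant
metadata travels as a plain :class:`pandas.DataFrame` so that standard
pandas idioms (boolean masks, merges on ``chrom``/``pos``) apply
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: canonical column order of a variant table
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]

#: snpEff-style impact categories, most to least severe
IMPACT_CLASSES = ["HIGH", "MODERATE", "LOW", "MODIFIER"]


@dataclass
class Genotypes:
    """Samples x sites ALT-allele dosage matrix with optional read depth.

    Parameters
    ----------
    g
        ``(n_samples, n_sites)`` int8 array with values in ``{0, 1, 2}``
        and :data:`MISSING` (= -1) for no-calls.
    samples
        Sample identifiers, one per row of ``g``.
    depth
        Optional per-genotype read depth, same shape as ``g``.
    """

    g: np.ndarray
    samples: list[str] = field(default_factory=list)
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int8)
        if self.g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x sites)")
        if not self.samples:
            self.samples = [f"S{i:04d}" for i in range(self.g.shape[0])]
        if len(self.samples) != self.g.shape[0]:
            raise ValueError("sample list length does not match matrix rows")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.g.shape:
                raise ValueError("depth shape does not match genotype shape")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.g.shape[0]

    @property
    def n_sites(self) -> int:
        return self.g.shape[1]

    def copy(self) -> "Genotypes":
        return Genotypes(
            self.g.copy(),
            list(self.samples),
            None if self.depth is None else self.depth.copy(),
        )

    # -- missingness ----------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.g == MISSING

    def sample_missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per sample."""
        return self.missing_mask().mean(axis=1)

    def site_missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per site."""
        return self.missing_mask().mean(axis=0)

    # -- allele frequencies --------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing genotypes.

        Sites with no called genotype return ``nan``.
        """
        miss = self.missing_mask()
        called = (~miss).sum(axis=0)
        alt = np.where(miss, 0, self.g).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / (2.0 * called), np.nan)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency (``min(p, 1-p)``)."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def minor_is_alt(self) -> np.ndarray:
        """Whether ALT is the minor allele; ties (p = 0.5) count ALT as minor.

        REF is treated as the major allele on a tie, the usual
        reference-preferring convention.
        """
        return self.alt_freq() <= 0.5

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx) -> "Genotypes":
        idx = np.asarray(idx, dtype=np.intp)
        return Genotypes(
            self.g[idx],
            [self.samples[i] for i in idx],
            None if self.depth is None else self.depth[idx],
        )

    def take_sites(self, idx) -> "Genotypes":
        idx = np.asarray(idx, dtype=np.intp)
        return Genotypes(
            self.g[:, idx],
            list(self.samples),
            None if self.depth is None else self.depth[:, idx],
        )


def variant_ids(vt: pd.DataFrame) -> pd.Series:
    """Marker ids in ``chr07_13314249`` style from a variant table."""
    return vt["chrom"].astype(str) + "_" + vt["pos"].astype(str)


def check_variant_table(vt: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in vt.columns]
    if missing:
        raise ValueError(f"variant table lacks columns: {missing}")
    if vt.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate chrom/pos in variant table")
    return vt


def as_float_matrix(gt: Genotypes) -> np.ndarray:
    """Genotypes as float with missing encoded as NaN."""
    out = gt.g.astype(float)
    out[gt.missing_mask()] = np.nan
    return out
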