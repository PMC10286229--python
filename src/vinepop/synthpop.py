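"""Synthetic half-sib study generator.

Emulates a wild-vine sampling design: mother plants placed along a
NW->SE transect with decreasing elevation, two weakly differentiated
demes at the transect ends plus admixed mothers in between, and four
open-pollinated (half-sib) offspring genotyped per mother.  Deme allele
frequencies follow the Balding-Nichols model, whose drift parameter is a
direct F_ST dial; a handful of "environmental" loci additionally carry a
logistic allele-frequency cline in standardized elevation, giving the
association scan a known truth set.

The generator writes a complete file study (VCF + metadata + monthly
climate normals + impact annotation + truth JSON) so every downstream
stage can be exercised without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Genotypes, variant_ids

# rough chromosome lengths (Mb) of the 19 grapevine chromosomes
CHROM_MB = np.array(
    [25, 19, 20, 24, 25, 22, 27, 22, 23, 19, 20, 24, 29, 30, 20, 22, 18, 30, 25],
    dtype=float,
)

EFFECT_VOCAB = {
    "HIGH": ["stop_gained", "frameshift_variant", "splice_acceptor_variant", "start_lost"],
    "MODERATE": ["missense_variant"],
    "LOW": ["synonymous_variant", "splice_region_variant&intron_variant"],
    "MODIFIER": [
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intron_variant",
        "intergenic_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
    ],
}

# NW and SE ends of the sampled transect (lat, lon), decimal degrees
TRANSECT_NW = (31.383, -100.033)
TRANSECT_SE = (29.717, -97.433)


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the emulated design: 78 mothers x 4 half-sib
    offspring subsampled to 286 genotyped plants, two demes at
    F_ST 0.03 with 40% admixed mothers, elevations spanning
    722-2295 m, and snpEff-like impact-class proportions
    (0.75% HIGH / 17% MODERATE / 17% LOW / 65% MODIFIER).
    """

    n_mothers: int = 78
    offspring_per_mother: int = 4
    n_selected: int = 286
    n_snps: int = 5000
    n_chromosomes: int = 19
    fst_target: float = 0.03
    admixture_fraction: float = 0.4
    n_env_loci: int = 5
    env_effect: float = 1.0
    missing_rate: float = 0.2
    mean_depth: float = 12.0
    impact_props: dict = field(
        default_factory=lambda: {
            "HIGH": 0.0075,
            "MODERATE": 0.17,
            "LOW": 0.17,
            "MODIFIER": 0.6525,
        }
    )
    elevation_range: tuple = (722.0, 2295.0)
    lapse_rate: float = 6.5  # degC per km of elevation
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must lie in (0, 1)")
        if abs(sum(self.impact_props.values()) - 1.0) > 1e-9:
            raise ValueError("impact_props must sum to 1")
        if self.n_env_loci >= self.n_snps:
            raise ValueError("n_env_loci must be smaller than n_snps")
        if not 0.0 <= self.admixture_fraction < 1.0:
            raise ValueError("admixture_fraction must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 0.9:
            raise ValueError("missing_rate must lie in [0, 0.9)")
        if self.n_selected > self.n_mothers * self.offspring_per_mother:
            raise ValueError("cannot select more offspring than are simulated")
        return self


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator for downstream validation."""

    deme_of_mother: dict
    env_locus_ids: list
    env_effects: dict
    ancestral_freqs: np.ndarray
    admix_weight: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "deme_of_mother": self.deme_of_mother,
                "env_locus_ids": list(self.env_locus_ids),
                "env_effects": self.env_effects,
                "ancestral_freqs": np.asarray(self.ancestral_freqs).tolist(),
                "admix_weight": self.admix_weight,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            deme_of_mother=d["deme_of_mother"],
            env_locus_ids=d["env_locus_ids"],
            env_effects=d["env_effects"],
            ancestral_freqs=np.asarray(d["ancestral_freqs"]),
            admix_weight=d["admix_weight"],
        )


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed * 1_000_003 + salt) % (2**31))


def make_landscape(cfg: SimConfig) -> pd.DataFrame:
    """Place mothers on the transect and enumerate genotyped offspring.

    Returns one row per *selected* offspring with columns
    ``sample, mother, site, longitude, latitude, elevation``.
    Mothers at the NW (start) end sit high on the elevation gradient and
    belong to deme 1; the SE end is deme 2; a central band of mothers is
    admixed.  The deme assignment itself is part of the truth set, not
    of the metadata file.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    m = cfg.n_mothers
    # position along transect, 0 = NW start, endpoints included
    t = np.arange(m) / (m - 1) if m > 1 else np.zeros(1)
    t = np.clip(t + rng.normal(0.0, 0.15 / max(m, 1), m), 0.0, 1.0)

    lat = TRANSECT_NW[0] + t * (TRANSECT_SE[0] - TRANSECT_NW[0]) + rng.normal(0, 0.05, m)
    lon = TRANSECT_NW[1] + t * (TRANSECT_SE[1] - TRANSECT_NW[1]) + rng.normal(0, 0.05, m)
    lo, hi = cfg.elevation_range
    elev = hi - t * (hi - lo) + rng.normal(0.0, 0.03 * (hi - lo), m)
    elev = np.clip(elev, lo, hi)

    rows = []
    for i in range(m):
        mother = f"M{i + 1:03d}"
        for j in range(cfg.offspring_per_mother):
            rows.append(
                {
                    "sample": f"{mother}_{j + 1}",
                    "mother": mother,
                    "site": mother,
                    "longitude": lon[i],
                    "latitude": lat[i],
                    "elevation": elev[i],
                    "transect_pos": t[i],
                }
            )
    meta = pd.DataFrame(rows)
    if len(meta) > cfg.n_selected:
        # vigor-based subsampling is not genotype-informed: uniform
        keep = np.sort(rng.choice(len(meta), size=cfg.n_selected, replace=False))
        meta = meta.iloc[keep].reset_index(drop=True)
    return meta


def _deme_of_mothers(cfg: SimConfig, meta: pd.DataFrame) -> tuple[dict, dict]:
    """Truth deme per mother from transect position; central band admixed."""
    rng = _rng(cfg, 2)
    pos = meta.drop_duplicates("mother").set_index("mother")["transect_pos"]
    lo_cut = (1.0 - cfg.admixture_fraction) / 2.0
    hi_cut = 1.0 - lo_cut
    deme, weight = {}, {}
    for mother, t in pos.items():
        if t < lo_cut:
            deme[mother] = "deme1"
        elif t > hi_cut:
            deme[mother] = "deme2"
        else:
            deme[mother] = "admixed"
            weight[mother] = float(rng.uniform(0.3, 0.7))
    return deme, weight


# monthly normals template for a warm semi-arid plateau at the low end of
# the elevation range (Jan..Dec)
_TMEAN_BASE = np.array([9, 12, 16, 20, 25, 28, 30, 29, 26, 20, 14, 10], dtype=float)
_PRECIP_BASE = np.array([40, 45, 60, 75, 95, 85, 55, 60, 80, 85, 50, 45], dtype=float)


def make_climate(meta: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Monthly climate normals per site, driven by elevation and transect.

    Temperature falls with elevation at ``cfg.lapse_rate`` degC/km;
    precipitation increases toward the NW (damper) end of the transect.
    PET follows a simple temperature-driven (Thornthwaite-like) shape.
    Columns: ``site, month, tmean, tmin, tmax, precip, pet, latitude``.
    """
    rng = _rng(cfg, 3)
    sites = meta.drop_duplicates("site").set_index("site")
    lo = cfg.elevation_range[0]
    rows = []
    for site, r in sites.iterrows():
        dz_km = (r["elevation"] - lo) / 1000.0
        noise_t = rng.normal(0.0, 0.2, 12)
        noise_p = rng.normal(0.0, 2.0, 12)
        tmean = _TMEAN_BASE - cfg.lapse_rate * dz_km + noise_t
        tmin = tmean - 6.0
        tmax = tmean + 7.0
        precip = np.clip(_PRECIP_BASE * (1.15 - 0.3 * r["transect_pos"]) + noise_p, 0.0, None)
        pet = np.clip(35.0 + 7.0 * (tmean - 10.0), 5.0, None)
        for month in range(12):
            rows.append(
                {
                    "site": site,
                    "month": month + 1,
                    "tmean": tmean[month],
                    "tmin": tmin[month],
                    "tmax": tmax[month],
                    "precip": precip[month],
                    "pet": pet[month],
                    "latitude": r["latitude"],
                }
            )
    return pd.DataFrame(rows)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def calibrate_env_effect(n_samples: int, n_markers: int, maf: float = 0.3,
                         power: float = 0.8, alpha: float = 0.05,
                         structure_r2: float = 0.0,
                         design_effect: float = 1.0) -> float:
    """Logistic cline steepness giving the target single-marker power.

    For a marker with frequency ``p`` and a standardized environmental
    covariate ``z``, a small logit shift ``b`` per unit ``z`` induces
    genotype-trait correlation ``r ~= b * sqrt(2 p (1-p))`` under HWE.
    The marker F-test at the Bonferroni level ``alpha/n_markers``
    reaches the requested power when the noncentrality
    ``n r^2 / (1 - r^2)`` matches ``(z_{a} + z_{power})^2``.

    ``structure_r2`` is the fraction of trait variance absorbed by the
    ancestry covariates of the scan: conditioning shrinks the usable
    correlation by ``sqrt(1 - structure_r2)``, so the planted cline must
    be steeper by the inverse factor to keep the conditional power.
    ``design_effect`` is the variance inflation from family replication
    of the trait (half-sib broods: ``1 + (mean sibs - 1) * 0.25``),
    which divides the effective sample size.
    """
    from scipy import stats

    z = stats.norm.isf(alpha / n_markers / 2.0) + stats.norm.ppf(power)
    lam = z**2
    n_eff = n_samples / design_effect
    r2 = lam / (lam + n_eff)
    r = np.sqrt(r2)
    return float(r / np.sqrt(2.0 * maf * (1.0 - maf)) / np.sqrt(1.0 - structure_r2))


def calibrate_env_effect_empirical(
    cfg: SimConfig,
    n_markers: int | None = None,
    power: float = 0.8,
    alpha: float = 0.05,
    n_probe: int = 300,
    beta_hi: float = 8.0,
) -> float:
    """Cline steepness giving 80% conditional single-marker power.

    The closed-form :func:`calibrate_env_effect` ignores three
    attenuations of the stated design: logistic saturation of the
    cline, shrinkage from major-allele imputation of missing calls, and
    the alignment of the cline with the ancestry axis that the
    structure covariate absorbs.  This version measures them directly:
    it simulates probe loci under the generator's own transmission
    model at a trial steepness, applies the MCAR missingness and
    major-allele fill, computes the partial correlation of imputed
    dosage with the environmental covariate given true ancestry, and
    converts it to power for the structure-conditioned marker F-test at
    the Bonferroni level with the half-sib design effect.  Bisection
    returns the smallest steepness reaching the target (or ``beta_hi``
    if the target is unattainable).

    Nothing here looks at scan output; the calibration is a function of
    the stated world only.
    """
    from scipy import stats

    cfg = cfg.validate()
    L = n_markers if n_markers is not None else cfg.n_snps
    meta = make_landscape(cfg)
    deme, weight = _deme_of_mothers(cfg, meta)
    elev = meta.drop_duplicates("mother").set_index("mother")["elevation"]
    z_m = (elev - elev.mean()) / elev.std(ddof=0)
    w_of = {m: {"deme1": 1.0, "deme2": 0.0}.get(deme[m], weight.get(m, 0.5))
            for m in elev.index}
    w = meta["mother"].map(w_of).to_numpy(float)
    z = meta["mother"].map(z_m).to_numpy(float)
    n = len(meta)
    fam_size = meta.groupby("mother").size().mean()
    design_effect = 1.0 + (fam_size - 1.0) * 0.25
    n_eff = n / design_effect
    z_crit = stats.norm.isf(alpha / L / 2.0)
    rng = np.random.default_rng((cfg.seed * 1_000_003 + 99) % (2**31))
    p_anc = rng.uniform(0.25, 0.75, n_probe)
    signs = rng.choice([-1.0, 1.0], n_probe)
    F = cfg.fst_target
    a_par = p_anc * (1 - F) / F
    b_par = (1 - p_anc) * (1 - F) / F
    p1 = rng.beta(a_par, b_par)
    p2 = rng.beta(a_par, b_par)
    miss = rng.random((n, n_probe)) < cfg.missing_rate
    u_mat = rng.random((2, n, n_probe))   # maternal gamete draws
    u_pol = rng.random((n, n_probe))
    pick = rng.integers(0, 2, (n, n_probe))

    logit = lambda p: np.log(p / (1 - p))  # noqa: E731

    def mean_power(beta: float) -> float:
        lo1, lo2 = logit(np.clip(p1, 1e-4, 1 - 1e-4)), logit(np.clip(p2, 1e-4, 1 - 1e-4))
        # per-sample local frequencies with the cline
        wv = w[:, None]
        base_m = wv * p1[None, :] + (1 - wv) * p2[None, :]
        base_p = np.where(wv == 1.0, p1[None, :],
                          np.where(wv == 0.0, p2[None, :],
                                   0.5 * p1[None, :] + 0.5 * p2[None, :]))
        shift = beta * signs[None, :] * z[:, None]
        pm = _sigmoid(logit(np.clip(base_m, 1e-4, 1 - 1e-4)) + shift)
        pp = _sigmoid(logit(np.clip(base_p, 1e-4, 1 - 1e-4)) + shift)
        mat = (u_mat[pick, np.arange(n)[:, None], np.arange(n_probe)[None, :]] < pm)
        g = mat.astype(float) + (u_pol < pp)
        # major-allele imputation of MCAR missing calls
        g_obs = np.where(miss, np.nan, g)
        freq = np.nanmean(g_obs, axis=0) / 2.0
        fill = np.where(freq > 0.5, 2.0, 0.0)
        g_imp = np.where(miss, fill[None, :], g)
        # partial correlation with z given true ancestry w
        def _part(x):
            rz = np.corrcoef(z, w)[0, 1]
            xs = (x - x.mean(0)) / np.maximum(x.std(0), 1e-9)
            rgz = xs.T @ ((z - z.mean()) / z.std()) / n
            rgw = xs.T @ ((w - w.mean()) / max(w.std(), 1e-9)) / n
            return (rgz - rgw * rz) / np.sqrt(np.maximum((1 - rgw**2) * (1 - rz**2), 1e-9))
        r = np.clip(np.abs(_part(g_imp)), 0.0, 0.99)
        ncp = n_eff * r**2 / (1 - r**2)
        return float(np.mean(stats.norm.sf(z_crit - np.sqrt(ncp))))

    lo, hi = 0.1, beta_hi
    if mean_power(hi) < power:
        return float(hi)
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if mean_power(mid) >= power:
            hi = mid
        else:
            lo = mid
    return float(hi)


def simulate_genotypes(
    meta: pd.DataFrame, cfg: SimConfig
) -> tuple[Genotypes, pd.DataFrame, TruthSet]:
    """Draw half-sib genotypes under the Balding-Nichols two-deme model.

    Deme frequencies are ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around
    ancestral ``p`` with ``F = fst_target``.  Each mother's genotype is
    drawn from her deme frequency (a ``w:1-w`` frequency mixture for
    admixed mothers); each offspring receives one Mendelian maternal
    gamete plus one pollen gamete from the local frequency, making the
    brood half-sibs under open pollination.  Environmental loci get an
    extra logit shift ``env_effect * z(elevation)`` in the local
    frequency.  Missingness is MCAR at ``missing_rate`` with a mild
    per-sample multiplier; depth is Poisson around ``mean_depth``.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    L = cfg.n_snps

    # variant table: positions uniform on chromosomes sized like grapevine
    lens = (CHROM_MB[: cfg.n_chromosomes] * 1e6).astype(int)
    n_per = rng.multinomial(L, lens / lens.sum())
    chroms, poss = [], []
    for c, (n_c, len_c) in enumerate(zip(n_per, lens)):
        pos = np.sort(rng.choice(np.arange(1, len_c), size=n_c, replace=False))
        chroms.extend([f"chr{c + 1:02d}"] * n_c)
        poss.extend(pos.tolist())
    vt = pd.DataFrame({"chrom": chroms, "pos": poss})
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, L)
    alt = (ref + rng.integers(1, 4, L)) % 4
    vt["ref"] = bases[ref]
    vt["alt"] = bases[alt]

    p_anc = rng.uniform(0.05, 0.95, L)
    F = cfg.fst_target
    if F < 1e-9:
        p1 = p2 = p_anc.copy()
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)

    # environmental loci: common variants so the cline is detectable
    common = np.flatnonzero((p_anc > 0.25) & (p_anc < 0.75))
    env_idx = np.sort(rng.choice(common, size=cfg.n_env_loci, replace=False))
    env_signs = rng.choice([-1.0, 1.0], size=cfg.n_env_loci)

    deme, weight = _deme_of_mothers(cfg, meta)
    elev = meta.drop_duplicates("mother").set_index("mother")["elevation"]
    z_elev = (elev - elev.mean()) / elev.std(ddof=0)

    mothers = list(elev.index)
    logit = lambda p: np.log(p / (1 - p))  # noqa: E731

    def _with_cline(p_m: np.ndarray, z: float) -> np.ndarray:
        p_m = p_m.copy()
        pe = np.clip(p_m[env_idx], 1e-4, 1 - 1e-4)
        p_m[env_idx] = _sigmoid(logit(pe) + cfg.env_effect * env_signs * z)
        return p_m

    # maternal pool: the mother's own ancestry mixture; pollen pool: the
    # local deme frequency (zone average in the admixed band) — open
    # pollination makes each brood half-sibs, with no extra
    # mother-specific pollen correlation
    p_maternal, p_pollen = {}, {}
    for mother in mothers:
        d = deme[mother]
        if d == "deme1":
            base_m = base_p = p1
        elif d == "deme2":
            base_m = base_p = p2
        else:
            base_m = weight[mother] * p1 + (1 - weight[mother]) * p2
            base_p = 0.5 * p1 + 0.5 * p2
        z = z_elev[mother]
        p_maternal[mother] = _with_cline(base_m, z)
        p_pollen[mother] = _with_cline(base_p, z)

    mother_gt = {
        m: (rng.random((2, L)) < p_maternal[m]).astype(np.int8) for m in mothers
    }

    n = len(meta)
    G = np.empty((n, L), dtype=np.int8)
    for i, row in enumerate(meta.itertuples()):
        mg = mother_gt[row.mother]
        maternal = mg[rng.integers(0, 2, L), np.arange(L)]
        pollen = (rng.random(L) < p_pollen[row.mother]).astype(np.int8)
        G[i] = maternal + pollen

    # MCAR missingness with per-sample multiplier (mean 1)
    mult = np.exp(rng.normal(0.0, 0.3, n))
    mult /= mult.mean()
    p_miss = np.clip(cfg.missing_rate * mult, 0.0, 0.85)
    miss = rng.random((n, L)) < p_miss[:, None]
    depth = rng.poisson(cfg.mean_depth, (n, L)).astype(np.int16)
    depth = np.maximum(depth, 1)
    G[miss] = -1
    depth[miss] = 0

    # site-quality annotations: mostly clean with realistic tails
    vt["qd"] = np.round(np.clip(rng.normal(22.0, 6.0, L), 0.1, None), 2)
    vt["fs"] = np.round(rng.exponential(6.0, L), 3)
    vt["mq"] = np.round(np.clip(rng.normal(55.0, 4.0, L), 5.0, 60.0), 2)
    vt["mq_rank_sum"] = np.round(rng.normal(0.0, 2.0, L), 3)
    vt["read_pos_rank_sum"] = np.round(rng.normal(0.0, 1.5, L), 3)

    ids = variant_ids(vt)
    truth = TruthSet(
        deme_of_mother=deme,
        env_locus_ids=[ids.iloc[j] for j in env_idx],
        env_effects={
            ids.iloc[j]: float(cfg.env_effect * s) for j, s in zip(env_idx, env_signs)
        },
        ancestral_freqs=p_anc,
        admix_weight=weight,
    )
    gt = Genotypes(G, list(meta["sample"]), depth)
    return gt, vt, truth


def assign_impacts(vt: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Attach one impact class, effect term and gene id per SNP."""
    rng = _rng(cfg, 5)
    classes = list(cfg.impact_props)
    props = np.array([cfg.impact_props[c] for c in classes])
    draw = rng.choice(len(classes), size=len(vt), p=props / props.sum())
    vt = vt.copy()
    vt["impact"] = [classes[i] for i in draw]
    vt["effect"] = [
        EFFECT_VOCAB[classes[i]][rng.integers(len(EFFECT_VOCAB[classes[i]]))]
        for i in draw
    ]
    gene_no = rng.integers(1, 3000, len(vt))
    vt["gene"] = [
        f"Vitvi{str(c).removeprefix('chr')}g{g:05d}"
        for c, g in zip(vt["chrom"], gene_no)
    ]
    return vt


def write_vcf(path, gt: Genotypes, vt: pd.DataFrame, n_chromosomes: int = 19) -> None:
    """Emit a VCF v4.2 with GT:DP genotypes and GATK-style INFO fields."""
    lens = (CHROM_MB[:n_chromosomes] * 1e6).astype(int)
    info_keys = [
        ("qd", "QD"),
        ("fs", "FS"),
        ("mq", "MQ"),
        ("mq_rank_sum", "MQRankSum"),
        ("read_pos_rank_sum", "ReadPosRankSum"),
    ]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vinepop-synthpop\n")
        for c in range(n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1:02d},length={lens[c]}>\n")
        for _, key in info_keys:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.samples)
            + "\n"
        )
        depth = gt.depth
        for j in range(len(vt)):
            row = vt.iloc[j]
            info = ";".join(
                f"{key}={row[col]:g}" for col, key in info_keys if col in vt.columns
            )
            cells = []
            for i in range(gt.n_samples):
                dp = int(depth[i, j]) if depth is not None else 0
                cells.append(f"{gt_str[int(gt.g[i, j])]}:{dp}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['chrom']}_{row['pos']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t{info or '.'}\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def write_study(outdir, cfg: SimConfig) -> dict:
    """Generate and write the full synthetic study; returns the file map."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = make_landscape(cfg)
    climate = make_climate(meta, cfg)
    gt, vt, truth = simulate_genotypes(meta, cfg)
    vt = assign_impacts(vt, cfg)

    files = {
        "vcf": outdir / "study.vcf",
        "meta": outdir / "samples.csv",
        "climate": outdir / "climate.csv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(files["vcf"], gt, vt, cfg.n_chromosomes)
    meta.drop(columns=["transect_pos"]).to_csv(files["meta"], index=False)
    climate.to_csv(files["climate"], index=False)
    vt[["chrom", "pos", "impact", "effect", "gene"]].to_csv(
        files["annotation"], sep="\t", index=False
    )
    files["truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in files.items()}
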