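"""End-to-end pipeline: simulate -> filter -> structure -> popgen ->
load -> climate -> GEA, driven by one declarative config.

Every stage writes plain-text tables into the output directory and a
manifest records the seed, all parameters, input-file hashes and every
output file, so that a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climod
from . import gea as geamod
from . import load as loadmod
from . import popgen, structure, synthpop, variants

log = logging.getLogger("vinepop")

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "vinepop_run",
    "simulate": {
        "n_mothers": 78,
        "offspring_per_mother": 4,
        "n_selected": 286,
        "n_snps": 4000,
        "fst_target": 0.03,
        "admixture_fraction": 0.4,
        "n_env_loci": 5,
        "env_effect": 1.0,
        "missing_rate": 0.2,
    },
    "filter": {
        "ind_max_missing": [0.8, 0.6],
        "min_depth": 3,
        "max_site_missing": 0.5,
        "min_maf": 0.05,
        "min_mean_depth": 5.0,
    },
    "structure": {"k_max": 5, "n_replicates": 3, "max_iter": 200, "tol": 1e-2,
                  "membership_threshold": 0.8, "kmeans_k_max": 8, "kmeans_repeats": 5,
                  "pca_components": 4},
    "popgen": {"ld_max_dist_bp": 500000, "mantel_permutations": 9999},
    "gea": {"ld_r2_threshold": 0.7, "max_iterations": 10},
}


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return _merged(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, float_format="%.10g", **kw)
    return path


def run_all(config: dict | None = None) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    cfg = _merged(config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "parameters": cfg, "inputs": {}, "outputs": []}

    def emit(name: str, path: Path):
        manifest["outputs"].append({"file": str(path.name), "sha256": _sha256(path)})

    # -- stage 1: simulate ------------------------------------------------
    log.info("stage simulate")
    sim_cfg = synthpop.SimConfig(seed=seed, **cfg["simulate"])
    study_dir = outdir / "study"
    files = synthpop.write_study(study_dir, sim_cfg)
    for key, f in files.items():
        manifest["inputs"][key] = {"file": str(Path(f).name), "sha256": _sha256(Path(f))}
    meta = pd.read_csv(files["meta"])
    climate_df = pd.read_csv(files["climate"])
    annotation = pd.read_csv(files["annotation"], sep="\t")

    # -- stage 2: filter --------------------------------------------------
    log.info("stage filter")
    gt, vt, sq = variants.read_vcf(files["vcf"])
    gt, vt, rep_q = variants.filter_sites_quality(gt, vt, sq)
    removed_samples: list[str] = []
    for cut in cfg["filter"]["ind_max_missing"]:
        gt, removed = variants.filter_individuals(gt, cut)
        removed_samples.extend(removed)
    gt, vt, rep_g = variants.filter_genotype_level(
        gt, vt,
        min_depth=cfg["filter"]["min_depth"],
        max_site_missing=cfg["filter"]["max_site_missing"],
        min_maf=cfg["filter"]["min_maf"],
        min_mean_depth=cfg["filter"]["min_mean_depth"],
    )
    meta = meta[meta["sample"].isin(gt.samples)].reset_index(drop=True)
    report = pd.concat([rep_q.to_frame(), rep_g.to_frame()], ignore_index=True)
    emit("filter_report", _write_csv(report, outdir / "filter_report.tsv", sep="\t", index=False))

    # -- stage 3: structure ----------------------------------------------
    log.info("stage structure")
    st = cfg["structure"]
    fits = {
        k: [
            structure.fit_admixture(
                gt, k, seed=seed * 10007 + 101 * k + r,
                max_iter=st["max_iter"], tol=st["tol"],
            )
            for r in range(st["n_replicates"])
        ]
        for k in range(1, st["k_max"] + 1)
    }
    evanno, best_k = structure.evanno_delta_k(fits)
    emit("evanno", _write_csv(evanno, outdir / "evanno.tsv", sep="\t", index=False))
    fit = max(fits[best_k], key=lambda f: f.loglik)
    qtable = fit.summary()
    labels = qtable["label"].to_numpy()
    emit("memberships", _write_csv(qtable, outdir / "memberships.tsv", sep="\t", index=False))

    scores, evr = structure.genotype_pca(gt, n_components=st["pca_components"])
    pca_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    pca_df.insert(0, "sample", gt.samples)
    emit("genotype_pca", _write_csv(pca_df, outdir / "genotype_pca.csv", index=False))

    curve, kmeans_k, _ = structure.kmeans_elbow(
        scores[:, : min(10, scores.shape[1])],
        k_range=range(1, st["kmeans_k_max"] + 1),
        n_repeats=st["kmeans_repeats"], seed=seed,
    )
    emit("kmeans_curve", _write_csv(curve, outdir / "kmeans_curve.tsv", sep="\t", index=False))

    # -- stage 4: popgen --------------------------------------------------
    log.info("stage popgen")
    pg = cfg["popgen"]
    fst = popgen.wc_fst(gt, labels) if len(set(labels)) >= 2 else None
    if fst is not None:
        emit("fst", _write_csv(fst.pairwise, outdir / "fst_pairwise.tsv", sep="\t", index=False))
        intra = popgen.intrapop_f(gt, labels)
        emit("intrapop_f", _write_csv(intra, outdir / "intrapop_f.tsv", sep="\t", index=False))

    decay_rows = []
    for chrom in pd.unique(vt["chrom"]):
        try:
            pairs = popgen.ld_r2(gt, vt, chrom, pg["ld_max_dist_bp"])
            res = popgen.fit_ld_decay(pairs, gt.n_samples)
            decay_rows.append(
                {"chrom": chrom, "rho": res.rho, "d02_bp": res.d02,
                 "n_pairs": res.n_pairs, "at_bound": res.at_bound}
            )
        except (ValueError, RuntimeError) as exc:
            decay_rows.append({"chrom": chrom, "rho": np.nan, "d02_bp": np.nan,
                               "n_pairs": 0, "at_bound": True, "note": str(exc)})
    emit("ld_decay", _write_csv(pd.DataFrame(decay_rows), outdir / "ld_decay.tsv",
                                sep="\t", index=False))

    nei = popgen.nei_distance(gt)
    fam, mothers = popgen.family_mean_distance(
        nei, gt.samples, dict(zip(meta["sample"], meta["mother"]))
    )
    geo, geo_mothers = popgen.geo_distance(meta)
    assert mothers == geo_mothers
    rho, pval = popgen.mantel_test(fam, geo, n_perm=pg["mantel_permutations"], seed=seed)
    mantel_df = pd.DataFrame([{"rho": rho, "p_value": pval,
                               "n_perm": pg["mantel_permutations"]}])
    emit("mantel", _write_csv(mantel_df, outdir / "mantel_ibd.tsv", sep="\t", index=False))

    # -- stage 5: load ----------------------------------------------------
    log.info("stage load")
    ann = annotation.merge(vt[["chrom", "pos"]], on=["chrom", "pos"], how="right")
    loads = loadmod.pdel(gt, ann["impact"])
    loads["group"] = labels
    emit("load", _write_csv(loads, outdir / "genetic_load.csv", index=False))
    try:
        comparison = loadmod.population_load(loads, labels)
        emit("load_tukey", _write_csv(comparison.tukey, outdir / "load_tukey.tsv",
                                      sep="\t", index=False))
    except ValueError as exc:
        log.warning("load comparison skipped: %s", exc)
        comparison = None

    # -- stage 6: climate -------------------------------------------------
    log.info("stage climate")
    indices = climod.index_table(meta, climate_df)
    emit("env_indices", _write_csv(indices, outdir / "env_indices.csv"))
    kept, dropped = climod.screen_correlations(indices)
    pca_env = climod.env_pca(kept)
    emit("env_pca_scores", _write_csv(pca_env.scores, outdir / "env_pca_scores.csv"))
    emit("env_pca_loadings", _write_csv(pca_env.loadings, outdir / "env_pca_loadings.csv"))

    # -- stage 7: GEA ------------------------------------------------------
    log.info("stage gea")
    gt_imp = variants.impute_major(gt)
    gt_imp, vt_imp, n_refiltered = variants.refilter_maf(gt_imp, vt)
    ann_imp = annotation.merge(vt_imp[["chrom", "pos"]], on=["chrom", "pos"], how="right")
    covar = fit.Q[:, :-1] if fit.K >= 2 else None  # K-1 membership columns

    site_of_sample = meta.set_index("sample")["site"]
    traits = {"elevation": meta.set_index("sample")["elevation"].loc[gt.samples].to_numpy()}
    for pc in pca_env.scores.columns:
        traits[pc.lower()] = (
            pca_env.scores[pc].loc[site_of_sample.loc[gt.samples]].to_numpy()
        )

    gcfg = geamod.GEAConfig(seed=seed, **cfg["gea"])
    all_hits = []
    for name, y in traits.items():
        scan = geamod.iterate_scan(gt_imp, y, covar, gcfg, trait_name=name)
        res = scan.summary(vt_imp)
        emit(f"gea_{name}", _write_csv(res, outdir / f"gea_{name}.tsv", sep="\t", index=False))
        all_hits.append(geamod.annotate_hits(scan, vt_imp, ann_imp))
    hits = pd.concat(all_hits, ignore_index=True)
    emit("gea_hits", _write_csv(hits, outdir / "gea_hits.tsv", sep="\t", index=False))

    manifest["summary"] = {
        "n_samples_retained": gt.n_samples,
        "n_snps_retained": gt.n_sites,
        "n_snps_gea": gt_imp.n_sites,
        "n_refiltered_maf": int(n_refiltered),
        "evanno_best_k": int(best_k),
        "kmeans_elbow_k": int(kmeans_k),
        "group_sizes": pd.Series(labels).value_counts().to_dict(),
        "fst_between": None if fst is None else fst.pairwise["fst"].tolist(),
        "mantel_rho": rho,
        "mantel_p": pval,
        "load_any_significant": None if comparison is None else comparison.any_significant(),
        "n_gea_hits": int(len(hits)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
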