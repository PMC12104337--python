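"""End-to-end orchestration: simulate/load -> normalize -> cluster -> compare.

A single validated config drives every stage. The master seed fans out to
per-stage seeds through a fixed spawn order (synthetic, tau clustering,
atrophy clustering, stability, compare, longitudinal), so any stage can be
reproduced in isolation. Every table is written as TSV and summarized in
``report.json`` together with a provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (ClusteringConfig, consensus_cluster, default_gamma_grid,
                      gamma_search, similarity_matrix)
from .compare import allocation_overlap, cluster_roi_profile, crossmodal_spearman, most_least_maps
from .io import load_dataset, write_dataset, write_matrix, write_partition
from .longitudinal import compare_slopes, slope_zscores, subject_slopes
from .normalization import fit_reference, parcel_means, vertex_zscores
from .stability import StabilityConfig, loo_stability
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger("adsubtype")

__all__ = ["validate_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "adsubtype_out",
    "log_level": "INFO",
    "synthetic": {},          # CohortSpec overrides; ignored when inputs given
    "inputs": None,           # {"dir": path} to load an existing bundle
    "clustering": {
        "tau": {"gamma": None, "target_k": 4},
        "atrophy": {"gamma": None, "target_k": 4},
        "n_iterations": 100,
        "coassignment_threshold": 0.5,
        "negative_weight_policy": "clip_zero",
        "grid_start": 0.8,
        "grid_stop": 1.6,
        "grid_step": 0.1,
    },
    "stability": {"enabled": False, "removal_sizes": [1, 2, 3, 4, 5],
                  "reps_per_size": 10, "n_iterations": 100},
    "compare": {"enabled": True, "contrasts": False, "n_perm": 300,
                "alpha": 0.05},
    "longitudinal": {"enabled": True, "model": "per_subject_ols",
                     "alpha": 0.05},
}

_MODALITY_KEYS = {"gamma", "target_k"}


_OPAQUE_KEYS = {"synthetic", "inputs"}  # validated by CohortSpec / load_dataset


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user and path == "" and key in _OPAQUE_KEYS:
            out[key] = user[key]
        elif key in user and isinstance(dval, dict) and isinstance(user[key], dict):
            out[key] = _merge(dval, user[key], f"{path}{key}.")
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): "
                         f"{', '.join(path + k for k in sorted(unknown))}")
    return out


def validate_config(user_config: dict | None) -> dict:
    """Merge with defaults, rejecting unknown keys; cheap sanity checks."""
    cfg = _merge(DEFAULT_CONFIG, user_config or {})
    for modality in ("tau", "atrophy"):
        mc = cfg["clustering"][modality]
        if mc["gamma"] is not None and mc["gamma"] <= 0:
            raise ValueError(f"clustering.{modality}.gamma must be > 0")
        if mc["gamma"] is None and mc["target_k"] is None:
            raise ValueError(f"clustering.{modality}: set gamma or target_k")
    if cfg["clustering"]["n_iterations"] < 1:
        raise ValueError("clustering.n_iterations must be >= 1")
    if cfg["synthetic"]:
        CohortSpec(**{**cfg["synthetic"], "seed": 0})  # field validation
    return cfg


def _stage_seeds(master_seed: int) -> dict[str, int]:
    names = ["synthetic", "cluster_tau", "cluster_atrophy", "stability",
             "compare", "longitudinal"]
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def _cluster_modality(z: pd.DataFrame, modality: str, cfg: dict, seed: int):
    cc = cfg["clustering"]
    S = similarity_matrix(z.to_numpy())
    base = ClusteringConfig(
        gamma=1.0, n_iterations=cc["n_iterations"],
        coassignment_threshold=cc["coassignment_threshold"],
        negative_weight_policy=cc["negative_weight_policy"], seed=seed)
    mc = cc[modality]
    if mc["gamma"] is not None:
        config = ClusteringConfig(
            gamma=mc["gamma"], n_iterations=cc["n_iterations"],
            coassignment_threshold=cc["coassignment_threshold"],
            negative_weight_policy=cc["negative_weight_policy"], seed=seed)
        part = consensus_cluster(S, config)
        gamma = mc["gamma"]
    else:
        grid = default_gamma_grid(cc["grid_start"], cc["grid_stop"],
                                  cc["grid_step"])
        gamma, part = gamma_search(S, mc["target_k"], grid, base)
    log.info("%s clustering: gamma=%.4g k=%d rounds=%d",
             modality, gamma, part.n_clusters, part.rounds)
    return S, gamma, part


def run_pipeline(user_config: dict | None = None) -> dict:
    """Run every enabled stage in order and write the report bundle."""
    cfg = validate_config(user_config)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(),
                                      logging.INFO))
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    report: dict = {"stages": {}}

    # ---- stage: dataset -------------------------------------------------
    try:
        if cfg["inputs"]:
            ds = load_dataset(cfg["inputs"]["dir"])
            log.info("loaded dataset from %s", cfg["inputs"]["dir"])
        else:
            spec = CohortSpec(**{**cfg["synthetic"], "seed": seeds["synthetic"]})
            ds = generate_cohort(spec)
            write_dataset(ds, outdir / "dataset")
            log.info("generated synthetic cohort: %d HC / %d ADS, %d vertices",
                     spec.n_hc, spec.n_ads, spec.total_vertices)
        report["stages"]["dataset"] = {
            "n_hc": int((ds.metadata["group"] == "HC").sum()),
            "n_ads": int((ds.metadata["group"] == "ADS").sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"[stage: dataset] {exc}") from exc

    # ---- stage: normalization ------------------------------------------
    try:
        hc_ids, ads_ids = ds.hc_ids, ds.ads_ids
        z = {}
        for modality, mat in (("tau", ds.tau), ("atrophy", ds.thickness)):
            ref = fit_reference(mat.loc[hc_ids])
            z[modality] = vertex_zscores(mat.loc[ads_ids], ref)
            write_matrix(z[modality], outdir / f"z_{modality}.tsv")
        z_roi = {m: parcel_means(z[m], ds.parcels) for m in z}
        report["stages"]["normalization"] = {
            "n_features": {m: int(z[m].shape[1]) for m in z}}
    except Exception as exc:
        raise RuntimeError(f"[stage: normalization] {exc}") from exc

    # ---- stage: clustering ---------------------------------------------
    partitions = {}
    gammas = {}
    try:
        for modality in ("tau", "atrophy"):
            S, gamma, part = _cluster_modality(
                z[modality], modality, cfg, seeds[f"cluster_{modality}"])
            partitions[modality] = part
            gammas[modality] = gamma
            ids = list(z[modality].index)
            write_partition(part.labels, ids, outdir / f"partition_{modality}.tsv")
            write_matrix(pd.DataFrame(part.coassignment, index=ids, columns=ids),
                         outdir / f"coassignment_{modality}.tsv")
        report["stages"]["clustering"] = {
            m: {"gamma": gammas[m], "k": partitions[m].n_clusters,
                "rounds": partitions[m].rounds,
                "cluster_sizes": np.bincount(partitions[m].labels)[1:].tolist()}
            for m in partitions}
    except Exception as exc:
        raise RuntimeError(f"[stage: clustering] {exc}") from exc

    # ---- stage: stability ----------------------------------------------
    if cfg["stability"]["enabled"]:
        try:
            sc = cfg["stability"]
            stab_cfg = StabilityConfig(removal_sizes=sc["removal_sizes"],
                                       reps_per_size=sc["reps_per_size"],
                                       master_seed=seeds["stability"])
            stab_results = {}
            for modality in ("tau", "atrophy"):
                cluster_cfg = ClusteringConfig(
                    gamma=gammas[modality], n_iterations=sc["n_iterations"],
                    seed=seeds["stability"])
                rep = loo_stability(z[modality].to_numpy(), gammas[modality],
                                    stab_cfg, cluster_cfg,
                                    cip=partitions[modality])
                rep.records.to_csv(outdir / f"stability_{modality}.tsv",
                                   sep="\t", index=False)
                stab_results[modality] = {
                    "median_ri_by_size": {int(k): float(v) for k, v
                                          in rep.medians.items()},
                    "overall_median_ri": rep.overall_median}
            report["stages"]["stability"] = stab_results
        except Exception as exc:
            raise RuntimeError(f"[stage: stability] {exc}") from exc

    # ---- stage: cross-modal comparison ---------------------------------
    if cfg["compare"]["enabled"]:
        try:
            alloc = allocation_overlap(partitions["tau"].labels,
                                       partitions["atrophy"].labels)
            alloc.counts.to_csv(outdir / "allocation.tsv", sep="\t")
            profiles = {m: cluster_roi_profile(z_roi[m], partitions[m].labels)
                        for m in ("tau", "atrophy")}
            xm = crossmodal_spearman(profiles["tau"], profiles["atrophy"])
            xm.rho.to_csv(outdir / "crossmodal_rho.tsv", sep="\t")
            report["stages"]["compare"] = {
                "allocation_chi2": alloc.chi2, "allocation_df": alloc.df,
                "allocation_p": alloc.p_value,
                "matched_rho": [float(xm.rho.loc[c, c]) for c in xm.rho.index
                                if c in xm.rho.columns]}
            if cfg["compare"]["contrasts"]:
                maps = most_least_maps(
                    z["tau"], partitions["tau"].labels,
                    n_perm=cfg["compare"]["n_perm"],
                    alpha=cfg["compare"]["alpha"], seed=seeds["compare"])
                summary = {int(c): {"n_most": int(m["most"].mask.sum()),
                                    "n_least": int(m["least"].mask.sum())}
                           for c, m in maps.items()}
                report["stages"]["compare"]["tau_contrasts"] = summary
        except Exception as exc:
            raise RuntimeError(f"[stage: compare] {exc}") from exc

    # ---- stage: longitudinal -------------------------------------------
    if cfg["longitudinal"]["enabled"] and ds.visits is not None:
        try:
            lcfg = cfg["longitudinal"]
            tau_cols = [c for c in ds.visits.columns if c.startswith("tau_")]
            slopes = subject_slopes(ds.visits, tau_cols, metadata=ds.metadata,
                                    model=lcfg["model"])
            hc_sl = slopes.loc[slopes.index.intersection(hc_ids)]
            ads_sl = slopes.loc[slopes.index.intersection(ads_ids)]
            change_z = slope_zscores(ads_sl, hc_sl)
            change_z.to_csv(outdir / "change_z.tsv", sep="\t")
            labels = pd.Series(partitions["tau"].labels,
                               index=z["tau"].index).loc[change_z.index]
            overall, pairwise = compare_slopes(change_z, labels,
                                               alpha=lcfg["alpha"])
            overall.to_csv(outdir / "kw_results.tsv", sep="\t", index=False)
            pairwise.to_csv(outdir / "kw_pairwise.tsv", sep="\t", index=False)
            report["stages"]["longitudinal"] = {
                "n_roi": int(len(overall)),
                "n_significant": int(overall["significant"].sum())}
        except Exception as exc:
            raise RuntimeError(f"[stage: longitudinal] {exc}") from exc

    # ---- provenance -----------------------------------------------------
    canon = json.dumps(cfg, sort_keys=True, default=str)
    report["provenance"] = {
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": cfg["seed"], "stage_seeds": seeds,
        "package_version": __version__, "numpy_version": np.__version__,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
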