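"""Annual change rates per ROI, HC-standardized, compared across clusters.

Subject-level slopes come either from a linear mixed model per ROI (random
intercept and slope per subject, optional fixed covariates) or from a
transparent per-subject OLS fallback. Slopes are z-scored against the HC
slope distribution and compared across clusters with Kruskal-Wallis tests,
FDR-corrected over the ROI family, with Bonferroni-corrected pairwise
follow-ups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "transform_scores",
    "subject_slopes",
    "slope_zscores",
    "compare_slopes",
]


def transform_scores(score, kind: str):
    """Variance-stabilizing transforms for clinical scores.

    ``kind="mmse"``: log10 (scores must be > 0); ``kind="cdr_sob"``: square
    root (scores must be >= 0).
    """
    arr = np.asarray(score, dtype=float)
    if kind == "mmse":
        if np.any(arr <= 0):
            raise ValueError("MMSE must be > 0 for the log transform")
        out = np.log10(arr)
    elif kind == "cdr_sob":
        if np.any(arr < 0):
            raise ValueError("CDR-SoB must be >= 0 for the sqrt transform")
        out = np.sqrt(arr)
    else:
        raise ValueError(f"unknown score kind {kind!r}")
    return out if np.ndim(score) else float(out)


def _ols_slopes(visits: pd.DataFrame, roi_cols: list[str]) -> pd.DataFrame:
    rows = {}
    for sid, grp in visits.groupby("subject_id", sort=False):
        t = grp["time_years"].to_numpy(dtype=float)
        if len(t) < 2 or np.ptp(t) == 0:
            continue
        tc = t - t.mean()
        denom = (tc ** 2).sum()
        Y = grp[roi_cols].to_numpy(dtype=float)
        rows[sid] = tc @ (Y - Y.mean(axis=0)) / denom
    return pd.DataFrame.from_dict(rows, orient="index", columns=roi_cols)


def _mixed_slopes(visits: pd.DataFrame, roi_cols: list[str],
                  metadata: pd.DataFrame | None,
                  covariates: tuple[str, ...]) -> pd.DataFrame:
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = visits.copy()
    if covariates:
        if metadata is None:
            raise ValueError("covariate adjustment requires a metadata table")
        df = df.join(metadata[list(covariates)], on="subject_id")
        df = pd.get_dummies(df, columns=[c for c in covariates
                                         if df[c].dtype == object],
                            drop_first=True, dtype=float)
    cov_cols = [c for c in df.columns
                if any(c == cv or c.startswith(f"{cv}_") for cv in covariates)]
    counts = df.groupby("subject_id")["time_years"].nunique()
    keep = counts.index[counts >= 2]
    df = df[df["subject_id"].isin(keep)]
    exog_cols = ["time_years"] + cov_cols
    exog = np.column_stack([np.ones(len(df))] +
                           [df[c].to_numpy(dtype=float) for c in exog_cols])
    exog_re = np.column_stack([np.ones(len(df)),
                               df["time_years"].to_numpy(dtype=float)])
    groups = df["subject_id"].to_numpy()
    out = {}
    subject_order = pd.unique(groups)
    for roi in roi_cols:
        model = MixedLM(df[roi].to_numpy(dtype=float), exog, groups,
                        exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        fe_slope = res.fe_params[1]
        re = res.random_effects
        out[roi] = {sid: fe_slope + re[sid].iloc[1] for sid in subject_order}
    slopes = pd.DataFrame(out)
    slopes.index.name = "subject_id"
    return slopes.loc[subject_order]


def subject_slopes(visits: pd.DataFrame, roi_cols: list[str] | None = None,
                   metadata: pd.DataFrame | None = None,
                   covariates: tuple[str, ...] = (),
                   model: str = "per_subject_ols") -> pd.DataFrame:
    """Per-subject annual change per ROI.

    ``visits`` is long-format with ``subject_id``, ``time_years`` and one
    column per ROI measurement. Subjects with fewer than two distinct visit
    times are excluded (and logged). ``model`` is ``per_subject_ols`` or
    ``mixed`` (random intercept + slope; subject slope = fixed + BLUP).
    """
    for col in ("subject_id", "time_years"):
        if col not in visits.columns:
            raise KeyError(f"visit table is missing column {col!r}")
    if roi_cols is None:
        roi_cols = [c for c in visits.columns
                    if c not in ("subject_id", "visit", "time_years")]
    n_visits = visits.groupby("subject_id")["time_years"].nunique()
    dropped = n_visits.index[n_visits < 2]
    if len(dropped):
        warnings.warn(f"{len(dropped)} subject(s) with a single visit excluded")
    if len(dropped) == len(n_visits):
        raise ValueError("all subjects have a single visit; no slopes estimable")
    if model == "per_subject_ols":
        return _ols_slopes(visits, roi_cols)
    if model == "mixed":
        return _mixed_slopes(visits, roi_cols, metadata, covariates)
    raise ValueError(f"unknown slope model {model!r}")


def slope_zscores(ads_slopes: pd.DataFrame, hc_slopes: pd.DataFrame,
                  ddof: int = 1) -> pd.DataFrame:
    """Standardize patient slopes against the HC slope distribution per ROI."""
    shared = ads_slopes.columns.intersection(hc_slopes.columns)
    if len(shared) == 0:
        raise ValueError("no shared ROI columns between the slope tables")
    mu = hc_slopes[shared].mean()
    sd = hc_slopes[shared].std(ddof=ddof)
    bad = sd.index[sd < 1e-12]
    if len(bad):
        warnings.warn(f"{len(bad)} ROI(s) with ~zero HC slope SD excluded: "
                      f"{list(bad)[:5]}")
        shared = shared.difference(bad)
    return (ads_slopes[shared] - mu[shared]) / sd[shared]


def compare_slopes(change_z: pd.DataFrame, partition, alpha: float = 0.05
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis comparison of HC-standardized change rates across clusters.

    Returns (overall table, pairwise table). Overall p-values are
    Benjamini-Hochberg adjusted over the ROI family; within ROIs that pass
    FDR at ``alpha``, pairwise Mann-Whitney tests are Bonferroni-corrected
    over the cluster pairs.
    """
    labels = pd.Series(np.asarray(partition), index=change_z.index)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters to compare")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("every cluster needs >= 2 subjects")
    rows = []
    for roi in change_z.columns:
        samples = [change_z.loc[labels == g, roi].to_numpy() for g in groups]
        h, p = stats.kruskal(*samples)
        rows.append({"roi": roi, "H": h, "p": p})
    overall = pd.DataFrame(rows)
    overall["p_fdr"] = multipletests(overall["p"], method="fdr_bh")[1]
    overall["significant"] = overall["p_fdr"] < alpha

    pair_rows = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for roi in overall.loc[overall["significant"], "roi"]:
        for i, gi in enumerate(groups):
            for gj in groups[i + 1:]:
                a = change_z.loc[labels == gi, roi]
                b = change_z.loc[labels == gj, roi]
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                pair_rows.append({
                    "roi": roi, "cluster_a": gi, "cluster_b": gj,
                    "p_bonferroni": min(1.0, p * n_pairs),
                    "median_diff": float(a.median() - b.median()),
                })
    pairwise = pd.DataFrame(
        pair_rows, columns=["roi", "cluster_a", "cluster_b",
                            "p_bonferroni", "median_diff"])
    return overall, pairwise
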