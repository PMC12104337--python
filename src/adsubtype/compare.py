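"""Cross-modal cluster comparison and permutation-based contrast maps.

Covers: tau-vs-atrophy cluster allocation (chi-square contingency), Spearman
correlation of cluster ROI profiles across modalities (volume/thickness
profiles sign-flipped so that larger = more abnormal in both modalities),
cluster-vs-rest contrast maps with max-statistic permutation FWE control, and
vertex-wise tau-thickness association maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllocationTable",
    "CrossModalResult",
    "ContrastMap",
    "allocation_overlap",
    "cluster_roi_profile",
    "crossmodal_spearman",
    "contrast_map",
    "most_least_maps",
    "vertexwise_correlation",
]


@dataclass
class AllocationTable:
    counts: pd.DataFrame            # tau cluster x atrophy cluster
    chi2: float
    df: int
    p_value: float
    row_fractions: pd.DataFrame     # share of each tau cluster per atrophy cluster


@dataclass
class CrossModalResult:
    rho: pd.DataFrame               # tau cluster x atrophy cluster Spearman rho
    p_bonferroni: pd.DataFrame      # adjusted over all cells
    n_roi: int


@dataclass
class ContrastMap:
    t_stat: np.ndarray
    p_fwe: np.ndarray
    mask: np.ndarray                # corrected p < alpha
    descriptor: str
    alpha: float
    feature_names: list | None = None


def allocation_overlap(p_tau, p_atrophy) -> AllocationTable:
    """Contingency of tau vs atrophy cluster membership with a chi-square test."""
    p_tau = pd.Series(np.asarray(p_tau))
    p_atr = pd.Series(np.asarray(p_atrophy))
    if len(p_tau) != len(p_atr):
        raise ValueError("partitions must cover the same subjects")
    counts = pd.crosstab(p_tau, p_atr)
    counts.index.name = "tau_cluster"
    counts.columns.name = "atrophy_cluster"
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table ({counts.shape[0]}x{counts.shape[1]}); "
            "both partitions need >= 2 clusters")
    obs = counts.to_numpy()
    expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
    if (expected < 5).any():
        warnings.warn("expected counts < 5 in some cells; chi-square "
                      "approximation may be inaccurate")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return AllocationTable(counts=counts, chi2=float(chi2), df=int(df),
                           p_value=float(p), row_fractions=fractions)


def cluster_roi_profile(z_roi: pd.DataFrame, partition) -> pd.DataFrame:
    """Per-cluster unweighted mean z per ROI (rows: clusters, columns: ROIs)."""
    labels = pd.Series(np.asarray(partition), index=z_roi.index)
    if labels.isna().any():
        raise ValueError("partition must cover all rows")
    profiles = z_roi.groupby(labels).mean()
    if (z_roi.groupby(labels).size() == 0).any():
        raise ValueError("empty cluster in partition")
    profiles.index.name = "cluster"
    return profiles


def crossmodal_spearman(tau_profiles: pd.DataFrame,
                        atrophy_profiles: pd.DataFrame,
                        flip_atrophy_sign: bool = True) -> CrossModalResult:
    """Spearman rho between every tau-cluster and atrophy-cluster ROI profile.

    Atrophy (volume/thickness) profiles are multiplied by -1 before ranking so
    that larger values mean more abnormality in both modalities. P-values are
    Bonferroni-adjusted over all cluster pairs.
    """
    shared = tau_profiles.columns.intersection(atrophy_profiles.columns)
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared ROIs; need >= 5 for a "
                         "stable rank correlation")
    tp = tau_profiles[shared]
    ap = atrophy_profiles[shared]
    if flip_atrophy_sign:
        ap = -ap
    n_tests = len(tp.index) * len(ap.index)
    rho = pd.DataFrame(index=tp.index, columns=ap.index, dtype=float)
    padj = pd.DataFrame(index=tp.index, columns=ap.index, dtype=float)
    for i in tp.index:
        for j in ap.index:
            r, p = stats.spearmanr(tp.loc[i], ap.loc[j])
            rho.loc[i, j] = r
            padj.loc[i, j] = min(1.0, p * n_tests)
    rho.index.name = padj.index.name = "tau_cluster"
    rho.columns.name = padj.columns.name = "atrophy_cluster"
    return CrossModalResult(rho=rho, p_bonferroni=padj, n_roi=len(shared))


def _t_stats(X: np.ndarray, group_a: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t per feature; group_a is a boolean mask."""
    a = X[group_a]
    b = X[~group_a]
    na, nb = len(a), len(b)
    ma, mb = a.mean(0), b.mean(0)
    va = a.var(0, ddof=1)
    vb = b.var(0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def _max_t_null(X: np.ndarray, na: int, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """Max-|t| permutation null via batched group-sum matrix products."""
    n, _ = X.shape
    nb = n - na
    # boolean membership matrix: row p marks the permuted group A
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    P = np.zeros((n_perm, n))
    np.put_along_axis(P, order[:, :na], 1.0, axis=1)
    X2 = X ** 2
    tot = X.sum(0)
    tot2 = X2.sum(0)
    sum_a = P @ X
    sumsq_a = P @ X2
    sum_b = tot - sum_a
    sumsq_b = tot2 - sumsq_a
    ma, mb = sum_a / na, sum_b / nb
    va = (sumsq_a - na * ma ** 2) / (na - 1)
    vb = (sumsq_b - nb * mb ** 2) / (nb - 1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(np.maximum(sp, 0.0) * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return np.abs(t).max(axis=1)


def contrast_map(z, group_a_idx, group_b_idx, n_perm: int = 1000,
                 alpha: float = 0.05, seed: int = 0,
                 descriptor: str = "A_vs_B") -> ContrastMap:
    """Two-sample contrast with family-wise error control by max-|t| permutation.

    The null distribution is the maximum absolute t over features under random
    relabeling of group membership; corrected p-values are exact under
    exchangeability and need no mesh geometry.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable FWE resolution")
    feature_names = list(z.columns) if isinstance(z, pd.DataFrame) else None
    if isinstance(z, pd.DataFrame):
        ia = z.index.get_indexer(group_a_idx)
        ib = z.index.get_indexer(group_b_idx)
        if (ia < 0).any() or (ib < 0).any():
            raise KeyError("group ids missing from the z matrix")
        X = z.to_numpy(dtype=float)
    else:
        X = np.asarray(z, dtype=float)
        ia = np.asarray(group_a_idx)
        ib = np.asarray(group_b_idx)
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs >= 2 subjects")
    sel = np.concatenate([ia, ib])
    Xs = X[sel]
    mask_a = np.zeros(len(sel), dtype=bool)
    mask_a[:len(ia)] = True
    t_obs = _t_stats(Xs, mask_a)

    rng = np.random.default_rng(seed)
    max_null = _max_t_null(Xs, len(ia), n_perm, rng)
    p_fwe = (1.0 + (max_null[None, :] >= np.abs(t_obs)[:, None]).sum(1)) / (n_perm + 1)
    return ContrastMap(t_stat=t_obs, p_fwe=p_fwe, mask=p_fwe < alpha,
                       descriptor=descriptor, alpha=alpha,
                       feature_names=feature_names)


def most_least_maps(z: pd.DataFrame, partition, n_perm: int = 1000,
                    alpha: float = 0.05, seed: int = 0
                    ) -> dict[int, dict[str, ContrastMap]]:
    """Cluster-vs-rest contrasts in both directions for every cluster.

    Returns {cluster: {"most": map, "least": map}} where "most" flags features
    where the cluster exceeds the remaining subjects and "least" the reverse.
    Singleton clusters are skipped with a warning.
    """
    labels = pd.Series(np.asarray(partition), index=z.index)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        warnings.warn("partition has a single cluster; no contrasts computed")
        return {}
    out: dict[int, dict[str, ContrastMap]] = {}
    for ci, c in enumerate(clusters):
        in_c = labels.index[labels == c]
        rest = labels.index[labels != c]
        if len(in_c) < 2:
            warnings.warn(f"cluster {c} has < 2 subjects; skipped")
            continue
        cm = contrast_map(z, in_c, rest, n_perm=n_perm, alpha=alpha,
                          seed=seed + ci, descriptor=f"cluster{c}_vs_rest")
        most = ContrastMap(t_stat=cm.t_stat, p_fwe=cm.p_fwe,
                           mask=cm.mask & (cm.t_stat > 0),
                           descriptor=f"cluster{c}_most", alpha=alpha,
                           feature_names=cm.feature_names)
        least = ContrastMap(t_stat=cm.t_stat, p_fwe=cm.p_fwe,
                            mask=cm.mask & (cm.t_stat < 0),
                            descriptor=f"cluster{c}_least", alpha=alpha,
                            feature_names=cm.feature_names)
        out[c] = {"most": most, "least": least}
    return out


def vertexwise_correlation(z_tau, z_thickness, subjects=None,
                           n_perm: int = 1000, alpha: float = 0.05,
                           seed: int = 0) -> ContrastMap:
    """Per-feature correlation of tau vs thickness z across subjects, FWE-corrected.

    The null shuffles subject rows of one modality; corrected p-values come
    from the max-|r| distribution. Constant feature columns are excluded and
    reported through a warning.
    """
    if isinstance(z_tau, pd.DataFrame) and isinstance(z_thickness, pd.DataFrame):
        if subjects is not None:
            z_tau = z_tau.loc[subjects]
            z_thickness = z_thickness.loc[subjects]
        shared = z_tau.columns.intersection(z_thickness.columns)
        names = list(shared)
        A = z_tau[shared].to_numpy(dtype=float)
        B = z_thickness[shared].to_numpy(dtype=float)
    else:
        A = np.asarray(z_tau, dtype=float)
        B = np.asarray(z_thickness, dtype=float)
        if subjects is not None:
            A, B = A[subjects], B[subjects]
        names = None
    if A.shape != B.shape:
        raise ValueError("matrices must cover the same subjects and features")
    if A.shape[0] < 5:
        raise ValueError("need >= 5 subjects")
    keep = (A.std(0) > 0) & (B.std(0) > 0)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant feature column(s) excluded")
        A, B = A[:, keep], B[:, keep]
        names = [n for n, k in zip(names, keep) if k] if names else None

    Az = (A - A.mean(0)) / A.std(0)
    Bz = (B - B.mean(0)) / B.std(0)
    n = A.shape[0]
    r_obs = (Az * Bz).sum(0) / n
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n)
        max_null[p] = np.abs((Az[perm] * Bz).sum(0) / n).max()
    p_fwe = (1.0 + (max_null[None, :] >= np.abs(r_obs)[:, None]).sum(1)) / (n_perm + 1)
    return ContrastMap(t_stat=r_obs, p_fwe=p_fwe, mask=p_fwe < alpha,
                       descriptor="tau_thickness_correlation", alpha=alpha,
                       feature_names=names)
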