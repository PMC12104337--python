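"""Synthetic two-modality cohorts with planted cluster structure.

Generates a control group and a patient group on a shared vertex grid. Each
patient cluster has a spatial abnormality pattern: a contiguous 0/1 core mask
plus a low-amplitude parcel-level gradient field, shared between modalities
unless ``independent_patterns`` is set. Tau values shift upward and thickness
values downward at pattern vertices, in units of the control SD. Ground-truth
labels, covariates and longitudinal visits with cluster-specific annual slopes
are included so every downstream stage can be tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .normalization import DK_REGIONS

__all__ = ["CohortSpec", "SyntheticDataset", "build_patterns",
           "generate_cohort", "generate_visits"]

#: fraction of the vertex grid jointly occupied by the pattern cores
_PATTERN_BUDGET = 0.4


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; same spec + seed => identical dataset."""

    n_hc: int = 154
    n_ads: int = 166
    cluster_sizes: Sequence[int] = (57, 53, 36, 20)
    n_vertices: int = 1000          # per hemisphere
    n_parcels: int = 34             # per hemisphere
    pattern_overlap: float = 0.0
    effect_size: float = 3.0        # abnormality shift in HC-SD units
    noise_sd: float = 1.0
    gradient_amp: float = 0.25      # amplitude of the parcel-level gradient field
    crossmodal_discordance: float = 0.0
    independent_patterns: bool = False
    n_visits: int = 3
    visit_spacing_years: float = 0.925
    visit_noise_sd: float = 0.05
    slope_by_cluster: Sequence[float] = (0.1, 0.2, 0.3, 0.4)  # z per year
    tau_baseline: float = 1.2       # SUVr-like
    thickness_baseline: float = 2.5  # mm-like
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        self.slope_by_cluster = tuple(float(s) for s in self.slope_by_cluster)
        if self.n_hc < 1 or self.n_ads < 1:
            raise ValueError("group sizes must be positive")
        if sum(self.cluster_sizes) != self.n_ads:
            raise ValueError(
                f"cluster_sizes sum to {sum(self.cluster_sizes)}, "
                f"expected n_ads={self.n_ads}")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if self.n_vertices < 1 or self.n_parcels < 1:
            raise ValueError("n_vertices and n_parcels must be positive")
        for name in ("pattern_overlap", "crossmodal_discordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if self.visit_spacing_years <= 0:
            raise ValueError("visit_spacing_years must be positive")
        if len(self.slope_by_cluster) != len(self.cluster_sizes):
            raise ValueError("slope_by_cluster must match cluster_sizes in length")

    @property
    def k(self) -> int:
        return len(self.cluster_sizes)

    @property
    def total_vertices(self) -> int:
        return 2 * self.n_vertices

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cluster_sizes"] = list(self.cluster_sizes)
        d["slope_by_cluster"] = list(self.slope_by_cluster)
        return d


@dataclass
class SyntheticDataset:
    """Generated cohort with ground truth.

    Matrices are row-aligned with ``metadata``; ``truth`` covers ADS rows only.
    """

    metadata: pd.DataFrame
    tau: pd.DataFrame
    thickness: pd.DataFrame
    parcels: pd.Series
    truth: pd.DataFrame
    spec: CohortSpec | None = None
    visits: pd.DataFrame | None = None
    tau_masks: np.ndarray | None = None      # k x vertices planted core masks
    atrophy_masks: np.ndarray | None = None

    @property
    def hc_ids(self) -> pd.Index:
        return self.metadata.index[self.metadata["group"] == "HC"]

    @property
    def ads_ids(self) -> pd.Index:
        return self.metadata.index[self.metadata["group"] == "ADS"]


def build_patterns(k: int, n_vertices: int, pattern_overlap: float = 0.0,
                   seed: int = 0) -> np.ndarray:
    """k contiguous 0/1 vertex masks with bounded pairwise Jaccard overlap.

    Blocks of equal length are laid out along the vertex index with a random
    global offset; adjacent blocks share a segment sized so their Jaccard
    overlap is ~``pattern_overlap``. Each mask covers at least 5% of vertices.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_vertices:
        raise ValueError(f"k={k} exceeds n_vertices={n_vertices}")
    if not 0.0 <= pattern_overlap <= 1.0:
        raise ValueError("pattern_overlap must lie in [0, 1]")
    # shared segment fraction of block length giving Jaccard == pattern_overlap
    sfrac = 2.0 * pattern_overlap / (1.0 + pattern_overlap)
    denom = k - (k - 1) * sfrac
    L = int(np.floor(_PATTERN_BUDGET * n_vertices / denom))
    L = max(L, int(np.ceil(0.05 * n_vertices)), 1)
    shared = int(round(L * sfrac))
    span = k * L - (k - 1) * shared
    if span > n_vertices:
        raise ValueError(
            f"cannot fit {k} patterns of length {L} into {n_vertices} vertices")
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, n_vertices - span + 1))
    masks = np.zeros((k, n_vertices), dtype=np.int8)
    for c in range(k):
        start = offset + c * (L - shared)
        masks[c, start:start + L] = 1
    rng.shuffle(masks)  # random block-to-cluster assignment
    return masks


def _parcel_names(n_parcels: int) -> list[str]:
    names = []
    for hemi in ("lh", "rh"):
        for i in range(n_parcels):
            region = DK_REGIONS[i] if n_parcels == len(DK_REGIONS) else f"parcel{i:03d}"
            names.append(f"{hemi}_{region}")
    return names


def _parcel_lookup(spec: CohortSpec, vertex_names: list[str]) -> pd.Series:
    names = _parcel_names(spec.n_parcels)
    per_hemi = spec.n_vertices
    lookup = np.empty(spec.total_vertices, dtype=object)
    for hemi_idx in range(2):
        bounds = np.linspace(0, per_hemi, spec.n_parcels + 1).astype(int)
        for i in range(spec.n_parcels):
            lo = hemi_idx * per_hemi + bounds[i]
            hi = hemi_idx * per_hemi + bounds[i + 1]
            lookup[lo:hi] = names[hemi_idx * spec.n_parcels + i]
    return pd.Series(lookup, index=vertex_names, name="parcel")


def _gradient_field(masks: np.ndarray, lookup_codes: np.ndarray,
                    n_parcels_total: int, amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Cluster effect fields: core mask plus zero-mean parcel-level gradient."""
    k = masks.shape[0]
    g = rng.normal(size=(k, n_parcels_total))
    g -= g.mean(axis=1, keepdims=True)
    fields = masks.astype(float) + amp * g[:, lookup_codes]
    return fields


def generate_cohort(spec: CohortSpec) -> SyntheticDataset:
    """Generate the full cohort: metadata, both modality matrices, truth labels."""
    ss = np.random.SeedSequence(spec.seed)
    (s_pat_tau, s_pat_atr, s_grad_tau, s_grad_atr, s_labels,
     s_meta, s_tau, s_thk) = ss.spawn(8)

    V = spec.total_vertices
    vertex_names = [f"v{i:05d}" for i in range(V)]
    parcels = _parcel_lookup(spec, vertex_names)
    parcel_names = _parcel_names(spec.n_parcels)
    codes = np.array([parcel_names.index(p) for p in parcels.to_numpy()])

    masks_tau = build_patterns(spec.k, V, spec.pattern_overlap,
                               seed=int(s_pat_tau.generate_state(1)[0]))
    field_tau = _gradient_field(masks_tau, codes, len(parcel_names),
                                spec.gradient_amp,
                                np.random.default_rng(s_grad_tau))
    if spec.independent_patterns:
        masks_atr = build_patterns(spec.k, V, spec.pattern_overlap,
                                   seed=int(s_pat_atr.generate_state(1)[0]))
        field_atr = _gradient_field(masks_atr, codes, len(parcel_names),
                                    spec.gradient_amp,
                                    np.random.default_rng(s_grad_atr))
    else:
        masks_atr = masks_tau
        field_atr = field_tau

    # ground-truth labels (1-based)
    rng_lab = np.random.default_rng(s_labels)
    tau_labels = np.repeat(np.arange(1, spec.k + 1),
                           np.asarray(spec.cluster_sizes))
    rng_lab.shuffle(tau_labels)
    atr_labels = tau_labels.copy()
    flip = rng_lab.random(spec.n_ads) < spec.crossmodal_discordance
    for i in np.flatnonzero(flip):
        others = [c for c in range(1, spec.k + 1) if c != tau_labels[i]]
        atr_labels[i] = rng_lab.choice(others)

    n_total = spec.n_hc + spec.n_ads
    ids = [f"S{i:04d}" for i in range(1, n_total + 1)]
    hc_ids, ads_ids = ids[:spec.n_hc], ids[spec.n_hc:]

    # modality matrices
    rng_tau = np.random.default_rng(s_tau)
    rng_thk = np.random.default_rng(s_thk)
    shift = spec.effect_size * spec.noise_sd
    tau = np.empty((n_total, V))
    thk = np.empty((n_total, V))
    tau[:spec.n_hc] = spec.tau_baseline + rng_tau.normal(0, spec.noise_sd,
                                                         (spec.n_hc, V))
    thk[:spec.n_hc] = spec.thickness_baseline + rng_thk.normal(
        0, spec.noise_sd, (spec.n_hc, V))
    tau[spec.n_hc:] = (spec.tau_baseline + shift * field_tau[tau_labels - 1]
                       + rng_tau.normal(0, spec.noise_sd, (spec.n_ads, V)))
    thk[spec.n_hc:] = (spec.thickness_baseline - shift * field_atr[atr_labels - 1]
                       + rng_thk.normal(0, spec.noise_sd, (spec.n_ads, V)))

    # covariates: generated, but exerting no effect on the maps by default
    rng_meta = np.random.default_rng(s_meta)
    age = np.round(rng_meta.normal(74, 7, n_total), 1)
    sex = rng_meta.choice(["F", "M"], n_total)
    apoe4 = (rng_meta.random(n_total)
             < np.where(np.arange(n_total) < spec.n_hc, 0.2, 0.65)).astype(int)
    education = rng_meta.integers(12, 21, n_total)
    site = rng_meta.integers(1, 4, n_total)
    is_hc = np.arange(n_total) < spec.n_hc
    csf = np.where(is_hc, rng_meta.uniform(0.08, 0.12, n_total),
                   rng_meta.uniform(0.03, 0.07, n_total))
    suvr = np.where(is_hc, rng_meta.uniform(0.9, 1.08, n_total),
                    rng_meta.uniform(1.15, 1.6, n_total))
    diagnosis = np.where(is_hc, "CN",
                         rng_meta.choice(["MCI", "ADD"], n_total, p=[0.67, 0.33]))
    metadata = pd.DataFrame({
        "group": np.where(is_hc, "HC", "ADS"),
        "diagnosis": diagnosis,
        "age": age, "sex": sex, "apoe4": apoe4,
        "education": education, "site": site,
        "csf_ab_ratio": np.round(csf, 4),
        "tracer": "AV45",
        "amyloid_suvr": np.round(suvr, 3),
    }, index=pd.Index(ids, name="subject_id"))

    tau_df = pd.DataFrame(tau, index=metadata.index, columns=vertex_names)
    thk_df = pd.DataFrame(thk, index=metadata.index, columns=vertex_names)
    truth = pd.DataFrame({"tau_cluster": tau_labels,
                          "atrophy_cluster": atr_labels},
                         index=pd.Index(ads_ids, name="subject_id"))
    ds = SyntheticDataset(metadata=metadata, tau=tau_df, thickness=thk_df,
                          parcels=parcels, truth=truth, spec=spec,
                          tau_masks=masks_tau, atrophy_masks=masks_atr)
    ds.visits = generate_visits(ds, spec)
    return ds


def generate_visits(dataset: SyntheticDataset, spec: CohortSpec) -> pd.DataFrame:
    """Longitudinal per-ROI visit table with cluster-specific annual slopes.

    ROI trajectories are linear: baseline parcel mean + cluster slope x time
    (+ visit noise); tau increases, volume decreases; the HC slope is zero.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(9)[-1]
    rng = np.random.default_rng(ss)
    from .normalization import parcel_means  # avoids cycle at import time

    tau_roi = parcel_means(dataset.tau, dataset.parcels)
    vol_roi = parcel_means(dataset.thickness, dataset.parcels)
    roi_names = list(tau_roi.columns)
    slopes = np.zeros(len(dataset.metadata))
    ads_pos = dataset.metadata.index.get_indexer(dataset.truth.index)
    slopes[ads_pos] = np.asarray(spec.slope_by_cluster)[
        dataset.truth["tau_cluster"].to_numpy() - 1]

    times = np.arange(spec.n_visits) * spec.visit_spacing_years
    rows = []
    for si, sid in enumerate(dataset.metadata.index):
        for vi, t in enumerate(times):
            rec = {"subject_id": sid, "visit": vi, "time_years": t}
            drift = slopes[si] * spec.noise_sd * t
            noise_t = rng.normal(0, spec.visit_noise_sd, len(roi_names)) if vi else 0.0
            noise_v = rng.normal(0, spec.visit_noise_sd, len(roi_names)) if vi else 0.0
            tau_vals = tau_roi.iloc[si].to_numpy() + drift + noise_t
            vol_vals = vol_roi.iloc[si].to_numpy() - drift + noise_v
            for j, roi in enumerate(roi_names):
                rec[f"tau_{roi}"] = tau_vals[j]
                rec[f"vol_{roi}"] = vol_vals[j]
            rows.append(rec)
    return pd.DataFrame(rows)
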