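"""Control-referenced z-scores, cohort filters and biomarker transforms.

Vertex- or ROI-level maps of patients are standardized against the healthy
control (HC) distribution: z = (x - mean_HC) / SD_HC per feature. Amyloid and
tau positivity, centiloid conversion, the temporal meta-ROI composite and the
cortex-to-hippocampus volume ratio live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DK_REGIONS",
    "META_ROI_REGIONS",
    "ReferenceStats",
    "BiomarkerThresholds",
    "TracerCalibration",
    "fit_reference",
    "vertex_zscores",
    "parcel_means",
    "meta_roi_suvr",
    "classify_amyloid",
    "classify_tau",
    "filter_cohort",
    "centiloid",
    "ctv_hv",
]

#: the 34 Desikan-Killiany cortical regions (per hemisphere)
DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: temporal composite used for tau positivity (amygdala is subcortical and
#: enters only through this composite)
META_ROI_REGIONS = ("entorhinal", "amygdala", "fusiform",
                    "inferiortemporal", "middletemporal")

_DEGENERATE_SD = 1e-8


@dataclass(frozen=True)
class BiomarkerThresholds:
    """Positivity cut-offs; all strict inequalities (boundary = negative)."""

    csf_ratio_cut: float = 0.075   # CSF Abeta42/40, below => positive
    av45_cut: float = 1.11         # SUVr, above => positive
    fbb_cut: float = 1.08          # SUVr, above => positive
    tau_metaroi_cut: float = 1.37  # SUVr, above => positive


@dataclass(frozen=True)
class TracerCalibration:
    """Centiloid = slope * SUVr + intercept, per amyloid tracer."""

    av45_slope: float = 196.9
    av45_intercept: float = -196.03
    fbb_slope: float = 159.08
    fbb_intercept: float = -151.65


THRESHOLDS = BiomarkerThresholds()
CALIBRATION = TracerCalibration()


@dataclass
class ReferenceStats:
    """Per-feature HC mean/SD used to standardize patient maps."""

    mean: np.ndarray
    sd: np.ndarray
    n_hc: int
    ddof: int = 1
    feature_names: list[str] | None = None

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of features whose HC SD is below tolerance."""
        return self.sd < _DEGENERATE_SD


def fit_reference(hc_matrix, ddof: int = 1,
                  feature_names=None) -> ReferenceStats:
    """Per-feature mean and SD of the HC group (sample SD by default)."""
    if isinstance(hc_matrix, pd.DataFrame):
        feature_names = list(hc_matrix.columns)
        hc_matrix = hc_matrix.to_numpy(dtype=float)
    hc = np.asarray(hc_matrix, dtype=float)
    if hc.ndim != 2 or hc.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 HC subjects")
    stats = ReferenceStats(
        mean=hc.mean(axis=0), sd=hc.std(axis=0, ddof=ddof),
        n_hc=hc.shape[0], ddof=ddof,
        feature_names=list(feature_names) if feature_names is not None else None)
    n_bad = int(stats.degenerate.sum())
    if n_bad:
        warnings.warn(f"{n_bad} feature(s) have near-zero HC SD and are "
                      "flagged degenerate")
    return stats


def vertex_zscores(ads_matrix, ref: ReferenceStats,
                   drop_degenerate: bool = True):
    """Standardize patient rows against the HC reference, feature by feature.

    Returns an array (or DataFrame, matching the input type) of
    z = (x - mean_HC) / SD_HC. Degenerate features (HC SD ~ 0) are dropped by
    default so every returned value is finite.
    """
    is_df = isinstance(ads_matrix, pd.DataFrame)
    X = ads_matrix.to_numpy(dtype=float) if is_df else np.asarray(ads_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != ref.mean.size:
        raise ValueError(
            f"feature dimension mismatch: matrix has {X.shape[-1]}, "
            f"reference has {ref.mean.size}")
    keep = ~ref.degenerate if drop_degenerate else np.ones(ref.mean.size, bool)
    z = (X[:, keep] - ref.mean[keep]) / ref.sd[keep]
    if is_df:
        cols = np.asarray(ads_matrix.columns)[keep]
        return pd.DataFrame(z, index=ads_matrix.index, columns=cols)
    return z


def parcel_means(values: pd.DataFrame, parcel_lookup: pd.Series) -> pd.DataFrame:
    """Unweighted mean of member vertices per parcel.

    ``parcel_lookup`` maps vertex name -> parcel name; vertices labeled
    "unassigned" are ignored. Parcels with zero member vertices yield NaN
    columns with a warning.
    """
    lookup = parcel_lookup.reindex(values.columns)
    if lookup.isna().any():
        missing = list(values.columns[lookup.isna()])[:5]
        raise ValueError(f"vertices without a parcel assignment, e.g. {missing}")
    assigned = lookup != "unassigned"
    grouped = values.loc[:, values.columns[assigned]]
    out = grouped.T.groupby(lookup[assigned]).mean().T
    all_parcels = pd.unique(parcel_lookup[parcel_lookup != "unassigned"])
    empty = [p for p in all_parcels if p not in out.columns]
    if empty:
        warnings.warn(f"parcels with zero vertices: {empty}")
        for p in empty:
            out[p] = np.nan
    return out


def meta_roi_suvr(roi_values) -> float:
    """Unweighted mean SUVr over the 5 temporal meta-ROI regions.

    ``roi_values`` is a mapping region name -> (bilateral) SUVr; hemisphere
    pairs should be averaged upstream. Raises naming any missing region.
    """
    missing = [r for r in META_ROI_REGIONS if r not in roi_values]
    if missing:
        raise KeyError(f"meta-ROI region(s) missing: {', '.join(missing)}")
    return float(np.mean([roi_values[r] for r in META_ROI_REGIONS]))


def classify_amyloid(csf_ratio: float | None = None,
                     suvr: float | None = None,
                     tracer: str | None = None,
                     thresholds: BiomarkerThresholds = THRESHOLDS) -> str:
    """Amyloid status from CSF Abeta42/40 (preferred) or tracer-specific PET SUVr.

    CSF ratio strictly below the cut-off is positive; otherwise SUVr strictly
    above the tracer cut-off is positive. Boundary values are negative.
    """
    if csf_ratio is not None and np.isfinite(csf_ratio):
        return "positive" if csf_ratio < thresholds.csf_ratio_cut else "negative"
    if suvr is None or not np.isfinite(suvr):
        raise ValueError("no amyloid biomarker available (CSF and PET both missing)")
    if tracer is None:
        raise ValueError("tracer required when classifying from PET SUVr")
    tracer = tracer.upper()
    if tracer == "AV45":
        cut = thresholds.av45_cut
    elif tracer == "FBB":
        cut = thresholds.fbb_cut
    else:
        raise ValueError(f"unknown amyloid tracer {tracer!r}")
    return "positive" if suvr > cut else "negative"


def classify_tau(meta_suvr: float,
                 thresholds: BiomarkerThresholds = THRESHOLDS) -> str:
    """Tau status from the temporal meta-ROI SUVr (strictly above cut = positive)."""
    if not np.isfinite(meta_suvr):
        raise ValueError("meta-ROI SUVr must be finite")
    return "positive" if meta_suvr > thresholds.tau_metaroi_cut else "negative"


#: exclusion rule tags used by filter_cohort
RULE_AB_POS_UNIMPAIRED = "amyloid_positive_unimpaired"
RULE_SNAP = "amyloid_negative_tau_positive"

_UNIMPAIRED = {"CN", "CU", "HC", "NC", "NORMAL"}


def filter_cohort(metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the two cohort exclusion rules and log each exclusion.

    Requires columns ``diagnosis``, ``amyloid_status`` and ``tau_status``.
    Excluded are (1) amyloid-positive cognitively unimpaired subjects and
    (2) amyloid-negative but tau-positive subjects (suspected non-AD
    pathology). Returns (included table, exclusion log).
    """
    for col in ("diagnosis", "amyloid_status", "tau_status"):
        if col not in metadata.columns:
            raise KeyError(f"metadata is missing required column {col!r}")
    unimpaired = metadata["diagnosis"].astype(str).str.upper().isin(_UNIMPAIRED)
    ab_pos = metadata["amyloid_status"] == "positive"
    tau_pos = metadata["tau_status"] == "positive"
    rule1 = ab_pos & unimpaired
    rule2 = (~ab_pos) & tau_pos
    log_rows = []
    for idx in metadata.index[rule1]:
        log_rows.append({"subject": idx, "rule": RULE_AB_POS_UNIMPAIRED})
    for idx in metadata.index[rule2 & ~rule1]:
        log_rows.append({"subject": idx, "rule": RULE_SNAP})
    excluded = rule1 | rule2
    log = pd.DataFrame(log_rows, columns=["subject", "rule"])
    return metadata.loc[~excluded].copy(), log


def centiloid(suvr: float, tracer: str,
              calibration: TracerCalibration = CALIBRATION) -> float:
    """Linear SUVr -> centiloid conversion with tracer-specific constants."""
    tracer = tracer.upper()
    if tracer == "AV45":
        return calibration.av45_slope * suvr + calibration.av45_intercept
    if tracer == "FBB":
        return calibration.fbb_slope * suvr + calibration.fbb_intercept
    raise ValueError(f"unknown amyloid tracer {tracer!r}")


def ctv_hv(cortical_volume: float, hippocampal_volume: float,
           inverse: bool = False) -> float:
    """Cortex-to-hippocampus volume ratio (``inverse=True`` for the reciprocal)."""
    if cortical_volume <= 0 or hippocampal_volume <= 0:
        raise ValueError("volumes must be positive")
    if inverse:
        return hippocampal_volume / cortical_volume
    return cortical_volume / hippocampal_volume
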