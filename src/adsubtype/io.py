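"""Plain-text serialization: TSV matrices, partitions, dataset bundles.

All artifacts round-trip through text so a run can be reproduced and audited
without binary files. Optional GIFTI/MGH surface maps are read through
nibabel into the same internal matrix representation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortSpec, SyntheticDataset

__all__ = [
    "write_matrix", "read_matrix", "write_partition", "read_partition",
    "write_dataset", "load_dataset", "read_surface_map",
]

_FLOAT_FMT = "%.12g"


def write_matrix(df: pd.DataFrame, path) -> None:
    """Subjects x features matrix as TSV with a subject-id index column."""
    df.to_csv(path, sep="\t", index_label=df.index.name or "subject_id",
              float_format="%.12g")


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - surfaced with file context
        raise ValueError(f"failed to parse matrix file {path}: {exc}") from exc
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5]
        raise ValueError(f"missing values in {path}, e.g. rows {list(bad)}")
    return df


def write_partition(labels, subject_ids, path) -> None:
    pd.DataFrame({"subject_id": list(subject_ids),
                  "cluster": np.asarray(labels)}).to_csv(path, sep="\t",
                                                         index=False)


def read_partition(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["subject_id", "cluster"]:
        raise ValueError(f"partition file {path} must have columns "
                         "subject_id, cluster")
    return df.set_index("subject_id")["cluster"]


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Dataset bundle: metadata/tau/thickness/parcels/visits TSVs + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    write_matrix(ds.tau, outdir / "tau_matrix.tsv")
    write_matrix(ds.thickness, outdir / "thickness_matrix.tsv")
    ds.parcels.rename_axis("vertex").to_frame().to_csv(
        outdir / "parcels.tsv", sep="\t")
    if ds.visits is not None:
        ds.visits.to_csv(outdir / "visits.tsv", sep="\t", index=False,
                         float_format="%.12g")
    sidecar = {
        "spec": ds.spec.to_dict() if ds.spec is not None else None,
        "truth": {
            "subject_id": list(ds.truth.index),
            "tau_cluster": [int(v) for v in ds.truth["tau_cluster"]],
            "atrophy_cluster": [int(v) for v in ds.truth["atrophy_cluster"]],
        },
    }
    (outdir / "dataset.json").write_text(json.dumps(sidecar, indent=2))


def load_dataset(indir) -> SyntheticDataset:
    """Read a dataset bundle back; validates metadata/matrix row alignment."""
    indir = Path(indir)
    metadata = pd.read_csv(indir / "metadata.tsv", sep="\t",
                           index_col="subject_id")
    tau = read_matrix(indir / "tau_matrix.tsv")
    thickness = read_matrix(indir / "thickness_matrix.tsv")
    parcels = pd.read_csv(indir / "parcels.tsv", sep="\t",
                          index_col="vertex")["parcel"]
    for name, mat in (("tau", tau), ("thickness", thickness)):
        if not mat.index.equals(metadata.index):
            offenders = list(mat.index.symmetric_difference(metadata.index))[:5]
            raise ValueError(
                f"{name} matrix rows do not align with metadata; "
                f"offending ids e.g. {offenders}")
    visits_path = indir / "visits.tsv"
    visits = pd.read_csv(visits_path, sep="\t") if visits_path.exists() else None
    sidecar_path = indir / "dataset.json"
    spec = None
    truth = pd.DataFrame(columns=["tau_cluster", "atrophy_cluster"])
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("spec"):
            spec = CohortSpec(**sidecar["spec"])
        t = sidecar.get("truth")
        if t:
            truth = pd.DataFrame(
                {"tau_cluster": t["tau_cluster"],
                 "atrophy_cluster": t["atrophy_cluster"]},
                index=pd.Index(t["subject_id"], name="subject_id"))
    return SyntheticDataset(metadata=metadata, tau=tau, thickness=thickness,
                            parcels=parcels, truth=truth, spec=spec,
                            visits=visits)


def read_surface_map(path) -> np.ndarray:
    """Read a per-vertex map from a GIFTI (.gii) or MGH/MGZ surface file."""
    import nibabel as nib

    path = Path(path)
    if path.suffix == ".gii" or path.name.endswith((".func.gii", ".shape.gii")):
        img = nib.load(str(path))
        return np.concatenate([d.data.ravel() for d in img.darrays])
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).ravel()
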