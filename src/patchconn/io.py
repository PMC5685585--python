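"""File formats: NIfTI volumes, gzipped delimited matrices, CSV labels, JSON.

Every reader validates strictly and names the offending file and check in
its error message; matrix files travel with a JSON sidecar recording the
subject id and the grid hash they were computed on.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from patchconn.errors import ValidationError
from patchconn.network import ConnectivityMatrix, PatchGrid

_ATOL = 1e-8


def read_labels(path) -> pd.DataFrame:
    """Two-column CSV (subject_id, group) with unique subject ids."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "group"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: labels CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"{path}: duplicate subject id(s) {dupes}")
    if df.empty:
        raise ValidationError(f"{path}: labels CSV is empty")
    if df[["subject_id", "group"]].isna().any().any():
        raise ValidationError(f"{path}: missing subject id or group entries")
    return df[["subject_id", "group"]]


def write_labels(labels: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels.to_csv(path, index=False)
    return path


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".tsv.gz", ".tsv", ".txt.gz", ".txt"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_matrix(matrix, path, header: dict | None = None) -> Path:
    """Gzipped TSV matrix plus a JSON sidecar header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(matrix, ConnectivityMatrix):
        values = matrix.values
        header = dict(header or {})
        header.setdefault("subject_id", matrix.subject_id)
        header.setdefault("grid_hash", matrix.grid_hash)
        header.setdefault("flagged_nodes", list(matrix.flagged_nodes))
    else:
        values = np.asarray(matrix, dtype=float)
        header = dict(header or {})
    with gzip.open(path, "wt") as fh:
        np.savetxt(fh, values, delimiter="\t", fmt="%.17g")
    _sidecar(path).write_text(json.dumps(header, indent=1))
    return path


def read_matrix(path, validate: bool = True) -> ConnectivityMatrix:
    """Read a matrix written by :func:`write_matrix`, validating shape,
    symmetry, unit diagonal, and finiteness."""
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    sidecar = _sidecar(path)
    header = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    matrix = ConnectivityMatrix(
        values=values,
        subject_id=str(header.get("subject_id", path.name.split(".")[0])),
        grid_hash=str(header.get("grid_hash", "")),
        flagged_nodes=tuple(header.get("flagged_nodes", ())),
    )
    if validate:
        try:
            matrix.validate(atol=_ATOL)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return matrix


def read_matrices_dir(directory, subject_ids=None) -> list[ConnectivityMatrix]:
    """All ``*.tsv.gz`` matrices in a directory, ordered by subject id list
    if given, else by filename."""
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv.gz"))
    if not files:
        raise ValidationError(f"{directory}: no *.tsv.gz matrix files found")
    matrices = [read_matrix(f) for f in files]
    if subject_ids is not None:
        by_id = {m.subject_id: m for m in matrices}
        missing = [s for s in subject_ids if s not in by_id]
        if missing:
            raise ValidationError(
                f"{directory}: no matrix file for subject(s) {missing}"
            )
        matrices = [by_id[s] for s in subject_ids]
    return matrices


def read_volume(path) -> np.ndarray:
    path = Path(path)
    data = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValidationError(f"{path}: volume must be 3-D, got ndim={data.ndim}")
    if not np.isfinite(data).all():
        raise ValidationError(f"{path}: volume contains non-finite voxels")
    return data


def write_volume(data, path, affine=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine  # 1 mm isotropic
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))
    return path


def write_grid(grid: PatchGrid, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(grid.to_dict(), indent=1))
    return path


def read_grid(path) -> PatchGrid:
    path = Path(path)
    return PatchGrid.from_dict(json.loads(path.read_text()))


def save_cohort(cohort, out_dir) -> dict:
    """Write a synthetic cohort to disk (NIfTI / TSV / CSV / JSON).

    Returns a dict of the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    labels = pd.DataFrame(
        {"subject_id": cohort.subject_ids, "group": cohort.labels}
    )
    written["labels"] = str(write_labels(labels, out_dir / "labels.csv"))
    (out_dir / "truth.json").write_text(
        json.dumps({"affected_nodes": sorted(cohort.truth)})
    )
    written["truth"] = str(out_dir / "truth.json")
    if cohort.volumes is not None:
        vol_dir = out_dir / "volumes"
        for sid, vol in zip(cohort.subject_ids, cohort.volumes):
            write_volume(vol, vol_dir / f"{sid}.nii.gz")
        written["volumes"] = str(vol_dir)
        written["mask"] = str(
            write_volume(cohort.mask.astype(np.uint8), out_dir / "mask.nii.gz")
        )
        if cohort.grid is not None:
            written["grid"] = str(write_grid(cohort.grid, out_dir / "grid.json"))
    if cohort.matrices is not None:
        mat_dir = out_dir / "matrices"
        for sid, values in zip(cohort.subject_ids, cohort.matrices):
            write_matrix(values, mat_dir / f"{sid}.tsv.gz",
                         header={"subject_id": sid})
        written["matrices"] = str(mat_dir)
    return written
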