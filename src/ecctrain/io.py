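"""File formats used across the pipeline.

Trials travel as CSV with the header ``time_s,angle_deg,torque_Nm,
velocity_dps`` (metadata in a JSON sidecar), cohort tables and 101-node
curves as TSV, phantoms as NIfTI (tensor volume as a 6-component symmetric
upper-triangle image plus a uint8 mask), fit/stat results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .isokin import DynamometerTrial, NormalizedTorqueCurve
from .tract import TensorVolume

TRIAL_HEADER = ["time_s", "angle_deg", "torque_Nm", "velocity_dps"]

# NIfTI tensor component order (upper triangle, row-major)
TENSOR_COMPONENTS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def write_trial_csv(trial: DynamometerTrial, path) -> None:
    """Trial series as CSV; metadata goes to ``<path>.meta.json``."""
    df = pd.DataFrame(
        dict(zip(TRIAL_HEADER,
                 [trial.time, trial.angle, trial.torque, trial.velocity]))
    )
    df.to_csv(path, index=False, float_format="%.6f")
    if trial.meta:
        dump_json(trial.meta, str(path) + ".meta.json")


def read_trial_csv(path, meta: dict | None = None) -> DynamometerTrial:
    df = pd.read_csv(path)
    missing = set(TRIAL_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV {path} missing columns {sorted(missing)}")
    if meta is None:
        sidecar = Path(str(path) + ".meta.json")
        meta = load_json(sidecar) if sidecar.exists() else {}
    return DynamometerTrial(
        time=df["time_s"].to_numpy(),
        angle=df["angle_deg"].to_numpy(),
        torque=df["torque_Nm"].to_numpy(),
        velocity=df["velocity_dps"].to_numpy(),
        meta=meta,
    )


_CURVE_META = ["subject", "group", "time", "mode", "speed",
               "angle_start", "angle_end"]


def write_curves_tsv(curves: list[NormalizedTorqueCurve], path) -> None:
    """One row per curve: metadata columns then t000..t{n-1}."""
    if not curves:
        raise ValueError("no curves to write")
    n = curves[0].n_nodes
    rows = []
    for c in curves:
        if c.n_nodes != n:
            raise ValueError("curves differ in node count")
        row = {k: c.meta.get(k, "") for k in _CURVE_META[:5]}
        row["angle_start"] = c.angle_start
        row["angle_end"] = c.angle_end
        row.update({f"t{i:03d}": c.torque[i] for i in range(n)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_curves_tsv(path) -> list[NormalizedTorqueCurve]:
    df = pd.read_csv(path, sep="\t")
    tcols = sorted(c for c in df.columns if c.startswith("t") and c[1:].isdigit())
    out = []
    for _, row in df.iterrows():
        meta = {k: row[k] for k in _CURVE_META[:5] if k in df.columns}
        out.append(NormalizedTorqueCurve(
            torque=row[tcols].to_numpy(dtype=float),
            angle_start=float(row["angle_start"]),
            angle_end=float(row["angle_end"]),
            meta=meta,
        ))
    return out


def write_cohort_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"subject", "group", "parameter", "pre", "post"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"cohort TSV {path} missing columns {sorted(missing)}")
    return df


def save_phantom_nifti(volume: TensorVolume, prefix) -> None:
    """Tensor volume as 4D NIfTI (6 upper-triangle components) + mask."""
    import nibabel as nib

    prefix = str(prefix)
    comp = np.stack(
        [volume.tensors[..., i, j] for i, j in TENSOR_COMPONENTS], axis=-1
    ).astype(np.float32)
    nib.save(nib.Nifti1Image(comp, volume.affine), prefix + "_tensor.nii")
    nib.save(
        nib.Nifti1Image(volume.mask.astype(np.uint8), volume.affine),
        prefix + "_mask.nii",
    )


def load_phantom_nifti(prefix) -> TensorVolume:
    import nibabel as nib

    prefix = str(prefix)
    timg = nib.load(prefix + "_tensor.nii")
    mimg = nib.load(prefix + "_mask.nii")
    comp = np.asarray(timg.dataobj, dtype=float)
    shape = comp.shape[:3]
    tensors = np.zeros(shape + (3, 3))
    for k, (i, j) in enumerate(TENSOR_COMPONENTS):
        tensors[..., i, j] = comp[..., k]
        tensors[..., j, i] = comp[..., k]
    affine = timg.affine
    voxel = tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return TensorVolume(
        tensors=tensors,
        mask=np.asarray(mimg.dataobj) > 0,
        voxel_size=voxel,
        affine=affine,
    )
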