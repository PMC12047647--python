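"""File formats: NIfTI volumes, CSV tables, HDF5 field/simulation stores.

Conventions: label and tensor volumes are NIfTI-1 with an RAS affine built
from the phantom origin/spacing; symmetric tensors are stored as 6
components in lower-triangular order (xx, yx, yy, zx, zy, zz); connectomes
are two CSV matrices (weights, lengths) plus a centroid/name table;
montages are CSV (label, x, y, z, radius); E-field bases and lead fields
are HDF5 with grid metadata; EEG records are CSV with a channels x samples
layout and a header row of sample times.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .conductivity import TensorField
from .em import EFieldBasis, LeadFieldMatrix
from .jansen_rit import SimOutput, JRParams
from .phantom import Connectome, ElectrodeMontage, TissuePhantom

__all__ = [
    "save_phantom", "load_phantom", "save_tensor_field", "load_tensor_field",
    "save_connectome", "load_connectome", "save_montage", "load_montage",
    "save_basis", "load_basis", "save_leadfield", "load_leadfield",
    "save_sim_output", "load_sim_output", "save_eeg_csv",
]

_TRIL = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


def _affine(origin, spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_phantom(phantom: TissuePhantom, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16),
                             _affine(phantom.origin, phantom.spacing)),
             d / "labels.nii.gz")
    meta = {
        "tissue_table": {str(k): [n, s] for k, (n, s) in phantom.tissue_table.items()},
        "landmarks": {k: list(map(float, v)) for k, v in phantom.landmarks.items()},
        "meta": phantom.meta,
    }
    (d / "phantom.json").write_text(json.dumps(meta, indent=1))
    return d


def load_phantom(directory) -> TissuePhantom:
    d = Path(directory)
    img = nib.load(d / "labels.nii.gz")
    meta = json.loads((d / "phantom.json").read_text())
    aff = img.affine
    return TissuePhantom(
        labels=np.asarray(img.dataobj).astype(np.int16),
        spacing=np.diag(aff)[:3].copy(),
        origin=aff[:3, 3].copy(),
        tissue_table={int(k): (n, float(s))
                      for k, (n, s) in meta["tissue_table"].items()},
        landmarks={k: np.array(v) for k, v in meta["landmarks"].items()},
        meta=meta.get("meta", {}),
    )


def save_tensor_field(tf: TensorField, path) -> Path:
    comp = np.stack([tf.tensors[..., i, j] for i, j in _TRIL], axis=-1)
    img = nib.Nifti1Image(comp.astype(np.float32), _affine(tf.origin, tf.spacing))
    img.header.set_intent("symmetric matrix", (3,))
    nib.save(img, path)
    return Path(path)


def load_tensor_field(path, units: str) -> TensorField:
    img = nib.load(path)
    comp = np.asarray(img.dataobj, dtype=float)
    t = np.zeros(comp.shape[:3] + (3, 3))
    for c, (i, j) in enumerate(_TRIL):
        t[..., i, j] = comp[..., c]
        t[..., j, i] = comp[..., c]
    mask = np.abs(comp).sum(axis=-1) > 0
    aff = img.affine
    return TensorField(tensors=t, mask=mask, units=units,
                       spacing=np.diag(aff)[:3].copy(), origin=aff[:3, 3].copy())


def save_connectome(con: Connectome, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(con.weights, index=con.names, columns=con.names).to_csv(d / "weights.csv")
    pd.DataFrame(con.lengths, index=con.names, columns=con.names).to_csv(d / "lengths.csv")
    pd.DataFrame({"name": con.names, "x": con.centroids[:, 0],
                  "y": con.centroids[:, 1], "z": con.centroids[:, 2],
                  "hemisphere": con.hemisphere}).to_csv(d / "regions.csv", index=False)
    return d


def load_connectome(directory) -> Connectome:
    d = Path(directory)
    w = pd.read_csv(d / "weights.csv", index_col=0)
    ln = pd.read_csv(d / "lengths.csv", index_col=0)
    reg = pd.read_csv(d / "regions.csv")
    return Connectome(weights=w.to_numpy(float), lengths=ln.to_numpy(float),
                      centroids=reg[["x", "y", "z"]].to_numpy(float),
                      names=list(reg["name"]),
                      hemisphere=reg["hemisphere"].to_numpy(int))


def save_montage(mon: ElectrodeMontage, path) -> Path:
    df = pd.DataFrame({"label": mon.labels, "x": mon.positions[:, 0],
                       "y": mon.positions[:, 1], "z": mon.positions[:, 2],
                       "radius": mon.radius_mm})
    df.attrs["reference"] = mon.reference
    with open(path, "w") as fh:
        fh.write(f"# reference={mon.reference}\n")
        df.to_csv(fh, index=False)
    return Path(path)


def load_montage(path) -> ElectrodeMontage:
    with open(path) as fh:
        first = fh.readline()
        ref = first.strip().split("=", 1)[1] if first.startswith("# reference=") else None
        df = pd.read_csv(fh) if ref is not None else None
    if df is None:
        df = pd.read_csv(path)
        ref = df["label"].iloc[0]
    return ElectrodeMontage(labels=list(df["label"]),
                            positions=df[["x", "y", "z"]].to_numpy(float),
                            radius_mm=float(df["radius"].iloc[0]), reference=ref)


def save_basis(basis: EFieldBasis, path) -> Path:
    with h5py.File(path, "w") as f:
        f.attrs["reference"] = basis.reference
        f.attrs["unit_current_A"] = basis.unit_current_A
        f.attrs["spacing_mm"] = basis.spacing_mm
        f.attrs["origin_mm"] = basis.origin_mm
        f.create_dataset("mask", data=basis.mask, compression="gzip")
        g = f.create_group("fields")
        for lab, fld in zip(basis.labels, basis.fields):
            g.create_dataset(lab, data=fld.astype(np.float32), compression="gzip")
        f.create_dataset("labels", data=np.array(basis.labels, dtype="S"))
    return Path(path)


def load_basis(path) -> EFieldBasis:
    with h5py.File(path, "r") as f:
        labels = [s.decode() for s in f["labels"][()]]
        fields = np.stack([f["fields"][lab][()] for lab in labels]).astype(float)
        return EFieldBasis(labels=labels, reference=f.attrs["reference"],
                           fields=fields, mask=f["mask"][()].astype(bool),
                           spacing_mm=f.attrs["spacing_mm"][:],
                           origin_mm=f.attrs["origin_mm"][:],
                           unit_current_A=float(f.attrs["unit_current_A"]))


def save_leadfield(lf: LeadFieldMatrix, path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=lf.matrix, compression="gzip")
        f.create_dataset("labels", data=np.array(lf.labels, dtype="S"))
        f.attrs["reference"] = lf.reference
        f.attrs["referenced"] = lf.referenced
    return Path(path)


def load_leadfield(path) -> LeadFieldMatrix:
    with h5py.File(path, "r") as f:
        return LeadFieldMatrix(matrix=f["matrix"][()],
                               labels=[s.decode() for s in f["labels"][()]],
                               reference=f.attrs["reference"],
                               referenced=f.attrs["referenced"])


def save_sim_output(sim: SimOutput, path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=sim.time)
        f.create_dataset("v_pyr", data=sim.v_pyr, compression="gzip")
        f.attrs["dt"] = sim.dt
        f.attrs["seed"] = sim.seed
        f.attrs["burn_in_s"] = sim.burn_in_s
        f.attrs["params"] = json.dumps(vars(sim.params))
        f.attrs["meta"] = json.dumps(sim.meta)
    return Path(path)


def load_sim_output(path) -> SimOutput:
    with h5py.File(path, "r") as f:
        return SimOutput(time=f["time"][()], v_pyr=f["v_pyr"][()],
                         dt=float(f.attrs["dt"]), seed=int(f.attrs["seed"]),
                         burn_in_s=float(f.attrs["burn_in_s"]),
                         params=JRParams(**json.loads(f.attrs["params"])),
                         meta=json.loads(f.attrs["meta"]))


def save_eeg_csv(rec, path) -> Path:
    """Channels x samples CSV; first column channel label, header sample times."""
    df = pd.DataFrame(rec.data, index=rec.labels,
                      columns=np.arange(rec.data.shape[1]) / rec.fs)
    df.to_csv(path)
    return Path(path)
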