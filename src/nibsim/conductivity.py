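"""Conductivity assignment: scalar tissue values and DTI-derived tensors.

White matter conductivity is strongly anisotropic (up to ~10x higher along
fiber bundles than across them), and a diffusion tensor field shares its
eigenvectors with the conductivity tensor.  This module maps a diffusion
tensor field to a conductivity tensor field — either by linear eigenvalue
scaling or by assigning database axial/radial values to the principal /
transverse axes — applies the standard two-step eigenvalue clamp, and merges
the result with the scalar tissue table of the phantom.

Clamping rule (applied voxelwise to conductivity eigenvalues):
  (i)  eigenvalues above ``sigma_cap`` (default 2 S/m) are clamped to it;
  (ii) any eigenvalue still above ``c`` times the smallest eigenvalue
       (default c = 3) is clamped to that threshold.
Step (ii) uses the minimum after step (i) and is applied once; clamping to
exactly ``c * min`` satisfies the ratio test, so the rule is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import TissuePhantom

__all__ = ["TensorField", "clamp_tensor", "dti_to_sigma", "assign_tissue_sigma",
           "synthetic_radial_dti", "isotropic_tensor_field"]


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensor volume with a validity mask.

    ``tensors`` has shape (nx, ny, nz, 3, 3); ``units`` is ``"mm2/s"`` for
    diffusion or ``"S/m"`` for conductivity; voxels outside ``mask`` are
    undefined.
    """

    tensors: np.ndarray
    mask: np.ndarray
    units: str
    spacing: np.ndarray | None = None   # mm per axis (grid geometry travels with the field)
    origin: np.ndarray | None = None    # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.tensors
        if t.ndim != 5 or t.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if self.mask.shape != t.shape[:3]:
            raise ValueError("mask shape must match the tensor grid")


def clamp_tensor(eigenvalues, sigma_cap: float = 2.0, c: float = 3.0) -> np.ndarray:
    """Apply the two-step conductivity eigenvalue clamp.

    Accepts a single triple or an (..., 3) array.  Output eigenvalues are
    <= ``sigma_cap`` and the max/min ratio is <= ``c`` (where min > 0);
    sorting order is preserved because clamping is monotone.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected triples of eigenvalues")
    if np.any(ev < 0):
        raise ValueError("negative conductivity eigenvalue (upstream mapping bug)")
    out = np.minimum(ev, sigma_cap)                      # step (i)
    mn = out.min(axis=-1, keepdims=True)
    out = np.minimum(out, c * mn)                        # step (ii), single pass
    return out


def _eigh_field(t: np.ndarray):
    # eigh on stacked symmetric 3x3, ascending eigenvalues
    w, v = np.linalg.eigh(t)
    return w, v


def dti_to_sigma(
    dti: TensorField,
    mode: str = "linear_scaling",
    k: float = 700.0,
    axial: float = 1.1,
    radial: float = 0.13,
    sigma_cap: float = 2.0,
    c: float = 3.0,
) -> TensorField:
    """Map a diffusion tensor field to a conductivity tensor field.

    Eigenvectors are kept; eigenvalues are set by ``mode``:

    - ``linear_scaling``: sigma_i = k * d_i (k in S*s/(m*mm^2); the default
      700 places typical WM diffusivities ~1e-3 mm^2/s near 0.7 S/m axially
      and is a configuration value, not a fitted constant);
    - ``database_axial_radial``: the largest eigenvalue maps to ``axial``
      and the two transverse ones to ``radial`` (S/m).

    The two-step clamp post-processes the DTI-derived (linear) magnitudes;
    database axial/radial values are trusted as-is, since magnitude
    assignment follows the clamping step.  Non-PSD voxels are masked out of
    the result rather than raising.
    """
    if dti.units not in ("mm2/s",):
        raise ValueError(f"expected a diffusion tensor field, got units {dti.units!r}")
    t = dti.tensors
    sym_err = np.abs(t - np.swapaxes(t, -1, -2)).max()
    if sym_err > 1e-9 * max(1.0, np.abs(t).max()):
        raise ValueError("diffusion tensors are not symmetric")
    w, v = _eigh_field(t)
    mask = dti.mask.copy()
    bad = (w.min(axis=-1) < -1e-12 * np.abs(w).max()) & mask
    n_bad = int(bad.sum())
    if n_bad:
        mask = mask & ~bad
    w = np.clip(w, 0.0, None)
    if mode == "linear_scaling":
        sig_ev = clamp_tensor(k * w, sigma_cap=sigma_cap, c=c)
    elif mode == "database_axial_radial":
        sig_ev = np.empty_like(w)
        sig_ev[..., :2] = radial   # eigh sorts ascending: two smallest -> radial
        sig_ev[..., 2] = axial
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sig = np.einsum("...ij,...j,...kj->...ik", v, sig_ev, v)
    meta = dict(dti.meta, mode=mode, k=k, axial=axial, radial=radial,
                sigma_cap=sigma_cap, c=c, masked_non_psd_voxels=n_bad)
    return TensorField(tensors=sig, mask=mask, units="S/m",
                       spacing=dti.spacing, origin=dti.origin, meta=meta)


def isotropic_tensor_field(phantom: TissuePhantom) -> TensorField:
    """Piecewise-constant isotropic sigma*I field from the tissue table."""
    labels = phantom.labels
    missing = sorted(set(np.unique(labels)) - {0} - set(phantom.tissue_table))
    if missing:
        raise KeyError(f"labels missing from tissue table: {missing}")
    sig = np.zeros(labels.shape, dtype=float)
    for lab, (_, s) in phantom.tissue_table.items():
        sig[labels == lab] = s
    t = np.zeros(labels.shape + (3, 3))
    for i in range(3):
        t[..., i, i] = sig
    return TensorField(tensors=t, mask=labels > 0, units="S/m",
                       spacing=phantom.spacing.copy(), origin=phantom.origin.copy())


def assign_tissue_sigma(phantom: TissuePhantom,
                        wm_tensor: TensorField | None = None) -> TensorField:
    """Full conductivity field: scalar tissues + tensor WM where provided.

    Non-WM voxels get sigma*I from the tissue table; WM voxels take the
    anisotropic tensor where ``wm_tensor`` is valid and fall back to the
    scalar WM value elsewhere.
    """
    out = isotropic_tensor_field(phantom)
    if wm_tensor is None:
        return out
    if wm_tensor.units != "S/m":
        raise ValueError("wm_tensor must be a conductivity field (S/m); run dti_to_sigma first")
    wm = phantom.labels == phantom.label_of("wm")
    if np.any(wm_tensor.mask & ~wm):
        raise ValueError("tensor mask extends outside the WM compartment")
    sel = wm_tensor.mask & wm
    out.tensors[sel] = wm_tensor.tensors[sel]
    out.meta["wm_tensor_voxels"] = int(sel.sum())
    return out


def synthetic_radial_dti(phantom: TissuePhantom, seed: int = 0,
                         d_axial: float = 1.4e-3, d_radial: float = 0.35e-3,
                         jitter: float = 0.05) -> TensorField:
    """Synthetic WM diffusion tensors with radially oriented principal axes.

    Emulates a prolate (cigar-shaped) fiber tensor pointing along the local
    radial direction in the WM shell, with seeded multiplicative jitter on
    the eigenvalues.  Diffusivities are in mm^2/s, typical of white matter.
    """
    rng = np.random.default_rng(seed)
    wm = phantom.labels == phantom.label_of("wm")
    shape = phantom.labels.shape
    idx = np.argwhere(wm)
    pos = phantom.origin + idx * phantom.spacing
    r = np.linalg.norm(pos, axis=1)
    e1 = np.zeros_like(pos)
    ok = r > 1e-9
    e1[ok] = pos[ok] / r[ok, None]
    e1[~ok] = [1.0, 0.0, 0.0]
    # complete an orthonormal frame
    ref = np.where(np.abs(e1[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    lam = np.stack([
        d_axial * np.exp(jitter * rng.standard_normal(len(idx))),
        d_radial * np.exp(jitter * rng.standard_normal(len(idx))),
        d_radial * np.exp(jitter * rng.standard_normal(len(idx))),
    ], axis=1)
    V = np.stack([e1, e2, e3], axis=-1)  # columns are eigenvectors
    tv = np.einsum("nij,nj,nkj->nik", V, lam, V)
    t = np.zeros(shape + (3, 3))
    t[wm] = tv
    return TensorField(tensors=t, mask=wm, units="mm2/s",
                       spacing=phantom.spacing.copy(), origin=phantom.origin.copy(),
                       meta={"seed": int(seed)})
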