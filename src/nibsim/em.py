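"""Electroquasistatic forward solver on the voxel phantom.

At transcranial stimulation frequencies (1-10 kHz) tissue currents are
Ohmic, so the electric potential obeys the anisotropic Laplace equation
``div(sigma grad phi) = 0`` with Dirichlet electrode patches and zero-flux
boundaries elsewhere, and the field follows as ``E = -grad phi``.

Discretization: cell-centered finite volumes on the voxel grid.  The
axis-aligned part of the flux uses a 7-point stencil with harmonic-mean
face conductivities; tensor off-diagonal terms are added through a
symmetric cell-centered cross-gradient correction, so the assembled system
is symmetric and amenable to preconditioned conjugate gradients.  Driven
electrode pads are Dirichlet equipotential patches of scalp-surface
voxels, rescaled post hoc to the unit current; every non-driven pad is a
floating perfect electric conductor, realized as an equipotential
super-node with zero net current.  Keeping all pads present in every
solve is what makes the basis exactly superposable: any pair's field is a
basis difference to solver tolerance, because each solution is determined
by the net currents injected at the pad super-nodes.

Superposition gives the field of any electrode pair from the per-electrode
basis, and the reciprocity theorem turns the same basis into an EEG lead
field: N electrode solves replace one solve per dipole source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import cg

from .conductivity import TensorField
from .phantom import CorticalMesh, ElectrodeMontage

__all__ = [
    "PotentialSolution", "EFieldBasis", "LeadFieldMatrix",
    "solve_potential", "efield_from_potential", "compute_field_basis",
    "leadfield_reciprocity", "solve_dipole_direct", "electrode_patch",
]

_MM = 1e-3  # grid geometry is stored in mm; the solver works in SI meters


@dataclass
class PotentialSolution:
    """Potential volume (V; NaN outside the conducting domain) plus drive data."""

    phi: np.ndarray
    drive: dict
    residual: float
    injected_current: float  # A, summed discrete face fluxes over the + patch
    mask: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray


@dataclass
class EFieldBasis:
    """Per-electrode unit-current (1 mA) E-field volumes.

    ``fields[i]`` is the (3, nx, ny, nz) V/m field of electrode ``labels[i]``
    driven against ``reference`` at 1 mA; the reference row is identically
    zero by convention.  Any pair (a, b) field at 1 mA is
    ``field(a) - field(b)``.
    """

    labels: list[str]
    reference: str
    fields: np.ndarray            # (n_electrodes, 3, nx, ny, nz), V/m per mA
    mask: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    unit_current_A: float = 1e-3
    meta: dict = field(default_factory=dict)

    def field_of(self, label: str) -> np.ndarray:
        try:
            return self.fields[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"electrode {label!r} not in basis") from None

    def pair_field(self, a: str, b: str, current_mA: float = 1.0) -> np.ndarray:
        """Superposed field of the pair (a -> b) at the given current."""
        return current_mA * (self.field_of(a) - self.field_of(b))


@dataclass
class LeadFieldMatrix:
    """Source-to-sensor map: rows electrodes, columns normal-oriented dipoles.

    Entries are V per unit dipole moment (A*m).  ``referenced`` records
    whether rows are against the reference electrode (its row is zero) or
    average-referenced.
    """

    matrix: np.ndarray
    labels: list[str]
    reference: str
    referenced: str = "reference"

    def average_referenced(self) -> "LeadFieldMatrix":
        m = self.matrix - self.matrix.mean(axis=0, keepdims=True)
        return LeadFieldMatrix(matrix=m, labels=list(self.labels),
                               reference=self.reference, referenced="average")


# ---------------------------------------------------------------------------
# System assembly


def _check_sigma(sigma: TensorField):
    if sigma.units != "S/m":
        raise ValueError("solver needs a conductivity field (S/m)")
    if sigma.spacing is None or sigma.origin is None:
        raise ValueError("conductivity field lacks grid geometry (spacing/origin)")


def _assemble(sigma: TensorField):
    """Assemble the symmetric conductance matrix over conducting voxels.

    Returns (A, idx_volume, n) where ``A`` is (n, n) in siemens and
    ``idx_volume`` maps voxel -> unknown index (-1 outside the domain).
    Entries of ``A @ phi`` are net outflow currents in amperes.
    """
    _check_sigma(sigma)
    mask = sigma.mask
    h = np.asarray(sigma.spacing, float) * _MM
    vol = float(np.prod(h))
    n = int(mask.sum())
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(n)

    diag_sig = [sigma.tensors[..., a, a] for a in range(3)]
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    # face terms: harmonic-mean sigma_aa, weight sigma_face * vol / h_a^2
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        m2 = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        s1 = diag_sig[a][tuple(sl_lo)][m2]
        s2 = diag_sig[a][tuple(sl_hi)][m2]
        sf = np.where(s1 + s2 > 0, 2 * s1 * s2 / np.where(s1 + s2 > 0, s1 + s2, 1.0), 0.0)
        w = sf * vol / h[a] ** 2
        i1 = idx[tuple(sl_lo)][m2]
        i2 = idx[tuple(sl_hi)][m2]
        add(i1, i1, w); add(i2, i2, w)
        add(i1, i2, -w); add(i2, i1, -w)

    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    off = sigma.tensors[..., 0, 1], sigma.tensors[..., 0, 2], sigma.tensors[..., 1, 2]
    if any(np.abs(o[mask]).max() > 0 for o in off if o[mask].size):
        G = [_central_gradient_op(mask, idx, h, a, n) for a in range(3)]
        for (a, b), o in zip(((0, 1), (0, 2), (1, 2)), off):
            d = sparse.diags(o[mask] * vol)
            A = A + (G[a].T @ d @ G[b] + G[b].T @ d @ G[a]).tocsr()
        A = (A + A.T) * 0.5
    return A, idx, n


def _central_gradient_op(mask, idx, h, axis, n):
    """Sparse cell-centered d/dx_axis (1/m): central interior, one-sided at edges."""
    shape = mask.shape
    ii = np.argwhere(mask)
    lo = ii.copy(); lo[:, axis] -= 1
    hi = ii.copy(); hi[:, axis] += 1

    def ok(pts):
        good = (pts[:, axis] >= 0) & (pts[:, axis] < shape[axis])
        out = np.zeros(len(pts), bool)
        out[good] = mask[tuple(pts[good].T)]
        return out

    has_lo, has_hi = ok(lo), ok(hi)
    rows, cols, vals = [], [], []
    r = idx[mask]

    both = has_lo & has_hi
    rows += [r[both], r[both]]
    cols += [idx[tuple(hi[both].T)], idx[tuple(lo[both].T)]]
    vals += [np.full(both.sum(), 0.5 / h[axis]), np.full(both.sum(), -0.5 / h[axis])]
    only_hi = has_hi & ~has_lo
    rows += [r[only_hi], r[only_hi]]
    cols += [idx[tuple(hi[only_hi].T)], r[only_hi]]
    vals += [np.full(only_hi.sum(), 1.0 / h[axis]), np.full(only_hi.sum(), -1.0 / h[axis])]
    only_lo = has_lo & ~has_hi
    rows += [r[only_lo], r[only_lo]]
    cols += [r[only_lo], idx[tuple(lo[only_lo].T)]]
    vals += [np.full(only_lo.sum(), 1.0 / h[axis]), np.full(only_lo.sum(), -1.0 / h[axis])]
    return sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


def electrode_patch(sigma: TensorField, center_mm, radius_mm: float) -> np.ndarray:
    """Surface-voxel patch under an electrode pad.

    Surface voxels are conducting voxels with at least one non-conducting
    6-neighbor; the patch collects those within ``radius_mm`` of the pad
    center.  Returns an (m, 3) array of voxel indices.
    """
    mask = sigma.mask
    surf = np.zeros_like(mask)
    for a in range(3):
        for d in (-1, 1):
            shifted = np.ones_like(mask)
            sl_src = [slice(None)] * 3
            sl_dst = [slice(None)] * 3
            if d == 1:
                sl_dst[a] = slice(None, -1); sl_src[a] = slice(1, None)
            else:
                sl_dst[a] = slice(1, None); sl_src[a] = slice(None, -1)
            shifted = np.zeros_like(mask)
            shifted[tuple(sl_dst)] = mask[tuple(sl_src)]
            surf |= mask & ~shifted
    ii = np.argwhere(surf)
    pos = sigma.origin + ii * sigma.spacing
    sel = np.linalg.norm(pos - np.asarray(center_mm, float), axis=1) <= radius_mm
    patch = ii[sel]
    if len(patch) == 0:
        raise ValueError(f"no scalp-surface voxels within {radius_mm} mm of {center_mm}")
    return patch


def _montage_patches(sigma: TensorField, montage: ElectrodeMontage) -> dict:
    """Unknown-index patch per electrode; validates pairwise disjointness."""
    mask = sigma.mask
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    patches = {}
    for lab in montage.labels:
        p = electrode_patch(sigma, montage.position_of(lab), montage.radius_mm)
        patches[lab] = idx[tuple(p.T)]
    labs = list(patches)
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            if len(np.intersect1d(patches[a], patches[b])):
                raise ValueError(f"electrode pads {a!r} and {b!r} overlap; "
                                 "reduce the pad radius or spread the montage")
    return patches


def _floating_projection(n: int, float_patches: list[np.ndarray]):
    """Sparse selector merging each floating pad into one super-node.

    Returns (P, supernode_ids): P is (n, n_reduced) with one unit entry per
    row; column ``supernode_ids[k]`` aggregates the k-th pad.
    """
    group = np.arange(n, dtype=np.int64)
    for k, p in enumerate(float_patches):
        group[p] = n + k
    uniq, inv = np.unique(group, return_inverse=True)
    P = sparse.coo_matrix((np.ones(n), (np.arange(n), inv)),
                          shape=(n, len(uniq))).tocsr()
    supernode = np.searchsorted(uniq, n + np.arange(len(float_patches)))
    return P, supernode


def _solve_system(A, b, free, fixed_vals, n, tol, maxiter):
    """Solve A phi = source with Dirichlet values fixed; returns full phi vector."""
    phi = fixed_vals.copy()
    Af = A[free][:, free]
    rhs = b[free] - A[free][:, ~free] @ fixed_vals[~free]
    d = Af.diagonal()
    d = np.where(d > 0, d, 1.0)
    M = sparse.diags(1.0 / d)
    x, info = cg(Af, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(Af @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if info > 0 and res > 10 * tol:
        raise RuntimeError(f"CG failed to converge in {maxiter} iterations "
                           f"(relative residual {res:.2e})")
    phi[free] = x
    return phi, res


def solve_potential(
    sigma: TensorField,
    montage: ElectrodeMontage,
    pair: tuple[str, str],
    potentials: tuple[float, float] = (0.5, -0.5),
    tol: float = 1e-8,
    maxiter: int = 10_000,
) -> PotentialSolution:
    """Solve the electroquasistatic problem for one driven electrode pair.

    The two driven pads are Dirichlet equipotential patches at
    ``potentials`` volts; every other montage electrode is a floating
    perfect conductor (equipotential, zero net current); remaining
    boundaries are zero-flux.  The injected current is obtained by summing
    the discrete face fluxes out of the positive patch.
    """
    A, idx, n = _assemble(sigma)
    patches = _montage_patches(sigma, montage)
    for lab in pair:
        if lab not in patches:
            raise KeyError(f"electrode {lab!r} not in montage")
    floating = [patches[lab] for lab in montage.labels if lab not in pair]
    P, _ = _floating_projection(n, floating)
    A_red = (P.T @ A @ P).tocsr()
    n_red = A_red.shape[0]
    red_of = np.asarray(P.argmax(axis=1)).ravel()  # unknown -> reduced index

    fixed = np.zeros(n_red, bool)
    vals = np.zeros(n_red)
    for lab, v in zip(pair, potentials):
        r = red_of[patches[lab]]
        fixed[r] = True
        vals[r] = v

    phi_red, res = _solve_system(A_red, np.zeros(n_red), ~fixed, vals,
                                 n_red, tol, maxiter)
    phi_vec = P @ phi_red

    flux = A @ phi_vec
    i_pos = float(flux[patches[pair[0]]].sum())
    i_neg = float(flux[patches[pair[1]]].sum())

    phi = np.full(sigma.mask.shape, np.nan)
    phi[sigma.mask] = phi_vec
    return PotentialSolution(
        phi=phi,
        drive={"pair": pair, "potentials": potentials,
               "current_pos_A": i_pos, "current_neg_A": i_neg,
               # per-voxel injected-current distribution of each pad: the
               # adjoint readout weights of an equipotential electrode
               "patch_idx": (patches[pair[0]], patches[pair[1]]),
               "patch_weights": (flux[patches[pair[0]]] / i_pos,
                                 flux[patches[pair[1]]] / i_neg)},
        residual=res,
        injected_current=i_pos,
        mask=sigma.mask,
        spacing_mm=np.asarray(sigma.spacing, float),
        origin_mm=np.asarray(sigma.origin, float),
    )


def efield_from_potential(phi: np.ndarray, spacing_mm, mask: np.ndarray) -> np.ndarray:
    """E = -grad phi in V/m: central differences interior, one-sided at the
    tissue boundary, zero outside the conducting domain."""
    h = np.asarray(spacing_mm, float) * _MM
    E = np.zeros((3,) + phi.shape)
    p = np.where(mask, phi, 0.0)
    for a in range(3):
        lo = np.zeros_like(mask); hi = np.zeros_like(mask)
        sl_dst = [slice(None)] * 3; sl_src = [slice(None)] * 3
        sl_dst[a] = slice(1, None); sl_src[a] = slice(None, -1)
        lo[tuple(sl_dst)] = mask[tuple(sl_src)]
        p_lo = np.zeros_like(p); p_lo[tuple(sl_dst)] = p[tuple(sl_src)]
        sl_dst2 = [slice(None)] * 3; sl_src2 = [slice(None)] * 3
        sl_dst2[a] = slice(None, -1); sl_src2[a] = slice(1, None)
        hi[tuple(sl_dst2)] = mask[tuple(sl_src2)]
        p_hi = np.zeros_like(p); p_hi[tuple(sl_dst2)] = p[tuple(sl_src2)]

        both = mask & lo & hi
        E[a][both] = -(p_hi[both] - p_lo[both]) / (2 * h[a])
        fwd = mask & hi & ~lo
        E[a][fwd] = -(p_hi[fwd] - p[fwd]) / h[a]
        bwd = mask & lo & ~hi
        E[a][bwd] = -(p[bwd] - p_lo[bwd]) / h[a]
    return E


def compute_field_basis(
    sigma: TensorField,
    montage: ElectrodeMontage,
    reference: str | None = None,
    tol: float = 1e-8,
    maxiter: int = 10_000,
    dtype=np.float64,
) -> EFieldBasis:
    """One solve per non-reference electrode, each rescaled to 1 mA.

    The reference electrode's entry is the zero field; superposition then
    yields any pair's unit-current field as a basis difference.
    """
    if len(montage.labels) < 2:
        raise ValueError("montage must contain at least 2 electrodes")
    ref = reference or montage.reference
    if ref not in montage.labels:
        raise ValueError(f"reference {ref!r} not in montage")
    shape = sigma.mask.shape
    fields = np.zeros((len(montage.labels), 3) + shape, dtype=dtype)
    meta = {"tol": tol, "solves": {}}
    for i, lab in enumerate(montage.labels):
        if lab == ref:
            continue
        try:
            sol = solve_potential(sigma, montage, (lab, ref), tol=tol, maxiter=maxiter)
        except Exception as exc:
            raise RuntimeError(f"basis solve failed for electrode {lab!r}: {exc}") from exc
        E = efield_from_potential(sol.phi, sol.spacing_mm, sol.mask)
        fields[i] = (1e-3 / sol.injected_current) * E
        meta["solves"][lab] = {"residual": sol.residual,
                               "injected_current_A": sol.injected_current,
                               "patch_idx": sol.drive["patch_idx"],
                               "patch_weights": sol.drive["patch_weights"]}
    return EFieldBasis(
        labels=list(montage.labels), reference=ref, fields=fields,
        mask=sigma.mask, spacing_mm=np.asarray(sigma.spacing, float),
        origin_mm=np.asarray(sigma.origin, float), meta=meta,
    )


def sample_field(field: np.ndarray, spacing_mm, origin_mm, points_mm) -> np.ndarray:
    """Trilinear interpolation of a (3, nx, ny, nz) vector volume at mm points."""
    pts = (np.asarray(points_mm, float) - origin_mm) / spacing_mm
    out = np.empty((len(pts), 3))
    for c in range(3):
        out[:, c] = map_coordinates(field[c], pts.T, order=1, mode="nearest")
    return out


def leadfield_reciprocity(basis: EFieldBasis, mesh: CorticalMesh) -> LeadFieldMatrix:
    """EEG lead field from the electrode E-field basis via reciprocity.

    Entry (e, l) is ``-E_e(r_l) . n_l / I_e``: the unit-current basis field
    of electrode e, trilinearly interpolated at vertex l and projected on
    the cortical normal, per drive current — V per unit normal dipole
    moment (A*m), with the sign such that a dipole pointing toward an
    electrode raises its potential (``V = LF @ m``).
    """
    vox = (mesh.vertices - basis.origin_mm) / basis.spacing_mm
    ivox = np.clip(np.round(vox).astype(int), 0, np.array(basis.mask.shape) - 1)
    inside = basis.mask[tuple(ivox.T)]
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        raise ValueError(f"mesh vertices outside the conducting domain: {bad.tolist()[:20]}"
                         + ("..." if len(bad) > 20 else ""))
    n_el = len(basis.labels)
    lf = np.zeros((n_el, mesh.n_vertices))
    for i in range(n_el):
        if basis.labels[i] == basis.reference:
            continue
        Ev = sample_field(basis.fields[i], basis.spacing_mm, basis.origin_mm, mesh.vertices)
        lf[i] = -np.einsum("ij,ij->i", Ev, mesh.normals) / basis.unit_current_A
    return LeadFieldMatrix(matrix=lf, labels=list(basis.labels), reference=basis.reference)


def solve_dipole_direct(
    sigma: TensorField,
    montage: ElectrodeMontage,
    vertex_mm,
    normal,
    moment_Am: float = 1e-9,
    tol: float = 1e-8,
    maxiter: int = 20_000,
) -> np.ndarray:
    """Direct dipole forward solve (independent check of the reciprocity LF).

    Realizes the dipole as three axis-aligned monopole pairs centered on
    the voxel nearest the source (so the moment is exactly ``m * n``),
    solves the current-source problem with every montage pad present as a
    floating equipotential conductor (one far voxel pinned to fix the
    gauge), and reads each pad's super-node potential.  Returns one
    potential per montage electrode, referenced to the montage reference.
    """
    A, idx, n = _assemble(sigma)
    h_mm = np.asarray(sigma.spacing, float)
    nrm = np.asarray(normal, float)
    nrm = nrm / np.linalg.norm(nrm)
    # center the dipole on the nearest voxel and realize the oblique moment
    # as a superposition of three axis-aligned two-monopole dipoles
    v0 = np.round((np.asarray(vertex_mm, float) - sigma.origin) / h_mm).astype(int)
    b = np.zeros(n)
    for ax in range(3):
        if abs(nrm[ax]) < 1e-12:
            continue
        I = moment_Am * nrm[ax] / (2.0 * h_mm[ax] * _MM)  # separation 2 h
        for d, s in ((+1, +I), (-1, -I)):
            v = v0.copy()
            v[ax] += d
            j = idx[tuple(v)]
            if j < 0:
                raise ValueError("dipole endpoint outside the conducting domain")
            b[j] += s

    patches = _montage_patches(sigma, montage)
    P, supernode = _floating_projection(n, [patches[lab] for lab in montage.labels])
    A_red = (P.T @ A @ P).tocsr()
    b_red = P.T @ b
    n_red = A_red.shape[0]
    red_of = np.asarray(P.argmax(axis=1)).ravel()

    ii = np.argwhere(sigma.mask)
    far = idx[tuple(ii[np.argmax(np.linalg.norm(ii - v0, axis=1))])]
    fixed = np.zeros(n_red, bool)
    fixed[red_of[far]] = True
    phi_red, _ = _solve_system(A_red, b_red, ~fixed, np.zeros(n_red), n_red,
                               tol, maxiter)

    out = np.array([phi_red[supernode[i]] for i in range(len(montage.labels))])
    return out - out[montage.index_of(montage.reference)]
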