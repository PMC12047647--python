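"""Synthetic volume-conductor head phantoms and derived geometry.

This module generates every geometric input the rest of the pipeline needs,
without any imaging data: a voxelized multi-shell spherical head phantom
(scalp / skull / CSF / GM / WM with realistic conductivity contrasts), scalp
landmarks (nasion, inion, pre-auricular points), a 10-10 electrode montage
constructed by geodesic subdivision of the scalp surface, a quasi-uniform
cortical surface mesh with outward normals, and a bi-hemispheric
distance-dependent structural connectome.

Coordinate convention (used everywhere in the package): right-handed RAS,
millimeters, 0-based voxel indices, world = origin + index * spacing
(voxel centers). +x is right, +y anterior (nasion), +z superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import marching_cubes
from scipy.ndimage import gaussian_filter

__all__ = [
    "TissuePhantom",
    "CorticalMesh",
    "Connectome",
    "ElectrodeMontage",
    "DEFAULT_RADII_MM",
    "DEFAULT_CONDUCTIVITIES",
    "DEFAULT_TISSUE_NAMES",
    "build_sphere_phantom",
    "place_electrodes_1010",
    "tessellate_cortex",
    "synth_connectome",
    "scalp_surface_mesh",
    "region_sectors",
]

#: Default 5-shell phantom, outer to inner.  Radii span an adult head;
#: conductivities follow low-frequency literature values (S/m): scalp 0.4,
#: cortical bone 0.01, CSF 1.8, grey matter 0.3, white matter 0.15.
DEFAULT_RADII_MM = (92.0, 86.0, 80.0, 78.0, 70.0)
DEFAULT_CONDUCTIVITIES = (0.4, 0.01, 1.8, 0.3, 0.15)
DEFAULT_TISSUE_NAMES = ("scalp", "skull", "csf", "gm", "wm")

#: Electrode pad area 3 cm^2 -> radius in mm.
DEFAULT_ELECTRODE_RADIUS_MM = float(np.sqrt(300.0 / np.pi))


@dataclass
class TissuePhantom:
    """Voxelized volume conductor: label volume + tissue table + landmarks.

    ``labels`` is an integer volume (0 = air / outside); ``tissue_table``
    maps each nonzero label to ``(name, conductivity S/m)``.  ``landmarks``
    holds the four scalp fiducials used for electrode placement.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    tissue_table: dict[int, tuple[str, float]]
    landmarks: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index -> world mm (voxel center)."""
        return self.origin + np.asarray(idx, float) * self.spacing

    def voxel_index(self, xyz: np.ndarray) -> np.ndarray:
        """World mm -> fractional voxel index."""
        return (np.asarray(xyz, float) - self.origin) / self.spacing

    def label_of(self, name: str) -> int:
        for lab, (nm, _) in self.tissue_table.items():
            if nm == name:
                return lab
        raise KeyError(f"no tissue named {name!r} in tissue table")

    def sigma_of_label(self, lab: int) -> float:
        if lab not in self.tissue_table:
            raise KeyError(f"label {lab} missing from tissue table")
        return self.tissue_table[lab][1]


@dataclass
class CorticalMesh:
    """Triangulated cortical surface with per-vertex outward normals."""

    vertices: np.ndarray      # (n, 3) mm
    triangles: np.ndarray     # (m, 3) int
    normals: np.ndarray       # (n, 3) unit
    region_of_vertex: np.ndarray  # (n,) int region ids

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class Connectome:
    """Region-wise structural connectivity (weights, tract lengths, centroids)."""

    weights: np.ndarray   # (n, n) nonneg, symmetric, zero diagonal
    lengths: np.ndarray   # (n, n) mm
    centroids: np.ndarray  # (n, 3) mm
    names: list[str]
    hemisphere: np.ndarray  # (n,) 0 = left, 1 = right

    @property
    def n_regions(self) -> int:
        return len(self.weights)


@dataclass
class ElectrodeMontage:
    """Named scalp electrodes: 10-10 labels, centers (mm) and pad radius."""

    labels: list[str]
    positions: np.ndarray  # (n, 3) mm, on the scalp surface
    radius_mm: float
    reference: str

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.index_of(label)]


# ---------------------------------------------------------------------------
# Phantom construction


def build_sphere_phantom(
    radii_mm=DEFAULT_RADII_MM,
    conductivities=DEFAULT_CONDUCTIVITIES,
    spacing: float = 2.0,
    seed: int = 0,
    names=None,
) -> TissuePhantom:
    """Build a nested concentric-shell phantom on a symmetric voxel grid.

    Shells are listed outer to inner (strictly decreasing radii) and are
    labeled 1..K outer to inner.  Landmarks are placed on the equator of the
    outer shell: nasion (0,+R,0), inion (0,-R,0), pre-auricular left/right
    (-+R,0,0).  The grid is centered on the origin so the phantom is exactly
    mirror-symmetric, and ``spacing`` must resolve every shell with at least
    one voxel.
    """
    radii = np.asarray(radii_mm, float)
    sig = np.asarray(conductivities, float)
    if len(radii) != len(sig):
        raise ValueError("radii and conductivities must have equal length")
    if np.any(np.diff(radii) >= 0):
        raise ValueError(f"shell radii must be strictly decreasing outer->inner, got {radii.tolist()}")
    if names is None:
        names = list(DEFAULT_TISSUE_NAMES[: len(radii)])
        names += [f"tissue{i}" for i in range(len(names), len(radii))]
    thickness = -np.diff(radii)
    for i, th in enumerate(thickness):
        if th < spacing:
            raise ValueError(
                f"shell {names[i + 1]!r} is {th:g} mm thick, thinner than one "
                f"voxel at spacing {spacing:g} mm"
            )

    R = radii[0]
    half = int(np.floor(R / spacing)) + 1
    n = 2 * half + 1
    sp = np.full(3, float(spacing))
    origin = -sp * half
    ax = (np.arange(n) - half) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    rr = np.sqrt(X**2 + Y**2 + Z**2)

    labels = np.zeros((n, n, n), dtype=np.int16)
    for k, rk in enumerate(radii):          # outer to inner; inner overwrites
        labels[rr <= rk] = k + 1

    table = {k + 1: (names[k], float(sig[k])) for k in range(len(radii))}
    landmarks = {
        "nasion": np.array([0.0, R, 0.0]),
        "inion": np.array([0.0, -R, 0.0]),
        "lpa": np.array([-R, 0.0, 0.0]),
        "rpa": np.array([R, 0.0, 0.0]),
    }
    return TissuePhantom(
        labels=labels, spacing=sp, origin=origin, tissue_table=table,
        landmarks=landmarks, meta={"radii_mm": radii.tolist(), "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# Scalp surface and geodesic machinery


def scalp_surface_mesh(phantom: TissuePhantom) -> trimesh.Trimesh:
    """Extract a smooth triangulated scalp (outer tissue boundary) surface.

    The binary head mask is smoothed with a one-voxel Gaussian before
    marching cubes so the isosurface is smooth enough for geodesic length
    measurements; the 0.5 level keeps it within a voxel of the true boundary.
    """
    mask = (phantom.labels > 0).astype(np.float32)
    smooth = gaussian_filter(mask, sigma=1.0)
    verts, faces, _, _ = marching_cubes(smooth, level=0.5, spacing=tuple(phantom.spacing))
    verts = verts + phantom.origin
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


class _SurfaceGeodesics:
    """Dijkstra shortest paths on a surface mesh's edge graph.

    Graph geodesics on a triangulation slightly overestimate true geodesic
    length, but electrode positions are defined through arc-length
    *fractions* along the same paths, which cancels the systematic part.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.v = np.asarray(mesh.vertices)
        e = np.asarray(mesh.edges_unique)
        w = np.linalg.norm(self.v[e[:, 0]] - self.v[e[:, 1]], axis=1)
        n = len(self.v)
        self.graph = coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        ).tocsr()
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def nearest_vertex(self, xyz) -> int:
        return int(np.argmin(np.linalg.norm(self.v - np.asarray(xyz, float), axis=1)))

    def _solve(self, src: int):
        if src not in self._cache:
            dist, pred = dijkstra(self.graph, indices=src, return_predecessors=True)
            self._cache[src] = (dist, pred)
        return self._cache[src]

    def path(self, src: int, dst: int) -> np.ndarray:
        """Vertex-coordinate polyline of the shortest path src -> dst."""
        _, pred = self._solve(src)
        chain = [dst]
        while chain[-1] != src:
            p = pred[chain[-1]]
            if p < 0:
                raise RuntimeError("surface graph disconnected")
            chain.append(int(p))
        return self.v[np.array(chain[::-1])]


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _point_at_fraction(pts: np.ndarray, frac: float) -> np.ndarray:
    """Point at a given arc-length fraction along a polyline."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.r_[0.0, np.cumsum(seg)]
    target = frac * cum[-1]
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = 0.0 if seg[i] == 0 else (target - cum[i]) / seg[i]
    return pts[i] + t * (pts[i + 1] - pts[i])


# 10-10 montage construction tables.  Each chain runs left -> right or
# anterior -> posterior through a midpoint electrode, with labels at the
# given arc-length fractions of the full chain.
_MIDLINE = [("Fpz", 0.1), ("AFz", 0.2), ("Fz", 0.3), ("FCz", 0.4), ("Cz", 0.5),
            ("CPz", 0.6), ("Pz", 0.7), ("POz", 0.8), ("Oz", 0.9)]
_CORONAL = [("T7", 0.1), ("C5", 0.2), ("C3", 0.3), ("C1", 0.4), ("Cz", 0.5),
            ("C2", 0.6), ("C4", 0.7), ("C6", 0.8), ("T8", 0.9)]
# Ring through Fpz -> left -> Oz -> right -> back, fractions of circumference.
_RING = [("Fp1", 0.05), ("AF7", 0.10), ("F7", 0.15), ("FT7", 0.20), ("T7", 0.25),
         ("TP7", 0.30), ("P7", 0.35), ("PO7", 0.40), ("O1", 0.45), ("Oz", 0.50),
         ("O2", 0.55), ("PO8", 0.60), ("P8", 0.65), ("TP8", 0.70), ("T8", 0.75),
         ("FT8", 0.80), ("F8", 0.85), ("AF8", 0.90), ("Fp2", 0.95)]
# Transverse chains from a left ring electrode through the midline to the
# right ring electrode; inner labels at eighths of the chain.
_CHAINS = {
    ("F7", "Fz", "F8"): [("F5", 0.125), ("F3", 0.25), ("F1", 0.375),
                         ("F2", 0.625), ("F4", 0.75), ("F6", 0.875)],
    ("FT7", "FCz", "FT8"): [("FC5", 0.125), ("FC3", 0.25), ("FC1", 0.375),
                            ("FC2", 0.625), ("FC4", 0.75), ("FC6", 0.875)],
    ("TP7", "CPz", "TP8"): [("CP5", 0.125), ("CP3", 0.25), ("CP1", 0.375),
                            ("CP2", 0.625), ("CP4", 0.75), ("CP6", 0.875)],
    ("P7", "Pz", "P8"): [("P5", 0.125), ("P3", 0.25), ("P1", 0.375),
                         ("P2", 0.625), ("P4", 0.75), ("P6", 0.875)],
    ("AF7", "AFz", "AF8"): [("AF3", 0.25), ("AF4", 0.75)],
    ("PO7", "POz", "PO8"): [("PO3", 0.25), ("PO4", 0.75)],
}


def place_electrodes_1010(
    phantom: TissuePhantom,
    radius_mm: float = DEFAULT_ELECTRODE_RADIUS_MM,
    reference: str = "Cz",
    subset=None,
) -> ElectrodeMontage:
    """Construct the 10-10 electrode system on the phantom scalp.

    Follows the landmark-based construction: the vertex Cz is found
    iteratively as the common midpoint of the nasion-inion and
    pre-auricular geodesics on the scalp surface; the midline, coronal and
    circumferential chains are then subdivided at 10% (5% on the ring)
    arc-length increments, and transverse chains fill in the remaining
    positions.  ``subset`` restricts the returned montage to the given
    labels (e.g. the 19-channel 10-20 subset) without changing positions.
    """
    lm = phantom.landmarks
    required = ("nasion", "inion", "lpa", "rpa")
    if any(k not in lm for k in required):
        raise ValueError(f"phantom must define landmarks {required}")
    nas, ini, lpa, rpa = (np.asarray(lm[k], float) for k in required)
    up = np.cross(rpa - lpa, nas - ini)
    nrm = np.linalg.norm(up)
    if nrm < 1e-9 * np.linalg.norm(nas - ini) * np.linalg.norm(rpa - lpa):
        raise ValueError("degenerate (collinear) landmarks")
    up = up / nrm

    surf = scalp_surface_mesh(phantom)
    geo = _SurfaceGeodesics(surf)
    i_nas, i_ini = geo.nearest_vertex(nas), geo.nearest_vertex(ini)
    i_lpa, i_rpa = geo.nearest_vertex(lpa), geo.nearest_vertex(rpa)

    center = np.mean([nas, ini, lpa, rpa], axis=0)
    # Initial Cz: surface vertex most aligned with the superior direction.
    i_cz = int(np.argmax((geo.v - center) @ up / np.linalg.norm(geo.v - center, axis=1)))
    for _ in range(6):
        sag = np.vstack([geo.path(i_nas, i_cz), geo.path(i_cz, i_ini)[1:]])
        i_new = geo.nearest_vertex(_point_at_fraction(sag, 0.5))
        cor = np.vstack([geo.path(i_lpa, i_new), geo.path(i_new, i_rpa)[1:]])
        i_cor = geo.nearest_vertex(_point_at_fraction(cor, 0.5))
        if i_cor == i_cz:
            break
        i_cz = i_cor

    pos: dict[str, np.ndarray] = {}

    def via(a: int, mid: int, b: int) -> np.ndarray:
        return np.vstack([geo.path(a, mid), geo.path(mid, b)[1:]])

    sag = via(i_nas, i_cz, i_ini)
    for lab, f in _MIDLINE:
        pos[lab] = _point_at_fraction(sag, f)
    cor = via(i_lpa, i_cz, i_rpa)
    for lab, f in _CORONAL:
        pos.setdefault(lab, _point_at_fraction(cor, f))

    # Circumferential ring through Fpz (front), T7 (left), Oz (back), T8.
    i_fpz, i_oz = geo.nearest_vertex(pos["Fpz"]), geo.nearest_vertex(pos["Oz"])
    i_t7, i_t8 = geo.nearest_vertex(pos["T7"]), geo.nearest_vertex(pos["T8"])
    left_half = np.vstack([geo.path(i_fpz, i_t7), geo.path(i_t7, i_oz)[1:]])
    right_half = np.vstack([geo.path(i_oz, i_t8), geo.path(i_t8, i_fpz)[1:]])
    len_l, len_r = _polyline_length(left_half), _polyline_length(right_half)
    total = len_l + len_r
    for lab, f in _RING:
        s = f * total
        if s <= len_l:
            p = _point_at_fraction(left_half, s / len_l)
        else:
            p = _point_at_fraction(right_half, (s - len_l) / len_r)
        pos.setdefault(lab, p)

    for (la, lm_, lb), inner in _CHAINS.items():
        ia, im, ib = (geo.nearest_vertex(pos[k]) for k in (la, lm_, lb))
        chain = via(ia, im, ib)
        for lab, f in inner:
            pos.setdefault(lab, _point_at_fraction(chain, f))

    labels = list(pos.keys())
    if subset is not None:
        missing = [s for s in subset if s not in pos]
        if missing:
            raise KeyError(f"unknown 10-10 labels requested: {missing}")
        labels = list(subset)
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among montage labels")
    return ElectrodeMontage(
        labels=labels,
        positions=np.array([pos[k] for k in labels]),
        radius_mm=float(radius_mm),
        reference=reference,
    )


# ---------------------------------------------------------------------------
# Cortical mesh and regions


def _icosphere_level(n_vertices: int) -> int:
    # icosphere vertex count at level l is 10*4^l + 2
    lvl = 0
    while 10 * 4**lvl + 2 < n_vertices:
        lvl += 1
    return lvl


def region_sectors(directions: np.ndarray, n_regions: int) -> np.ndarray:
    """Assign unit directions to equal-solid-angle sectors, per hemisphere.

    The sphere is split into left (x<0) and right hemispheres; each
    hemisphere is divided into ``n_regions/2`` approximately equal-area
    sectors by equal-area bands in the polar angle about the +-x pole and
    uniform azimuthal slices within each band.
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even (two hemispheres)")
    m = n_regions // 2
    nb = max(1, int(round(np.sqrt(m / 2))))
    base, extra = divmod(m, nb)
    counts = [base + (1 if b < extra else 0) for b in range(nb)]
    edges = np.r_[0.0, np.cumsum(counts)] / m  # cos-theta band edges, equal area

    d = np.asarray(directions, float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    hemi = (d[:, 0] >= 0).astype(int)  # 0 left, 1 right
    pole_x = np.where(hemi == 1, 1.0, -1.0)
    ct = np.clip(d[:, 0] * pole_x, 0.0, 1.0)  # cos angle from hemisphere pole
    band = np.clip(np.searchsorted(edges, ct, side="right") - 1, 0, nb - 1)
    phi = np.mod(np.arctan2(d[:, 2], d[:, 1]), 2 * np.pi)
    out = np.empty(len(d), dtype=int)
    offs = np.r_[0, np.cumsum(counts)]
    for b in range(nb):
        sel = band == b
        sec = np.minimum((phi[sel] / (2 * np.pi) * counts[b]).astype(int), counts[b] - 1)
        out[sel] = offs[b] + sec
    return out + hemi * m


def sector_centroids(n_regions: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Representative center direction of each sector, scaled to ``radius``.

    Returns (centroids (n,3), hemisphere (n,)).  Mirror-symmetric between
    hemispheres by construction.
    """
    m = n_regions // 2
    nb = max(1, int(round(np.sqrt(m / 2))))
    base, extra = divmod(m, nb)
    counts = [base + (1 if b < extra else 0) for b in range(nb)]
    edges = np.r_[0.0, np.cumsum(counts)] / m
    cents = []
    for side, pole in ((0, -1.0), (1, 1.0)):
        for b in range(nb):
            ct_mid = 0.5 * (edges[b] + edges[b + 1])
            st = np.sqrt(1 - ct_mid**2)
            for s in range(counts[b]):
                phi = 2 * np.pi * (s + 0.5) / counts[b]
                cents.append([pole * ct_mid, st * np.cos(phi), st * np.sin(phi)])
    c = np.asarray(cents) * radius
    hemi = np.r_[np.zeros(m, int), np.ones(m, int)]
    # order: left block then right block, matching region_sectors ids
    return c, hemi


def tessellate_cortex(phantom: TissuePhantom, n_vertices: int = 162,
                      n_regions: int = 84, seed: int = 0) -> CorticalMesh:
    """Quasi-uniform icosphere triangulation of the mid-GM surface.

    Vertices sit on the sphere midway through the grey-matter shell, with
    radial outward normals; each vertex is assigned to one of ``n_regions``
    equal-solid-angle sectors (two hemispheric blocks) so surface nodes can
    be aggregated to connectome regions.
    """
    if n_vertices < 12:
        raise ValueError("n_vertices must be >= 12")
    radii = phantom.meta.get("radii_mm")
    gm = phantom.label_of("gm")
    if radii is None or gm >= len(radii) + 1:
        raise ValueError("phantom lacks a GM shell")
    r_mid = 0.5 * (radii[gm - 1] + radii[gm])  # outer and inner GM radii
    ico = trimesh.creation.icosphere(subdivisions=_icosphere_level(n_vertices), radius=1.0)
    verts = np.asarray(ico.vertices)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return CorticalMesh(
        vertices=normals * r_mid,
        triangles=np.asarray(ico.faces),
        normals=normals,
        region_of_vertex=region_sectors(normals, n_regions),
    )


# ---------------------------------------------------------------------------
# Synthetic connectome


def synth_connectome(
    n_regions: int = 84,
    decay_mm: float = 40.0,
    interhemispheric_scale: float = 0.5,
    seed: int = 0,
    radius_mm: float = 74.0,
    jitter_sigma: float = 0.5,
    normalize: bool = True,
) -> Connectome:
    """Bi-hemispheric distance-dependent synthetic structural connectome.

    Region centroids are the equal-solid-angle sector centers on a sphere of
    ``radius_mm`` (matching :func:`tessellate_cortex`).  Weights follow
    ``exp(-d_ij / decay_mm)``, attenuated by ``interhemispheric_scale`` for
    cross-hemisphere pairs and multiplied by seeded symmetric log-normal
    jitter; tract lengths are the Euclidean centroid distances.  When
    ``normalize`` is set, weights are globally rescaled to unit mean row sum
    so the global coupling G acts on a defined scale.
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even")
    if decay_mm <= 0:
        raise ValueError("decay_mm must be positive")
    rng = np.random.default_rng(seed)
    cents, hemi = sector_centroids(n_regions, radius_mm)
    d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
    w = np.exp(-d / decay_mm)
    cross = hemi[:, None] != hemi[None, :]
    w = w * np.where(cross, interhemispheric_scale, 1.0)
    jit = np.exp(jitter_sigma * rng.standard_normal((n_regions, n_regions)))
    jit = np.sqrt(jit * jit.T)  # symmetric log-normal, median 1
    w = w * jit
    np.fill_diagonal(w, 0.0)
    if normalize and w.sum() > 0:
        w = w / w.sum(axis=1).mean()
    names = [f"{'L' if h == 0 else 'R'}{i % (n_regions // 2):02d}" for i, h in enumerate(hemi)]
    return Connectome(weights=w, lengths=d, centroids=cents, names=names, hemisphere=hemi)
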