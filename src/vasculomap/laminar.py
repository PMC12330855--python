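"""Equivolumetric cortical layers, the superficial-white-matter offset
surface, ribbon-constrained volume-to-surface sampling and surface
gradients.

White and pial meshes must share vertex count and topology (the output of
any correspondence-preserving surface pipeline); all geometry lives in a
shared scanner-mm frame with voxel↔mm conversion through the NIfTI affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .meshes import SurfaceMesh

__all__ = [
    "LAYER_NAMES",
    "LayerStack",
    "SWMSurface",
    "equivolumetric_layers",
    "equivolume_fraction",
    "offset_surface",
    "ribbon_sample",
    "surface_gradient",
]

log = logging.getLogger(__name__)

#: Layer names ordered pial -> white, mirroring anatomical lamina labels.
LAYER_NAMES = tuple(f"EL{i}{s}" for i in range(1, 7) for s in ("a", "b"))

SWM_OFFSET_MM = 0.32


@dataclass
class LayerStack:
    """13 per-vertex boundary depth fractions delimiting 12 layers.

    ``fractions[:, j]`` is the depth fraction (0 = white surface, 1 = pial)
    of boundary j; ``layer_surfaces`` interpolate white→pial coordinates at
    those fractions.  Layer j sits between boundaries j and j+1.
    """

    fractions: np.ndarray  # (n_vertices, n_layers + 1), increasing 0 -> 1
    names: tuple[str, ...]
    layer_surfaces: list[SurfaceMesh]
    fallback_vertices: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_layers(self) -> int:
        return self.fractions.shape[1] - 1

    def midlayer_fraction(self, name: str) -> np.ndarray:
        """Per-vertex mid-slab depth fraction for a named layer."""
        j = self.names.index(name)
        # names run pial->white, fractions run white->pial
        lo = self.fractions[:, self.n_layers - 1 - j]
        hi = self.fractions[:, self.n_layers - j]
        return 0.5 * (lo + hi)


@dataclass
class SWMSurface:
    mesh: SurfaceMesh
    distance_mm: float
    n_flipped_faces: int = 0  # crude self-intersection indicator


def equivolume_fraction(alpha: np.ndarray, area_white: np.ndarray,
                        area_pial: np.ndarray) -> np.ndarray:
    """Depth fraction r (0 = white, 1 = pial) enclosing cumulative volume
    fraction ``alpha`` of a truncated-prism column.

    r(α) = (-A_w + sqrt(α A_p² + (1-α) A_w²)) / (A_p - A_w), reducing to the
    equidistant limit r = α when A_p = A_w.
    """
    alpha = np.asarray(alpha, dtype=float)
    aw = np.asarray(area_white, dtype=float)
    ap = np.asarray(area_pial, dtype=float)
    diff = ap - aw
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (-aw + np.sqrt(alpha * ap**2 + (1 - alpha) * aw**2)) / diff
    # equidistant limit when areas (nearly) equal
    near = np.abs(diff) <= 1e-9 * np.maximum(aw, ap)
    return np.where(near, alpha, r)


def equivolumetric_layers(white: SurfaceMesh, pial: SurfaceMesh,
                          n_layers: int = 12) -> LayerStack:
    """Equivolumetric layering between corresponding white/pial surfaces.

    Boundary fractions per vertex solve the equivolume rule with the local
    white and pial vertex areas; vertices with non-positive area fall back to
    equidistant spacing with a logged warning.
    """
    if white.n_vertices != pial.n_vertices:
        raise ValueError("white and pial must share vertex count")
    if n_layers == 12:
        names = LAYER_NAMES
    else:
        names = tuple(f"L{i}" for i in range(1, n_layers + 1))
    aw = white.vertex_areas
    ap = pial.vertex_areas
    bad = (aw <= 0) | (ap <= 0) | ~np.isfinite(aw) | ~np.isfinite(ap)
    if bad.any():
        log.warning("equivolume fallback to equidistant at %d vertices", bad.sum())
    alphas = np.linspace(0.0, 1.0, n_layers + 1)
    fractions = np.empty((white.n_vertices, n_layers + 1))
    for j, a in enumerate(alphas):
        r = equivolume_fraction(a, aw, ap)
        r = np.where(bad, a, r)
        fractions[:, j] = r
    fractions[:, 0] = 0.0
    fractions[:, -1] = 1.0
    surfaces = [
        SurfaceMesh(white.vertices + fractions[:, j, None] * (pial.vertices - white.vertices),
                    white.faces)
        for j in range(n_layers + 1)
    ]
    return LayerStack(fractions=fractions, names=names, layer_surfaces=surfaces,
                      fallback_vertices=bad)


def offset_surface(white: SurfaceMesh, distance_mm: float = SWM_OFFSET_MM) -> SWMSurface:
    """Displace the white surface inward along its (pial-ward) normals.

    Self-intersections are not repaired; the count of faces whose normal
    flips is reported as a degeneracy indicator.
    """
    displaced = SurfaceMesh(white.vertices - distance_mm * white.vertex_normals,
                            white.faces)
    fn0, _ = white.face_normals_areas()
    fn1, _ = displaced.face_normals_areas()
    flipped = int(((fn0 * fn1).sum(axis=1) < 0).sum())
    if flipped:
        log.warning("offset surface has %d flipped faces (self-intersection likely)",
                    flipped)
    return SWMSurface(mesh=displaced, distance_mm=distance_mm,
                      n_flipped_faces=flipped)


def ribbon_sample(volume: np.ndarray, inner: SurfaceMesh, outer: SurfaceMesh,
                  affine: np.ndarray | None = None,
                  n_sub: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Ribbon-constrained volume-to-surface mapping.

    Per vertex, voxel values are averaged with weights equal to the
    fractional occupancy of the wedge between the corresponding inner and
    outer patches, estimated by ``n_sub``³ corner subsampling of each
    candidate voxel.  The wedge is approximated as the capsule around the
    inner→outer vertex segment whose radius derives from the local vertex
    area (a column of equivalent cross-section).  Vertices with an empty
    wedge get the nearest voxel's value and a flag.

    Returns (values, flagged) per vertex.
    """
    if inner.n_vertices != outer.n_vertices:
        raise ValueError("inner and outer must share vertex count")
    volume = np.asarray(volume, dtype=float)
    if affine is None:
        affine = np.eye(4)
    inv = np.linalg.inv(affine)
    vsize = float(np.cbrt(abs(np.linalg.det(affine[:3, :3]))))

    a_mm = inner.vertices
    b_mm = outer.vertices
    radius = np.sqrt(np.maximum(0.5 * (inner.vertex_areas + outer.vertex_areas), 1e-12) / np.pi)
    radius = np.maximum(radius, 0.5 * vsize)

    # subvoxel corner offsets in voxel units
    offs = (np.stack(np.meshgrid(*([np.arange(n_sub)] * 3), indexing="ij"), axis=-1)
            .reshape(-1, 3) + 0.5) / n_sub - 0.5

    values = np.empty(inner.n_vertices)
    flagged = np.zeros(inner.n_vertices, dtype=bool)
    shape = np.array(volume.shape)

    def to_vox(p):
        return p @ inv[:3, :3].T + inv[:3, 3]

    a_vox = to_vox(a_mm)
    b_vox = to_vox(b_mm)
    r_vox = radius / vsize

    for i in range(inner.n_vertices):
        a, b, r = a_vox[i], b_vox[i], r_vox[i]
        lo = np.clip(np.floor(np.minimum(a, b) - r - 1).astype(int), 0, shape - 1)
        hi = np.clip(np.ceil(np.maximum(a, b) + r + 1).astype(int), 0, shape - 1)
        grids = np.meshgrid(*[np.arange(lo[k], hi[k] + 1) for k in range(3)],
                            indexing="ij")
        centers = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        if centers.size == 0:
            flagged[i] = True
            values[i] = _nearest_voxel(volume, 0.5 * (a + b), shape)
            continue
        sub = centers[:, None, :] + offs[None, :, :]  # (n_vox, n_sub^3, 3)
        ab = b - a
        ab2 = float(ab @ ab)
        if ab2 <= 1e-18:
            # degenerate wedge: inner == outer
            flagged[i] = True
            values[i] = _nearest_voxel(volume, a, shape)
            continue
        t = ((sub - a) @ ab) / ab2
        proj = a + np.clip(t, 0.0, 1.0)[..., None] * ab
        dist = np.linalg.norm(sub - proj, axis=-1)
        inside = (t >= 0.0) & (t <= 1.0) & (dist <= r)
        w = inside.mean(axis=1)
        if w.sum() <= 0:
            flagged[i] = True
            values[i] = _nearest_voxel(volume, 0.5 * (a + b), shape)
            continue
        vals = volume[grids[0].ravel(), grids[1].ravel(), grids[2].ravel()]
        values[i] = float((w * vals).sum() / w.sum())
    return values, flagged


def _nearest_voxel(volume: np.ndarray, p_vox: np.ndarray, shape: np.ndarray) -> float:
    idx = np.clip(np.round(p_vox).astype(int), 0, shape - 1)
    return float(volume[tuple(idx)])


def surface_gradient(metric: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex magnitude of the tangential gradient of a vertex metric.

    The gradient of the linear interpolant is constant per triangle and lies
    in the triangle plane; per-vertex magnitudes are area-weighted averages
    over incident triangles.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.shape != (mesh.n_vertices,):
        raise ValueError("metric must be per-vertex")
    v = mesh.vertices
    f = mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    m0, m1, m2 = metric[f[:, 0]], metric[f[:, 1]], metric[f[:, 2]]
    e1 = p1 - p0
    e2 = p2 - p0
    n = np.cross(e1, e2)
    n2 = (n**2).sum(axis=1)
    n2 = np.maximum(n2, 1e-300)
    # gradient of linear interpolant: ((m1-m0) e2×n + (m2-m0) n×e1) / |n|^2
    grad = ((m1 - m0)[:, None] * np.cross(e2, n)
            + (m2 - m0)[:, None] * np.cross(n, e1)) / n2[:, None]
    gmag = np.linalg.norm(grad, axis=1)
    _, fa = mesh.face_normals_areas()
    acc = np.zeros(mesh.n_vertices)
    wacc = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(acc, f[:, k], gmag * fa)
        np.add.at(wacc, f[:, k], fa)
    wacc[wacc == 0] = 1.0
    return acc / wacc
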