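"""Triangle surface meshes with per-vertex normals and areas.

Meshes are plain vertex/face arrays in a shared scanner-mm frame.  White and
pial surfaces produced by the phantom generator (and expected from real
surface pipelines) share vertex count and topology, so laminar operations can
work vertex-by-vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurfaceMesh", "make_grid_sheet_mesh"]


@dataclass
class SurfaceMesh:
    """Triangle mesh with cached per-vertex outward normals and areas.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray
    _normals: np.ndarray | None = field(default=None, repr=False)
    _areas: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit face normals and face areas."""
        v = self.vertices
        f = self.faces
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        cr = np.cross(e1, e2)
        nrm = np.linalg.norm(cr, axis=1)
        areas = 0.5 * nrm
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.where(nrm[:, None] > 0, cr / np.maximum(nrm, 1e-300)[:, None], 0.0)
        return normals, areas

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals."""
        if self._normals is None:
            fn, fa = self.face_normals_areas()
            acc = np.zeros_like(self.vertices)
            w = fn * fa[:, None]
            for k in range(3):
                np.add.at(acc, self.faces[:, k], w)
            nrm = np.linalg.norm(acc, axis=1)
            nrm[nrm == 0] = 1.0
            self._normals = acc / nrm[:, None]
        return self._normals

    @property
    def vertex_areas(self) -> np.ndarray:
        """One third of the incident triangle areas per vertex."""
        if self._areas is None:
            _, fa = self.face_normals_areas()
            acc = np.zeros(self.n_vertices)
            for k in range(3):
                np.add.at(acc, self.faces[:, k], fa / 3.0)
            self._areas = acc
        return self._areas

    def translated(self, offset: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset, dtype=float), self.faces)

    def displaced(self, displacement: np.ndarray) -> "SurfaceMesh":
        """New mesh with per-vertex displacement added (same topology)."""
        return SurfaceMesh(self.vertices + displacement, self.faces)

    def subdivide(self, n: int = 1) -> "SurfaceMesh":
        """Loop-style midpoint subdivision (linear, no smoothing), n times."""
        mesh = self
        for _ in range(n):
            mesh = _midpoint_subdivide(mesh)
        return mesh


def _midpoint_subdivide(mesh: SurfaceMesh) -> SurfaceMesh:
    v, f = mesh.vertices, mesh.faces
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    midx = len(v) + np.arange(len(uniq))
    e01, e12, e20 = (midx[inv[i * len(f):(i + 1) * len(f)]] for i in range(3))
    new_faces = np.concatenate([
        np.stack([f[:, 0], e01, e20], axis=1),
        np.stack([f[:, 1], e12, e01], axis=1),
        np.stack([f[:, 2], e20, e12], axis=1),
        np.stack([e01, e12, e20], axis=1),
    ])
    return SurfaceMesh(np.concatenate([v, mid]), new_faces)


def make_grid_sheet_mesh(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, flip: bool = False
) -> SurfaceMesh:
    """Triangulated height-field sheet z(x, y) over a rectangular grid.

    ``x``/``y`` are 1-D coordinate vectors, ``z`` is (len(x), len(y)).
    Faces are oriented so normals point toward +z unless ``flip``.
    """
    nx, ny = len(x), len(y)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    verts = np.stack([xx.ravel(), yy.ravel(), np.asarray(z, float).ravel()], axis=1)
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate([
        np.stack([a, b, c], axis=1),
        np.stack([b, d, c], axis=1),
    ])
    if flip:
        faces = faces[:, ::-1]
    return SurfaceMesh(verts, faces)
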