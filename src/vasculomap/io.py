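"""File I/O helpers: NIfTI volumes, GIFTI surfaces and metrics, TCK
streamlines and CSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import gifti

from .meshes import SurfaceMesh

__all__ = [
    "save_nifti", "load_nifti",
    "save_surface", "load_surface",
    "save_metric", "load_metric",
    "save_tck", "load_tck",
]


def save_nifti(path: str | Path, volume: np.ndarray,
               affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def save_surface(path: str | Path, mesh: SurfaceMesh) -> None:
    coords = gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                  intent="NIFTI_INTENT_POINTSET")
    tris = gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                intent="NIFTI_INTENT_TRIANGLE")
    nib.save(gifti.GiftiImage(darrays=[coords, tris]), str(path))


def load_surface(path: str | Path) -> SurfaceMesh:
    img = nib.load(str(path))
    coords = faces = None
    for da in img.darrays:
        if da.intent == 1008:  # POINTSET
            coords = da.data
        elif da.intent == 1009:  # TRIANGLE
            faces = da.data
    if coords is None or faces is None:
        raise ValueError(f"{path} lacks pointset/triangle arrays")
    return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, int))


def save_metric(path: str | Path, values: np.ndarray) -> None:
    da = gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                              intent="NIFTI_INTENT_NONE")
    nib.save(gifti.GiftiImage(darrays=[da]), str(path))


def load_metric(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


def save_tck(path: str | Path, streamlines: list[np.ndarray]) -> None:
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def load_tck(path: str | Path) -> list[np.ndarray]:
    tf = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tf.streamlines]
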