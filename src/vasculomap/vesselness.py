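"""Multi-scale Hessian-based tubular-structure (Frangi) filtering.

Scales are specified in mm and converted to voxels via the isotropic voxel
size.  Second derivatives use gamma-normalized Gaussian derivatives
(multiplied by sigma² in voxel units) with reflect padding, so responses are
comparable across scales and edge behaviour is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FrangiParams",
    "VesselnessMap",
    "hessian_eigenvalues",
    "frangi",
    "average_echoes",
    "vessel_mask_stats",
]


@dataclass
class FrangiParams:
    """Filter constants.

    ``gamma`` (the structureness cutoff, the original filter's constant c —
    renamed to avoid clashing with depth-model coefficients) defaults to half
    the maximum Frobenius norm of the Hessian per scale when left None.
    ``polarity`` selects dark tubes on bright background or the reverse.
    """

    sigmas_mm: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    alpha: float = 0.5
    beta: float = 0.5
    gamma: float | None = None
    polarity: str = "dark_tubes"

    def __post_init__(self) -> None:
        if len(self.sigmas_mm) == 0:
            raise ValueError("need at least one scale")
        if any(s <= 0 for s in self.sigmas_mm):
            raise ValueError("sigmas must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.polarity not in ("dark_tubes", "bright_tubes"):
            raise ValueError("polarity must be dark_tubes or bright_tubes")


@dataclass
class VesselnessMap:
    response: np.ndarray  # in [0, 1]
    best_scale: np.ndarray  # mm, element of sigmas
    params: FrangiParams | None = None
    meta: dict = field(default_factory=dict)


def hessian_eigenvalues(volume: np.ndarray, sigma_mm: float,
                        voxel_size_mm: float = 1.0) -> np.ndarray:
    """Sorted eigenvalues (|λ1| ≤ |λ2| ≤ |λ3|) of the scale-space Hessian.

    Returns an array of shape volume.shape + (3,).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    sigma_vox = sigma_mm / voxel_size_mm
    if sigma_vox < 0.5:
        warnings.warn(
            f"sigma {sigma_mm} mm is below half a voxel ({voxel_size_mm} mm); "
            "derivatives are under-resolved", stacklevel=2)

    # scipy's sampled second-derivative kernel has a small nonzero DC gain;
    # subtract it so constant volumes map to an exactly-zero Hessian
    probe = np.ones(int(2 * np.ceil(4 * sigma_vox) + 9))
    dc_gain = ndimage.gaussian_filter1d(probe, sigma_vox, order=2)[len(probe) // 2]
    smooth0 = ndimage.gaussian_filter(volume, sigma_vox, mode="reflect")

    h = np.empty(volume.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = ndimage.gaussian_filter(volume, sigma_vox, order=order,
                                        mode="reflect")
            if i == j:
                d = d - dc_gain * smooth0
            h[..., i, j] = d
            h[..., j, i] = d
    h *= sigma_vox**2  # gamma-normalization

    lam = np.linalg.eigvalsh(h)  # ascending by value
    order = np.argsort(np.abs(lam), axis=-1)
    return np.take_along_axis(lam, order, axis=-1)


def _vesselness_single_scale(lam: np.ndarray, alpha: float, beta: float,
                             gamma: float | None) -> np.ndarray:
    l1 = lam[..., 0]
    l2 = lam[..., 1]
    l3 = lam[..., 2]
    eps = 1e-30
    ra = np.abs(l2) / np.maximum(np.abs(l3), eps)
    rb = np.abs(l1) / np.maximum(np.sqrt(np.abs(l2 * l3)), eps)
    s = np.sqrt(l1**2 + l2**2 + l3**2)
    if gamma is None:
        gamma = 0.5 * s.max()
    if gamma <= 0:
        return np.zeros_like(l1)
    v = ((1.0 - np.exp(-(ra**2) / (2 * alpha**2)))
         * np.exp(-(rb**2) / (2 * beta**2))
         * (1.0 - np.exp(-(s**2) / (2 * gamma**2))))
    # bright tube on (possibly negated) input: λ2, λ3 strongly negative
    v = np.where((l2 < 0) & (l3 < 0), v, 0.0)
    return v


def frangi(volume: np.ndarray, params: FrangiParams,
           voxel_size_mm: float = 1.0) -> VesselnessMap:
    """Multi-scale vesselness: maximum response over scales.

    Dark tubes are handled by negating the volume so that the bright-tube
    eigenvalue condition (λ2 < 0 and λ3 < 0) applies in all cases.
    """
    volume = np.asarray(volume, dtype=float)
    work = -volume if params.polarity == "dark_tubes" else volume

    response = np.zeros(volume.shape)
    best = np.full(volume.shape, params.sigmas_mm[0], dtype=float)
    if np.ptp(volume) == 0:  # structureless: zero response at every scale
        return VesselnessMap(response=response, best_scale=best, params=params,
                             meta={"voxel_size_mm": voxel_size_mm,
                                   "sigmas_mm": list(params.sigmas_mm),
                                   "alpha": params.alpha, "beta": params.beta,
                                   "gamma": params.gamma,
                                   "polarity": params.polarity})
    for sigma in params.sigmas_mm:
        lam = hessian_eigenvalues(work, sigma, voxel_size_mm)
        v = _vesselness_single_scale(lam, params.alpha, params.beta, params.gamma)
        better = v > response
        best[better] = sigma
        response = np.where(better, v, response)
    return VesselnessMap(
        response=np.clip(response, 0.0, 1.0),
        best_scale=best,
        params=params,
        meta={"voxel_size_mm": voxel_size_mm,
              "sigmas_mm": list(params.sigmas_mm),
              "alpha": params.alpha, "beta": params.beta,
              "gamma": params.gamma, "polarity": params.polarity},
    )


def average_echoes(*echo_stacks: np.ndarray) -> np.ndarray:
    """Equal-weight average over runs and echoes (SNR pre-step before
    filtering)."""
    vols = [np.asarray(e, dtype=float) for stack in echo_stacks for e in stack]
    if not vols:
        raise ValueError("no volumes to average")
    return np.mean(vols, axis=0)


def vessel_mask_stats(vmap: VesselnessMap, threshold: float,
                      roi_mask: np.ndarray, voxel_volume_mm3: float) -> dict:
    """Thresholded vessel volume (mm³) and ROI fraction."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    mask = (vmap.response >= threshold) & roi_mask
    n = int(mask.sum())
    return {
        "vessel_volume_mm3": n * voxel_volume_mm3,
        "fraction_of_roi": n / n_roi,
        "n_vessel_voxels": n,
        "n_roi_voxels": n_roi,
    }
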