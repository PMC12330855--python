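"""Synthetic digital phantoms, streamline bundles and parcel tables.

Everything downstream needs is generated here with known ground truth: a
folded cortical sheet with embedded tubular vessels (radial in gray matter,
tangential in superficial white matter), multi-echo signal decay before and
after a susceptibility contrast agent, commissural-style bundles whose
per-node metrics follow exponential depth models, and parcel tables with a
prescribed cross-metric correlation structure.

Conventions
-----------
* The cortical sheet is a single sinusoidal fold, simple enough for
  analytic normals yet folded enough to vary cos²(normal, B0) across
  vertices.
* Noise is additive Gaussian on the magnitude signal (the Rician regime is
  ignored at the SNRs used here).
* Vessel seeds are Poisson-disk samples on the surface, so vessels do not
  overlap systematically.
* All randomness flows from the integer seed carried by each spec; there is
  no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meshes import SurfaceMesh, make_grid_sheet_mesh
from .relaxometry import DEFAULT_TE_MS, MultiEchoSeries
from .tracts import Bundle, BundleSet

__all__ = [
    "PhantomSpec",
    "DigitalPhantom",
    "SyntheticBundleSpec",
    "ParcelTableSpec",
    "make_cortical_phantom",
    "make_bundles",
    "make_parcel_table",
    "make_stepwise_dataset",
    "LABELS",
]

#: Tissue label codes used throughout.
LABELS = {"background": 0, "gm": 1, "swm": 2, "deep_wm": 3}

#: Group-level exponential depth models in display form A e^{-b d} + c.
DEFAULT_DEPTH_MODELS = {
    "delta_r2star": (11.64, 0.05, 19.13),
    "odi": (0.30, 0.02, 0.07),
    "ndi": (-0.32, 0.01, 0.87),
}


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.23
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    tissue_r2star_pre: dict[str, float] = field(
        default_factory=lambda: {"gm": 30.0, "swm": 25.0, "deep_wm": 20.0})
    vessel_radius_mm: float = 0.3
    vessel_density_gm: float = 0.6   # vessels per mm² of white surface
    vessel_density_swm: float = 0.9
    delta_r2star_per_vvf: float = 120.0
    angular_modulation: float = -0.5
    noise_sd: float = 0.0
    seed: int = 0
    #: half-width (rad) of the jitter of SWM tangent directions around the
    #: in-plane (downhill) tangent; pi gives isotropic tangents
    swm_tangent_jitter: float = np.pi / 8
    # geometry of the folded sheet
    fold_amplitude_mm: float = 1.6
    fold_wavelength_mm: float = 12.0
    cortical_thickness_mm: float = 1.6
    swm_thickness_mm: float = 0.20
    s0: float = 100.0
    te_ms: tuple[float, ...] = DEFAULT_TE_MS

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.te_ms = tuple(float(t) for t in self.te_ms)
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        b0 = np.asarray(self.b0_direction, dtype=float)
        n = np.linalg.norm(b0)
        if n == 0:
            raise ValueError("b0_direction must be nonzero")
        self.b0_direction = tuple(b0 / n)
        if any(v <= 0 for v in self.tissue_r2star_pre.values()):
            raise ValueError("all baseline R2* values must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class DigitalPhantom:
    spec: PhantomSpec
    pre_echoes: MultiEchoSeries
    post_echoes: MultiEchoSeries
    white_surface: SurfaceMesh
    pial_surface: SurfaceMesh
    tissue_labels: np.ndarray
    vessel_mask: np.ndarray
    vessel_orientations: np.ndarray  # (*grid, 3), unit where vessel_mask
    true_delta_r2star: np.ndarray
    affine: np.ndarray
    r2star_pre: np.ndarray
    #: 0 = no vessel, 1 = radial (gray matter), 2 = tangential (SWM)
    vessel_class: np.ndarray = None  # type: ignore[assignment]
    #: per-voxel vessel volume fraction (sums to the imposed vessel volume)
    vessel_volume_fraction: np.ndarray = None  # type: ignore[assignment]
    #: surface normal of the cortical column each vessel is anchored to
    vessel_local_normals: np.ndarray = None  # type: ignore[assignment]

    @property
    def b0(self) -> np.ndarray:
        return np.asarray(self.spec.b0_direction)

    def surface_normal_cos2(self, mesh: SurfaceMesh | None = None) -> np.ndarray:
        """cos²θ between (white) surface normals and B0, per vertex."""
        mesh = mesh or self.white_surface
        return (mesh.vertex_normals @ self.b0) ** 2


def _poisson_disk_2d(rng: np.random.Generator, lx: float, ly: float,
                     n_target: int, min_dist: float,
                     max_tries: int = 30) -> np.ndarray:
    """Dart-throwing Poisson-disk sampling in a [0,lx]×[0,ly] rectangle."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_target and tries < max_tries * max(n_target, 1):
        p = rng.uniform([0, 0], [lx, ly])
        if all(np.hypot(*(p - q)) >= min_dist for q in pts):
            pts.append(p)
        tries += 1
    return np.array(pts).reshape(-1, 2)


def _accumulate_capsule(vvf: np.ndarray, ori: np.ndarray, delta: np.ndarray,
                        p0: np.ndarray, p1: np.ndarray, radius_vox: float,
                        delta_per_vvf: float, modulation: float,
                        b0: np.ndarray, n_sub: int = 2,
                        vclass: np.ndarray | None = None, class_code: int = 0,
                        vnorm: np.ndarray | None = None,
                        anchor_normal: np.ndarray | None = None,
                        store_dir: np.ndarray | None = None) -> None:
    """Add one cylinder segment (voxel coordinates) into the accumulators."""
    shape = np.array(vvf.shape)
    u = p1 - p0
    length = np.linalg.norm(u)
    if length == 0:
        return
    u = u / length
    cos2 = float((u @ b0) ** 2)
    lo = np.clip(np.floor(np.minimum(p0, p1) - radius_vox - 1).astype(int), 0, shape - 1)
    hi = np.clip(np.ceil(np.maximum(p0, p1) + radius_vox + 1).astype(int), 0, shape - 1)
    gx, gy, gz = np.meshgrid(*[np.arange(lo[k], hi[k] + 1) for k in range(3)],
                             indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
    offs = (np.stack(np.meshgrid(*([np.arange(n_sub)] * 3), indexing="ij"),
                     axis=-1).reshape(-1, 3) + 0.5) / n_sub - 0.5
    sub = centers[:, None, :] + offs[None, :, :]
    t = (sub - p0) @ u
    proj = p0 + np.clip(t, 0.0, length)[..., None] * u
    dist = np.linalg.norm(sub - proj, axis=-1)
    inside = (t >= 0) & (t <= length) & (dist <= radius_vox)
    occ = inside.mean(axis=1)
    nz = occ > 0
    if not nz.any():
        return
    ii = (gx.ravel()[nz], gy.ravel()[nz], gz.ravel()[nz])
    add = np.minimum(occ[nz], 1.0 - vvf[ii])  # cap total vvf at 1
    vvf[ii] += add
    delta[ii] += delta_per_vvf * add * (1.0 + modulation * cos2)
    dominant = add >= 0.5 * (vvf[ii])
    dom = tuple(a[dominant] for a in ii)
    u_store = u if store_dir is None else store_dir
    for k in range(3):
        ori[..., k][dom] = u_store[k]
        if vnorm is not None and anchor_normal is not None:
            vnorm[..., k][dom] = anchor_normal[k]
    if vclass is not None:
        vclass[dom] = class_code


def make_cortical_phantom(spec: PhantomSpec) -> DigitalPhantom:
    """Build the folded-sheet phantom with embedded vessels and echo stacks.

    Gray-matter vessels are cylinders along the local surface normal
    spanning white→pial; superficial-white-matter vessels are polylines
    following the surface tangent at a fixed depth beneath the white
    surface.  The imposed contrast change is

        true ΔR2* = delta_r2star_per_vvf · VVF · (1 + angular_modulation · cos²θ)

    accumulated per vessel segment, and post-contrast echoes follow
    S(TE) = S0 exp(-(R2*_pre + ΔR2*) TE) plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    v = spec.voxel_size_mm
    lx, ly, lz = nx * v, ny * v, nz * v
    if lx < spec.fold_wavelength_mm:
        raise ValueError(
            f"grid x-extent {lx:.1f} mm cannot contain one full gyral fold "
            f"of wavelength {spec.fold_wavelength_mm:.1f} mm")
    amp = spec.fold_amplitude_mm
    lam = spec.fold_wavelength_mm
    thick = spec.cortical_thickness_mm
    z0 = 0.55 * lz
    if z0 + amp + thick >= lz or z0 - amp - 1.0 <= 0:
        raise ValueError("grid z-extent too small for the folded sheet")
    b0 = np.asarray(spec.b0_direction)
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = 0.5 * v  # voxel centers at (i + 0.5) * v

    def zw(x):
        return z0 + amp * np.sin(2 * np.pi * x / lam)

    def dzw(x):
        return amp * (2 * np.pi / lam) * np.cos(2 * np.pi * x / lam)

    # --- tissue labels on the voxel grid (vertical distance to the sheet)
    xs = (np.arange(nx) + 0.5) * v
    zs = (np.arange(nz) + 0.5) * v
    height = zs[None, :] - zw(xs)[:, None]  # signed height above white surface
    slab = np.zeros((nx, nz), dtype=np.int8)
    slab[(height > 0) & (height <= thick)] = LABELS["gm"]
    slab[(height <= 0) & (height > -spec.swm_thickness_mm)] = LABELS["swm"]
    slab[height <= -spec.swm_thickness_mm] = LABELS["deep_wm"]
    labels = np.repeat(slab[:, None, :], ny, axis=1)

    # --- surfaces (margin of one voxel to stay clear of the volume edge)
    n_grid = max(nx // 2, 24)
    gx = np.linspace(v, lx - v, n_grid)
    gy = np.linspace(v, ly - v, n_grid)
    white = make_grid_sheet_mesh(gx, gy, np.tile(zw(gx)[:, None], (1, n_grid)))
    pial = make_grid_sheet_mesh(gx, gy, np.tile(zw(gx)[:, None] + thick, (1, n_grid)))

    def normal_at(x):
        d = dzw(x)
        s = np.sqrt(1.0 + d**2)
        return np.stack([-d / s, np.zeros_like(d), 1.0 / s], axis=-1)

    # --- vessels
    vvf = np.zeros(spec.grid_shape)
    delta = np.zeros(spec.grid_shape)
    ori = np.zeros(spec.grid_shape + (3,))
    vclass = np.zeros(spec.grid_shape, dtype=np.int8)
    vnorm = np.zeros(spec.grid_shape + (3,))
    r_vox = spec.vessel_radius_mm / v

    # seed in (arc length, y) so vessel density is uniform per unit surface
    # area, not per projected area (a tilt-dependent density would confound
    # the angular-modulation signal)
    x_dense = np.linspace(0.0, lx, 4096)
    arc = np.concatenate([[0.0], np.cumsum(
        np.sqrt(1.0 + dzw(0.5 * (x_dense[1:] + x_dense[:-1]))**2)
        * np.diff(x_dense))])
    lu = arc[-1]

    def arc_to_x(u):
        return float(np.interp(u, arc, x_dense))

    area = lu * ly  # true sheet area

    n_gm = rng.poisson(spec.vessel_density_gm * area)
    seeds_gm = _poisson_disk_2d(rng, lu, ly, n_gm, min_dist=2.5 * spec.vessel_radius_mm)
    seeds_gm = [(arc_to_x(su), sy) for su, sy in seeds_gm]
    for sx, sy in seeds_gm:
        n = normal_at(sx)
        p0 = np.array([sx, sy, zw(sx)])
        p1 = p0 + (thick + 0.2) * n
        _accumulate_capsule(vvf, ori, delta, p0 / v - 0.5, p1 / v - 0.5, r_vox,
                            spec.delta_r2star_per_vvf, spec.angular_modulation, b0,
                            vclass=vclass, class_code=1, vnorm=vnorm,
                            anchor_normal=n)

    n_swm = rng.poisson(spec.vessel_density_swm * area)
    seeds_swm = _poisson_disk_2d(rng, lu, ly, n_swm, min_dist=2.5 * spec.vessel_radius_mm)
    seeds_swm = [(arc_to_x(su), sy) for su, sy in seeds_swm]
    depth = 0.5 * spec.swm_thickness_mm
    seg_len = 0.6  # mm, short segments so polylines hug the curved sheet
    n_seg = 4
    for sx, sy in seeds_swm:
        phi = (rng.uniform(-spec.swm_tangent_jitter, spec.swm_tangent_jitter)
               + rng.choice([0.0, np.pi]))
        pts, dirs, norms = [], [], []
        x, y = sx, sy
        for k in range(n_seg + 1):
            n = normal_at(x)
            tx = np.array([n[2], 0.0, -n[0]])  # in-plane (downhill) tangent
            ty = np.array([0.0, 1.0, 0.0])
            u = np.cos(phi) * tx + np.sin(phi) * ty
            pts.append(np.array([x, y, zw(x)]) - depth * n)
            if k < n_seg:
                dirs.append(u)
                norms.append(n)
            x = x + seg_len * u[0]
            y = y + seg_len * u[1]
            x = float(np.clip(x, v, lx - v))
            y = float(np.clip(y, v, ly - v))
        for k in range(n_seg):
            _accumulate_capsule(vvf, ori, delta, pts[k] / v - 0.5,
                                pts[k + 1] / v - 0.5, r_vox,
                                spec.delta_r2star_per_vvf,
                                spec.angular_modulation, b0,
                                vclass=vclass, class_code=2, vnorm=vnorm,
                                anchor_normal=norms[k], store_dir=dirs[k])

    tissue = labels != LABELS["background"]
    vvf *= tissue
    delta = np.where(tissue, np.maximum(delta, 0.0), 0.0)
    vessel_mask = vvf > 0
    vclass[~vessel_mask] = 0

    # --- relaxometry ground truth and echo stacks
    r2_pre = np.zeros(spec.grid_shape)
    for name, code in LABELS.items():
        if name == "background":
            continue
        r2_pre[labels == code] = spec.tissue_r2star_pre[name]
    r2_post = r2_pre + delta

    te_s = np.asarray(spec.te_ms) / 1000.0
    s0 = np.where(tissue, spec.s0, 0.0)

    def echoes(r2):
        out = []
        for te in te_s:
            sig = s0 * np.exp(-r2 * te)
            if spec.noise_sd > 0:
                sig = sig + rng.normal(0.0, spec.noise_sd, size=sig.shape)
            out.append(sig)
        return MultiEchoSeries(out, np.asarray(spec.te_ms))

    return DigitalPhantom(
        spec=spec,
        pre_echoes=echoes(r2_pre),
        post_echoes=echoes(r2_post),
        white_surface=white,
        pial_surface=pial,
        tissue_labels=labels,
        vessel_mask=vessel_mask,
        vessel_orientations=ori,
        true_delta_r2star=delta,
        affine=affine,
        r2star_pre=r2_pre,
        vessel_class=vclass,
        vessel_local_normals=vnorm,
        vessel_volume_fraction=vvf,
    )


# ---------------------------------------------------------------------------
# bundles


@dataclass
class SyntheticBundleSpec:
    n_bundles: int = 8
    streamlines_per_bundle: int = 30
    nodes_per_streamline: int = 20
    depth_models: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_MODELS))
    node_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"delta_r2star": 0.5, "odi": 0.01, "ndi": 0.01})
    outlier_fraction: float = 0.0
    outlier_displacement_sd: float = 5.0
    seed: int = 0
    bundle_length_mm: float = 40.0

    def __post_init__(self) -> None:
        if self.nodes_per_streamline < 2:
            raise ValueError("nodes_per_streamline must be >= 2")
        if any(sd < 0 for sd in self.node_noise_sd.values()):
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction in [0, 1)")


def depth_model_curve(d_percent: np.ndarray,
                      params: tuple[float, float, float]) -> np.ndarray:
    """Display-form depth model A·exp(-b·d) + c with d in percent."""
    amp, rate, offset = params
    return amp * np.exp(-rate * np.asarray(d_percent, dtype=float)) + offset


def make_bundles(spec: SyntheticBundleSpec) -> BundleSet:
    """Commissural-style bundles with per-node metrics from depth models.

    Each streamline is a gently curved polyline from a cortical endpoint
    (x = bundle_length_mm) to the midsagittal plane (x = 0).  Per-node
    metrics are the depth-model value at the node's relative distance plus
    Gaussian noise; the requested fraction of streamlines is displaced as
    geometric outliers.  Ground-truth parameters and planted outlier
    indices are recorded in ``meta``.
    """
    rng = np.random.default_rng(spec.seed)
    n_nodes = spec.nodes_per_streamline
    d = np.linspace(0.0, 100.0, n_nodes)
    bundles = []
    outlier_idx: dict[str, np.ndarray] = {}
    for bi in range(spec.n_bundles):
        base_y = 10.0 * bi
        base_z = 5.0 * rng.standard_normal()
        bow = rng.uniform(2.0, 6.0)
        streamlines = []
        metrics = {m: np.empty((spec.streamlines_per_bundle, n_nodes))
                   for m in spec.depth_models}
        for si in range(spec.streamlines_per_bundle):
            # bounded jitter keeps coherent streamlines within the 3-SD
            # cleaning criterion with certainty (no false removals)
            jit = rng.uniform(-0.9, 0.9, size=2)
            t = np.linspace(0.0, 1.0, 50)
            x = spec.bundle_length_mm * (1.0 - t)
            y = base_y + jit[0] + bow * np.sin(np.pi * t) * 0.3
            z = base_z + jit[1] + bow * np.sin(np.pi * t)
            streamlines.append(np.stack([x, y, z], axis=1))
            for m, params in spec.depth_models.items():
                noise = rng.normal(0.0, spec.node_noise_sd.get(m, 0.0), size=n_nodes)
                vals = depth_model_curve(d, params) + noise
                if m in ("ndi", "odi"):
                    vals = np.clip(vals, 0.0, 1.0)
                metrics[m][si] = vals
        n_out = int(round(spec.outlier_fraction * spec.streamlines_per_bundle))
        oidx = rng.choice(spec.streamlines_per_bundle, size=n_out, replace=False)
        for si in oidx:
            shift = rng.standard_normal(3)
            shift = shift / np.linalg.norm(shift) * spec.outlier_displacement_sd
            streamlines[si] = streamlines[si] + shift
        name = f"bundle_{bi:02d}"
        outlier_idx[name] = np.sort(oidx)
        bundles.append(Bundle(streamlines, name=name, node_metrics=metrics))
    return BundleSet(
        bundles,
        meta={
            "depth_models": dict(spec.depth_models),
            "relative_distance": d,
            "outlier_indices": outlier_idx,
            "spec": spec,
        },
    )


def make_stepwise_dataset(
    n_bundles: int = 8,
    nodes_per_bundle: int = 20,
    coef_ndi: float = -20.0,
    coef_odi: float = 25.0,
    exp_amplitude: float = 10.0,
    exp_rate: float = 0.05,
    intercept: float = 20.0,
    noise_sd: float = 0.5,
    predictor_noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(bundle, node) predictor table with a known generative model.

    NDI and ODI follow their depth models (plus independent noise so they
    are not collinear), and the response is
    intercept + coef_ndi·NDI + coef_odi·ODI + exp_amplitude·e^{-exp_rate·d}
    plus Gaussian noise.  Used to exercise stepwise selection and
    leave-one-bundle-out cross-validation with known truth.
    """
    rng = np.random.default_rng(seed)
    d = np.linspace(0.0, 100.0, nodes_per_bundle)
    rows = []
    for bi in range(n_bundles):
        ndi = depth_model_curve(d, DEFAULT_DEPTH_MODELS["ndi"]) \
            + rng.normal(0, predictor_noise_sd, nodes_per_bundle)
        odi = depth_model_curve(d, DEFAULT_DEPTH_MODELS["odi"]) \
            + rng.normal(0, predictor_noise_sd, nodes_per_bundle)
        resp = (intercept + coef_ndi * ndi + coef_odi * odi
                + exp_amplitude * np.exp(-exp_rate * d)
                + rng.normal(0, noise_sd, nodes_per_bundle))
        for j in range(nodes_per_bundle):
            rows.append({"bundle": f"bundle_{bi:02d}", "node": j,
                         "relative_distance": d[j], "ndi": ndi[j],
                         "odi": odi[j], "delta_r2star": resp[j]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parcel tables


@dataclass
class ParcelTableSpec:
    n_areas: int = 103
    metrics: tuple[str, ...] = ("delta_r2star", "neuron", "receptor", "myelin")
    target_correlations: np.ndarray | None = None
    means: dict[str, float] = field(
        default_factory=lambda: {"delta_r2star": 25.0, "neuron": 70.0,
                                 "receptor": 2600.0, "myelin": 1.5})
    sds: dict[str, float] = field(
        default_factory=lambda: {"delta_r2star": 4.0, "neuron": 20.0,
                                 "receptor": 400.0, "myelin": 0.3})
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        m = len(self.metrics)
        if self.target_correlations is None:
            return np.eye(m)
        c = np.asarray(self.target_correlations, dtype=float)
        if c.shape != (m, m):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("target_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("target_correlations is not positive semidefinite")
        return c


def make_parcel_table(spec: ParcelTableSpec) -> pd.DataFrame:
    """Joint parcel samples via a Gaussian copula with the target
    correlations, rescaled to the stated means and SDs."""
    corr = spec.correlation_matrix()
    rng = np.random.default_rng(spec.seed)
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ v.T
    z = rng.standard_normal((spec.n_areas, len(spec.metrics))) @ root.T
    df = pd.DataFrame({"area": [f"area_{i:03d}" for i in range(spec.n_areas)]})
    for j, m in enumerate(spec.metrics):
        df[m] = spec.means[m] + spec.sds[m] * z[:, j]
    return df
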