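import numpy as np
import pytest

from vasculomap.laminar import (LAYER_NAMES, equivolume_fraction,
                                equivolumetric_layers, offset_surface,
                                ribbon_sample, surface_gradient)
from vasculomap.meshes import make_grid_sheet_mesh
from vasculomap.synthetic import LABELS


def flat_pair(n=8, spacing=1.0, thickness=2.0, z0=0.0):
    x = np.arange(n) * spacing
    white = make_grid_sheet_mesh(x, x, np.full((n, n), z0))
    pial = make_grid_sheet_mesh(x, x, np.full((n, n), z0 + thickness))
    return white, pial


def prism_boundaries_numeric(aw, ap, n_layers=12):
    """Oracle: invert cumulative volume of a truncated prism numerically."""
    r = np.linspace(0, 1, 20001)
    area = aw + (ap - aw) * r
    cumvol = np.concatenate([[0.0], np.cumsum(0.5 * (area[1:] + area[:-1])
                                              * np.diff(r))])
    cumvol /= cumvol[-1]
    targets = np.linspace(0, 1, n_layers + 1)
    return np.interp(targets, cumvol, r)


class TestEquivolumetricLayers:
    def test_flat_slab_equidistant(self):
        white, pial = flat_pair()
        stack = equivolumetric_layers(white, pial)
        expected = np.linspace(0, 1, 13)
        assert np.allclose(stack.fractions, expected[None, :], atol=1e-9)

    def test_names_el1a_to_el6b(self):
        white, pial = flat_pair()
        stack = equivolumetric_layers(white, pial)
        assert stack.names == LAYER_NAMES
        assert stack.names[0] == "EL1a"
        assert stack.names[-1] == "EL6b"
        assert stack.n_layers == 12

    def test_wedge_matches_prism_oracle(self):
        # closed form vs numeric inversion for A_p = 2 A_w
        frac = equivolume_fraction(np.linspace(0, 1, 13), 1.0, 2.0)
        oracle = prism_boundaries_numeric(1.0, 2.0)
        assert np.allclose(frac, oracle, atol=1e-4)

    def test_wedge_slab_volumes_equal_within_1pc(self):
        aw, ap = 1.0, 2.0
        frac = equivolume_fraction(np.linspace(0, 1, 13), aw, ap)
        r = np.linspace(0, 1, 200001)
        area = aw + (ap - aw) * r
        cumvol = np.concatenate([[0.0], np.cumsum(
            0.5 * (area[1:] + area[:-1]) * np.diff(r))])
        vols = np.diff(np.interp(frac, r, cumvol))
        assert np.ptp(vols) / vols.mean() < 0.01

    def test_scale_invariance(self):
        white, pial = flat_pair()
        stack1 = equivolumetric_layers(white, pial)
        stack2 = equivolumetric_layers(
            type(white)(white.vertices * 3.7, white.faces),
            type(pial)(pial.vertices * 3.7, pial.faces))
        assert np.allclose(stack1.fractions, stack2.fractions, atol=1e-10)

    def test_total_volume_conserved(self, default_phantom):
        ph = default_phantom
        stack = equivolumetric_layers(ph.white_surface, ph.pial_surface)
        # per-vertex column: sum of slab thickness fractions = 1 exactly
        assert np.allclose(stack.fractions[:, -1] - stack.fractions[:, 0], 1.0)
        assert np.all(np.diff(stack.fractions, axis=1) >= -1e-12)

    def test_vertex_count_mismatch_rejected(self):
        white, _ = flat_pair(n=8)
        _, pial = flat_pair(n=9)
        with pytest.raises(ValueError):
            equivolumetric_layers(white, pial)


class TestOffsetSurface:
    def test_zero_distance_identity(self):
        white, _ = flat_pair()
        out = offset_surface(white, 0.0)
        assert np.allclose(out.mesh.vertices, white.vertices)

    def test_flat_sheet_z_reduced(self):
        white, _ = flat_pair(z0=5.0)
        out = offset_surface(white, 0.32)
        assert np.allclose(out.mesh.vertices[:, 2], 5.0 - 0.32)
        assert out.distance_mm == 0.32

    def test_phantom_offset_lands_in_deep_wm(self, default_phantom):
        ph = default_phantom
        out = offset_surface(ph.white_surface, 0.32)
        inv = np.linalg.inv(ph.affine)
        vox = out.mesh.vertices @ inv[:3, :3].T + inv[:3, 3]
        idx = np.clip(np.round(vox).astype(int), 0,
                      np.array(ph.tissue_labels.shape) - 1)
        lab = ph.tissue_labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert (lab == LABELS["deep_wm"]).mean() > 0.99


class TestRibbonSample:
    def test_constant_volume(self):
        white, pial = flat_pair(n=6, thickness=2.0, z0=2.0)
        vol = np.full((8, 8, 8), 3.25)
        vals, flagged = ribbon_sample(vol, white, pial)
        assert np.allclose(vals, 3.25)
        assert not flagged.any()

    def test_linear_in_z_gives_midwedge_value(self):
        # volume value = z coordinate of voxel center; flat wedge z in [2, 6]
        white, pial = flat_pair(n=6, spacing=1.4, thickness=4.0, z0=2.0)
        zc = np.arange(10) + 0.5
        vol = np.tile(zc[None, None, :], (10, 10, 1)).astype(float)
        affine = np.eye(4)
        affine[:3, 3] = 0.5
        vals, _ = ribbon_sample(vol, white, pial, affine)
        assert np.allclose(vals, 4.0, atol=1.0)  # within one voxel

    def test_degenerate_wedge_nearest_fallback(self):
        white, _ = flat_pair(n=4, thickness=0.0, z0=2.0)
        vol = np.arange(64).reshape(4, 4, 4).astype(float)
        vals, flagged = ribbon_sample(vol, white, white)
        assert flagged.all()
        assert np.all(np.isfinite(vals))

    def test_phantom_gm_swm_contrast_ordering(self, default_phantom):
        # the sampler must reproduce the ordering the generator imposed
        ph = default_phantom
        stack = equivolumetric_layers(ph.white_surface, ph.pial_surface)
        n_b = stack.n_layers
        j = stack.names.index("EL4a")
        gm_vals, _ = ribbon_sample(ph.true_delta_r2star,
                                   stack.layer_surfaces[n_b - 1 - j],
                                   stack.layer_surfaces[n_b - j], ph.affine)
        swm_out = offset_surface(ph.white_surface)
        swm_vals, _ = ribbon_sample(ph.true_delta_r2star, swm_out.mesh,
                                    ph.white_surface, ph.affine)
        true_gm = ph.true_delta_r2star[ph.tissue_labels == LABELS["gm"]].mean()
        true_swm = ph.true_delta_r2star[ph.tissue_labels == LABELS["swm"]].mean()
        assert (swm_vals.mean() > gm_vals.mean()) == (true_swm > true_gm)


class TestSurfaceGradient:
    def test_constant_metric_zero_gradient(self):
        white, _ = flat_pair()
        g = surface_gradient(np.full(white.n_vertices, 2.0), white)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_x_coordinate_gradient_is_one(self):
        white, _ = flat_pair(n=12, spacing=0.8)
        g = surface_gradient(white.vertices[:, 0].copy(), white)
        assert np.allclose(g, 1.0, atol=1e-9)

    def test_swm_gradient_ridges_follow_tangential_vessels(self, default_phantom):
        # thresholded high-gradient set overlaps the dilated projection of
        # the tangential vessel ground truth (IoU > 0.3)
        from scipy import ndimage

        ph = default_phantom
        swm_out = offset_surface(ph.white_surface)
        vals, _ = ribbon_sample(ph.true_delta_r2star, swm_out.mesh,
                                ph.white_surface, ph.affine)
        g = surface_gradient(vals, ph.white_surface)
        n = int(np.sqrt(ph.white_surface.n_vertices))
        gimg = g.reshape(n, n)

        # vessel trace: tangential (class 2) vessel voxels projected to the
        # surface vertex grid in (x, y)
        idx = np.argwhere((ph.vessel_class == 2))
        vox_mm = idx * ph.spec.voxel_size_mm + 0.5 * ph.spec.voxel_size_mm
        vx = ph.white_surface.vertices[:, 0].reshape(n, n)[:, 0]
        vy = ph.white_surface.vertices[:, 1].reshape(n, n)[0, :]
        trace = np.zeros((n, n), dtype=bool)
        ix = np.clip(np.searchsorted(vx, vox_mm[:, 0]), 0, n - 1)
        iy = np.clip(np.searchsorted(vy, vox_mm[:, 1]), 0, n - 1)
        trace[ix, iy] = True
        dilated = ndimage.binary_dilation(trace, iterations=2)

        k = int(dilated.sum())
        thresh = np.sort(gimg.ravel())[-k]
        ridges = gimg >= thresh
        iou = (ridges & dilated).sum() / (ridges | dilated).sum()
        assert iou > 0.3
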