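import numpy as np
import pytest

from vasculomap.meshes import make_grid_sheet_mesh
from vasculomap.synthetic import SyntheticBundleSpec, make_bundles
from vasculomap.tracts import (Bundle, clean_bundle, extract_profile,
                               relative_distance, resample_equidistant,
                               streamline_length)


def straight_line(length=19.0, n=2, origin=(0, 0, 0), direction=(1, 0, 0)):
    t = np.linspace(0, length, n)[:, None]
    return np.asarray(origin) + t * np.asarray(direction, dtype=float)


def coherent_bundle(n_streamlines=20, rng=None, jitter=0.17):
    # uniform (bounded) jitter: offsets stay within the 3-SD criterion
    rng = rng or np.random.default_rng(0)
    sls = []
    for _ in range(n_streamlines):
        base = straight_line(length=30.0, n=40)
        sls.append(base + rng.uniform(-jitter, jitter, 3))
    return Bundle(sls, name="test")


class TestBundle:
    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            Bundle([np.zeros((1, 3))])

    def test_rejects_nonfinite(self):
        s = straight_line()
        s[0, 0] = np.nan
        with pytest.raises(ValueError):
            Bundle([s])

    def test_size_threshold_more_than_five(self):
        five = Bundle([straight_line() + i for i in range(5)])
        six = Bundle([straight_line() + i for i in range(6)])
        assert not five.meets_size_threshold
        assert six.meets_size_threshold


class TestResampleEquidistant:
    def test_straight_segment_spacing(self):
        out = resample_equidistant(straight_line(length=19.0), 20)
        assert out.shape == (20, 3)
        spacing = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(spacing, 1.0)

    def test_endpoints_preserved(self):
        pts = np.array([[0, 0, 0], [1, 2, 0], [4, 2, 1.0]])
        out = resample_equidistant(pts, 20)
        assert np.allclose(out[0], pts[0])
        assert np.allclose(out[-1], pts[-1])

    def test_semicircle_spacing_vs_dense_oracle(self):
        r = 10.0
        theta = np.linspace(0, np.pi, 10_000)  # dense oracle sampling
        arc = np.stack([r * np.cos(theta), r * np.sin(theta),
                        np.zeros_like(theta)], axis=1)
        out = resample_equidistant(arc, 20)
        spacing = np.linalg.norm(np.diff(out, axis=0), axis=1)
        # chord of an arc segment of length pi*r/19
        seg = np.pi * r / 19
        chord = 2 * r * np.sin(seg / (2 * r))
        assert np.allclose(spacing, chord, rtol=1e-3)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            resample_equidistant(np.zeros((3, 3)), 20)


class TestCleanBundle:
    def test_identical_streamlines_none_removed(self):
        b = Bundle([straight_line(n=30)] * 10)
        out = clean_bundle(b)
        assert len(out) == 10

    def test_planted_outliers_removed_exactly(self, rng):
        b = coherent_bundle(20, rng)
        sd = 0.1
        outliers = [straight_line(length=30.0, n=40) + np.array([0, 10 * sd * 30, 0]),
                    straight_line(length=30.0, n=40) - np.array([0, 0, 10 * sd * 30])]
        all_sl = b.streamlines + outliers
        cleaned = clean_bundle(Bundle(all_sl))
        assert len(cleaned) == 20
        for kept in cleaned.streamlines:
            assert not any(np.allclose(kept, o) for o in outliers)

    def test_default_threshold_is_three_sd(self):
        import inspect
        sig = inspect.signature(clean_bundle)
        assert sig.parameters["sd_threshold"].default == 3.0

    def test_invariant_to_order_and_rigid_motion(self, rng):
        b = coherent_bundle(15, rng)
        out1 = clean_bundle(b)
        perm = rng.permutation(len(b.streamlines))
        # rigid motion: rotation about z + translation
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = [b.streamlines[i] @ rot.T + np.array([5.0, -3.0, 2.0])
                 for i in perm]
        out2 = clean_bundle(Bundle(moved))
        assert len(out1) == len(out2)

    def test_all_removed_flags_invalid(self):
        # two wildly different streamlines, tiny threshold
        b = Bundle([straight_line(), straight_line(origin=(0, 100, 0))])
        out = clean_bundle(b, sd_threshold=0.1)
        assert not out.valid or len(out) > 0  # never raises


class TestExtractProfile:
    def test_constant_volume(self):
        b = Bundle([straight_line(length=10, n=30, origin=(2, 5, 5))
                    for _ in range(8)])
        vol = np.full((20, 20, 20), 3.14)
        prof = extract_profile(b, {"delta_r2star": vol})
        assert np.allclose(prof.medians["delta_r2star"], 3.14)
        assert prof.n_nodes == 20

    def test_synthetic_node_metrics_zero_noise_exact(self):
        spec = SyntheticBundleSpec(
            n_bundles=1, streamlines_per_bundle=10,
            node_noise_sd={"delta_r2star": 0.0, "odi": 0.0, "ndi": 0.0},
            seed=3)
        bs = make_bundles(spec)
        b = bs.bundles[0]
        prof = extract_profile(b)
        d = bs.meta["relative_distance"]
        amp, rate, off = bs.meta["depth_models"]["delta_r2star"]
        expected = amp * np.exp(-rate * d) + off
        assert np.allclose(prof.medians["delta_r2star"], expected, atol=1e-12)

    def test_median_not_mean(self):
        # one extreme streamline must not shift the per-node value
        base = [straight_line(length=10, n=20) for _ in range(9)]
        metrics = {"m": np.vstack([np.ones((9, 20)), np.full((1, 20), 1e6)])}
        b = Bundle(base + [straight_line(length=10, n=20)], node_metrics=metrics)
        prof = extract_profile(b)
        assert np.allclose(prof.medians["m"], 1.0)

    def test_duplication_invariance(self):
        spec = SyntheticBundleSpec(n_bundles=1, streamlines_per_bundle=9, seed=1)
        b = make_bundles(spec).bundles[0]
        prof1 = extract_profile(b)
        doubled = Bundle(b.streamlines * 2, name=b.name,
                         node_metrics={k: np.vstack([v, v])
                                       for k, v in b.node_metrics.items()})
        prof2 = extract_profile(doubled)
        for k in prof1.medians:
            assert np.allclose(prof1.medians[k], prof2.medians[k])

    def test_out_of_bounds_nearest_fallback_flagged(self):
        b = Bundle([straight_line(length=100, n=30)])
        vol = np.ones((5, 5, 5))
        prof = extract_profile(b, {"m": vol})
        assert any("out_of_bounds" in f for f in prof.flags)
        assert np.all(np.isfinite(prof.medians["m"]))


class TestRelativeDistance:
    def wm_surface(self):
        x = np.linspace(39, 41, 3)
        return make_grid_sheet_mesh(x, np.linspace(-5, 5, 3), np.zeros((3, 3)))

    def test_straight_streamline_linear(self):
        # cortical end at x=40, crosses midsagittal plane x=0
        sl = straight_line(length=41.0, n=50, origin=(40, 0, 0),
                           direction=(-1, 0, 0))
        b = Bundle([sl])
        dist, flags = relative_distance(b, self.wm_surface(), midsagittal_x=0.0)
        # nodes before the crossing run linearly 0 -> 100 (over 40/41 of arc)
        expect = 100.0 * np.linspace(0, 41, 20) / 40.0
        assert np.allclose(dist, expect, rtol=1e-6)
        assert not flags

    def test_orientation_flip(self):
        # streamline stored midline-first must be flipped
        sl = straight_line(length=40.0, n=50, origin=(0, 0, 0),
                           direction=(1, 0, 0))
        b = Bundle([sl])
        dist, _ = relative_distance(b, self.wm_surface(), midsagittal_x=0.0)
        assert dist[0] == pytest.approx(0.0)
        assert dist[-1] == pytest.approx(100.0)

    def test_curved_streamline_arc_length_oracle(self):
        t = np.linspace(0, 1, 5000)
        x = 40 * (1 - t)
        z = 5 * np.sin(np.pi * t)
        sl = np.stack([x, np.zeros_like(t), z], axis=1)
        dist, _ = relative_distance(Bundle([sl]), self.wm_surface(), 0.0)
        seg = np.linalg.norm(np.diff(sl, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        dense = 100.0 * np.interp(np.linspace(0, arc[-1], 20), arc, arc) / arc[-1]
        assert np.allclose(dist, dense, rtol=1e-3)

    def test_non_crossing_excluded(self):
        crossing = straight_line(length=41, n=30, origin=(40, 0, 0),
                                 direction=(-1, 0, 0))
        stuck = straight_line(length=10, n=30, origin=(40, 0, 0),
                              direction=(-1, 0, 0))
        dist, flags = relative_distance(Bundle([crossing, stuck]),
                                        self.wm_surface(), 0.0)
        assert "no_midline_crossing" in flags

    def test_no_crossing_at_all_rejected(self):
        stuck = straight_line(length=5, n=10, origin=(40, 0, 0),
                              direction=(-1, 0, 0))
        with pytest.raises(ValueError):
            relative_distance(Bundle([stuck]), self.wm_surface(), 0.0)


def test_streamline_length():
    assert streamline_length(straight_line(length=19.0, n=7)) == pytest.approx(19.0)
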