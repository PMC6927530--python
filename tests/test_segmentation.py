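"""Smoothing, embryo geometry, nuclear segmentation, and dot detection."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import small_config
from ms2quant import synthetic
from ms2quant.movie_io import max_project
from ms2quant.segmentation import (Dot, EmbryoGeometry, NucleiLabels,
                                   ThresholdPolicy, detect_dots,
                                   estimate_geometry, segment_nuclei, smooth,
                                   window_dot_size)


class TestSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 3.7)
        assert np.allclose(smooth(img, 0.55), img)

    def test_impulse_conserves_total_intensity(self):
        img = np.zeros((21, 21))
        img[10, 10] = 5.0
        out = smooth(img, 0.55)
        assert out[10, 10] < 5.0
        assert np.isclose(out.sum(), 5.0)

    def test_matches_dense_direct_convolution(self):
        """Independent oracle: explicit sampled-Gaussian kernel applied by
        brute-force convolution with symmetric (reflective) padding."""
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(32, 32))
        sigma = 0.55
        radius = int(4 * sigma + 0.5)
        offsets = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (offsets / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = np.pad(img, radius, mode="symmetric")
        expected = np.zeros_like(img)
        for i in range(32):
            for j in range(32):
                expected[i, j] = np.sum(
                    padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel
                )
        got = smooth(img, sigma)
        assert np.max(np.abs(got - expected) / np.abs(expected)) < 1e-6

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.ones((4, 4)), 0.0)


class TestGeometry:
    def test_boundary_within_two_pixels_of_true_ellipse(self, small_scene, small_cfg):
        _, geometry, _, _ = small_scene
        cy, cx = small_cfg.center()
        b, a = small_cfg.semi_axes
        th = np.linspace(0, 2 * np.pi, 3000)
        ellipse = np.column_stack([cy + b * np.sin(th), cx + a * np.cos(th)])
        d1 = cKDTree(ellipse).query(geometry.boundary)[0].max()
        d2 = cKDTree(geometry.boundary).query(ellipse)[0].max()
        assert max(d1, d2) <= 2.0

    def test_manual_extremes_define_ew_0_and_100(self, small_movie, small_scene):
        movie, truth = small_movie
        proj, _, _, _ = small_scene
        geometry = estimate_geometry(
            proj.channel("NUP")[0],
            manual_extremes=(truth.ventral_extreme, truth.dorsal_extreme),
        )
        assert geometry.ew_of(np.array([geometry.ventral_extreme]))[0] == pytest.approx(0.0)
        assert geometry.ew_of(np.array([geometry.dorsal_extreme]))[0] == pytest.approx(100.0)

    def test_automatic_extremes_near_true_poles(self, small_scene, small_movie):
        _, geometry, _, truth = small_scene
        assert np.linalg.norm(
            np.array(geometry.ventral_extreme) - np.array(truth.ventral_extreme)
        ) < 8
        assert np.linalg.norm(
            np.array(geometry.dorsal_extreme) - np.array(truth.dorsal_extreme)
        ) < 8

    def test_blank_frame_rejected(self):
        with pytest.raises(ValueError, match="blank|region"):
            estimate_geometry(np.zeros((64, 64)))

    def test_coincident_extremes_rejected(self):
        boundary = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="coincide"):
            EmbryoGeometry(boundary, (0.0, 0.0), (0.0, 0.0))


class TestNuclei:
    def test_sixty_nuclei_sixty_labels_each_holding_its_center(self):
        cfg = synthetic.default_config(
            seed=7, n_nuclei=60, window_frames={"nc13": 1},
            activity={"nc13": synthetic.WindowActivity(0)},
        )
        movie, truth = synthetic.generate_movie(cfg)
        nup = max_project(movie).channel("NUP")[0]
        nuclei = segment_nuclei(nup, estimate_geometry(nup))
        assert nuclei.n_nuclei == 60
        labels = {nuclei.label_at(n.center) for n in truth.nuclei}
        assert 0 not in labels and len(labels) == 60

    def test_empty_frame_zero_labels(self):
        nuclei = segment_nuclei(np.zeros((32, 32)))
        assert nuclei.n_nuclei == 0

    def test_touching_rings_split_by_seeded_watershed(self):
        img = np.zeros((40, 60))
        yy, xx = np.mgrid[0:40, 0:60]
        for cy, cx in ((20.0, 24.0), (20.0, 35.0)):  # centers 11 px apart, R=6
            d = np.hypot(yy - cy, xx - cx)
            img[(d <= 6) & (d >= 4)] = 1.0
        nuclei = segment_nuclei(img, min_area=15)
        assert nuclei.n_nuclei == 2
        l1, l2 = nuclei.label_at((20, 24)), nuclei.label_at((20, 35))
        assert l1 > 0 and l2 > 0 and l1 != l2


def _disk_nuclei(shape=(40, 40), center=(20, 12), radius=6):
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    labels[np.hypot(yy - center[0], xx - center[1]) <= radius] = 1
    return NucleiLabels(labels, {1: (float(center[0]), float(center[1]))})


def _cluster(img, cy, cx, n, value=1.0):
    # a compact 4-connected cluster of n pixels around (cy, cx)
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    d = np.hypot(yy - cy, xx - cx).ravel()
    order = np.argsort(d, kind="stable")[:n]
    img.ravel()[order] = value


class TestDetectDots:
    policy = ThresholdPolicy()

    def test_blank_frame_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            dots = detect_dots(np.zeros((32, 32)), self.policy, _disk_nuclei(),
                               presmoothed=True)
        assert dots == []

    def test_cluster_outside_nuclei_excluded(self):
        img = np.zeros((40, 40))
        _cluster(img, 20, 12, 9)   # inside the nucleus
        _cluster(img, 20, 32, 9)   # outside all nuclei
        dots = detect_dots(img, self.policy, _disk_nuclei(), presmoothed=True)
        assert len(dots) == 1
        assert dots[0].nucleus == 1 and dots[0].pixel_count == 9

    def test_three_pixel_cluster_never_called(self):
        img = np.zeros((40, 40))
        _cluster(img, 20, 12, 3)
        assert detect_dots(img, self.policy, _disk_nuclei(), presmoothed=True) == []

    def test_largest_cluster_wins_within_a_nucleus(self):
        img = np.zeros((40, 40))
        _cluster(img, 17, 12, 5)
        _cluster(img, 23, 12, 8)
        dots = detect_dots(img, self.policy, _disk_nuclei(), presmoothed=True)
        assert len(dots) == 1 and dots[0].pixel_count == 8

    def test_movie_scope_requires_movie_max(self):
        policy = dataclasses.replace(self.policy, max_scope="movie")
        with pytest.raises(ValueError, match="movie_max"):
            detect_dots(np.ones((8, 8)), policy, _disk_nuclei(), presmoothed=True)

    def test_counts_match_truth_on_synthetic_frames(self, small_scene):
        proj, _, nuclei, truth = small_scene
        for f in truth.frames:
            dots = detect_dots(proj.channel("MCP")[f.frame], self.policy, nuclei,
                               frame_index=f.frame)
            assert len(dots) == f.n_active

    def test_at_most_one_dot_per_nucleus(self, small_scene):
        proj, _, nuclei, truth = small_scene
        for f in truth.frames:
            dots = detect_dots(proj.channel("MCP")[f.frame], self.policy, nuclei,
                               frame_index=f.frame)
            owners = [d.nucleus for d in dots]
            assert len(owners) == len(set(owners))


class TestThresholdMonotonicity:
    def test_suprathreshold_support_nested_and_counts_non_increasing(self, small_scene):
        proj, _, nuclei, truth = small_scene
        from ms2quant.segmentation import smooth as _smooth

        for f in truth.frames:
            sm = _smooth(proj.channel("MCP")[f.frame], 0.55)
            masks = {b: sm > b * sm.max() for b in (0.25, 0.30, 0.35)}
            assert np.all(masks[0.35] <= masks[0.30])
            assert np.all(masks[0.30] <= masks[0.25])
            counts = {
                b: len(detect_dots(sm, dataclasses.replace(ThresholdPolicy(), bth_fraction=b),
                                   nuclei, presmoothed=True))
                for b in (0.25, 0.30, 0.35)
            }
            assert counts[0.25] >= counts[0.30] >= counts[0.35]


def _flood_fill_components(mask):
    """Independent 4-connected component oracle (BFS flood fill)."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    ny, nx = mask.shape
    for sy in range(ny):
        for sx in range(nx):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            queue, comp = [(sy, sx)], set()
            seen[sy, sx] = True
            while queue:
                y, x = queue.pop()
                comp.add((y, x))
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        queue.append((yy, xx))
            comps.append(frozenset(comp))
    return set(comps)


def test_connected_components_match_flood_fill_oracle():
    from skimage.measure import label as cc_label

    rng = np.random.default_rng(123)
    for density in (0.2, 0.4, 0.6):
        for _ in range(20):
            mask = rng.uniform(size=(16, 16)) < density
            lbl = cc_label(mask, connectivity=1)
            got = {
                frozenset(map(tuple, np.argwhere(lbl == k)))
                for k in range(1, lbl.max() + 1)
            }
            assert got == _flood_fill_components(mask)


class TestDotSize:
    def test_eight_pixel_dot_has_size_two(self):
        dot = Dot(0, np.zeros((8, 2), dtype=int), (0.0, 0.0), 1, 1.0)
        assert dot.size_metric == 2.0

    def test_frame_mean_of_4_and_12_pixels_is_two(self):
        dots = [
            Dot(0, np.zeros((4, 2), dtype=int), (0.0, 0.0), 1, 1.0),
            Dot(0, np.zeros((12, 2), dtype=int), (5.0, 5.0), 2, 1.0),
        ]
        assert window_dot_size({0: dots}) == 2.0

    def test_no_dots_raises(self):
        with pytest.raises(ValueError, match="no dots"):
            window_dot_size({0: []})

    def test_recovered_window_size_within_ten_percent_of_truth(self, small_scene):
        proj, _, nuclei, truth = small_scene
        dots_by_frame = {
            f.frame: detect_dots(proj.channel("MCP")[f.frame], ThresholdPolicy(),
                                 nuclei, frame_index=f.frame)
            for f in truth.frames
        }
        for lbl, w in truth.windows.items():
            if w["mean_dot_area"] is None:
                continue
            frames = range(*w["frames"])
            got = window_dot_size({t: dots_by_frame[t] for t in frames})
            assert got == pytest.approx(w["mean_dot_area"] / 4.0, rel=0.10)
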