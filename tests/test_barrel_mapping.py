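"""Normalized-barrel transform, Gaussian maps, position statistics."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon

from texturemap import barrel_mapping as bm
from texturemap import synthetic_data as sd

DIAG = np.sqrt(2) / 2


def canonical_circle(n=64):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([np.cos(th), np.sin(th)]))


CANONICAL_ANCHORS = ((-DIAG, -DIAG), (DIAG, DIAG))


class TestNormalizeToBarrel:
    def test_canonical_input_is_identity(self, rng):
        pts = rng.random((10, 2)) * 1.2 - 0.6
        nb = bm.normalize_to_barrel(pts, canonical_circle(), CANONICAL_ANCHORS)
        assert np.allclose(nb.coords, pts, atol=1e-9)

    def test_center_maps_to_zero_radial(self):
        poly = sd.default_barrel_polygon()
        anchors = ((150 - 130 * DIAG, 150 - 130 * DIAG), (150 + 130 * DIAG, 150 + 130 * DIAG))
        nb = bm.normalize_to_barrel(np.array([[150.0, 150.0]]), poly, anchors)
        assert nb.radial_distance[0] < 1e-9

    def test_on_diagonal_points_have_zero_diagonal_distance(self):
        poly = sd.default_barrel_polygon()
        anchors = ((150 - 130 * DIAG, 150 - 130 * DIAG), (150 + 130 * DIAG, 150 + 130 * DIAG))
        pts = np.array([[150 + t * DIAG, 150 + t * DIAG] for t in (-50, 0, 30)])
        nb = bm.normalize_to_barrel(pts, poly, anchors)
        assert np.abs(nb.diagonal_distance).max() < 1e-9

    def test_membership_preserved(self, clustered_population):
        poly = sd.default_barrel_polygon()
        anchors = ((150 - 130 * DIAG, 150 - 130 * DIAG), (150 + 130 * DIAG, 150 + 130 * DIAG))
        pts = clustered_population.table[["x_px", "y_px"]].to_numpy()
        nb = bm.normalize_to_barrel(pts, poly, anchors)
        out_poly = Polygon(nb.outline)
        inside = shapely.contains_xy(out_poly, nb.coords[:, 0], nb.coords[:, 1])
        assert inside.all()

    def test_degenerate_polygon_rejected(self):
        flat = np.array([[0, 0], [1, 0], [2, 0], [0, 0]])
        with pytest.raises(Exception):
            bm.normalize_to_barrel(np.zeros((1, 2)), flat, CANONICAL_ANCHORS)


def brute_force_map(coords_px, sigma, shape):
    """Per-pixel double loop oracle for the Gaussian-sum map."""
    h, w = shape
    m = np.zeros(shape)
    for yy in range(h):
        for xx in range(w):
            for x0, y0 in coords_px:
                m[yy, xx] += np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))
    return m


class TestBuildTextureMaps:
    def test_single_neuron_dominates_its_map(self):
        stack = bm.build_texture_maps(np.array([[0.0, 0.0]]), ["P120"])
        cy, cx = (np.array(bm.RASTER_SHAPE) - 1) // 2
        assert stack.norm["P120"][cy, cx] > 0.99

    def test_mirror_symmetric_labels_give_mirror_maps(self):
        coords = np.array([[-0.5, 0.0], [0.5, 0.0]])
        stack = bm.build_texture_maps(coords, ["P120", "P320"], shape=(41, 41))
        a = stack.raw["P120"]
        b = stack.raw["P320"]
        assert np.abs(a - b[:, ::-1]).max() < 1e-9

    def test_matches_per_pixel_oracle(self, rng):
        coords = rng.random((5, 2)) * 1.6 - 0.8
        labels = ["P120", "P120", "P320", "P600", "P1000"]
        shape, sigma = (16, 16), 3.0
        stack = bm.build_texture_maps(coords, labels, sigma=sigma, shape=shape)
        pix = bm.normalized_to_pixels(coords, shape)
        for lab in ("P120", "P320"):
            sel = pix[np.asarray(labels, object) == lab]
            oracle = brute_force_map(sel, sigma, shape)
            assert np.abs(stack.raw[lab] - oracle).max() < 1e-12

    def test_duplicating_a_neuron_doubles_its_contribution(self):
        c = np.array([[0.2, -0.1]])
        one = bm.build_texture_maps(c, ["P120"], shape=(21, 21))
        two = bm.build_texture_maps(np.vstack([c, c]), ["P120", "P120"], shape=(21, 21))
        assert np.allclose(two.raw["P120"], 2 * one.raw["P120"], atol=1e-12)

    def test_normalized_maps_sum_to_one_where_signal(self, clustered_population):
        t = clustered_population.table
        m = t["cluster_id"] >= 0
        coords = (t.loc[m, ["x_px", "y_px"]].to_numpy() - 150.0) / 130.0
        stack = bm.build_texture_maps(coords, t.loc[m, "truth_label"].to_numpy())
        total_raw = np.sum(list(stack.raw.values()), axis=0)
        total_norm = np.sum(list(stack.norm.values()), axis=0)
        strong = total_raw > 100 * stack.eps
        assert np.abs(total_norm[strong] - 1.0).max() < 0.01

    def test_weak_pixels_render_white(self):
        stack = bm.build_texture_maps(np.array([[0.0, 0.0]]), ["P120"], shape=(61, 61), sigma=2.0)
        assert np.allclose(stack.color[0, 0], 1.0)  # far corner: no cells

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            bm.build_texture_maps(np.zeros((1, 2)), ["P120"], sigma=0.0)

    def test_tiff_output(self, tmp_path):
        import tifffile

        stack = bm.build_texture_maps(np.zeros((1, 2)), ["P120"], shape=(32, 32))
        p = tmp_path / "maps.tif"
        stack.write_tiff(p)
        assert tifffile.imread(p).shape == (1, 32, 32)  # one channel per label
        assert tifffile.imread(tmp_path / "maps_rgb.tif").shape == (32, 32, 3)


class TestDiagonalRadialStats:
    def test_planted_radial_gradient_detected(self, rng):
        # coarse textures at the perimeter, fine near the center
        n = 60
        th = rng.uniform(0, 2 * np.pi, n)
        r = np.concatenate([rng.uniform(0.7, 1.0, n // 2), rng.uniform(0.0, 0.3, n - n // 2)])
        labels = np.array(
            list(rng.choice(["P120", "P320"], n // 2)) + list(rng.choice(["P600", "P1000"], n - n // 2))
        )
        diag = r * np.sin(th)
        st = bm.diagonal_radial_stats(None, labels, diagonal_distance=diag, radial_distance=r)
        assert st.coarse_mean_radial > st.fine_mean_radial
        assert st.p_coarse_fine_radial < 0.01

    def test_single_label_reports_distances_without_tests(self, rng):
        r = rng.uniform(0, 1, 10)
        st = bm.diagonal_radial_stats(None, ["P120"] * 10, diagonal_distance=r - 0.5, radial_distance=r)
        assert np.isnan(st.p_anova_radial)
        assert len(st.per_label) == 1

    def test_small_groups_excluded_from_tests(self, rng):
        labels = ["P120"] * 8 + ["P320"]
        r = rng.uniform(0, 1, 9)
        st = bm.diagonal_radial_stats(None, labels, diagonal_distance=r, radial_distance=r)
        assert st.excluded_labels == ("P320",)


class TestDominantTexture:
    @staticmethod
    def _counts(rows):
        return pd.DataFrame(rows, columns=["barrel", "row", "arc", "label", "count"])

    def test_strict_argmax(self):
        df = self._counts([("C2", "C", 2, l, c) for l, c in
                           zip(["P120", "P320", "P600", "P1000"], [5, 1, 1, 1])])
        out = bm.dominant_texture(df)
        assert out.loc[0, "dominant"] == "P120"
        assert out.loc[0, "n_preferring"] == 8

    def test_tie_yields_no_dominant(self):
        df = self._counts([("D1", "D", 1, "P120", 3), ("D1", "D", 1, "P320", 3)])
        assert bm.dominant_texture(df).loc[0, "dominant"] is None

    def test_agrees_with_brute_force_argmax(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 6, 4)
            df = self._counts([("B", "B", 1, l, int(c)) for l, c in
                               zip(["P120", "P320", "P600", "P1000"], counts)])
            dom = bm.dominant_texture(df).loc[0, "dominant"]
            mx = counts.max()
            if counts.sum() == 0 or (counts == mx).sum() > 1:
                assert dom is None
            else:
                assert dom == ["P120", "P320", "P600", "P1000"][int(np.argmax(counts))]
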