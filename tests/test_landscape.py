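"""Landscape-level analyses: familiarity fields, volcanoes, IDF/RIDF, quiver."""

import numpy as np
import pytest

import scenefam as sf
from scenefam.landscape import pairwise_sad_matrix

from conftest import identical_landscape, random_scene


def toy_landscape(rng, t=3, p=3, n=8, g=10):
    scenes = [[random_scene(rng, n=n, g=g) for _ in range(p)] for _ in range(t)]
    return sf.GridLandscape.from_scenes(scenes, g), scenes


class TestFamiliarityLandscape:
    def test_identical_scene_landscape_is_zero(self, rng):
        ls = identical_landscape(random_scene(rng), 3, 4)
        assert np.all(sf.familiarity_landscape(ls).values == 0)

    def test_matches_explicit_enumeration(self, rng):
        ls, scenes = toy_landscape(rng, 2, 2, n=4)
        field = sf.familiarity_landscape(ls)
        flat = [s for row in scenes for s in row]
        for r in range(2):
            for c in range(2):
                want = np.mean([sf.sad(scenes[r][c], o) for o in flat])
                assert field.values[r, c] == pytest.approx(want)

    def test_bounded_by_max_possible_sad(self, small_landscape):
        field = sf.familiarity_landscape(small_landscape)
        n = small_landscape.resolution
        bound = (small_landscape.gray_levels - 1) * int(
            np.asarray(sf.circular_mask(n)).sum())
        assert np.all(field.values <= bound)
        assert np.all(field.values >= 0)


class TestVolcano:
    def test_focal_cell_zero_and_oracle(self, rng):
        ls, scenes = toy_landscape(rng, 3, 3, n=6)
        field = sf.volcano(ls, (1, 2))
        assert field.values[1, 2] == 0
        for r in range(3):
            for c in range(3):
                assert field.values[r, c] == sf.sad(scenes[1][2], scenes[r][c])

    def test_out_of_bounds_focal(self, rng):
        ls, _ = toy_landscape(rng)
        with pytest.raises(IndexError):
            sf.volcano(ls, (5, 0))


class TestIdfSummary:
    @pytest.mark.parametrize("t,p", [(2, 2), (3, 5), (4, 1)])
    def test_vector_count_is_4tp(self, rng, t, p):
        ls, _ = toy_landscape(rng, t, p, n=6)
        _, nvec = sf.idf_summary(ls)
        assert nvec == 4 * t * p

    def test_distance_zero_mean_is_zero(self, small_landscape):
        summary, _ = sf.idf_summary(small_landscape)
        assert summary.mean_norm_diff[0] == 0
        assert np.all(summary.mean_norm_diff <= 1.0)
        assert np.all(summary.mean_norm_diff >= 0.0)

    def test_identical_landscape_flat_with_missing_p50(self, rng):
        ls = identical_landscape(random_scene(rng), 3, 3)
        summary, _ = sf.idf_summary(ls)
        assert np.all(summary.mean_norm_diff == 0)
        assert summary.p50_m is None

    def test_p50_matches_half_slice_enumeration_oracle(self, small_landscape):
        # independent oracle: enumerate every half-slice explicitly from
        # per-pair SADs, average per distance, locate the half-max crossing
        ls = small_landscape
        t, p = ls.shape
        def s(r, c):
            return ls.scene(r, c)
        gmax = 0
        pair = {}
        for r in range(t):
            for c in range(p):
                for r2 in range(t):
                    for c2 in range(p):
                        v = sf.sad(s(r, c), s(r2, c2))
                        pair[(r, c, r2, c2)] = v
                        gmax = max(gmax, v)
        halves = []
        for r in range(t):
            for c in range(p):
                east = [pair[(r, c, r, c2)] for c2 in range(c, p)]
                west = [pair[(r, c, r, c2)] for c2 in range(c, -1, -1)]
                north = [pair[(r, c, r2, c)] for r2 in range(r, t)]
                south = [pair[(r, c, r2, c)] for r2 in range(r, -1, -1)]
                halves += [east, west, north, south]
        assert len(halves) == 4 * t * p
        dmax = max(t, p) - 1
        mean = np.zeros(dmax + 1)
        for d in range(dmax + 1):
            vals = [h[d] for h in halves if len(h) > d]
            mean[d] = np.mean(vals) / gmax
        half = mean.max() / 2
        i = int(np.argmax(mean >= half))
        frac = (half - mean[i - 1]) / (mean[i] - mean[i - 1])
        want_p50 = ((i - 1) + frac) * ls.spacing_m
        summary, _ = sf.idf_summary(ls)
        np.testing.assert_allclose(summary.mean_norm_diff, mean)
        assert summary.p50_m == pytest.approx(want_p50)


class TestRidfSummary:
    @pytest.mark.parametrize("t,p", [(2, 3), (1, 4)])
    def test_vector_count_is_2tp(self, rng, t, p):
        ls, _ = toy_landscape(rng, t, p, n=6)
        _, nvec = sf.ridf_summary(ls, 45.0)
        assert nvec == 2 * t * p

    def test_angle_zero_mean_zero_and_fold_oracle(self, rng):
        ls, scenes = toy_landscape(rng, 2, 2, n=8)
        step = 30.0
        summary, _ = sf.ridf_summary(ls, step)
        assert summary.mean_norm_diff[0] == 0
        # oracle: explicit fold of each scene's full-turn curve
        curves = [sf.ridf_curve(s, step) for row in scenes for s in row]
        gmax = max(c.max() for c in curves)
        k = int(360 / step)
        nh = int(180 / step)
        vectors = []
        for c in curves:
            vectors.append([c[i] for i in range(nh + 1)])
            vectors.append([c[0]] + [c[k - i] for i in range(1, nh + 1)])
        want = np.mean(vectors, axis=0) / gmax
        np.testing.assert_allclose(summary.mean_norm_diff, want)

    def test_rotationally_symmetric_landscape_p50_missing(self):
        mask = np.asarray(sf.circular_mask(10))
        disk = sf.Scene(np.where(mask, 3, 0).astype(np.int16), 10)
        ls = identical_landscape(disk, 2, 2)
        summary, _ = sf.ridf_summary(ls, 30.0)
        assert np.all(summary.mean_norm_diff == 0)
        assert summary.p50_deg is None

    def test_resolution_trend_p50_non_increasing(self, small_world):
        """Coarser sensors have wider catchments: p50 falls as N rises."""
        idf_p50, ridf_p50 = [], []
        for n in (10, 20, 40):
            cfg = sf.RenderConfig(resolution=n, gray_levels=10)
            ls = sf.generate_landscape(small_world, 6, 6, 0.127, cfg)
            i, _ = sf.idf_summary(ls)
            r, _ = sf.ridf_summary(ls, 3.0)
            idf_p50.append(i.p50_m)
            ridf_p50.append(r.p50_deg)
        assert all(a >= b for a, b in zip(idf_p50[:-1], idf_p50[1:]))
        assert all(a >= b for a, b in zip(ridf_p50[:-1], ridf_p50[1:]))


class TestPathTroughAndQuiver:
    def test_zero_along_exact_copy_path(self, small_landscape, straight_path):
        # path scenes are rotated copies; the trough minimizes over rotation,
        # so cells on the path recover SAD 0
        field = sf.path_trough(small_landscape, straight_path, 45.0)
        for r, c in straight_path.cells:
            assert field.values[r, c] == 0

    def test_matches_double_loop_oracle(self, rng):
        ls, scenes = toy_landscape(rng, 3, 3, n=8)
        path = sf.rasterize_path(ls, [sf.Waypoint(0, 0), sf.Waypoint(0, 1)])
        step = 45.0
        field = sf.path_trough(ls, path, step)
        q = sf.quiver_field(ls, path, step)
        for r in range(3):
            for c in range(3):
                m, ang, _ = sf.best_rotation_match(scenes[r][c], path.scenes,
                                                   step)
                assert field.values[r, c] == m
                assert q.best_angle_deg[r, c] == ang % 360.0
        top = field.values.max()
        np.testing.assert_allclose(
            q.strength, np.clip(1 - field.values / top, 0, 1))

    def test_identical_landscape_all_zero_trough_full_strength(self, rng):
        ls = identical_landscape(random_scene(rng, n=8), 3, 3)
        path = sf.rasterize_path(ls, [sf.Waypoint(0, 0), sf.Waypoint(2, 0)])
        field = sf.path_trough(ls, path, 90.0)
        q = sf.quiver_field(ls, path, 90.0)
        # every cell matches the unrotated path copy at angle 0 exactly
        assert np.all(field.values == 0)
        assert np.all(q.strength == 1.0)

    def test_planted_quarter_turn_cell(self, rng):
        base = random_scene(rng, n=12)
        ls = identical_landscape(base, 2, 3)
        # plant a 90-degree rotated copy of the path scene at (1, 2)
        rot = sf.rotate_scene(base, 90)
        stack = ls.stack.copy()
        stack[1, 2] = rot.matrix
        ls = sf.GridLandscape(stack, ls.gray_levels, ls.spacing_m)
        path = sf.TrainingPath([base], np.array([0.0]), [(0, 0)], (0, 0))
        q = sf.quiver_field(ls, path, 1.0)
        trough = sf.path_trough(ls, path, 1.0)
        # a small plateau of angles near 270 undoes the quarter turn exactly
        # (nearest-neighbor angle quantization); ties break low
        assert trough.values[1, 2] == 0
        assert abs(q.best_angle_deg[1, 2] - 270.0) <= 6.0

    def test_empty_path_rejected(self, small_landscape):
        with pytest.raises(ValueError):
            sf.TrainingPath([], np.array([]), [], None)


def test_pairwise_matrix_symmetry(small_landscape):
    m = pairwise_sad_matrix(small_landscape)
    assert np.array_equal(m, m.T)
    assert np.all(np.diag(m) == 0)
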