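"""Scene filtering, cloud masking, medoid compositing, aggregation."""

import numpy as np
import pandas as pd
import pytest

import designmap as dm
from designmap.errors import ValidationError
from designmap.compositing import (Scene, SceneStack, filter_scenes,
                                   mask_clouds, medoid_composite,
                                   aggregate_to_pixels, build_predictor_table,
                                   read_scene_stack, write_scene_stack)


def _grid(ny, nx, side=10.0):
    return dm.GridDefinition(x0=0.0, y0=ny * side, nx=nx, ny=ny,
                             pixel_side=side)


def _scene(date, bands, cloud_prob=None, cloud_fraction=0.0, names=None):
    bands = np.asarray(bands, float)
    if cloud_prob is None:
        cloud_prob = np.zeros(bands.shape[1:])
    names = names or tuple(f"b{i}" for i in range(bands.shape[0]))
    return Scene(date=date, bands=bands, band_names=tuple(names),
                 cloud_prob=np.asarray(cloud_prob, float),
                 cloud_fraction=cloud_fraction)


def _medoid_oracle(stack):
    """Exhaustive per-cell medoid search, loop form."""
    S = stack.n_scenes
    B, H, W = stack.scenes[0].bands.shape
    out = np.full((B, H, W), np.nan)
    chosen = np.full((H, W), -1)
    for r in range(H):
        for c in range(W):
            obs = [(s, stack.scenes[s].bands[:, r, c])
                   for s in range(S) if stack.scenes[s].valid_mask[r, c]]
            if not obs:
                continue
            med = np.median(np.array([v for _, v in obs]), axis=0)
            best, best_d = None, np.inf
            for s, v in obs:  # earliest date wins ties (scenes sorted)
                d = float(((v - med) ** 2).sum())
                if d < best_d:
                    best, best_d = s, d
            out[:, r, c] = stack.scenes[best].bands[:, r, c]
            chosen[r, c] = best
    return out, chosen


class TestFilterScenes:
    def _stack(self):
        g = _grid(2, 2)
        scenes = [
            _scene("2020-06-05", np.ones((1, 2, 2)), cloud_fraction=5),
            _scene("2020-07-01", np.ones((1, 2, 2)), cloud_fraction=15),
            _scene("2020-08-25", np.ones((1, 2, 2)), cloud_fraction=10),
            _scene("2020-07-15", np.ones((1, 2, 2)), cloud_fraction=25),
        ]
        return SceneStack(tuple(scenes), g)

    def test_window_and_cloud_threshold(self):
        out = filter_scenes(self._stack(), "2020-06-10", "2020-08-20", 20.0)
        assert [s.date for s in out.scenes] == ["2020-07-01"]

    def test_identity_filter(self):
        st = self._stack()
        out = filter_scenes(st, "2020-01-01", "2020-12-31", 100.0)
        assert out.n_scenes == st.n_scenes

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError, match="no scenes"):
            filter_scenes(self._stack(), "2020-06-10", "2020-08-20", 5.0)


class TestMaskClouds:
    def test_threshold_rule(self):
        g = _grid(1, 2)
        s1 = _scene("2020-06-01", np.ones((1, 1, 2)), [[40.0, 40.0]])
        s2 = _scene("2020-06-02", np.ones((1, 1, 2)), [[60.0, 40.0]])
        out = mask_clouds(SceneStack((s1, s2), g), 50.0)
        assert out.scenes[0].valid_mask.all()
        np.testing.assert_array_equal(out.scenes[1].valid_mask,
                                      [[False, True]])

    def test_all_masked_scene_contributes_nothing(self):
        g = _grid(1, 1)
        s1 = _scene("2020-06-01", [[[5.0]]], [[100.0]])
        s2 = _scene("2020-06-02", [[[7.0]]], [[0.0]])
        comp = medoid_composite(mask_clouds(SceneStack((s1, s2), g)))
        assert comp.bands[0, 0, 0] == 7.0


class TestMedoid:
    def test_single_observation(self):
        g = _grid(2, 2)
        s = _scene("2020-06-01", np.random.default_rng(0).random((3, 2, 2)))
        comp = medoid_composite(SceneStack((s,), g))
        np.testing.assert_array_equal(comp.bands, s.bands)
        assert comp.valid.all()

    def test_idempotent_on_identical_scenes(self):
        g = _grid(3, 3)
        bands = np.random.default_rng(1).random((4, 3, 3))
        scenes = tuple(_scene(f"2020-06-0{i+1}", bands) for i in range(3))
        comp = medoid_composite(SceneStack(scenes, g))
        np.testing.assert_array_equal(comp.bands, bands)

    def test_exact_median_vector_selected(self):
        g = _grid(1, 1)
        obs = [[[[1.0]], [[10.0]]], [[[2.0]], [[20.0]]], [[[3.0]], [[30.0]]]]
        scenes = tuple(_scene(f"2020-06-0{i+1}", np.array(o))
                       for i, o in enumerate(obs))
        comp = medoid_composite(SceneStack(scenes, g))
        # middle observation equals the per-band median vector exactly
        np.testing.assert_array_equal(comp.bands[:, 0, 0], [2.0, 20.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        """Medoid selection equals brute-force search at every cell."""
        rng = np.random.default_rng(seed)
        g = _grid(8, 8)
        scenes = []
        for i in range(5):
            prob = np.where(rng.random((8, 8)) < 0.3, 90.0, 10.0)
            scenes.append(_scene(f"2020-06-{10 + i:02d}",
                                 rng.random((10, 8, 8)), prob))
        stack = mask_clouds(SceneStack(tuple(scenes), g))
        comp = medoid_composite(stack)
        oracle_bands, oracle_choice = _medoid_oracle(stack)
        # the chosen observation must achieve the oracle's minimal distance
        # (exact ties may resolve to either tied scene)
        for r in range(8):
            for c in range(8):
                if oracle_choice[r, c] < 0:
                    assert np.isnan(comp.bands[:, r, c]).all()
                    continue
                obs = np.array([stack.scenes[s].bands[:, r, c]
                                for s in range(stack.n_scenes)
                                if stack.scenes[s].valid_mask[r, c]])
                med = np.median(obs, axis=0)
                d_impl = ((comp.bands[:, r, c] - med) ** 2).sum()
                d_best = ((oracle_bands[:, r, c] - med) ** 2).sum()
                assert d_impl <= d_best + 1e-12

    def test_scene_order_invariance(self):
        rng = np.random.default_rng(5)
        g = _grid(6, 6)
        scenes = [_scene(f"2020-06-{10 + i:02d}", rng.random((4, 6, 6)))
                  for i in range(6)]
        c1 = medoid_composite(SceneStack(tuple(scenes), g))
        c2 = medoid_composite(SceneStack(tuple(reversed(scenes)), g))
        np.testing.assert_array_equal(c1.bands, c2.bands)

    def test_all_invalid_cell_flagged(self):
        g = _grid(1, 2)
        s = _scene("2020-06-01", np.ones((1, 1, 2)), [[100.0, 0.0]])
        comp = medoid_composite(mask_clouds(SceneStack((s,), g)))
        assert not comp.valid[0, 0] and comp.valid[0, 1]
        assert np.isnan(comp.bands[0, 0, 0])


def _bilinear_oracle(comp, px, py):
    """Hand-coded 4-neighbor bilinear at one point, band 0."""
    g = comp.grid
    fx = (px - g.x0) / g.pixel_side - 0.5
    fy = (g.y0 - py) / g.pixel_side - 0.5
    c0, r0 = int(np.floor(fx)), int(np.floor(fy))
    tx, ty = fx - c0, fy - r0
    v = comp.bands[0]
    c1, r1 = min(c0 + 1, g.nx - 1), min(r0 + 1, g.ny - 1)
    c0, r0 = max(c0, 0), max(r0, 0)
    tx, ty = min(max(tx, 0.0), 1.0), min(max(ty, 0.0), 1.0)
    return ((1 - ty) * ((1 - tx) * v[r0, c0] + tx * v[r0, c1]) +
            ty * ((1 - tx) * v[r1, c0] + tx * v[r1, c1]))


class TestAggregation:
    def _pop(self, nx=4, ny=4, side=20.0):
        return dm.tessellate_grid((0, 0, nx * side, ny * side), side,
                                  min(2, nx * ny))

    def test_mean_of_covered_cells(self):
        # one 20 m analysis pixel covers four 10 m cells
        pop = self._pop(1, 1)
        comp = medoid_composite(SceneStack(
            (_scene("2020-06-01", [[[1.0, 2.0], [3.0, 4.0]]]),), _grid(2, 2)))
        out = aggregate_to_pixels(comp, pop, "mean")
        assert out.iloc[0, 0] == pytest.approx(2.5)

    @pytest.mark.parametrize("method", ["mean", "bilinear"])
    def test_constant_field(self, method):
        pop = self._pop(3, 3)
        comp = medoid_composite(SceneStack(
            (_scene("2020-06-01", np.full((2, 12, 12), 7.0)),), _grid(12, 12, 5.0)))
        out = aggregate_to_pixels(comp, pop, method)
        np.testing.assert_allclose(out.to_numpy(), 7.0)

    def test_bilinear_matches_oracle(self):
        rng = np.random.default_rng(8)
        pop = dm.tessellate_grid((0, 0, 92, 92), 23.0, 2)  # 4x4 of 23 m
        comp = medoid_composite(SceneStack(
            (_scene("2020-06-01", rng.random((1, 10, 10))),), _grid(10, 10)))
        out = aggregate_to_pixels(comp, pop, "bilinear")
        for i in range(pop.n_pixels):
            px, py = pop.data.loc[i, ["x", "y"]]
            assert out.iloc[i, 0] == pytest.approx(
                _bilinear_oracle(comp, px, py), abs=1e-12)

    @pytest.mark.parametrize("method", ["mean", "bilinear"])
    def test_linearity(self, method):
        rng = np.random.default_rng(9)
        pop = self._pop(4, 4)
        base = rng.random((2, 16, 16))
        g = _grid(16, 16, 5.0)
        comp_x = medoid_composite(SceneStack((_scene("2020-06-01", base),), g))
        comp_ax = medoid_composite(SceneStack(
            (_scene("2020-06-01", 3.0 * base + 2.0),), g))
        fx = aggregate_to_pixels(comp_x, pop, method).to_numpy()
        fax = aggregate_to_pixels(comp_ax, pop, method).to_numpy()
        np.testing.assert_allclose(fax, 3.0 * fx + 2.0, rtol=1e-10)

    def test_uncovered_pixel_gets_nan(self):
        pop = self._pop(4, 4)  # 80 m extent
        comp = medoid_composite(SceneStack(
            (_scene("2020-06-01", np.ones((1, 2, 2))),), _grid(2, 2)))  # 20 m
        out = aggregate_to_pixels(comp, pop, "mean")
        assert out.iloc[:, 0].isna().sum() > 0


class TestPredictorTable:
    def test_bands_times_years(self, tmp_path):
        """10 bands and three yearly composites give 30 predictor columns."""
        pop = dm.tessellate_grid((0, 0, 160, 160), 20.0, 4)
        stacks = {y: dm.simulate_scene_stack(_grid(16, 16), n_scenes=4,
                                             n_bands=10,
                                             cloud_cover_fraction=0.1,
                                             seed=y, year=y)
                  for y in (2020, 2021, 2022)}
        pop2 = build_predictor_table(stacks, pop, start_date="06-10",
                                     end_date="08-20", max_cloud_pct=20.0,
                                     gap_fill=True)
        assert len(pop2.predictor_names) == 30
        assert "red_2020" in pop2.predictor_names
        assert "swir2_2022" in pop2.predictor_names

    def test_persistent_cloud_without_gap_fill_rejected(self):
        """Pixels never observed cloud-free must fail validation."""
        pop = dm.tessellate_grid((0, 0, 40, 40), 20.0, 2)
        bands = np.ones((1, 4, 4))
        prob = np.zeros((4, 4))
        prob[:2, :2] = 100.0  # one analysis pixel permanently cloudy
        stack = SceneStack(
            (_scene("2020-07-01", bands, prob, names=("nir",)),), _grid(4, 4))
        with pytest.raises(ValidationError, match="missing"):
            build_predictor_table({2020: stack}, pop)

    def test_single_band_single_year(self):
        pop = dm.tessellate_grid((0, 0, 40, 40), 20.0, 2)
        stack = SceneStack(
            (_scene("2021-07-01", np.ones((1, 4, 4)), names=("nir",)),),
            _grid(4, 4))
        pop2 = build_predictor_table({2021: stack}, pop)
        assert pop2.predictor_names == ["nir_2021"]

    def test_duplicate_year_rejected(self):
        pop = dm.tessellate_grid((0, 0, 40, 40), 20.0, 2)
        with pytest.raises(ValidationError, match="at least one"):
            build_predictor_table({}, pop)

    def test_stack_round_trip(self, tmp_path):
        stack = dm.simulate_scene_stack(_grid(6, 6), n_scenes=3, n_bands=4,
                                        seed=3)
        write_scene_stack(stack, tmp_path / "y2020")
        back = read_scene_stack(tmp_path / "y2020")
        assert back.n_scenes == 3
        assert back.band_names == stack.band_names
        np.testing.assert_allclose(back.scenes[0].bands,
                                   stack.scenes[0].bands, rtol=1e-6)
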