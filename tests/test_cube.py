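"""Data-cube calibration pipeline, parameter mapping and phantoms."""

import numpy as np
import pytest

from hsiq.cube import (
    DataCube,
    ParameterMaps,
    PhantomScene,
    Tile,
    TileSet,
    calibrate_tiles,
    flat_field,
    make_phantom_cube,
    map_parameters,
    roi_stats,
    tile_reflectances_from_standards,
    to_reflectance,
    LAB_STANDARD_REFLECTANCES,
)
from hsiq.envi import read_envi, write_envi
from hsiq.tissue import TissueParams

WL = np.linspace(420.0, 830.0, 8)


def flat_cube(value, shape=(20, 30), wl=WL, state="raw"):
    return DataCube(np.full(shape + (wl.size,), float(value)), wl, state)


class TestFlatField:
    def test_uniform_standard_is_identity(self):
        raw = flat_cube(7.0)
        std = flat_cube(3.0)
        out = flat_field(raw, std)
        assert np.allclose(out.data, raw.data)
        assert out.state == "flat-fielded"

    def test_half_maximum_pixel_doubles(self):
        raw = flat_cube(10.0)
        std = flat_cube(4.0)
        std.data[5, 5, :] = 2.0  # half of the per-band max
        out = flat_field(raw, std)
        assert np.allclose(out.data[5, 5], 20.0)
        assert np.allclose(out.data[0, 0], 10.0)

    def test_gradient_scene_flattens_to_uniform(self):
        """Flat scene x smooth illumination gradient: after correction the
        per-band coefficient of variation vanishes."""
        rows, cols = 24, 36
        g = 1.0 - 0.4 * (np.linspace(-1, 1, rows)[:, None] ** 2
                         + np.linspace(-1, 1, cols)[None, :] ** 2) / 2
        scene = 5.0 * g[:, :, None] * np.ones(WL.size)
        std = 2.0 * g[:, :, None] * np.ones(WL.size)
        out = flat_field(DataCube(scene, WL), DataCube(std, WL))
        cv = out.data.std(axis=(0, 1)) / out.data.mean(axis=(0, 1))
        assert np.all(cv < 1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            flat_field(flat_cube(1.0, (10, 10)), flat_cube(1.0, (12, 10)))

    def test_zero_standard_pixel_rejected(self):
        std = flat_cube(1.0)
        std.data[0, 0, 0] = 0.0
        with pytest.raises(ValueError):
            flat_field(flat_cube(1.0), std)


def six_tiles(values=(0.02, 0.10, 0.20, 0.40, 0.60, 0.80)):
    rects = [(2, 6, 2 + 5 * i, 6 + 5 * i) for i in range(len(values))]
    return TileSet(tuple(Tile(r, v) for r, v in zip(rects, values)))


class TestCalibration:
    def test_exact_line_recovered(self):
        tiles = six_tiles()
        cube = flat_cube(0.0, (10, 40), state="flat-fielded")
        for t in tiles.tiles:
            r0, r1, c0, c1 = t.rect
            cube.data[r0:r1, c0:c1] = 100.0 * t.reflectance + 5.0
        curves = calibrate_tiles(cube, tiles)
        assert np.allclose(curves.slope, 100.0, rtol=1e-10)
        assert np.allclose(curves.intercept, 5.0, rtol=1e-8)

    def test_lab_standard_values_noise_free(self):
        """The five manufacturer standards reproduce the generating line."""
        tiles = six_tiles(LAB_STANDARD_REFLECTANCES)
        cube = flat_cube(0.0, (10, 40), state="flat-fielded")
        for t in tiles.tiles:
            r0, r1, c0, c1 = t.rect
            cube.data[r0:r1, c0:c1] = 812.5 * t.reflectance + 13.25
        curves = calibrate_tiles(cube, tiles)
        assert np.allclose(curves.slope, 812.5, atol=1e-10 * 812.5)
        assert np.allclose(curves.intercept, 13.25, atol=1e-8)
        assert np.all(curves.residual_rms < 1e-10)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        tiles = six_tiles()
        rng = np.random.default_rng(8)
        cube = flat_cube(0.0, (10, 40), state="flat-fielded")
        cube.data += rng.standard_normal(cube.data.shape)
        for t in tiles.tiles:
            r0, r1, c0, c1 = t.rect
            cube.data[r0:r1, c0:c1] += 50.0 * t.reflectance + 2.0
        curves = calibrate_tiles(cube, tiles)
        refl = np.array([t.reflectance for t in tiles.tiles])
        means = np.array([
            cube.data[t.rect[0]:t.rect[1], t.rect[2]:t.rect[3]].mean(axis=(0, 1))
            for t in tiles.tiles
        ])
        for band in range(WL.size):
            m_ref, b_ref = np.polyfit(refl, means[:, band], 1)
            assert curves.slope[band] == pytest.approx(m_ref, rel=1e-10)
            assert curves.intercept[band] == pytest.approx(b_ref, rel=1e-8)

    def test_too_few_tiles_rejected(self):
        with pytest.raises(ValueError):
            TileSet((Tile((0, 2, 0, 2), 0.5),))

    def test_identical_tile_values_rejected(self):
        tiles = six_tiles((0.4,) * 6)
        cube = flat_cube(1.0, (10, 40), state="flat-fielded")
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_tiles(cube, tiles)


class TestToReflectance:
    def test_identity_curves(self):
        from hsiq.cube import CalibrationCurves

        cube = flat_cube(0.37, state="flat-fielded")
        curves = CalibrationCurves(
            np.ones(WL.size), np.zeros(WL.size), np.zeros(WL.size)
        )
        out = to_reflectance(cube, curves)
        assert np.allclose(out.data, 0.37)
        assert out.state == "reflectance"

    def test_tile_pixels_map_to_known_reflectance(self):
        tiles = six_tiles()
        cube = flat_cube(0.0, (10, 40), state="flat-fielded")
        for t in tiles.tiles:
            r0, r1, c0, c1 = t.rect
            cube.data[r0:r1, c0:c1] = 240.0 * t.reflectance + 11.0
        curves = calibrate_tiles(cube, tiles)
        refl = to_reflectance(cube, curves)
        for t in tiles.tiles:
            r0, r1, c0, c1 = t.rect
            assert np.allclose(refl.data[r0:r1, c0:c1], t.reflectance,
                               atol=1e-10)

    def test_phantom_round_trip_exact(self, gingiva_lookup):
        """Known (gradient, m, b), zero noise: flat-field then calibration
        recovers the generated reflectance to numerical precision."""
        scene = _scene(noise_sigma=0.0)
        raw, std, tiles, truth = make_phantom_cube(scene, gingiva_lookup)
        ff = flat_field(raw, std)
        curves = calibrate_tiles(ff, tiles)
        rd = to_reflectance(ff, curves)
        assert np.allclose(rd.data, truth["reflectance"], atol=1e-9)


def _scene(noise_sigma=0.0, s_top=0.70, s_bottom=0.35):
    # two-finger occlusion scene: perfused tissue near resting arterial
    # saturation on top, an occluded desaturated region below
    return PhantomScene(
        shape=(48, 64),
        regions=(
            ((4, 20, 4, 60), TissueParams(0.02, s_top, 0.02, 2.0)),
            ((24, 40, 4, 60), TissueParams(0.02, s_bottom, 0.02, 2.0)),
        ),
        tile_rects=tuple((42, 47, 3 + 10 * i, 9 + 10 * i) for i in range(6)),
        tile_reflectances=(0.02, 0.10, 0.20, 0.40, 0.60, 0.80),
        noise_sigma=noise_sigma,
    )


class TestMapping:
    def test_uniform_scene_gives_constant_maps(self, gingiva_ann,
                                               gingiva_lookup):
        spec = gingiva_lookup.spectrum(TissueParams(0.02, 0.6, 0.02, 2.0))
        cube = DataCube(
            np.broadcast_to(spec, (12, 14, spec.size)).copy(),
            gingiva_lookup.wavelengths, "reflectance",
        )
        maps = map_parameters(cube, gingiva_ann, binning=1)
        for name in maps.names:
            img = getattr(maps, name)
            assert np.nanstd(img) < 1e-12

    def test_masked_pixels_are_excluded(self, gingiva_ann, gingiva_lookup):
        spec = gingiva_lookup.spectrum(TissueParams(0.02, 0.6, 0.02, 2.0))
        cube = DataCube(
            np.broadcast_to(spec, (10, 10, spec.size)).copy(),
            gingiva_lookup.wavelengths, "reflectance",
        )
        mask = np.ones((10, 10), bool)
        mask[:5] = False
        maps = map_parameters(cube, gingiva_ann, mask=mask, binning=1)
        assert np.all(np.isnan(maps.S[:5]))
        assert not np.any(np.isnan(maps.S[5:]))

    def test_commutes_with_cropping(self, gingiva_ann, gingiva_lookup):
        rng = np.random.default_rng(9)
        base = gingiva_lookup.spectra(
            10 ** rng.uniform(-2.5, -1.5, 64), rng.uniform(0, 1, 64),
            rng.uniform(0, 0.1, 64), rng.uniform(1, 4, 64)
        ).reshape(8, 8, -1)
        cube = DataCube(base, gingiva_lookup.wavelengths, "reflectance")
        full = map_parameters(cube, gingiva_ann, binning=1).crop((2, 6, 1, 7))
        sub = map_parameters(
            DataCube(base[2:6, 1:7], gingiva_lookup.wavelengths,
                     "reflectance"),
            gingiva_ann, binning=1,
        )
        assert np.allclose(full.S, sub.S, equal_nan=True)

    def test_requires_reflectance_state(self, gingiva_ann):
        cube = flat_cube(0.5, wl=gingiva_ann.wavelengths)
        with pytest.raises(ValueError):
            map_parameters(cube, gingiva_ann)


class TestRoiStats:
    @staticmethod
    def const_maps(value=0.4, shape=(10, 10)):
        imgs = [np.full(shape, value + i) for i in range(4)]
        return ParameterMaps(*imgs, mask=np.ones(shape, bool))

    def test_constant_map(self):
        stats = roi_stats(self.const_maps(0.4), (2, 8, 2, 8))
        assert stats["B"] == (pytest.approx(0.4), pytest.approx(0.0))

    def test_fully_masked_roi_rejected(self):
        maps = self.const_maps()
        maps.mask[:] = False
        with pytest.raises(ValueError):
            roi_stats(maps, (0, 5, 0, 5))

    def test_checkerboard_mean(self):
        maps = self.const_maps()
        board = np.indices((10, 10)).sum(0) % 2
        maps.B[:] = np.where(board, 0.2, 0.6)
        stats = roi_stats(maps, (0, 10, 0, 10))
        assert stats["B"][0] == pytest.approx(0.4)


class TestPhantomEndToEnd:
    def test_regeneration_is_deterministic(self, gingiva_lookup):
        scene = _scene(noise_sigma=0.01)
        a = make_phantom_cube(scene, gingiva_lookup, seed=4)[0]
        b = make_phantom_cube(scene, gingiva_lookup, seed=4)[0]
        assert np.array_equal(a.data, b.data)

    def test_recovers_region_mean_saturation(self, gingiva_ann,
                                             gingiva_lookup):
        """Full pipeline (flat-field -> tile calibration -> reflectance ->
        per-pixel prediction) recovers each region's mean S within 0.1 at
        ~20 dB phantom SNR, and orders the two regions correctly."""
        scene = _scene(noise_sigma=0.015)
        raw, std, tiles, truth = make_phantom_cube(
            scene, gingiva_lookup, seed=11
        )
        ff = flat_field(raw, std)
        curves = calibrate_tiles(ff, tiles)
        rd = to_reflectance(ff, curves)
        maps = map_parameters(rd, gingiva_ann,
                              mask=truth["tissue_mask"], binning=2)
        top = roi_stats(maps, (6, 18, 8, 56))["S"][0]
        bottom = roi_stats(maps, (26, 38, 8, 56))["S"][0]
        assert abs(top - 0.70) < 0.1
        assert abs(bottom - 0.35) < 0.1
        assert top > bottom


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_round_trip(self, tmp_path, interleave):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 1, (6, 7, 5)).astype(np.float32)
        path = tmp_path / "cube"
        write_envi(path, data, wavelengths=WL[:5], interleave=interleave)
        back, wl = read_envi(path)
        assert np.allclose(back, data, atol=1e-7)
        assert np.allclose(wl, WL[:5])


def test_tile_bootstrap_from_standards():
    """Unknown gray tiles inferred through the five-standard line fit."""
    rng = np.random.default_rng(5)
    m = rng.uniform(50, 150, WL.size)
    b = rng.uniform(0, 10, WL.size)
    std_vals = np.array(LAB_STANDARD_REFLECTANCES)[:, None] * m + b
    tile_truth = np.array([0.05, 0.30, 0.65])
    tile_vals = tile_truth[:, None] * m + b
    est = tile_reflectances_from_standards(std_vals,
                                           LAB_STANDARD_REFLECTANCES,
                                           tile_vals)
    assert np.allclose(est, tile_truth[:, None], atol=1e-10)
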