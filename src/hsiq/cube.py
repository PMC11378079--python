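"""Hyperspectral data-cube handling.

Pipeline for a raw (rows, cols, bands) cube with an in-frame grayscale
calibration bar:

1. flat-field correction against a uniform-standard cube,
   Ic = Iraw * Istd_max(band) / Istd;
2. per-band linear calibration from the known reflectances of the in-frame
   tiles (ordinary least squares of tile pixel value vs. reflectance giving
   slope m and intercept b per band);
3. conversion to diffuse reflectance, Rd = (Ic - b) / m;
4. per-pixel inverse-model prediction (optionally on k x k binned spectra)
   into parameter maps, and rectangular ROI statistics.

A phantom-cube generator builds synthetic raw cubes with known ground truth
(tissue regions forward-modelled through a lookup table, known tiles,
smooth illumination non-uniformity, a synthetic calibration line, additive
noise) for end-to-end round-trip testing.

Coordinates are row-major, 0-based, (row, col); rectangles are half-open
(row0, row1, col0, col1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ann import InverseModel, predict
from .tissue import TissueParams

__all__ = [
    "DataCube",
    "Tile",
    "TileSet",
    "CalibrationCurves",
    "ParameterMaps",
    "PhantomScene",
    "flat_field",
    "calibrate_tiles",
    "to_reflectance",
    "map_parameters",
    "roi_stats",
    "make_phantom_cube",
    "tile_reflectances_from_standards",
    "LAB_STANDARD_REFLECTANCES",
]

# manufacturer-specified reflectances of the five lab standards used to
# bootstrap the in-frame grayscale tiles
LAB_STANDARD_REFLECTANCES = (0.02, 0.10, 0.20, 0.40, 0.80)


@dataclass
class DataCube:
    """(rows, cols, bands) image stack with its wavelength vector."""

    data: np.ndarray
    wavelengths: np.ndarray
    state: str = "raw"  # raw | flat-fielded | reflectance

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.wavelengths = np.asarray(self.wavelengths, float).ravel()
        if self.data.ndim != 3:
            raise ValueError("cube must be (rows, cols, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count must equal wavelength count")
        if self.state not in ("raw", "flat-fielded", "reflectance"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def shape(self):
        return self.data.shape


def _check_rect(rect, shape):
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"rectangle {rect} outside image {shape[:2]}")
    return r0, r1, c0, c1


@dataclass(frozen=True)
class Tile:
    """Rectangular tile region with its known diffuse reflectance.

    ``reflectance`` is a scalar (gray tile) or a per-band vector.
    """

    rect: tuple
    reflectance: object


@dataclass(frozen=True)
class TileSet:
    tiles: tuple

    def __post_init__(self):
        tiles = tuple(self.tiles)
        if len(tiles) < 2:
            raise ValueError("need at least 2 tiles for a line fit")
        object.__setattr__(self, "tiles", tiles)

    def __len__(self):
        return len(self.tiles)


@dataclass(frozen=True)
class CalibrationCurves:
    """Per-band line mapping pixel value to reflectance: I = m*R + b."""

    slope: np.ndarray
    intercept: np.ndarray
    residual_rms: np.ndarray

    def __post_init__(self):
        if np.any(self.slope == 0):
            raise ValueError("zero calibration slope")


@dataclass
class ParameterMaps:
    """Per-pixel parameter images aligned to the cube's spatial grid."""

    B: np.ndarray
    S: np.ndarray
    fm: np.ndarray
    a: np.ndarray
    mask: np.ndarray

    names = ("B", "S", "fm", "a")

    def crop(self, rect) -> "ParameterMaps":
        r0, r1, c0, c1 = _check_rect(rect, self.B.shape + (0,))
        return ParameterMaps(
            self.B[r0:r1, c0:c1], self.S[r0:r1, c0:c1],
            self.fm[r0:r1, c0:c1], self.a[r0:r1, c0:c1],
            self.mask[r0:r1, c0:c1],
        )


def flat_field(raw: DataCube, std: DataCube) -> DataCube:
    """Correct illumination non-uniformity with a uniform-standard cube.

    Ic(x,y,band) = Iraw * max_xy(Istd(band)) / Istd(x,y,band).
    """
    if raw.data.shape != std.data.shape or not np.array_equal(
        raw.wavelengths, std.wavelengths
    ):
        raise ValueError("raw and standard cubes must share shape and bands")
    if np.any(std.data <= 0):
        raise ValueError("standard cube contains non-positive pixels")
    std_max = std.data.max(axis=(0, 1))
    corrected = raw.data * (std_max / std.data)
    return DataCube(corrected, raw.wavelengths.copy(), state="flat-fielded")


def _tile_means(cube: DataCube, tiles: TileSet) -> np.ndarray:
    out = []
    for tile in tiles.tiles:
        r0, r1, c0, c1 = _check_rect(tile.rect, cube.shape)
        out.append(cube.data[r0:r1, c0:c1].mean(axis=(0, 1)))
    return np.vstack(out)  # (T, bands)


def calibrate_tiles(cube: DataCube, tiles: TileSet) -> CalibrationCurves:
    """Per-band least-squares line of tile pixel value vs. known reflectance.

    The mean over each tile region is the tile statistic (the sum differs
    only by a constant that is absorbed into the slope, and the mean is
    invariant to region size).
    """
    if cube.state != "flat-fielded":
        raise ValueError("calibrate on a flat-fielded cube")
    y = _tile_means(cube, tiles)  # (T, bands)
    refl = np.vstack(
        [np.broadcast_to(np.asarray(t.reflectance, float), (cube.shape[2],))
         for t in tiles.tiles]
    )  # (T, bands)
    rbar = refl.mean(axis=0)
    ybar = y.mean(axis=0)
    var = ((refl - rbar) ** 2).sum(axis=0)
    if np.any(var <= 1e-18 * np.maximum(np.abs(rbar), 1.0) ** 2):
        raise ValueError("degenerate tile reflectances (all equal)")
    slope = ((refl - rbar) * (y - ybar)).sum(axis=0) / var
    intercept = ybar - slope * rbar
    resid = y - (slope * refl + intercept)
    return CalibrationCurves(
        slope, intercept, np.sqrt(np.mean(resid**2, axis=0))
    )


def to_reflectance(cube: DataCube, curves: CalibrationCurves) -> DataCube:
    """Invert the calibration line: Rd = (Ic - b) / m per band."""
    if cube.state != "flat-fielded":
        raise ValueError("convert a flat-fielded cube")
    if curves.slope.size != cube.shape[2]:
        raise ValueError("calibration curves on a different band grid")
    rd = (cube.data - curves.intercept) / curves.slope
    return DataCube(rd, cube.wavelengths.copy(), state="reflectance")


def _bin_spectra(data: np.ndarray, k: int) -> np.ndarray:
    rows, cols, bands = data.shape
    rb, cb = rows // k, cols // k
    d = data[: rb * k, : cb * k]
    return d.reshape(rb, k, cb, k, bands).mean(axis=(1, 3))


def map_parameters(
    cube: DataCube,
    model: InverseModel,
    mask: np.ndarray | None = None,
    binning: int = 2,
) -> ParameterMaps:
    """Per-pixel inverse-model prediction into parameter maps.

    Cube bands are linearly interpolated onto the model's wavelength grid if
    they differ.  With ``binning=k`` spectra are averaged over k x k pixel
    blocks before prediction and the block values are replicated back to
    pixel resolution.  Masked-out pixels are NaN in the maps.
    """
    if cube.state != "reflectance":
        raise ValueError("parameter mapping needs a reflectance cube")
    grid = model.wavelengths
    if grid.min() < cube.wavelengths.min() or grid.max() > cube.wavelengths.max():
        raise ValueError("model grid extends beyond cube bands")
    rows, cols, _ = cube.shape
    if mask is None:
        mask = np.ones((rows, cols), bool)
    elif mask.shape != (rows, cols):
        raise ValueError("mask shape mismatch")

    data = cube.data
    if not np.array_equal(cube.wavelengths, grid):
        # vectorized per-band linear interpolation onto the model grid
        idx = np.argsort(cube.wavelengths)
        flat = data.reshape(-1, cube.wavelengths.size)
        wl = cube.wavelengths[idx]
        pos = np.searchsorted(wl, grid).clip(1, wl.size - 1)
        w0 = wl[pos - 1]
        w1 = wl[pos]
        t = (grid - w0) / (w1 - w0)
        interp = (1 - t) * flat[:, idx][:, pos - 1] + t * flat[:, idx][:, pos]
        data = interp.reshape(rows, cols, grid.size)

    if binning > 1:
        binned = _bin_spectra(data, binning)
        bm = _bin_spectra(mask[:, :, None].astype(float), binning)[:, :, 0] > 0.5
        spectra = binned[bm]
        B, S, fm, a = predict(model, spectra)
        maps = []
        for vals in (B, S, fm, a):
            blk = np.full(bm.shape, np.nan)
            blk[bm] = vals
            full = np.full((rows, cols), np.nan)
            rep = np.repeat(np.repeat(blk, binning, 0), binning, 1)
            full[: rep.shape[0], : rep.shape[1]] = rep
            full[~mask] = np.nan
            maps.append(full)
        return ParameterMaps(*maps, mask=mask & ~np.isnan(maps[0]))

    spectra = data[mask]
    B, S, fm, a = predict(model, spectra)
    maps = []
    for vals in (B, S, fm, a):
        img = np.full((rows, cols), np.nan)
        img[mask] = vals
        maps.append(img)
    return ParameterMaps(*maps, mask=mask.copy())


def roi_stats(maps: ParameterMaps, roi) -> dict:
    """Mean and standard deviation of each parameter over roi ∩ mask."""
    r0, r1, c0, c1 = _check_rect(roi, maps.B.shape + (0,))
    sel = maps.mask[r0:r1, c0:c1]
    if not sel.any():
        raise ValueError("ROI does not intersect the analyzed mask")
    out = {}
    for name in maps.names:
        vals = getattr(maps, name)[r0:r1, c0:c1][sel]
        out[name] = (float(np.mean(vals)), float(np.std(vals)))
    return out


def tile_reflectances_from_standards(
    standard_values: np.ndarray,
    standard_reflectances,
    tile_values: np.ndarray,
) -> np.ndarray:
    """Infer unknown tile reflectances from imaged lab standards.

    Fits the per-band line of measured value vs. known standard reflectance
    and inverts it at the measured tile values.  ``standard_values`` is
    (n_standards, bands), ``tile_values`` (n_tiles, bands).
    """
    sv = np.atleast_2d(np.asarray(standard_values, float))
    refl = np.asarray(standard_reflectances, float)[:, None]
    rbar = refl.mean(axis=0)
    ybar = sv.mean(axis=0)
    slope = ((refl - rbar) * (sv - ybar)).sum(axis=0) / ((refl - rbar) ** 2).sum(
        axis=0
    )
    intercept = ybar - slope * rbar
    return (np.atleast_2d(tile_values) - intercept) / slope


@dataclass(frozen=True)
class PhantomScene:
    """Synthetic scene: tissue regions, tiles, illumination and calibration."""

    shape: tuple  # (rows, cols)
    regions: tuple  # ((rect, TissueParams), ...)
    tile_rects: tuple  # rectangles for the in-frame tiles
    tile_reflectances: tuple  # scalar reflectance per tile
    background_reflectance: float = 0.3
    slope: float = 1000.0  # synthetic calibration m (counts per reflectance)
    intercept: float = 20.0  # synthetic calibration b (counts)
    illumination_amplitude: float = 0.3  # peak-to-edge falloff of the gradient
    noise_sigma: float = 0.0  # additive noise in reflectance units


def make_phantom_cube(
    scene: PhantomScene,
    forward,
    wavelengths=None,
    seed: int = 0,
):
    """Build a raw phantom cube plus its calibration inputs and ground truth.

    Returns ``(raw, std, tiles, truth)`` where ``raw`` is the synthetic raw
    cube, ``std`` the matching uniform-standard cube, ``tiles`` the
    :class:`TileSet`, and ``truth`` a dict with the generated reflectance
    stack, per-region parameters and the synthetic (m, b, gradient).
    """
    wl = np.asarray(
        forward.wavelengths if wavelengths is None else wavelengths, float
    )
    rows, cols = scene.shape
    nb = wl.size
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rd = np.full((rows, cols, nb), scene.background_reflectance)
    tissue_mask = np.zeros((rows, cols), bool)
    for rect, params in scene.regions:
        r0, r1, c0, c1 = _check_rect(rect, (rows, cols, nb))
        spec = forward.spectra(params.B, params.S, params.fm, params.a)[0]
        rd[r0:r1, c0:c1] = spec
        tissue_mask[r0:r1, c0:c1] = True

    tiles = []
    for rect, refl in zip(scene.tile_rects, scene.tile_reflectances):
        r0, r1, c0, c1 = _check_rect(rect, (rows, cols, nb))
        rd[r0:r1, c0:c1] = refl
        tiles.append(Tile(rect, refl))

    # smooth separable illumination falloff toward the frame edges
    ry = np.linspace(-1, 1, rows)[:, None]
    cx = np.linspace(-1, 1, cols)[None, :]
    gradient = 1.0 - scene.illumination_amplitude * 0.5 * (ry**2 + cx**2)

    if scene.noise_sigma > 0:
        rd_noisy = rd + rng.standard_normal(rd.shape) * scene.noise_sigma
    else:
        rd_noisy = rd
    counts = scene.slope * rd_noisy + scene.intercept
    raw = DataCube(counts * gradient[:, :, None], wl, state="raw")
    std_counts = (scene.slope * 0.5 + scene.intercept) * gradient
    std = DataCube(
        np.broadcast_to(std_counts[:, :, None], (rows, cols, nb)).copy(),
        wl, state="raw",
    )
    truth = {
        "reflectance": rd,
        "regions": tuple(scene.regions),
        "slope": scene.slope,
        "intercept": scene.intercept,
        "gradient": gradient,
        "tissue_mask": tissue_mask,
    }
    return raw, std, TileSet(tuple(tiles)), truth
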