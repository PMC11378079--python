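"""Photon-transport kernel, white-MC engine and Rd lookup table."""

import numpy as np
import pytest

from hsiq.mc import (
    RdLookup,
    build_lookup,
    sample_hg_cosines,
    simulate_rd,
    simulate_spectrum,
)
from hsiq.tissue import LayerStack, OpticalLayer, TissueParams


def single_layer(mu_a, mu_sp, g=0.0, n=1.0, n_ambient=1.0, thickness=np.inf):
    lay = OpticalLayer("medium", thickness, n, np.array([mu_a]),
                       np.array([mu_sp]), g)
    return LayerStack((lay,), n_ambient=n_ambient)


def naive_random_walk_rd(mu_a, mu_s, n_photons, seed, max_iter=100_000):
    """Brute-force oracle: unit-weight photons, absorb-or-scatter sampling,
    isotropic deflection, matched boundary, semi-infinite medium."""
    rng = np.random.default_rng(seed)
    mu_t = mu_a + mu_s
    p_absorb = mu_a / mu_t
    z = np.zeros(n_photons)
    uz = np.ones(n_photons)
    alive = np.ones(n_photons, bool)
    escaped = 0
    for _ in range(max_iter):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        step = rng.exponential(1.0 / mu_t, idx.size)
        z[idx] += step * uz[idx]
        out = z[idx] < 0
        escaped += int(out.sum())
        alive[idx[out]] = False
        idx = idx[~out]
        absorbed = rng.random(idx.size) < p_absorb
        alive[idx[absorbed]] = False
        idx = idx[~absorbed]
        uz[idx] = rng.uniform(-1.0, 1.0, idx.size)
    return escaped / n_photons


class TestSimulateRd:
    def test_no_scattering_no_return(self):
        res = simulate_rd(single_layer(1.0, 0.0), n_photons=5000, seed=0)
        assert res.Rd == 0.0

    def test_no_absorption_everything_returns(self):
        res = simulate_rd(single_layer(0.0, 2.0), n_photons=3000, seed=0,
                          max_steps=200_000)
        assert res.Rd > 0.98  # 1-D z-walk recurrence; step cap loses a tail

    def test_matches_naive_random_walk_oracle(self):
        """mu_a=0.1, mu_s'=1, g=0, matched semi-infinite boundary: the
        weighted kernel and a unit-weight absorb-or-scatter walk agree."""
        res = simulate_rd(single_layer(0.1, 1.0, g=0.0), n_photons=100_000,
                          seed=3)
        oracle_runs = [naive_random_walk_rd(0.1, 1.0, 50_000, s)
                       for s in (11, 12, 13, 14)]
        oracle = float(np.mean(oracle_runs))
        oracle_se = float(np.std(oracle_runs, ddof=1) / np.sqrt(len(oracle_runs)))
        tol = 3.0 * np.hypot(res.rd_stderr, oracle_se)
        assert res.Rd == pytest.approx(oracle, abs=max(tol, 0.004))

    def test_energy_conservation_without_roulette(self, band_grid):
        """Rd + Td + A equals the launched weight exactly when sub-threshold
        photons deposit their remainder instead of playing roulette."""
        p = TissueParams(0.02, 0.5, 0.03, 1.5)
        from hsiq.tissue import build_gingiva

        stack = build_gingiva(p, band_grid)
        res = simulate_rd(stack, 120, n_photons=4000, seed=5, roulette=False)
        assert res.Rd + res.Td + res.A == pytest.approx(1.0, abs=1e-9)
        assert 0 <= res.Rd <= 1 and 0 <= res.Td <= 1 and 0 <= res.A <= 1

    def test_rd_monotone_in_absorption(self):
        rds = [
            simulate_rd(single_layer(mu_a, 2.0, g=0.9, n=1.4), n_photons=20_000,
                        seed=7).Rd
            for mu_a in (0.01, 0.1, 1.0)
        ]
        assert rds[0] > rds[1] > rds[2]

    def test_disjoint_seeds_statistically_compatible(self):
        a = simulate_rd(single_layer(0.05, 1.0, g=0.5), n_photons=100_000, seed=1)
        b = simulate_rd(single_layer(0.05, 1.0, g=0.5), n_photons=100_000, seed=2)
        z = abs(a.Rd - b.Rd) / np.hypot(a.rd_stderr, b.rd_stderr)
        assert z < 4.0

    def test_zero_photons_rejected(self):
        with pytest.raises(ValueError):
            simulate_rd(single_layer(0.1, 1.0), n_photons=0)


class TestSpectrum:
    def test_seeded_determinism(self, band_grid):
        p = TissueParams(0.01, 0.6, 0.05, 2.0)
        grid = band_grid[::70]
        r1, _ = simulate_spectrum(p, "gingiva", grid, n_photons=2000, seed=9)
        r2, _ = simulate_spectrum(p, "gingiva", grid, n_photons=2000, seed=9)
        assert np.array_equal(r1, r2)

    def test_blood_darkens_hemoglobin_band(self, gingiva_engine, band_grid):
        """More blood lowers Rd at 550 nm (strong hemoglobin absorption)."""
        iw = int(np.argmin(np.abs(band_grid - 550.0)))
        Bs = np.array([0.002, 0.01, 0.05])
        rd = gingiva_engine.reflectance(
            Bs, np.full(3, 0.6), np.full(3, 0.02), np.full(3, 2.0),
            wl_indices=[iw],
        )[:, 0]
        assert rd[0] > rd[1] > rd[2]


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_mean_cosine_equals_g(self, g):
        cos = sample_hg_cosines(g, 1_000_000, seed=21)
        se = cos.std(ddof=1) / np.sqrt(cos.size)
        assert abs(cos.mean() - g) < 3 * se + 1e-4
        assert cos.min() >= -1 and cos.max() <= 1


class TestLookup:
    def test_node_query_returns_stored_value(self, gingiva_lookup):
        lut = gingiva_lookup
        val = lut.spectra_log(
            lut.log10B[2], lut.S[3], lut.fm[1], lut.a[4]
        )[0]
        assert np.allclose(val, lut.table[2, 3, 1, 4, :], rtol=1e-12)

    def test_midway_in_saturation_is_arithmetic_mean(self, gingiva_lookup):
        lut = gingiva_lookup
        mid_S = 0.5 * (lut.S[2] + lut.S[3])
        val = lut.spectra_log(lut.log10B[2], mid_S, lut.fm[1], lut.a[4])[0]
        mean = 0.5 * (lut.table[2, 2, 1, 4, :] + lut.table[2, 3, 1, 4, :])
        assert np.allclose(val, mean, rtol=1e-12)

    def test_out_of_range_query_raises_without_clip(self, gingiva_lookup):
        with pytest.raises(ValueError, match="outside lookup range"):
            gingiva_lookup.spectra(0.5, 0.5, 0.05, 2.0)
        # clip mode clamps instead
        gingiva_lookup.spectra(0.5, 0.5, 0.05, 2.0, clip=True)

    def test_interpolated_rd_matches_fresh_mc_on_held_out_params(
        self, gingiva_lookup, band_grid
    ):
        """Lookup interpolation vs direct weighted MCML at off-node params."""
        rng = np.random.default_rng(17)
        n_checked = 0
        for _ in range(4):
            p = TissueParams(
                B=float(10 ** rng.uniform(-2.7, -1.2)),
                S=float(rng.uniform(0.1, 0.9)),
                fm=float(rng.uniform(0.0, 0.15)),
                a=float(rng.uniform(0.8, 4.5)),
            )
            iw = int(rng.integers(0, band_grid.size))
            direct = simulate_rd(
                __import__("hsiq").tissue.build_gingiva(p, band_grid), iw,
                n_photons=30_000, seed=int(rng.integers(2**31)),
            )
            interp = gingiva_lookup.spectra(p.B, p.S, p.fm, p.a)[0, iw]
            tol = 3 * direct.rd_stderr + 0.015  # MC noise + stated interp tol
            assert interp == pytest.approx(direct.Rd, abs=tol)
            n_checked += 1
        assert n_checked == 4

    def test_save_load_round_trip(self, gingiva_lookup, tmp_path):
        path = tmp_path / "lut.npz"
        gingiva_lookup.save(path)
        loaded = RdLookup.load(path)
        assert np.array_equal(loaded.table, gingiva_lookup.table)
        assert np.array_equal(loaded.wavelengths, gingiva_lookup.wavelengths)


class TestWhiteEngine:
    def test_reflectance_within_unit_interval(self, gingiva_lookup):
        assert np.all(gingiva_lookup.table >= 0)
        assert np.all(gingiva_lookup.table <= 1)

    def test_spectrum_shape_and_smoothness(self, gingiva_engine):
        spec = gingiva_engine.spectrum(TissueParams(0.01, 0.6, 0.05, 2.0))
        assert spec.shape == (gingiva_engine.wavelengths.size,)
        # shared photon paths make adjacent-band estimates strongly
        # correlated, so spectra are smooth
        assert np.max(np.abs(np.diff(spec))) < 0.05
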