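"""Generators: helix geometry, H-bond breaking, noise/switching, surfaces,
decays, CD curves, and calibrated double wells."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import helixspec as hx
from helixspec.core import InvalidInputError, PeptideSpec
from helixspec.synthetic_data import (
    SyntheticPeak2D,
    hbond_distances,
    make_synthetic_2dir,
    tilted_gaussian,
    _kabsch_rmsd,
)


class TestIdealHelix:
    def test_interior_hbond_distances_alpha_helical(self, ideal_helix):
        """φ/ψ = −57.8°/−47.0° places all interior O(i)···H(i+4) near 0.2 nm."""
        d = hbond_distances(ideal_helix)
        vals = np.array(list(d.values()))
        assert len(d) == 31
        assert np.all(vals < 0.35)
        assert np.allclose(vals, 0.206, atol=0.03)

    def test_rise_per_residue(self, ideal_helix):
        """Least-squares axis fit of CA positions gives ≈0.15 nm/residue."""
        ca = np.array([ideal_helix.coords[0, ideal_helix.atom_index(i, "CA")]
                       for i in range(1, 36)])
        cac = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(cac)
        proj = cac @ vt[0]
        rise = abs(np.polyfit(np.arange(35), proj, 1)[0])
        assert rise == pytest.approx(0.15, abs=0.01)

    def test_extended_chain_end_to_end_monotone(self):
        """φ/ψ = 180/180 gives an extended chain growing with length."""
        dists = []
        for n in (5, 10, 15, 20):
            spec = PeptideSpec("A" * n, "none", "carboxylic_acid")
            t = hx.make_ideal_helix(spec, 180.0, 180.0)
            n0 = t.atom_index(1, "N")
            cn = t.atom_index(n, "C")
            dists.append(np.linalg.norm(t.coords[0, cn] - t.coords[0, n0]))
        assert np.all(np.diff(dists) > 0)

    def test_short_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            PeptideSpec("A")

    def test_angle_out_of_range_rejected(self, relay_spec):
        with pytest.raises(InvalidInputError):
            hx.make_ideal_helix(relay_spec, -200.0, -47.0)


class TestBentHelix:
    def test_relay_kink_breaks_exactly_requested_pairs(self, bent_helix):
        """Bent fixture breaks (22,26) and (23,27) — the relay-helix kink —
        and nothing else."""
        d = hbond_distances(bent_helix)
        broken = {k for k, v in d.items() if v > 0.35}
        assert broken == {(22, 26), (23, 27)}

    def test_empty_break_list_is_ideal_helix(self, relay_spec, ideal_helix):
        t = hx.make_bent_helix(relay_spec, [])
        assert np.array_equal(t.coords, ideal_helix.coords)

    def test_terminal_break_leaves_interior_unchanged(self, relay_spec,
                                                      ideal_helix):
        t = hx.make_bent_helix(relay_spec, [(1, 5)])
        d = hbond_distances(t)
        di = hbond_distances(ideal_helix)
        assert d[(1, 5)] > 0.35
        others = [abs(d[k] - di[k]) for k in di if k != (1, 5)]
        assert max(others) < 0.01

    def test_rmsd_outside_break_window(self, bent_helix, ideal_helix):
        mask = ~((bent_helix.res_ids >= 22) & (bent_helix.res_ids <= 27))
        r = _kabsch_rmsd(bent_helix.coords[0][mask],
                         ideal_helix.coords[0][mask])
        assert r < 0.05

    def test_invalid_pair_rejected(self, relay_spec):
        with pytest.raises(InvalidInputError):
            hx.make_bent_helix(relay_spec, [(5, 8)])


class TestTrajectory:
    def test_zero_noise_zero_switching_identical_frames(self, ideal_helix):
        t = hx.make_trajectory(ideal_helix, 5, 0.0, 0.0, seed=1)
        assert np.array_equal(t.coords, np.repeat(ideal_helix.coords, 5, axis=0))

    def test_seed_reproducibility(self, ideal_helix):
        a = hx.make_trajectory(ideal_helix, 50, 0.003, 0.2, seed=9,
                               switch_pairs=[(22, 26)])
        b = hx.make_trajectory(ideal_helix, 50, 0.003, 0.2, seed=9,
                               switch_pairs=[(22, 26)])
        assert np.array_equal(a.coords, b.coords)

    def test_broken_fraction_near_markov_stationary(self, ideal_helix):
        """Symmetric two-state chain: stationary broken fraction 1/2.

        With switch probability p the lag-1 autocorrelation is (1−2p), so
        var(mean) ≈ (1/4n)·(1−p)/p; assert within 3 standard errors.
        """
        n, p = 10000, 0.1
        t = hx.make_trajectory(ideal_helix, n, 0.0, p, seed=5,
                               switch_pairs=[(22, 26)])
        series = hx.hbond_series(t, [(22, 26)])
        frac = series.broken_fraction((22, 26))
        se = np.sqrt((1 - p) / p / (4 * n))
        assert abs(frac - 0.5) < 3 * se

    def test_invalid_args(self, ideal_helix):
        with pytest.raises(InvalidInputError):
            hx.make_trajectory(ideal_helix, 0, 0.0, 0.0, seed=0)
        with pytest.raises(InvalidInputError):
            hx.make_trajectory(ideal_helix, 1, -1.0, 0.0, seed=0)
        with pytest.raises(InvalidInputError):
            hx.make_trajectory(ideal_helix, 1, 0.0, 1.5, seed=0)


class TestSynthetic2D:
    GRID = np.arange(1600.0, 1720.5, 0.5)

    def test_single_peak_analytic_volume(self):
        p = SyntheticPeak2D(1660, 1660, 6.0, 5.0, 3.0, 0.0, 0.0)
        _, vols = make_synthetic_2dir([p], self.GRID, self.GRID)
        assert vols[0]["positive"] == pytest.approx(
            2 * np.pi * 3.0 * 6.0 * 5.0, rel=1e-9
        )

    def test_two_separated_peaks_match_grid_integrals(self):
        peaks = [SyntheticPeak2D(1630, 1630, 4, 4, 2.0, 30.0, 0.0),
                 SyntheticPeak2D(1690, 1690, 5, 4, 1.0, 30.0, 0.0)]
        grid = np.arange(1580.0, 1740.25, 0.25)
        sp, vols = make_synthetic_2dir(peaks, grid, grid)
        step = 0.25**2
        half = np.argmin(np.abs(grid - 1660.0))
        low = sp.grid[:half, :half].sum() * step
        high = sp.grid[half:, half:].sum() * step
        assert low == pytest.approx(vols[0]["positive"], rel=0.01)
        assert high == pytest.approx(vols[1]["positive"], rel=0.01)

    def test_empty_peak_list_zero_surface(self):
        sp, vols = make_synthetic_2dir([], self.GRID, self.GRID)
        assert not vols and not sp.grid.any()

    def test_anharmonic_pair_integrates_to_zero(self):
        p = SyntheticPeak2D(1660, 1660, 5, 5, 2.0, 30.0, 16.0)
        sp, _ = make_synthetic_2dir([p], self.GRID, self.GRID)
        assert abs(sp.grid.sum()) * 0.25 < 1e-6 * 2 * np.pi * 2 * 25

    @given(tilt=st.floats(-90, 90), a=st.floats(0.1, 10),
           sx=st.floats(2, 10), sy=st.floats(2, 10))
    def test_tilt_preserves_gaussian_mass(self, tilt, a, sx, sy):
        """Rotation cannot change the integral of the Gaussian."""
        grid = np.arange(1560.0, 1760.0, 1.0)
        g = tilted_gaussian(grid, grid, a, 1660.0, 1660.0, sx, sy, tilt)
        assert g.sum() == pytest.approx(2 * np.pi * a * sx * sy, rel=1e-6)


class TestBiexpDecay:
    def test_closed_form_value(self):
        t = np.linspace(0, 10, 101)
        tab = hx.make_biexp_decay(1.0, 1.38, 0.3, 0.2, t)
        k = np.argmin(np.abs(t - 0.5))
        expect = 1.0 * np.exp(-1.38 * 0.5) + 0.3 * np.exp(-0.2 * 0.5)
        assert tab[k, 1] == pytest.approx(expect, rel=1e-12)

    def test_single_exponential_log_linear(self):
        t = np.linspace(0, 5, 51)
        tab = hx.make_biexp_decay(2.0, 0.7, 0.0, 1.0, t)
        slope = np.polyfit(t, np.log(tab[:, 1]), 1)
        assert slope[0] == pytest.approx(-0.7, rel=1e-9)

    def test_seed_reproducibility(self):
        t = np.linspace(0, 5, 51)
        a = hx.make_biexp_decay(1, 1, 0.1, 0.1, t, noise_sd=0.05, seed=3)
        b = hx.make_biexp_decay(1, 1, 0.1, 0.1, t, noise_sd=0.05, seed=3)
        assert np.array_equal(a, b)


class TestCDCurve:
    def test_boundary_fh_zero_gives_coil_baseline(self):
        tab = hx.make_cd_curve(np.array([[25.0, 0.0]]), 35)
        assert tab[0, 1] == pytest.approx(2220 - 53 * 25.0)

    def test_boundary_fh_one_gives_helix_baseline(self):
        tab = hx.make_cd_curve(np.array([[25.0, 1.0]]), 35)
        assert tab[0, 1] == pytest.approx(float(hx.theta_helix(25.0, 35)))

    def test_round_trip_through_helical_fraction(self):
        tab = hx.make_cd_curve(np.array([[70.0, 0.56]]), 35)
        rec = hx.helical_fraction(tab[0, 1], 70.0, 35)
        assert rec.fh == pytest.approx(0.56, abs=1e-12)


class TestDoubleWell:
    def test_relay_fes_minima_difference(self):
        """Minima at the relay-helix FES basin positions differ by 3.36 kJ/mol."""
        pot = hx.make_double_well(3.36, 5.0, ((0.47, 0.34), (0.48, 0.64)))
        gx = np.linspace(0.32, 0.63, 601)
        gy = np.linspace(0.19, 0.79, 601)
        v = pot(gx[:, None], gy[None, :])
        lower = v[:, gy < 0.49].min()
        upper = v[:, gy >= 0.49].min()
        assert upper - lower == pytest.approx(3.36, abs=0.01)

    def test_symmetric_wells_equal_depth(self):
        pot = hx.make_double_well(0.0, 4.0, ((0.3, 0.3), (0.7, 0.3)))
        gx = np.linspace(0.1, 0.9, 801)
        gy = np.linspace(0.1, 0.5, 401)
        v = pot(gx[:, None], gy[None, :])
        left = v[gx < 0.5].min()
        right = v[gx >= 0.5].min()
        assert left == pytest.approx(right, abs=0.02)

    def test_saddle_height_along_path(self):
        pot = hx.make_double_well(2.0, 5.0, ((0.3, 0.3), (0.7, 0.7)))
        lam = np.linspace(0.0, 1.0, 2001)
        x = 0.3 + lam * 0.4
        y = 0.3 + lam * 0.4
        line = pot(x, y)
        barrier = line[500:1500].max() - line.min()
        assert barrier == pytest.approx(5.0, abs=0.05)

    def test_malformed_landscape_rejected(self):
        with pytest.raises(InvalidInputError):
            hx.make_double_well(4.0, 1.0, ((0.3, 0.3), (0.7, 0.7)))
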