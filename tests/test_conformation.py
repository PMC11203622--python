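"""Conformational analysis: H-bond series, PCA, metadynamics, FES."""

import numpy as np
import pytest

import helixspec as hx
from helixspec.core import InvalidInputError, PeptideSpec
from helixspec.conformation import FESGrid, _local_minima, _saddle_between


class TestHBondSeries:
    def test_ideal_helix_all_interior_pairs_formed(self, ideal_helix):
        s = hx.hbond_series(ideal_helix)
        assert len(s.distances) == 31
        for pair, broken in s.broken.items():
            assert not broken.any(), pair

    def test_bent_fixture_breaks_relay_kink_pairs(self, bent_helix):
        s = hx.hbond_series(bent_helix)
        broken = {p for p in s.broken if s.broken[p].all()}
        assert broken == {(22, 26), (23, 27)}

    def test_infinite_cutoff_classifies_nothing_broken(self, bent_helix):
        s = hx.hbond_series(bent_helix, cutoff_nm=np.inf)
        assert not any(b.any() for b in s.broken.values())

    def test_frame_order_invariance(self, ideal_helix):
        """Distances are a pure per-frame function."""
        t = hx.make_trajectory(ideal_helix, 6, 0.004, 0.0, seed=8)
        rev = hx.Trajectory(t.coords[::-1].copy(), t.atom_names,
                            t.res_ids, t.res_names, t.timestep_ps, t.spec)
        s1 = hx.hbond_series(t, [(10, 14)])
        s2 = hx.hbond_series(rev, [(10, 14)])
        assert np.allclose(s1.distances[(10, 14)][::-1],
                           s2.distances[(10, 14)])

    def test_proline_donor_flagged_missing(self):
        spec = PeptideSpec("AAAAAPAAAA", "acetyl", "carboxylic_acid")
        traj = hx.make_ideal_helix(spec)
        s = hx.hbond_series(traj)
        assert (2, 6) in s.missing  # residue 6 is the proline
        assert (2, 6) not in s.distances


class TestPCA:
    def test_rank_one_translation_dominates(self, ideal_helix):
        """Pure translation along x (alignment disabled): PC1 ≥ 99.9%."""
        base = ideal_helix.coords[0]
        shifts = np.linspace(0.0, 0.5, 10)
        coords = np.stack([base + [s, 0.0, 0.0] for s in shifts])
        t = hx.Trajectory(coords, ideal_helix.atom_names,
                          ideal_helix.res_ids, ideal_helix.res_names)
        res = hx.pca(t, align=False)
        assert res.eigenvalues[0] / res.eigenvalues.sum() > 0.999

    def test_orthonormality_and_variance_conservation(self, ideal_helix):
        t = hx.make_trajectory(ideal_helix, 40, 0.005, 0.0, seed=12)
        res = hx.pca(t)
        v = res.eigenvectors
        gram = v.T @ v
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-10
        # total variance equals the covariance trace (sum of eigenvalues)
        nf = t.n_frames
        fitted = res.projections @ v.T
        total_var = (fitted**2).sum() / (nf - 1)
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_isotropic_noise_eigenvalue_spread(self, ideal_helix):
        """Isotropic-noise trajectory: the leading eigenvalue stays within
        the empirical bulk-edge range of a simulation oracle at the same
        shape (n frames ≪ 3K dims keeps the ratio modest)."""
        sd = 0.004
        t = hx.make_trajectory(ideal_helix, 60, sd, 0.0, seed=7)
        res = hx.pca(t, align=False)
        # oracle: leading-eigenvalue distribution of same-shape white noise
        rng = np.random.default_rng(0)
        dims = res.eigenvectors.shape[0]
        oracle = []
        for _ in range(20):
            x = rng.normal(0.0, sd, (60, dims))
            x -= x.mean(axis=0)
            ev = np.linalg.svd(x, compute_uv=False) ** 2 / 59
            oracle.append(ev[0])
        assert min(oracle) * 0.8 < res.eigenvalues[0] < max(oracle) * 1.2

    def test_degenerate_trajectory_flagged(self, ideal_helix):
        t = hx.make_trajectory(ideal_helix, 5, 0.0, 0.0, seed=0)
        res = hx.pca(t)
        assert res.degenerate
        assert res.eigenvalues[0] == pytest.approx(0.0, abs=1e-14)

    def test_too_few_frames_rejected(self, ideal_helix):
        t = hx.make_trajectory(ideal_helix, 2, 0.001, 0.0, seed=0)
        with pytest.raises(InvalidInputError):
            hx.pca(t)


class TestPseudoTrajectory:
    @pytest.fixture(scope="class")
    def noisy_pca(self, ideal_helix):
        t = hx.make_trajectory(ideal_helix, 30, 0.004, 0.0, seed=3)
        return hx.pca(t)

    def test_two_frames_are_projection_extremes(self, noisy_pca):
        frames = hx.pseudo_trajectory(noisy_pca, 1, 2)
        proj = noisy_pca.projections[:, 0]
        vec = noisy_pca.eigenvectors[:, 0].reshape(-1, 3)
        lo = noisy_pca.mean_structure + proj.min() * vec
        hi = noisy_pca.mean_structure + proj.max() * vec
        assert np.allclose(frames[0], lo)
        assert np.allclose(frames[-1], hi)

    def test_midpoint_is_mean_when_projections_symmetric(self, noisy_pca):
        """With λ spanning [−a, a], the middle frame is the mean structure."""
        p = noisy_pca
        sym = hx.PCAResult(p.eigenvalues, p.eigenvectors,
                           np.vstack([p.projections, -p.projections]),
                           p.mean_structure, p.atom_selection)
        frames = hx.pseudo_trajectory(sym, 1, 3)
        assert np.allclose(frames[1], p.mean_structure, atol=1e-12)

    def test_bend_mode_sweep_spans_constructed_range(self, relay_spec,
                                                     ideal_helix, bent_helix):
        """A two-state bend trajectory yields a pseudo-trajectory whose
        end-to-end helix angle spans the constructed range."""

        def bend_angle(coords, traj):
            ca = np.array([coords[traj.atom_index(i, "CA")]
                           for i in range(1, 36)])
            v1 = ca[17] - ca[0]
            v2 = ca[34] - ca[17]
            cosang = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
            return np.degrees(np.arccos(np.clip(cosang, -1, 1)))

        # interleave ideal and bent frames (tiny jitter for full rank)
        rng = np.random.default_rng(5)
        frames = []
        for k in range(20):
            base = ideal_helix.coords[0] if k % 2 == 0 else bent_helix.coords[0]
            frames.append(base + rng.normal(0, 1e-4, base.shape))
        t = hx.Trajectory(np.stack(frames), ideal_helix.atom_names,
                          ideal_helix.res_ids, ideal_helix.res_names)
        res = hx.pca(t)
        pseudo = hx.pseudo_trajectory(res, 1, 7)
        sel = res.atom_selection
        sub = hx.Trajectory(t.coords[:, sel], [t.atom_names[k] for k in sel],
                            t.res_ids[sel], [t.res_names[k] for k in sel])
        angles = [bend_angle(f, sub) for f in pseudo]
        built = abs(bend_angle(ideal_helix.coords[0], ideal_helix)
                    - bend_angle(bent_helix.coords[0], bent_helix))
        swept = max(angles) - min(angles)
        assert swept == pytest.approx(built, rel=0.05)


class TestMetadynamics:
    def test_double_well_recovery_at_reduced_budget(self):
        """At a quarter of the production step budget the FES already orders
        the basins correctly and places their offset at the right scale
        (the full-budget 0.5 kJ/mol check runs with the acceptance suite)."""
        pot = hx.make_double_well(3.36, 5.0, ((0.47, 0.34), (0.48, 0.64)))
        fes = hx.wtmetad(pot, ((0.3, 0.7), (0.15, 0.85)), steps=500_000,
                         seed=3, x0=(0.48, 0.64))

        def basin_min(center, radius=0.08):
            mask = ((fes.d1[:, None] - center[0]) ** 2
                    + (fes.d2[None, :] - center[1]) ** 2) < radius**2
            return fes.free_energy[mask].min()

        dg = basin_min((0.48, 0.64)) - basin_min((0.47, 0.34))
        assert dg > 0  # deeper basin identified correctly
        assert abs(dg - 3.36) < 1.5

    def test_harmonic_well_curvature(self):
        """FES of a harmonic well is quadratic with ~10% curvature error."""

        class Harmonic:
            k = 80.0

            def __call__(self, x, y):
                return self.k * ((np.asarray(x) - 0.5) ** 2
                                 + (np.asarray(y) - 0.5) ** 2)

            def gradient(self, x, y):
                return 2 * self.k * np.array([x - 0.5, y - 0.5])

        fes = hx.wtmetad(Harmonic(), ((0.3, 0.7), (0.3, 0.7)),
                         steps=400_000, seed=11, dt=1e-4, x0=(0.5, 0.5))
        # fit G = a·(d1−c)² along the centre cut over the well width
        j0 = np.argmin(np.abs(fes.d2 - 0.5))
        sel = np.abs(fes.d1 - 0.5) < 0.15
        x = fes.d1[sel] - 0.5
        g = fes.free_energy[sel, j0]
        a = np.polyfit(x, g, 2)[0]
        assert a == pytest.approx(80.0, rel=0.15)

    def test_zero_steps_flat_flagged(self):
        pot = hx.make_double_well(2.0, 4.0, ((0.4, 0.4), (0.6, 0.6)))
        fes = hx.wtmetad(pot, ((0.3, 0.7), (0.3, 0.7)), steps=0, seed=0)
        assert not fes.free_energy.any()
        assert "empty bias" in fes.offset_note

    def test_seed_reproducibility(self):
        pot = hx.make_double_well(2.0, 4.0, ((0.4, 0.4), (0.6, 0.6)))
        kw = dict(steps=20_000, seed=9, x0=(0.4, 0.4))
        f1 = hx.wtmetad(pot, ((0.3, 0.7), (0.3, 0.7)), **kw)
        f2 = hx.wtmetad(pot, ((0.3, 0.7), (0.3, 0.7)), **kw)
        assert np.array_equal(f1.free_energy, f2.free_energy)


class TestFESAnalysis:
    def test_kt_conversion_of_observed_basin_offsets(self):
        """At 298.15 K, 4.67 kJ/mol ≈ 1.9 kT and 3.36 kJ/mol ≈ 1.4 kT."""
        assert round(hx.kj_per_mol_to_kt(4.67), 1) == 1.9
        assert round(hx.kj_per_mol_to_kt(3.36), 1) == 1.4
        assert round(hx.kj_per_mol_to_kt(3.21), 1) == 1.3
        assert round(hx.kj_per_mol_to_kt(6.01), 1) == 2.4

    def test_kt_conversion_exact_round_trip(self):
        from helixspec.core import R_KJ_PER_MOL_K

        kt = hx.kj_per_mol_to_kt(5.3, 310.0)
        assert kt * R_KJ_PER_MOL_K * 310.0 == pytest.approx(5.3, abs=1e-12)

    def test_flat_grid_no_minima(self):
        g = FESGrid(np.linspace(0, 1, 20), np.linspace(0, 1, 20),
                    np.ones((20, 20)))
        ana = hx.fes_analyze(g)
        assert ana.minima == []

    def test_constructed_two_minimum_grid(self):
        """Analytic double-well grid: ΔG and saddle recovered to grid
        accuracy."""
        pot = hx.make_double_well(3.36, 5.0, ((0.47, 0.34), (0.48, 0.64)))
        gx = np.linspace(0.3, 0.7, 161)
        gy = np.linspace(0.15, 0.85, 281)
        v = pot(gx[:, None], gy[None, :])
        ana = hx.fes_analyze(FESGrid(gx, gy, v - v.min()))
        assert len(ana.minima) == 2
        pair = ana.delta_g[0]
        assert pair["delta_g_kjmol"] == pytest.approx(3.36, abs=0.02)
        assert pair["barrier_kjmol"] == pytest.approx(5.0, abs=0.1)
        assert pair["delta_g_kt"] == pytest.approx(3.36 / 2.479, abs=0.02)

    def test_saddle_search_on_hand_built_grid(self):
        """Max-over-min path level on a tiny grid, checked by hand."""
        f = np.array([
            [0.0, 5.0, 9.0],
            [6.0, 7.0, 3.0],
            [9.0, 4.0, 1.0],
        ])
        minima = _local_minima(f)
        assert set(minima) == {(0, 0), (2, 2)}
        # cheapest 8-connected path (0,0)→(1,1)→(2,2) crosses level 7;
        # via (1,2): (0,0)→(0,1)→(1,2)→(2,2) crosses only 5
        assert _saddle_between(f, (0, 0), (2, 2)) == 5.0
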