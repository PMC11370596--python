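import numpy as np
import pytest

from conftest import direct_ewald_potential
from memflux.fields import (
    E_PER_EPS0_ANGSTROM_V,
    KT_OVER_E_310_V,
    align_trajectory,
    charge_density_grid,
    electrostatic_map,
    hydration_continuity,
    kabsch,
    solve_poisson_periodic,
    water_density,
)
from memflux.geometry import PoreRegion, fit_membrane
from memflux.model import Atom, Box, Topology, Trajectory


def _rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _protein_trajectory(coords_per_frame, box=Box(40, 40, 40)):
    n_atoms = coords_per_frame[0].shape[0]
    atoms = [
        Atom(index=i, name="CA", element="C", residue_name="ALA", residue_id=i + 1,
             role="protein")
        for i in range(n_atoms)
    ]
    coords = np.stack(coords_per_frame)
    times = np.arange(len(coords_per_frame)) * 10.0
    return Trajectory(Topology(atoms), coords, times, box)


class TestAlignment:
    def test_identity_frame_gives_identity_transform(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(15, 3)) * 4
        traj = _protein_trajectory([ref, ref.copy()])
        aligned, result = align_trajectory(traj, np.arange(15))
        assert np.allclose(result.rotations[1], np.eye(3), atol=1e-12)
        assert result.rmsd[1] < 1e-12

    def test_recovers_known_rotation_translation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(20, 3)) * 5
        rot = _rotation([0, 0, 1], np.pi / 6)
        moved = ref @ rot.T + np.array([1.0, 2.0, 3.0])
        traj = _protein_trajectory([ref, moved])
        aligned, result = align_trajectory(traj, np.arange(20))
        assert result.rmsd[1] < 1e-9
        assert np.abs(aligned.coordinates[1] - ref).max() < 1e-9
        assert np.linalg.det(result.rotations[1]) == pytest.approx(1.0, abs=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(12, 3)) * 5
        frames = [ref] + [ref @ _rotation([1, 1, 0], a).T + rng.normal(size=3)
                          for a in (0.3, 1.1, 2.0)]
        traj = _protein_trajectory(frames)
        aligned, _ = align_trajectory(traj, np.arange(12))
        again, result2 = align_trajectory(aligned, np.arange(12))
        assert np.allclose(result2.rotations, np.eye(3), atol=1e-9)
        assert np.abs(again.coordinates - aligned.coordinates).max() < 1e-9

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        traj = _protein_trajectory([line, line])
        with pytest.raises(ValueError, match="degenerate alignment"):
            align_trajectory(traj, np.arange(5))

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3))
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        rot, _ = kabsch(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_copy_rmsd_matches_monte_carlo_expectation(self):
        """Residual RMSD after fitting a noisy copy matches the noise model.

        Fitting rotation+translation absorbs 6 degrees of freedom, so
        E[RMSD^2] ~= sigma^2 (3N - 6)/N; checked against an independent
        Monte-Carlo average.
        """
        rng = np.random.default_rng(4)
        n, sigma = 30, 0.1
        ref = rng.normal(size=(n, 3)) * 6
        reps = 150
        sq = []
        for _ in range(reps):
            noisy = ref + rng.normal(0, sigma, size=(n, 3))
            rot, tr = kabsch(noisy, ref)
            fitted = noisy @ rot.T + tr
            sq.append(((fitted - ref) ** 2).sum() / n)
        mc = np.mean(sq)
        expected = sigma ** 2 * (3 * n - 6) / n
        assert mc == pytest.approx(expected, rel=0.1)


class TestWaterDensity:
    def _water_traj(self, positions, n_frames=10, box=Box(10, 10, 10)):
        n = positions.shape[0]
        atoms = [
            Atom(index=i, name="OH2", element="O", residue_name="TIP3",
                 residue_id=i + 1, role="water")
            for i in range(n)
        ]
        coords = np.tile(positions, (n_frames, 1, 1))
        return Trajectory(Topology(atoms), coords, np.arange(n_frames) * 10.0, box)

    def test_single_static_oxygen_fills_one_voxel(self):
        traj = self._water_traj(np.array([[0.5, 0.5, 0.5]]))
        grid = water_density(traj, voxel_size=1.0)
        assert grid.values.max() == pytest.approx(1.0)
        assert np.count_nonzero(grid.values) == 1
        assert grid.frames_averaged == 10

    def test_mass_conservation(self):
        rng = np.random.default_rng(5)
        traj = self._water_traj(rng.uniform(-5, 5, size=(40, 3)))
        grid = water_density(traj, voxel_size=1.0)
        total = grid.values.sum() * grid.voxel_size ** 3
        assert total == pytest.approx(40.0)

    def test_uniform_bulk_recovers_density(self):
        rng = np.random.default_rng(6)
        n, box = 500, 10.0
        frames = [rng.uniform(-box / 2, box / 2, size=(n, 3)) for _ in range(50)]
        atoms = [
            Atom(index=i, name="OH2", element="O", residue_name="TIP3",
                 residue_id=i + 1, role="water")
            for i in range(n)
        ]
        traj = Trajectory(Topology(atoms), np.stack(frames),
                          np.arange(50) * 10.0, Box(box, box, box))
        grid = water_density(traj, voxel_size=1.0)
        rho = n / box ** 3
        assert grid.values.mean() == pytest.approx(rho, rel=1e-9)  # exact by conservation
        # per-voxel Poisson noise: mean count 0.5 over 50 frames
        assert np.abs(grid.values - rho).max() < 6 * np.sqrt(rho / 50)

    def test_no_water_errors(self):
        atoms = [Atom(index=0, name="NA", element="N", residue_name="SOD",
                      residue_id=1, role="ion", ion_species="NA", ion_valence=1)]
        traj = Trajectory(Topology(atoms), np.zeros((2, 1, 3)), [0.0, 10.0],
                          Box(10, 10, 10))
        with pytest.raises(ValueError, match="no water"):
            water_density(traj)


class TestHydrationContinuity:
    def test_open_pore_is_continuous(self, preset_open):
        spec, top, traj, ledger = preset_open
        mem = fit_membrane(traj)
        grid = water_density(traj, 1.0, stride_ps=100.0)
        pore = PoreRegion(center_xy=spec.pore_center, radius=spec.pore_radius,
                          axial_extent=(-21.0, 21.0))
        prof = hydration_continuity(grid, pore, midplane=float(np.mean(mem.midplane)))
        assert prof.continuity is True
        assert prof.gap_intervals == []

    def test_programmed_dry_band_reported_as_gap(self, preset_closed):
        spec, top, traj, ledger = preset_closed
        mem = fit_membrane(traj)
        grid = water_density(traj, 1.0, stride_ps=25.0)
        pore = PoreRegion(center_xy=spec.pore_center, radius=spec.pore_radius,
                          axial_extent=(-21.0, 21.0))
        prof = hydration_continuity(grid, pore, midplane=float(np.mean(mem.midplane)))
        assert prof.continuity is False
        assert len(prof.gap_intervals) == 1
        lo, hi = prof.gap_intervals[0]
        band = ledger.dewetted_band
        assert lo == pytest.approx(band[0], abs=1.5)
        assert hi == pytest.approx(band[1], abs=1.5)

    def test_zero_threshold_always_continuous(self, preset_closed):
        spec, top, traj, ledger = preset_closed
        mem = fit_membrane(traj)
        grid = water_density(traj, 1.0, stride_ps=25.0)
        pore = PoreRegion(center_xy=spec.pore_center, radius=spec.pore_radius,
                          axial_extent=(-21.0, 21.0))
        prof = hydration_continuity(grid, pore, threshold=0.0,
                                    midplane=float(np.mean(mem.midplane)))
        assert prof.continuity is True


def _charged_trajectory(positions, charges, box_len=24.0, n_frames=1):
    atoms = []
    for i, q in enumerate(charges):
        atoms.append(
            Atom(index=i, name="NA" if q > 0 else "CL", element="N" if q > 0 else "C",
                 residue_name="SOD" if q > 0 else "CLA", residue_id=i + 1,
                 partial_charge=float(q), role="ion",
                 ion_species="NA" if q > 0 else "CL", ion_valence=int(np.sign(q)))
        )
    coords = np.tile(np.asarray(positions, float), (n_frames, 1, 1))
    return Trajectory(Topology(atoms), coords, np.arange(n_frames) * 25.0,
                      Box(box_len, box_len, box_len))


class TestElectrostatics:
    def test_unit_charge_matches_direct_ewald_sum(self):
        L, kappa = 24.0, 0.25
        sigma = 1.0 / (np.sqrt(2) * kappa)
        pos = np.array([[5.3, 11.1, 17.2]])
        traj = _charged_trajectory(pos - L / 2, [1.0], box_len=L)
        grid = electrostatic_map(traj, voxel_size=1.0, kappa=kappa)
        rng = np.random.default_rng(7)
        idx = rng.integers(0, grid.values.shape[0], size=(12, 3))
        probes = idx * grid.voxel_size  # grid nodes, box-corner coordinates
        oracle = direct_ewald_potential(pos, [1.0], [L, L, L], probes, sigma)
        oracle_kt = oracle * E_PER_EPS0_ANGSTROM_V / KT_OVER_E_310_V
        mine = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.abs(mine - oracle_kt).max() < 1e-3

    def test_antisymmetric_pair(self):
        L = 20.0
        pos = np.array([[-4.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        traj = _charged_trajectory(pos, [1.0, -1.0], box_len=L)
        grid = electrostatic_map(traj, voxel_size=1.0, kappa=0.25)
        v = grid.values
        # mirror through x -> -x maps the +1 onto the -1: potential negates
        mirrored = np.roll(v[::-1], 1, axis=0)
        assert np.abs(v + mirrored).max() < 1e-9
        assert abs(v.mean()) < 1e-12
        # midpoint plane between the charges carries the grid-mean potential
        mid = v[v.shape[0] // 2]
        assert np.abs(mid.mean() - v.mean()) < 1e-9

    def test_linearity_in_charge(self):
        pos = np.array([[3.0, -2.0, 5.0], [-6.0, 1.0, -3.0]])
        t1 = _charged_trajectory(pos, [1.0, -0.5], box_len=20.0)
        t2 = _charged_trajectory(pos, [2.0, -1.0], box_len=20.0)
        g1 = electrostatic_map(t1, voxel_size=1.0, kappa=0.25)
        g2 = electrostatic_map(t2, voxel_size=1.0, kappa=0.25)
        assert np.abs(g2.values - 2 * g1.values).max() < 1e-9

    def test_zero_charges_rejected(self):
        atoms = [Atom(index=0, name="OH2", element="O", residue_name="TIP3",
                      residue_id=1, role="water")]
        traj = Trajectory(Topology(atoms), np.zeros((1, 1, 3)), [0.0], Box(10, 10, 10))
        with pytest.raises(ValueError, match="no charges"):
            electrostatic_map(traj)

    def test_poisson_solver_spectral_laplacian(self):
        """Applying the spectral Laplacian to phi recovers -(rho - mean rho)."""
        rng = np.random.default_rng(8)
        box = np.array([16.0, 16.0, 16.0])
        pos = rng.uniform(0, 16, size=(5, 3))
        q = rng.normal(size=5)
        rho = charge_density_grid(pos, q, box, (16, 16, 16), sigma=2.0)
        phi = solve_poisson_periodic(rho, box)
        k = [2 * np.pi * np.fft.fftfreq(16, d=1.0)] * 3
        kx, ky, kz = np.meshgrid(*k, indexing="ij")
        lap = np.fft.ifftn(-(kx ** 2 + ky ** 2 + kz ** 2) * np.fft.fftn(phi)).real
        target = -(rho - rho.mean())
        assert np.abs(lap - target).max() < 1e-6 * max(1.0, np.abs(rho).max())


class TestDensitySmoothing:
    def test_gaussian_smoothing_conserves_mass_and_spreads(self):
        atoms = [Atom(index=0, name="OH2", element="O", residue_name="TIP3",
                      residue_id=1, role="water")]
        coords = np.tile([[0.5, 0.5, 0.5]], (5, 1, 1))
        traj = Trajectory(Topology(atoms), coords, np.arange(5) * 10.0,
                          Box(10, 10, 10))
        sharp = water_density(traj, voxel_size=1.0)
        smooth = water_density(traj, voxel_size=1.0, smoothing_sigma=1.0)
        for grid in (sharp, smooth):
            assert grid.values.sum() * grid.voxel_size ** 3 == pytest.approx(1.0)
        assert np.count_nonzero(smooth.values > 1e-6) > np.count_nonzero(sharp.values)
        assert smooth.values.max() < sharp.values.max()
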