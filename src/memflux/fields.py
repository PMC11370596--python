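"""Trajectory alignment, averaged density grids and periodic electrostatics.

Alignment is the standard Kabsch least-squares rigid superposition of a
selection (typically protein backbone) onto a reference frame, with the same
rotation/translation applied to all atoms so that time-averaged maps are
computed in the protein frame.

Water density is a VolMap-style occupancy map: water oxygens are binned to
their nearest voxel each sampled frame and the per-voxel mean count is
divided by the voxel volume (units Å^-3).

The electrostatic map treats each partial charge as a Gaussian of width
sigma = 1/(sqrt(2) kappa) — kappa being the Ewald splitting factor in Å^-1 —
and solves the periodic Poisson equation spectrally on the grid, zeroing the
k=0 mode (uniform neutralizing background).  Potentials are averaged over
sampled frames and reported in kT/e at 310 K; multiply by KT_OVER_E_310_V to
get volts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MembraneModel, PoreRegion, wrap_displacement
from .model import Box, Topology, Trajectory

#: SI constants
ELEMENTARY_CHARGE = 1.602176634e-19   # C
EPSILON_0 = 8.8541878128e-12          # F/m
BOLTZMANN = 1.380649e-23              # J/K

#: volts per reduced potential unit (charge in e, length in Å, eps0 = 1)
E_PER_EPS0_ANGSTROM_V = ELEMENTARY_CHARGE / (EPSILON_0 * 1e-10)

#: kT/e in volts at 310 K
KT_OVER_E_310_V = BOLTZMANN * 310.0 / ELEMENTARY_CHARGE


@dataclass
class DensityGrid:
    """A time-averaged scalar field on a regular grid with isotropic voxels."""

    origin: np.ndarray            # (3,) Å, corner of voxel (0,0,0)
    voxel_size: float             # Å
    values: np.ndarray            # (nx, ny, nz)
    quantity: str                 # "number_density" (Å^-3) or "potential" (kT/e)
    frames_averaged: int

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.quantity == "number_density" and np.any(self.values < 0):
            raise ValueError("number density must be non-negative")

    @property
    def dimensions(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size


@dataclass
class AlignmentResult:
    rotations: np.ndarray         # (F, 3, 3), proper rotations
    translations: np.ndarray     # (F, 3) Å
    rmsd: np.ndarray              # (F,) Å over the alignment selection

    def __post_init__(self) -> None:
        dets = np.linalg.det(self.rotations)
        if not np.allclose(dets, 1.0, atol=1e-9):
            raise ValueError("rotations must be proper (det = +1)")
        if np.any(self.rmsd < -1e-12):
            raise ValueError("RMSD must be non-negative")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ mobile + t ≈ reference.

    Proper rotation enforced (reflections corrected by flipping the smallest
    singular direction).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = rc - rot @ mc
    return rot, trans


def align_trajectory(
    traj: Trajectory,
    selection: np.ndarray,
    reference_frame: int = 0,
) -> tuple[Trajectory, AlignmentResult]:
    """Superpose every frame's selection onto the reference frame (Kabsch)."""
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    ref = traj.coordinates[reference_frame, sel]
    centered = ref - ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate alignment: selection atoms are collinear")

    n_frames = traj.n_frames
    coords = np.empty_like(traj.coordinates)
    rots = np.empty((n_frames, 3, 3))
    trans = np.empty((n_frames, 3))
    rmsd = np.empty(n_frames)
    for f in range(n_frames):
        rot, t = kabsch(traj.coordinates[f, sel], ref)
        coords[f] = traj.coordinates[f] @ rot.T + t
        rots[f] = rot
        trans[f] = t
        diff = coords[f, sel] - ref
        rmsd[f] = np.sqrt((diff ** 2).sum() / sel.size)
    aligned = Trajectory(traj.topology, coords, traj.times.copy(), list(traj.boxes))
    return aligned, AlignmentResult(rotations=rots, translations=trans, rmsd=rmsd)


def _frame_indices_for_stride(traj: Trajectory, stride_ps: float | None) -> np.ndarray:
    if not stride_ps or traj.n_frames < 2:
        return np.arange(traj.n_frames)
    dt = traj.stride_ps
    step = max(1, int(round(stride_ps / dt))) if dt > 0 else 1
    return np.arange(0, traj.n_frames, step)


def water_density(
    traj: Trajectory,
    voxel_size: float = 1.0,
    selection: np.ndarray | None = None,
    stride_ps: float | None = None,
    smoothing_sigma: float | None = None,
) -> DensityGrid:
    """Time-averaged water number-density grid (Å^-3), nearest-voxel binning.

    The grid covers the first frame's box, centred on the coordinate origin.
    Default selection is all water oxygens (water-role atoms whose element is
    O, or all water atoms for single-site water models).  ``smoothing_sigma``
    (Å) optionally applies a periodic Gaussian kernel to the binned counts,
    giving a KDE-style map; total density is conserved either way.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    top = traj.topology
    if selection is None:
        waters = top.select(role="water")
        oxy = waters[np.array([top.atoms[i].element == "O" for i in waters], dtype=bool)] if waters.size else waters
        selection = oxy if oxy.size else waters
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("no water atoms to bin")

    box = traj.boxes[0].lengths
    dims = np.maximum(1, np.floor(box / voxel_size).astype(int))
    origin = -box / 2.0
    counts = np.zeros(tuple(dims))
    frames = _frame_indices_for_stride(traj, stride_ps)
    for f in frames:
        pos = traj.coordinates[f, sel]
        # wrap into the grid box
        rel = np.mod(pos - origin, box)
        idx = np.floor(rel / voxel_size).astype(int)
        np.minimum(idx, dims - 1, out=idx)
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    if smoothing_sigma is not None and smoothing_sigma > 0:
        from scipy.ndimage import gaussian_filter

        counts = gaussian_filter(counts, sigma=smoothing_sigma / voxel_size,
                                 mode="wrap")
        counts = np.clip(counts, 0.0, None)
    values = counts / (len(frames) * voxel_size ** 3)
    return DensityGrid(
        origin=origin,
        voxel_size=voxel_size,
        values=values,
        quantity="number_density",
        frames_averaged=len(frames),
    )


@dataclass
class HydrationProfile:
    """Axial water-density profile inside the pore cylinder and its verdict."""

    bin_centers: np.ndarray        # Å, midplane-relative
    density: np.ndarray            # Å^-3 per axial bin inside the cylinder
    bulk_density: float            # Å^-3
    threshold: float               # fraction of bulk below which a bin is dry
    continuity: bool
    gap_intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if bool(self.gap_intervals) == bool(self.continuity):
            raise ValueError("continuity must be true iff there are no gaps")


def hydration_continuity(
    grid: DensityGrid,
    pore: PoreRegion,
    threshold: float = 0.25,
    midplane: float = 0.0,
    normal_axis: int = 2,
) -> HydrationProfile:
    """Test whether the water column through the pore is axially continuous.

    Bulk density is estimated from voxels axially outside the pore's
    ``axial_extent``; an axial bin (one voxel layer restricted to the pore
    cylinder) is dry when its mean density falls below ``threshold`` x bulk.
    Maximal dry runs become gap intervals; continuity holds iff none exist.
    """
    if grid.quantity != "number_density":
        raise ValueError("hydration continuity requires a number-density grid")
    if pore.center_xy is None:
        raise ValueError("hydration continuity requires an explicit pore centre")
    axes = [a for a in range(3) if a != normal_axis]
    zc = grid.axis_centers(normal_axis) - midplane
    xc = grid.axis_centers(axes[0])
    yc = grid.axis_centers(axes[1])
    xx, yy = np.meshgrid(xc - pore.center_xy[0], yc - pore.center_xy[1], indexing="ij")
    in_cyl = np.hypot(xx, yy) <= pore.radius

    vals = np.moveaxis(grid.values, normal_axis, -1)          # (nx', ny', nz)
    lo, hi = pore.axial_extent
    outside = (zc < lo) | (zc > hi)
    if not outside.any():
        raise ValueError("grid does not extend beyond the pore axial extent")
    bulk = float(vals[:, :, outside].mean())
    if bulk <= 0:
        raise ValueError("bulk density estimate is non-positive")

    inside_bins = np.flatnonzero((zc >= lo) & (zc <= hi))
    dens = np.array([vals[in_cyl, k].mean() for k in inside_bins])
    dry = dens < threshold * bulk

    gaps: list[tuple[float, float]] = []
    k = 0
    half = grid.voxel_size / 2.0
    while k < len(dry):
        if dry[k]:
            start = k
            while k < len(dry) and dry[k]:
                k += 1
            gaps.append(
                (float(zc[inside_bins[start]] - half), float(zc[inside_bins[k - 1]] + half))
            )
        else:
            k += 1
    return HydrationProfile(
        bin_centers=zc[inside_bins],
        density=dens,
        bulk_density=bulk,
        threshold=threshold,
        continuity=not gaps,
        gap_intervals=gaps,
    )


def _grid_wavevectors(shape: tuple[int, int, int], box: np.ndarray):
    ks = [2.0 * np.pi * np.fft.fftfreq(n, d=l / n) for n, l in zip(shape, box)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    return kx, ky, kz


def charge_density_grid(
    positions: np.ndarray,
    charges: np.ndarray,
    box: np.ndarray,
    shape: tuple[int, int, int],
    sigma: float,
) -> np.ndarray:
    """Periodic Gaussian-smeared charge density (e/Å^3) on a regular grid.

    Each point charge is replaced by a periodic Gaussian of width ``sigma``;
    the smearing is applied exactly in reciprocal space via the structure
    factor, so the grid density is spectrally accurate (no assignment-order
    error).
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    box = np.asarray(box, dtype=float)
    nx, ny, nz = shape
    k1 = [2.0 * np.pi * np.fft.fftfreq(n, d=l / n) for n, l in zip(shape, box)]

    s_k = np.zeros(shape, dtype=complex)
    chunk = 256
    for a in range(0, len(charges), chunk):
        sl = slice(a, a + chunk)
        ax = np.exp(-1j * np.outer(positions[sl, 0], k1[0]))
        ay = np.exp(-1j * np.outer(positions[sl, 1], k1[1]))
        az = np.exp(-1j * np.outer(positions[sl, 2], k1[2]))
        s_k += np.einsum("j,jx,jy,jz->xyz", charges[sl], ax, ay, az)

    kx, ky, kz = _grid_wavevectors(shape, box)
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    s_k *= np.exp(-0.5 * sigma ** 2 * k2)
    volume = float(np.prod(box))
    n_total = nx * ny * nz
    # rho(r_m) = (1/V) sum_k S(k) e^{i k r_m}; grid points at origin 0
    rho = np.fft.ifftn(s_k) * n_total / volume
    return rho.real


def solve_poisson_periodic(rho: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Solve nabla^2 phi = -rho on a periodic grid (reduced units, eps0 = 1).

    The k=0 mode is zeroed, which is equivalent to adding a uniform
    neutralizing background charge; the returned potential has zero mean.
    """
    rho = np.asarray(rho, dtype=float)
    box = np.asarray(box, dtype=float)
    kx, ky, kz = _grid_wavevectors(rho.shape, box)
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    rho_k = np.fft.fftn(rho)
    phi_k = np.zeros_like(rho_k)
    nonzero = k2 > 0
    phi_k[nonzero] = rho_k[nonzero] / k2[nonzero]
    return np.fft.ifftn(phi_k).real


def electrostatic_map(
    traj: Trajectory,
    voxel_size: float = 1.0,
    kappa: float = 0.25,
    stride_ps: float | None = 25.0,
    temperature: float = 310.0,
) -> DensityGrid:
    """Frame-averaged periodic electrostatic potential map in kT/e.

    ``kappa`` is the Ewald splitting factor (Å^-1); charges are smeared as
    Gaussians of sigma = 1/(sqrt(2) kappa).  The net system charge is
    implicitly neutralized by a uniform background (k=0 mode zeroed).
    """
    top = traj.topology
    charges = top.charges
    if not np.any(charges != 0):
        raise ValueError("no charges in topology: cannot compute an electrostatic map")
    if kappa <= 0 or voxel_size <= 0:
        raise ValueError("kappa and voxel_size must be positive")
    sigma = 1.0 / (np.sqrt(2.0) * kappa)
    charged = np.flatnonzero(charges != 0)
    q_net = float(charges.sum())
    if abs(q_net) > 1e-9:
        import logging

        logging.getLogger("memflux").info(
            "net charge %.3f e neutralized by uniform background", q_net
        )

    box = traj.boxes[0].lengths
    shape = tuple(np.maximum(2, np.floor(box / voxel_size).astype(int)))
    frames = _frame_indices_for_stride(traj, stride_ps)
    # grid points at r_m = m * (L/n); shift coordinates so the grid origin
    # coincides with the box corner at -L/2
    origin = -box / 2.0
    acc = np.zeros(shape)
    for f in frames:
        pos = np.mod(traj.coordinates[f, charged] - origin, box)
        rho = charge_density_grid(pos, charges[charged], box, shape, sigma)
        acc += solve_poisson_periodic(rho, box)
    phi_reduced = acc / len(frames)
    kt_over_e = BOLTZMANN * temperature / ELEMENTARY_CHARGE
    phi_kt = phi_reduced * E_PER_EPS0_ANGSTROM_V / kt_over_e
    return DensityGrid(
        origin=origin,
        voxel_size=float(box[0] / shape[0]),
        values=phi_kt,
        quantity="potential",
        frames_averaged=len(frames),
    )
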