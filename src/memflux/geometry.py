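"""Membrane frame of reference and pore region.

The membrane normal is fixed to a box axis (default z).  The midplane is the
per-frame median of all lipid headgroup coordinates along the normal; each
leaflet plane is the per-frame mean of its own headgroups.  The headgroup ->
leaflet partition is established once, on the first frame, and never changes
here: leaflet reassignment is the scrambling module's job, so a lipid in
mid-flip does not drag its plane with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Topology, Trajectory

AXES = {"x": 0, "y": 1, "z": 2}


def wrap_displacement(delta, box_length):
    """Minimum-image displacement(s) mapped into (-L/2, L/2].

    Works elementwise on arrays; ``box_length`` may be scalar or broadcastable.
    """
    box_length = np.asarray(box_length, dtype=float)
    if np.any(box_length <= 0):
        raise ValueError("box_length must be positive")
    delta = np.asarray(delta, dtype=float)
    out = delta - box_length * np.ceil(delta / box_length - 0.5)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class MembraneModel:
    """Per-frame membrane planes along the normal axis (Å)."""

    normal_axis: int
    midplane: np.ndarray          # (n_frames,)
    upper_plane: np.ndarray       # (n_frames,)
    lower_plane: np.ndarray       # (n_frames,)
    headgroup_indices: np.ndarray  # atom indices used for the fit
    leaflet_of_headgroup: np.ndarray  # +1 upper / -1 lower, frame-0 partition

    def __post_init__(self) -> None:
        if not np.all(self.lower_plane < self.midplane) or not np.all(
            self.midplane < self.upper_plane
        ):
            raise ValueError("planes must satisfy lower < midplane < upper in every frame")

    @property
    def slab_halfwidth(self) -> float:
        return float(np.mean(self.upper_plane - self.lower_plane) / 2.0)


def fit_membrane(
    traj: Trajectory,
    headgroup_selection: Sequence[int] | None = None,
    normal_axis: str | int = "z",
) -> MembraneModel:
    """Fit per-frame midplane and leaflet planes from lipid headgroup atoms."""
    axis = AXES[normal_axis] if isinstance(normal_axis, str) else int(normal_axis)
    if headgroup_selection is None:
        headgroup_selection = traj.topology.select(headgroup=True)
    hg = np.asarray(headgroup_selection, dtype=int)
    if hg.size < 8:
        raise ValueError("need at least 8 headgroup atoms to fit a membrane")

    z = traj.coordinates[:, hg, axis]  # (F, H)

    # initial leaflet partition by sign about the frame-0 median; the
    # partition is then propagated unchanged (reassignment is the scrambling
    # module's job, never the fit's)
    leaflet = np.where(z[0] >= np.median(z[0]), 1, -1)
    for sign in (1, -1):
        if int(np.sum(leaflet == sign)) < 4:
            raise ValueError("degenerate leaflet: fewer than 4 headgroup atoms")

    upper = z[:, leaflet == 1].mean(axis=1)
    lower = z[:, leaflet == -1].mean(axis=1)
    if not np.all(lower < upper):
        raise ValueError("degenerate leaflet: leaflet planes cross")
    # midpoint of the fixed-partition planes; a global per-frame median is
    # not robust here — one flipped lipid leaves the leaflet counts uneven
    # and drags the median of an even-sized sample into a headgroup cluster
    midplane = 0.5 * (upper + lower)
    return MembraneModel(
        normal_axis=axis,
        midplane=midplane,
        upper_plane=upper,
        lower_plane=lower,
        headgroup_indices=hg,
        leaflet_of_headgroup=leaflet,
    )


@dataclass
class PoreRegion:
    """Cylindrical pore membership region.

    ``center_xy`` is the in-plane centre (ignored when ``track_selection`` is
    given, in which case the centre follows the selection centroid each
    frame); ``axial_extent`` is relative to the membrane midplane.
    """

    center_xy: tuple[float, float] | None = None
    radius: float = 10.0
    axial_extent: tuple[float, float] = (-25.0, 25.0)
    track_selection: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pore radius must be positive")
        if self.center_xy is None and self.track_selection is None:
            raise ValueError("pore needs either an explicit center_xy or a track_selection")
        if self.axial_extent[0] >= self.axial_extent[1]:
            raise ValueError("axial_extent must be an increasing interval")

    def center(self, traj: Trajectory, frame: int, normal_axis: int = 2) -> np.ndarray:
        """In-plane pore centre for one frame."""
        in_plane = [a for a in range(3) if a != normal_axis]
        if self.track_selection is not None:
            sel = np.asarray(self.track_selection, dtype=int)
            return traj.coordinates[frame, sel][:, in_plane].mean(axis=0)
        return np.asarray(self.center_xy, dtype=float)

    def centers(self, traj: Trajectory, normal_axis: int = 2) -> np.ndarray:
        """(n_frames, 2) array of in-plane pore centres."""
        in_plane = [a for a in range(3) if a != normal_axis]
        if self.track_selection is not None:
            sel = np.asarray(self.track_selection, dtype=int)
            return traj.coordinates[:, sel][:, :, in_plane].mean(axis=1)
        return np.tile(np.asarray(self.center_xy, dtype=float), (traj.n_frames, 1))

    def inside(
        self,
        traj: Trajectory,
        membrane,
        atom_indices: np.ndarray,
        frame: int,
    ) -> np.ndarray:
        """Boolean pore membership of atoms in one frame (radial AND axial)."""
        axis = membrane.normal_axis
        in_plane = [a for a in range(3) if a != axis]
        box = traj.boxes[frame].lengths
        pos = traj.coordinates[frame, np.asarray(atom_indices, dtype=int)]
        ctr = self.center(traj, frame, axis)
        d = np.stack(
            [
                wrap_displacement(pos[:, in_plane[0]] - ctr[0], box[in_plane[0]]),
                wrap_displacement(pos[:, in_plane[1]] - ctr[1], box[in_plane[1]]),
            ],
            axis=1,
        )
        radial_ok = np.hypot(d[:, 0], d[:, 1]) <= self.radius
        z_rel = wrap_displacement(pos[:, axis] - membrane.midplane[frame], box[axis])
        axial_ok = (z_rel >= self.axial_extent[0]) & (z_rel <= self.axial_extent[1])
        return radial_ok & axial_ok


def define_pore(
    config: dict,
    topology: Topology | None = None,
    membrane: MembraneModel | None = None,
    buffer: float = 5.0,
) -> PoreRegion:
    """Build a :class:`PoreRegion` from config keys.

    Recognised keys: ``center_xy`` (pair, Å), ``radius_A`` (Å, default 10),
    ``axial_extent`` (pair, Å relative to midplane), ``track_selection``
    (residue ids of a protein selection whose centroid the pore follows).
    """
    center = config.get("center_xy")
    track = config.get("track_selection")
    if center is None and track is None:
        raise ValueError("pore config needs center_xy or track_selection")
    radius = float(config.get("radius_A", 10.0))
    track_idx = None
    if track is not None:
        if topology is None:
            raise ValueError("track_selection requires a topology")
        track_idx = topology.select(residue_ids=list(track))
        if track_idx.size == 0:
            raise ValueError(f"track_selection {track!r} matches no atoms")
    extent = config.get("axial_extent")
    if extent is None:
        if membrane is not None:
            extent = (
                float(np.min(membrane.lower_plane - membrane.midplane)) - buffer - 1.0,
                float(np.max(membrane.upper_plane - membrane.midplane)) + buffer + 1.0,
            )
        else:
            extent = (-25.0, 25.0)
    extent = (float(extent[0]), float(extent[1]))
    if membrane is not None:
        lo_needed = float(np.min(membrane.lower_plane - membrane.midplane)) - buffer
        if extent[0] > lo_needed + 1e-9:
            import warnings

            warnings.warn(
                "pore axial_extent does not span the membrane slab plus buffer",
                stacklevel=2,
            )
    return PoreRegion(
        center_xy=tuple(center) if center is not None else None,
        radius=radius,
        axial_extent=extent,
        track_selection=track_idx,
    )
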