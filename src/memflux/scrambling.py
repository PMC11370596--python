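"""Lipid leaflet assignment and flip-flop (scrambling) detection.

Leaflet identity is defined by the headgroup position along the membrane
normal, with hysteresis: a lipid keeps its current label until its headgroup
has spent ``dwell`` consecutive frames beyond the midplane +/- ``band``
hysteresis zone on the opposite side.  Excursions that enter the band (or
even cross the midplane) and return never change the label, so headgroup
jitter around the midplane cannot fabricate flip events.

Headgroup coordinates are unwrapped (minimum-image continuous) relative to
the per-frame midplane before any labelling, so a lipid carried across the
periodic boundary does not appear to teleport between leaflets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import MembraneModel, wrap_displacement
from .model import Trajectory

UPPER, LOWER = 1, -1
_LEAFLET_NAME = {UPPER: "upper", LOWER: "lower"}


@dataclass(frozen=True)
class FlipEvent:
    lipid_residue_id: int
    start_leaflet: str            # "upper" or "lower"
    end_leaflet: str
    start_time: float             # ps, last frame committed to origin leaflet
    end_time: float               # ps, first frame committed to destination
    start_frame: int
    end_frame: int
    transit_duration_ns: float
    max_midplane_penetration: float  # Å past the midplane reached in transit

    def __post_init__(self) -> None:
        if self.start_leaflet == self.end_leaflet:
            raise ValueError("start and end leaflet must differ")
        if self.end_time <= self.start_time:
            raise ValueError("end_time must be after start_time")


@dataclass
class LeafletSeries:
    """Per-lipid leaflet labels and raw normal coordinates over time."""

    residue_ids: np.ndarray        # (L,)
    times: np.ndarray              # (F,) ps
    z_rel: np.ndarray              # (F, L) unwrapped headgroup coord, midplane-relative
    labels: np.ndarray             # (F, L) +1 upper / -1 lower
    band: float
    dwell: int


def _unwrapped_z_rel(traj: Trajectory, membrane: MembraneModel, hg: np.ndarray) -> np.ndarray:
    axis = membrane.normal_axis
    box_l = np.array([b.lengths[axis] for b in traj.boxes])
    z = traj.coordinates[:, hg, axis]
    zr = wrap_displacement(z - membrane.midplane[:, None], box_l[:, None])
    out = np.empty_like(zr)
    out[0] = zr[0]
    steps = wrap_displacement(np.diff(zr, axis=0), box_l[1:, None])
    out[1:] = out[0] + np.cumsum(steps, axis=0)
    return out


def leaflet_series(
    traj: Trajectory,
    membrane: MembraneModel,
    band: float = 5.0,
    dwell: int = 10,
) -> LeafletSeries:
    """Assign every lipid a committed leaflet label in every frame."""
    if band <= 0:
        raise ValueError("hysteresis band must be positive")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    top = traj.topology
    lipid_resids = np.unique(top.residue_ids[top.roles == "lipid"])
    if lipid_resids.size == 0:
        raise ValueError("no lipid residues in topology")
    hg = []
    for rid in lipid_resids:
        idx = top.select(residue_ids=[rid], headgroup=True)
        if idx.size != 1:
            raise ValueError(f"lipid residue {rid} lacks a headgroup reference atom")
        hg.append(int(idx[0]))
    hg = np.asarray(hg)

    z = _unwrapped_z_rel(traj, membrane, hg)                  # (F, L)
    n_frames, n_lip = z.shape

    # candidate side per frame: beyond the band, else 0
    cand = np.zeros_like(z, dtype=np.int8)
    cand[z > band] = UPPER
    cand[z < -band] = LOWER

    labels = np.empty_like(cand)
    init = np.where(z[0] >= 0, UPPER, LOWER).astype(np.int8)
    for j in range(n_lip):
        cur = init[j]
        run_side, run_len = 0, 0
        lbl = np.empty(n_frames, dtype=np.int8)
        pending_from = -1
        for f in range(n_frames):
            c = int(cand[f, j])
            if c == 0 or c == cur:
                run_side, run_len = 0, 0
                lbl[f] = cur
                continue
            if c == run_side:
                run_len += 1
            else:
                run_side, run_len = c, 1
                pending_from = f
            if run_len >= dwell:
                # commit retroactively from the first frame of the run
                lbl[pending_from:f + 1] = c
                cur = c
                run_side, run_len = 0, 0
            else:
                lbl[f] = cur
        labels[:, j] = lbl
    return LeafletSeries(
        residue_ids=lipid_resids,
        times=traj.times.copy(),
        z_rel=z,
        labels=labels,
        band=band,
        dwell=dwell,
    )


def detect_flips(series: LeafletSeries) -> list[FlipEvent]:
    """One :class:`FlipEvent` per committed leaflet change."""
    events: list[FlipEvent] = []
    t = series.times
    for j, rid in enumerate(series.residue_ids):
        lbl = series.labels[:, j]
        z = series.z_rel[:, j]
        changes = np.flatnonzero(np.diff(lbl)) + 1            # first frame with new label
        for f_end in changes:
            origin = int(lbl[f_end - 1])
            dest = int(lbl[f_end])
            # last frame before the switch with the headgroup committed-side
            # positioned beyond the band on the origin side
            before = np.flatnonzero(
                (np.arange(len(z)) < f_end) & (origin * z > series.band)
            )
            f_start = int(before[-1]) if before.size else max(0, f_end - 1)
            transit = slice(f_start, f_end + 1)
            penetration = float(max(0.0, np.max(dest * z[transit])))
            events.append(
                FlipEvent(
                    lipid_residue_id=int(rid),
                    start_leaflet=_LEAFLET_NAME[origin],
                    end_leaflet=_LEAFLET_NAME[dest],
                    start_time=float(t[f_start]),
                    end_time=float(t[f_end]),
                    start_frame=f_start,
                    end_frame=int(f_end),
                    transit_duration_ns=float(t[f_end] - t[f_start]) / 1000.0,
                    max_midplane_penetration=penetration,
                )
            )
    events.sort(key=lambda e: (e.end_time, e.lipid_residue_id))
    return events


def flip_trace(
    lipid_residue_id: int,
    traj: Trajectory,
    membrane: MembraneModel,
) -> pd.DataFrame:
    """Midplane-relative, unwrapped headgroup trace of one lipid.

    Returns a tidy table (time_ps, time_ns, z_rel_A) suitable for plotting the
    full trajectory of a flipping lipid.
    """
    top = traj.topology
    idx = top.select(residue_ids=[lipid_residue_id], headgroup=True)
    if idx.size != 1:
        raise ValueError(f"residue {lipid_residue_id} is not a lipid with a headgroup atom")
    z = _unwrapped_z_rel(traj, membrane, idx)[:, 0]
    return pd.DataFrame(
        {
            "time_ps": traj.times,
            "time_ns": traj.times / 1000.0,
            "z_rel_A": z,
        }
    )
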