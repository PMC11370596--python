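"""Ion permeation detection, conductance, and ion-residue contacts.

A permeation (crossing) event is one ion moving from the bulk solution on one
side of the bilayer to the bulk on the other side through the membrane slab.
Detection runs a three-zone state machine per ion along the membrane normal:

* below-bulk:  z_rel < lower_plane - buffer
* slab (transit zone): between the two buffered planes
* above-bulk:  z_rel > upper_plane + buffer

where z_rel is the minimum-image coordinate relative to the per-frame
midplane.  An event is emitted when an ion committed to one bulk zone reaches
commitment in the opposite bulk zone with all intermediate frames spent
contiguously in the slab zone.  Because in a periodic slab system the two
bulk regions are also connected through the box boundary, a jump between
bulk zones that never visits the slab zone (a periodic wrap) is never
scored as a crossing.

Conductance is the "upper limit" estimate used for voltage-clamp counting
simulations: gross field-consistent transported charge Q (cations moving
with the electric field plus anions moving against it, each weighted by
|valence|) divided by |V| and elapsed time,

    Lambda = Q e / (|V| t),   reported in pS.

Field-inconsistent events are tallied separately as backward events and do
not enter Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import MembraneModel, PoreRegion, wrap_displacement
from .model import Trajectory

#: exact SI elementary charge, C
ELEMENTARY_CHARGE = 1.602176634e-19

#: pore-mouth basic residues reported to coordinate the permeant anion,
#: shipped as annotation presets for contact analysis
PORE_CONTACT_RESIDUES = {
    "TMC4": ("R419", "R488", "R635"),
    "TMC5": ("R641", "R736", "R659", "K549"),
}

#: charged-group atom names per basic residue type (salt-bridge partners)
CHARGED_GROUP_ATOMS = {
    "ARG": ("NH1", "NH2", "NE", "CZ"),
    "LYS": ("NZ",),
}


@dataclass(frozen=True)
class CrossingEvent:
    atom_index: int
    ion_species: str
    ion_valence: int
    direction: str                # "up" (+normal) or "down" (-normal)
    entry_time: float             # ps, first frame inside the slab zone
    exit_time: float              # ps, first frame committed to destination bulk
    entry_frame: int
    exit_frame: int
    path_through_pore: bool

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.exit_time <= self.entry_time:
            raise ValueError("exit_time must be after entry_time")


def detect_crossings(
    traj: Trajectory,
    membrane: MembraneModel,
    pore: PoreRegion | None = None,
    species: Sequence[str] = ("NA", "CL"),
    buffer: float = 5.0,
    dwell: int = 1,
    mode: str = "radial",
) -> list[CrossingEvent]:
    """Detect completed transmembrane crossings for the given ion species.

    ``mode="radial"`` keeps only events whose every in-slab frame lies within
    the pore cylinder; ``mode="slab"`` scores any transmembrane crossing.
    ``dwell`` is the number of consecutive frames beyond plane+buffer required
    to commit an ion to a bulk zone (suppresses boundary chatter).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to detect crossings")
    if mode not in ("radial", "slab"):
        raise ValueError("mode must be 'radial' or 'slab'")
    if mode == "radial" and pore is None:
        raise ValueError("radial mode requires a pore region")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")

    top = traj.topology
    ions = top.select(role="ion", species=list(species))
    if ions.size == 0:
        raise ValueError(f"species filter {tuple(species)} matches no ions")

    axis = membrane.normal_axis
    in_plane = [a for a in range(3) if a != axis]
    n_frames = traj.n_frames
    box_l = np.array([b.lengths[axis] for b in traj.boxes])  # (F,)

    z = traj.coordinates[:, ions, axis]                       # (F, I)
    z_rel = wrap_displacement(z - membrane.midplane[:, None], box_l[:, None])
    up_rel = membrane.upper_plane - membrane.midplane         # (F,)
    lo_rel = membrane.lower_plane - membrane.midplane

    # zone codes: +1 above-bulk, -1 below-bulk, 0 slab/transit
    zones = np.zeros_like(z_rel, dtype=np.int8)
    zones[z_rel > (up_rel + buffer)[:, None]] = 1
    zones[z_rel < (lo_rel - buffer)[:, None]] = -1

    # stride-coarseness check: per-frame normal displacement of the tracked ions
    steps = wrap_displacement(np.diff(z, axis=0), box_l[1:, None])
    if np.median(np.abs(steps)) > buffer:
        import warnings

        warnings.warn(
            "median per-frame ion displacement exceeds the bulk buffer: "
            "possible missed crossings at this save stride",
            stacklevel=2,
        )

    # radial membership of each ion in each frame (within pore cylinder)
    if pore is not None:
        centers = pore.centers(traj, axis)                    # (F, 2)
        dx = wrap_displacement(
            traj.coordinates[:, ions, in_plane[0]] - centers[:, 0][:, None],
            np.array([b.lengths[in_plane[0]] for b in traj.boxes])[:, None],
        )
        dy = wrap_displacement(
            traj.coordinates[:, ions, in_plane[1]] - centers[:, 1][:, None],
            np.array([b.lengths[in_plane[1]] for b in traj.boxes])[:, None],
        )
        radial_ok = np.hypot(dx, dy) <= pore.radius           # (F, I)
    else:
        radial_ok = np.ones_like(zones, dtype=bool)

    in_slab = (z_rel >= lo_rel[:, None]) & (z_rel <= up_rel[:, None])

    events: list[CrossingEvent] = []
    for col, atom_idx in enumerate(ions):
        zcol = zones[:, col]
        committed = 0          # last committed bulk zone (0 = none yet)
        last_committed_frame = -1  # most recent frame spent in that zone
        run_zone = 0           # current bulk-zone run being accumulated
        run_len = 0
        for f in range(n_frames):
            zn = int(zcol[f])
            if zn == 0:
                run_zone, run_len = 0, 0
                continue
            if zn == run_zone:
                run_len += 1
            else:
                run_zone, run_len = zn, 1
            if zn == committed:
                last_committed_frame = f
                continue
            if run_len < dwell:
                continue
            first = f - dwell + 1  # first frame of the committing run
            if committed != 0:
                # a crossing only if every frame since the ion last sat in its
                # committed bulk zone was spent contiguously in the slab zone;
                # a direct bulk-to-bulk jump (periodic wrap) has no such frames
                between = np.arange(last_committed_frame + 1, first)
                if between.size and np.all(zcol[between] == 0):
                    mid = between[in_slab[between, col]]
                    through = bool(np.all(radial_ok[mid, col])) if mid.size else True
                    if mode == "slab" or through:
                        entry = int(between[0])
                        events.append(
                            CrossingEvent(
                                atom_index=int(atom_idx),
                                ion_species=str(top.ion_species[atom_idx]),
                                ion_valence=int(top.ion_valences[atom_idx]),
                                direction="up" if zn == 1 else "down",
                                entry_time=float(traj.times[entry]),
                                exit_time=float(traj.times[first]),
                                entry_frame=entry,
                                exit_frame=int(first),
                                path_through_pore=through,
                            )
                        )
            committed = zn
            last_committed_frame = f
    events.sort(key=lambda e: (e.exit_time, e.atom_index))
    return events


def conductance(
    transported_charge: float,
    voltage: float,
    duration_ns: float,
) -> float:
    """Conductance in pS from gross transported charge under voltage.

    ``transported_charge`` is the field-consistent charge in elementary
    charges, ``voltage`` in volts (sign ignored), ``duration_ns`` in ns.
    """
    if voltage == 0:
        raise ValueError("conductance undefined at 0 V")
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    if transported_charge < 0:
        raise ValueError("transported charge must be non-negative")
    coulombs = transported_charge * ELEMENTARY_CHARGE
    siemens = coulombs / (abs(voltage) * duration_ns * 1e-9)
    return siemens * 1e12


def cation_field_direction(voltage: float) -> str:
    """Direction along +normal in which the field pushes cations.

    Convention: positive voltage holds the upper (greater-normal) compartment
    at the higher potential, driving cations down; negative voltage drives
    cations up.
    """
    if voltage == 0:
        raise ValueError("no field at 0 V")
    return "down" if voltage > 0 else "up"


def event_is_field_consistent(event: CrossingEvent, voltage: float) -> bool:
    cat_dir = cation_field_direction(voltage)
    if event.ion_valence > 0:
        return event.direction == cat_dir
    if event.ion_valence < 0:
        return event.direction != cat_dir
    return False


@dataclass
class PermeationResult:
    """Species counts, transported charge and conductance for one run."""

    counts: dict[str, int]
    transported_charge: float      # gross field-consistent, elementary charges
    backward_events: int
    voltage: float                 # V, signed
    duration_ns: float
    conductance_pS: float
    cumulative: pd.DataFrame       # tidy: species, time_ns, count

    @property
    def conductance_pS_rounded(self) -> float:
        return round(self.conductance_pS, 1)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "transported_charge_e": self.transported_charge,
            "backward_events": self.backward_events,
            "voltage_V": self.voltage,
            "duration_ns": self.duration_ns,
            "conductance_pS": self.conductance_pS,
            "conductance_pS_rounded": self.conductance_pS_rounded,
        }


def summarize_permeation(
    events: Sequence[CrossingEvent],
    voltage: float,
    duration_ns: float,
    species: Sequence[str] | None = None,
) -> PermeationResult:
    """Aggregate events into counts, transported charge and conductance."""
    if species is None:
        species = sorted({e.ion_species for e in events})
    counts = {s: 0 for s in species}
    q = 0.0
    backward = 0
    for e in events:
        counts[e.ion_species] = counts.get(e.ion_species, 0) + 1
        if event_is_field_consistent(e, voltage):
            q += abs(e.ion_valence)
        else:
            backward += 1
    lam = conductance(q, voltage, duration_ns) if q > 0 else 0.0
    cum = cumulative_crossings(events, duration_ns, list(counts))
    return PermeationResult(
        counts=counts,
        transported_charge=q,
        backward_events=backward,
        voltage=voltage,
        duration_ns=duration_ns,
        conductance_pS=lam,
        cumulative=cum,
    )


def cumulative_crossings(
    events: Sequence[CrossingEvent],
    duration_ns: float,
    species: Sequence[str],
) -> pd.DataFrame:
    """Per-species cumulative crossing-count step series (tidy table).

    Rows are (species, time_ns, count): a zero anchor at t=0, one step per
    event at its exit time, and a final row at ``duration_ns`` holding the
    total, so the series plots as the familiar staircase.
    """
    rows = []
    for s in species:
        ev = sorted(
            (e for e in events if e.ion_species == s), key=lambda e: e.exit_time
        )
        rows.append((s, 0.0, 0))
        for n, e in enumerate(ev, start=1):
            rows.append((s, e.exit_time / 1000.0, n))
        rows.append((s, float(duration_ns), len(ev)))
    return pd.DataFrame(rows, columns=["species", "time_ns", "count"])


@dataclass
class ContactSeries:
    """Per-frame ion contact flags for one residue."""

    residue_label: str
    species: str
    times: np.ndarray
    contact: np.ndarray            # boolean, per frame

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.contact)) if self.contact.size else 0.0

    @property
    def dwell_segments(self) -> list[tuple[int, int]]:
        """Maximal runs of contact as (start_frame, end_frame) inclusive."""
        segs = []
        c = np.asarray(self.contact, dtype=bool)
        if not c.any():
            return segs
        edges = np.diff(c.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1))
        if c[0]:
            starts.insert(0, 0)
        if c[-1]:
            ends.append(len(c) - 1)
        return list(zip(starts, ends))


def _residue_atoms_for_label(topology, label: str) -> np.ndarray:
    """Atom indices of the charged group for a residue label like 'R419'."""
    one_letter = {"R": "ARG", "K": "LYS", "H": "HIS", "D": "ASP", "E": "GLU"}
    resname = one_letter.get(label[0].upper())
    if resname is None or not label[1:].isdigit():
        raise ValueError(f"unknown residue label {label!r} (expected e.g. 'R419')")
    resid = int(label[1:])
    idx = topology.select(residue_ids=[resid])
    idx = idx[topology.residue_names[idx] == resname]
    if idx.size == 0:
        raise ValueError(f"residue {label} not found in topology")
    group_names = CHARGED_GROUP_ATOMS.get(resname)
    if group_names:
        grp = idx[np.isin(topology.names[idx], group_names)]
        if grp.size:
            return grp
    return idx


def ion_residue_contacts(
    traj: Trajectory,
    residue_labels: Sequence[str],
    species: str,
    cutoff: float = 4.0,
) -> list[ContactSeries]:
    """Per-frame contact occupancy between an ion species and named residues.

    A frame counts as a contact when any ion of ``species`` is within
    ``cutoff`` (minimum-image) of any charged-group atom of the residue.
    The default 4 Å cutoff to Arg/Lys side-chain nitrogens is the usual
    salt-bridge criterion.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not residue_labels:
        raise ValueError("no residues given")
    top = traj.topology
    ions = top.select(role="ion", species=[species])
    if ions.size == 0:
        raise ValueError(f"no ions of species {species!r}")

    out = []
    box = np.stack([b.lengths for b in traj.boxes])           # (F, 3)
    ion_pos = traj.coordinates[:, ions]                       # (F, I, 3)
    for label in residue_labels:
        grp = _residue_atoms_for_label(top, label)
        grp_pos = traj.coordinates[:, grp]                    # (F, G, 3)
        d = ion_pos[:, :, None, :] - grp_pos[:, None, :, :]   # (F, I, G, 3)
        d = wrap_displacement(d, box[:, None, None, :])
        dist = np.sqrt((d ** 2).sum(axis=-1))
        contact = (dist <= cutoff).any(axis=(1, 2))
        out.append(
            ContactSeries(
                residue_label=label,
                species=species,
                times=traj.times.copy(),
                contact=contact,
            )
        )
    return out
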