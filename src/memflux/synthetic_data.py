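"""Ledgered synthetic membrane trajectories for detector validation.

The generator emulates the statistical structure of a solvated,
membrane-embedded channel system — a POPC-like bilayer slab with two
leaflets, a cylindrical aqueous pore, Na+/Cl- ions at roughly 300 mM, waters
filling the bulk and the pore — without any physics.  Events are programmed
first and coordinates are synthesized *from* them, so the ground-truth
ledger is exact by construction and never depends on the detectors it is
used to validate.

Ion behaviours:

* programmed crossing ions follow a smooth three-phase transit (approach the
  pore axis in bulk, cosine ramp through the slab inside the pore cylinder,
  settle in the destination bulk) and otherwise perform reflective random
  walks confined to their current bulk compartment;
* confined walkers never leave their compartment (reflective walls), so they
  can rattle against the buffered zone boundary but cannot cross;
* wrap walkers diffuse through the periodic box boundary between the upper
  and lower bulk — which are the same water compartment in a periodic slab
  system — exercising the detector's periodic-jump rejection;
* excursion ions dip deep into the slab through the pore and return to the
  side they came from.

Lipids are 3-bead caricatures (headgroup + two tail beads) with per-frame
headgroup jitter; a programmed flip carries one lipid's headgroup from its
leaflet plane to the opposite plane through the pore axis over a declared
transit window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import Atom, Box, Topology, Trajectory

#: detector bulk-zone buffer the ledger bookkeeping assumes (Å)
DEFAULT_BUFFER = 5.0


@dataclass(frozen=True)
class ProgrammedCrossing:
    species: str                  # "NA" or "CL"
    direction: str                # "up" or "down"
    start_time_ps: float
    transit_ps: float


@dataclass(frozen=True)
class ProgrammedFlip:
    time_ps: float                # midpoint of the transit window
    transit_ps: float
    from_leaflet: str = "lower"   # origin leaflet


@dataclass(frozen=True)
class Beacon:
    """A static charged residue used as a contact-analysis target."""

    label: str                    # e.g. "R419"
    position: tuple[float, float, float]


@dataclass(frozen=True)
class ProgrammedContact:
    beacon_label: str
    species: str
    occupancy: float              # fraction of frames spent in contact


@dataclass
class ScenarioSpec:
    """Declarative description of one synthetic scenario."""

    box: tuple[float, float, float] = (50.0, 50.0, 100.0)
    leaflet_z: float = 19.0                 # leaflet planes at +/- leaflet_z
    lipids_per_leaflet: int = 36
    headgroup_sigma: float = 1.0            # per-frame headgroup jitter, Å
    pore_center: tuple[float, float] = (0.0, 0.0)
    pore_radius: float = 8.0
    na_count: int = 45                      # ~300 mM in the default box
    cl_count: int = 45
    water_count: int = 300
    stride_ps: float = 20.0
    duration_ns: float = 20.0
    seed: int = 0
    crossings: list[ProgrammedCrossing] = field(default_factory=list)
    flips: list[ProgrammedFlip] = field(default_factory=list)
    dewetted_band: tuple[float, float] | None = None
    beacons: list[Beacon] = field(default_factory=list)
    contacts: list[ProgrammedContact] = field(default_factory=list)
    excursion_count: int = 0
    wrap_fraction: float = 0.3              # share of free ions that wrap-walk
    walk_sigma: float = 1.0                 # random-walk step per frame, Å
    bulk_margin: float = 8.0                # commit depth beyond the planes, Å
    voltage: float = -0.5                   # V, annotation used downstream
    name: str = "custom"

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ns * 1000.0 / self.stride_ps)) + 1

    def validate(self) -> None:
        lx, ly, lz = self.box
        if self.leaflet_z + self.bulk_margin + 2 >= lz / 2:
            raise ValueError("box too short along the normal for the bulk compartments")
        if self.pore_radius <= 0:
            raise ValueError("pore radius must be positive")
        dur_ps = self.duration_ns * 1000.0
        for c in self.crossings:
            if not (0 <= c.start_time_ps and c.start_time_ps + c.transit_ps <= dur_ps):
                raise ValueError("programmed crossing outside trajectory duration")
            if c.direction not in ("up", "down"):
                raise ValueError("crossing direction must be 'up' or 'down'")
        for fl in self.flips:
            if not (0 < fl.time_ps - fl.transit_ps / 2) or (
                fl.time_ps + fl.transit_ps / 2 >= dur_ps
            ):
                raise ValueError("programmed flip outside trajectory duration")
        if self.dewetted_band is not None:
            lo, hi = self.dewetted_band
            if lo >= hi or lo < -self.leaflet_z or hi > self.leaflet_z:
                raise ValueError("dewetted band must lie within the membrane slab")
        n_cross = {"NA": 0, "CL": 0}
        for c in self.crossings:
            n_cross[c.species] = n_cross.get(c.species, 0) + 1
        n_contact = {"NA": 0, "CL": 0}
        for pc in self.contacts:
            n_contact[pc.species] = n_contact.get(pc.species, 0) + 1
        if n_cross.get("NA", 0) + n_contact.get("NA", 0) + self.excursion_count > self.na_count:
            raise ValueError("not enough Na+ ions for the programmed behaviours")
        if n_cross.get("CL", 0) + n_contact.get("CL", 0) > self.cl_count:
            raise ValueError("not enough Cl- ions for the programmed behaviours")


@dataclass
class LedgerCrossing:
    atom_index: int
    species: str
    valence: int
    direction: str
    entry_frame: int
    exit_frame: int
    window_frames: tuple[int, int]   # programmed transit window (inclusive)


@dataclass
class LedgerFlip:
    lipid_residue_id: int
    start_leaflet: str
    end_leaflet: str
    window_ps: tuple[float, float]


@dataclass
class LedgerContact:
    beacon_label: str
    species: str
    atom_index: int
    contact_frames: int
    occupancy: float


@dataclass
class GroundTruthLedger:
    """Exact record of everything the generator programmed."""

    crossings: list[LedgerCrossing]
    flips: list[LedgerFlip]
    contacts: list[LedgerContact]
    upper_plane: np.ndarray          # realized per-frame mean headgroup planes
    lower_plane: np.ndarray
    dewetted_band: tuple[float, float] | None
    spec: ScenarioSpec

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.crossings:
            out[c.species] = out.get(c.species, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "crossings": [asdict(c) for c in self.crossings],
            "flips": [asdict(f) for f in self.flips],
            "contacts": [asdict(c) for c in self.contacts],
            "upper_plane": self.upper_plane.tolist(),
            "lower_plane": self.lower_plane.tolist(),
            "dewetted_band": self.dewetted_band,
            "spec": asdict(self.spec),
        }


def _smooth_ramp(p: np.ndarray) -> np.ndarray:
    """Monotone cosine ramp from 0 to 1 on p in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(p, 0.0, 1.0)))


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold an unbounded walk into [lo, hi] by reflection (triangle wave)."""
    width = hi - lo
    y = np.mod(values - lo, 2.0 * width)
    return lo + np.where(y <= width, y, 2.0 * width - y)


def _reflective_walk(
    rng: np.random.Generator,
    start: float,
    lo: float,
    hi: float,
    n: int,
    sigma: float,
) -> np.ndarray:
    steps = rng.normal(0.0, sigma, size=n)
    raw = start + np.concatenate([[0.0], np.cumsum(steps[1:])])
    return _reflect(raw, lo, hi)


class _TrajectoryBuilder:
    def __init__(self, spec: ScenarioSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.n_frames = spec.n_frames
        self.times = np.arange(self.n_frames) * spec.stride_ps
        self.atoms: list[Atom] = []
        self.paths: list[np.ndarray] = []   # (n_frames, 3) per atom
        self.water_block: np.ndarray | None = None  # (n_frames, n_waters, 3)
        self.next_resid = 1

    def add_atom(self, path: np.ndarray, **kw) -> int:
        idx = len(self.atoms)
        self.atoms.append(Atom(index=idx, **kw))
        self.paths.append(path)
        return idx

    def stacked_coordinates(self) -> np.ndarray:
        coords = np.stack(self.paths, axis=1) if self.paths else np.empty((self.n_frames, 0, 3))
        if self.water_block is not None:
            coords = np.concatenate([coords, self.water_block], axis=1)
        return coords

    def _walk_xy(self, start_xy: np.ndarray) -> np.ndarray:
        lx, ly, _ = self.spec.box
        steps = self.rng.normal(0.0, self.spec.walk_sigma, size=(self.n_frames, 2))
        steps[0] = 0.0
        raw = start_xy + np.cumsum(steps, axis=0)
        raw[:, 0] = np.mod(raw[:, 0] + lx / 2, lx) - lx / 2
        raw[:, 1] = np.mod(raw[:, 1] + ly / 2, ly) - ly / 2
        return raw


def generate(spec: ScenarioSpec) -> tuple[Topology, Trajectory, GroundTruthLedger]:
    """Generate a ledgered synthetic topology + trajectory.

    Deterministic for a given spec (including its seed).
    """
    spec.validate()
    b = _TrajectoryBuilder(spec)
    rng = b.rng
    lx, ly, lz = spec.box
    n_frames = b.n_frames
    times = b.times
    commit_z = spec.leaflet_z + spec.bulk_margin

    upper_hgz, lower_hgz = _build_lipids(b)
    _build_beacons(b)
    ledger_crossings, ledger_contacts = _build_ions(b)
    _build_waters(b)

    topology = Topology(b.atoms)
    coords = b.stacked_coordinates()    # (n_frames, n_atoms, 3)
    box = Box(lx, ly, lz)
    traj = Trajectory(topology, coords, times, box)

    ledger = GroundTruthLedger(
        crossings=ledger_crossings,
        flips=b.ledger_flips,
        contacts=ledger_contacts,
        upper_plane=upper_hgz.mean(axis=1),
        lower_plane=lower_hgz.mean(axis=1),
        dewetted_band=spec.dewetted_band,
        spec=spec,
    )
    return topology, traj, ledger


def _lipid_grid_positions(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """In-plane lipid positions on a jittered grid, keeping the pore clear."""
    lx, ly, _ = spec.box
    n_side = int(np.ceil(np.sqrt(spec.lipids_per_leaflet * 2.0)))
    xs = (np.arange(n_side) + 0.5) / n_side * lx - lx / 2
    ys = (np.arange(n_side) + 0.5) / n_side * ly - ly / 2
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    cx, cy = spec.pore_center
    keep = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) > spec.pore_radius + 2.0
    pts = pts[keep]
    if len(pts) < spec.lipids_per_leaflet:
        raise ValueError("box too small to place the requested lipids outside the pore")
    order = rng.permutation(len(pts))[: spec.lipids_per_leaflet]
    return pts[order] + rng.normal(0.0, 0.5, size=(spec.lipids_per_leaflet, 2))


def _build_lipids(b: _TrajectoryBuilder) -> tuple[np.ndarray, np.ndarray]:
    spec, rng, n_frames = b.spec, b.rng, b.n_frames
    b.ledger_flips = []
    flip_assignments: dict[int, ProgrammedFlip] = {}

    hgz_per_leaflet = {}
    for sign, leaflet in ((1, "upper"), (-1, "lower")):
        xy = _lipid_grid_positions(spec, rng)
        plane = sign * spec.leaflet_z
        hgz = plane + rng.normal(0.0, spec.headgroup_sigma, size=(n_frames, spec.lipids_per_leaflet))
        # assign programmed flips originating from this leaflet
        flips_here = [f for f in spec.flips if f.from_leaflet == leaflet]
        flip_cols = rng.choice(spec.lipids_per_leaflet, size=len(flips_here), replace=False)
        for col, fl in zip(flip_cols, flips_here):
            t0 = fl.time_ps - fl.transit_ps / 2
            t1 = fl.time_ps + fl.transit_ps / 2
            p = (b.times - t0) / (t1 - t0)
            ramp = _smooth_ramp(p)
            z = plane - 2 * plane * ramp  # plane -> -plane
            jitter = rng.normal(0.0, 0.3, size=n_frames)
            in_window = (b.times >= t0) & (b.times <= t1)
            hgz[:, col] = np.where(
                in_window, z + jitter, np.where(b.times < t0, hgz[:, col], -plane + rng.normal(0.0, spec.headgroup_sigma, size=n_frames))
            )
            flip_assignments[(sign, int(col))] = fl

        for col in range(spec.lipids_per_leaflet):
            resid = b.next_resid
            b.next_resid += 1
            head_z = hgz[:, col]
            if (sign, col) in flip_assignments:
                fl = flip_assignments[(sign, col)]
                t0 = fl.time_ps - fl.transit_ps / 2
                t1 = fl.time_ps + fl.transit_ps / 2
                ramp = _smooth_ramp((b.times - t0) / (t1 - t0))
                cx, cy = spec.pore_center
                # slide to the pore axis over the first part of the window
                approach = _smooth_ramp((b.times - t0) / (0.25 * (t1 - t0)))
                x = xy[col, 0] + (cx - xy[col, 0]) * approach
                y = xy[col, 1] + (cy - xy[col, 1]) * approach
                xy_path = np.stack([x, y], axis=1)
                b.ledger_flips.append(
                    LedgerFlip(
                        lipid_residue_id=resid,
                        start_leaflet="upper" if sign == 1 else "lower",
                        end_leaflet="lower" if sign == 1 else "upper",
                        window_ps=(t0, t1),
                    )
                )
            else:
                xy_path = np.tile(xy[col], (n_frames, 1)) + rng.normal(
                    0.0, 0.3, size=(n_frames, 2)
                )
            head = np.column_stack([xy_path, head_z])
            # two tail beads scaled toward the midplane; placeholders only
            tail1 = np.column_stack([xy_path, head_z * 0.7])
            tail2 = np.column_stack([xy_path, head_z * 0.4])
            for name, path, is_head in (("P", head, True), ("C2", tail1, False), ("C3", tail2, False)):
                b.add_atom(
                    path,
                    name=name,
                    element="P" if is_head else "C",
                    residue_name="POPC",
                    residue_id=resid,
                    role="lipid",
                    is_headgroup=is_head,
                )
        hgz_per_leaflet[sign] = hgz
    return hgz_per_leaflet[1], hgz_per_leaflet[-1]


def _build_beacons(b: _TrajectoryBuilder) -> None:
    one_letter = {"R": ("ARG", "NH1"), "K": ("LYS", "NZ")}
    for beacon in b.spec.beacons:
        resname, atom_name = one_letter[beacon.label[0].upper()]
        resid = int(beacon.label[1:])
        if resid < b.next_resid:
            raise ValueError(
                f"beacon residue id {resid} collides with generated residues"
            )
        path = np.tile(np.asarray(beacon.position, dtype=float), (b.n_frames, 1))
        b.add_atom(
            path,
            name=atom_name,
            element="N",
            residue_name=resname,
            residue_id=resid,
            role="protein",
        )


def _crossing_path(b: _TrajectoryBuilder, c: ProgrammedCrossing) -> tuple[np.ndarray, int, int]:
    """Coordinates for one programmed crossing ion plus ledger entry/exit frames."""
    spec, rng = b.spec, b.rng
    lz = spec.box[2]
    commit_z = spec.leaflet_z + spec.bulk_margin
    sgn = 1.0 if c.direction == "up" else -1.0  # destination side sign
    n = b.n_frames
    t = b.times

    f0 = int(np.searchsorted(t, c.start_time_ps))
    f1 = int(np.searchsorted(t, c.start_time_ps + c.transit_ps, side="right")) - 1
    f1 = max(f1, f0 + 4)

    z = np.empty(n)
    origin_lo, origin_hi = (-(lz / 2 - 1.0), -commit_z) if sgn > 0 else (commit_z, lz / 2 - 1.0)
    dest_lo, dest_hi = (commit_z, lz / 2 - 1.0) if sgn > 0 else (-(lz / 2 - 1.0), -commit_z)
    start = rng.uniform(origin_lo + 1, origin_hi - 1)
    z[: f0 + 1] = _reflective_walk(rng, start, origin_lo, origin_hi, f0 + 1, spec.walk_sigma)

    # transit: hold/approach (20%), cosine through the slab (60%), settle (20%)
    span = np.arange(f0 + 1, f1 + 1)
    p = (span - f0) / (f1 - f0)
    z_pre = z[f0]
    z_edge0 = -sgn * (commit_z + 0.5)
    z_edge1 = sgn * (commit_z + 0.5)
    z_t = np.where(
        p < 0.2,
        z_pre + (z_edge0 - z_pre) * _smooth_ramp(p / 0.2),
        np.where(
            p < 0.8,
            z_edge0 + (z_edge1 - z_edge0) * _smooth_ramp((p - 0.2) / 0.6),
            z_edge1 + sgn * 1.5 * _smooth_ramp((p - 0.8) / 0.2),
        ),
    )
    z[f0 + 1 : f1 + 1] = z_t
    if f1 < n - 1:
        z[f1 + 1 :] = _reflective_walk(
            rng, z[f1], dest_lo, dest_hi, n - f1 - 1, spec.walk_sigma
        )

    # xy: free walk outside the transit, pinned to the pore axis inside it
    xy = b._walk_xy(np.array([rng.uniform(-spec.box[0] / 2, spec.box[0] / 2),
                              rng.uniform(-spec.box[1] / 2, spec.box[1] / 2)]))
    cx, cy = spec.pore_center
    in_transit = np.zeros(n, dtype=bool)
    in_transit[f0:f1 + 1] = True
    blend = np.zeros(n)
    blend[f0:f1 + 1] = np.minimum(1.0, ((np.arange(f0, f1 + 1) - f0) / max(1, int(0.15 * (f1 - f0)))))
    jit = rng.normal(0.0, min(1.0, spec.pore_radius / 6.0), size=(n, 2))
    xy_target = np.column_stack([cx + jit[:, 0], cy + jit[:, 1]])
    xy = xy * (1 - blend)[:, None] + xy_target * blend[:, None]
    xy[f1 + 1 :] = xy_target[f1 + 1 :]

    path = np.column_stack([xy, z])

    # ledger bookkeeping against the programmed planes and default buffer
    thresh = spec.leaflet_z + DEFAULT_BUFFER
    inside = np.abs(z) <= thresh
    entry = int(np.flatnonzero(inside)[0])
    beyond = np.flatnonzero((sgn * z > thresh) & (np.arange(n) > entry))
    exit_ = int(beyond[0])
    return path, entry, exit_


def _excursion_path(b: _TrajectoryBuilder) -> np.ndarray:
    """Committed-upper ion that dips through the pore past the midplane and returns."""
    spec, rng = b.spec, b.rng
    lz = spec.box[2]
    commit_z = spec.leaflet_z + spec.bulk_margin
    n = b.n_frames
    t0 = rng.integers(n // 8, n // 2)
    dur = max(8, n // 10)
    f1 = min(n - 2, t0 + dur)
    z = _reflective_walk(rng, commit_z + 2.0, commit_z, lz / 2 - 1.0, n, spec.walk_sigma)
    span = np.arange(t0, f1 + 1)
    p = (span - t0) / (f1 - t0)
    z_min = -(spec.leaflet_z + 1.0)
    dip = z[t0] + (z_min - z[t0]) * np.sin(np.pi * p)
    z[t0:f1 + 1] = dip
    if f1 + 1 < n:
        z[f1 + 1 :] = _reflect(z[f1] + np.cumsum(rng.normal(0, spec.walk_sigma, n - f1 - 1)),
                               commit_z, lz / 2 - 1.0)
    cx, cy = spec.pore_center
    xy = np.tile([cx, cy], (n, 1)) + rng.normal(0.0, min(1.0, spec.pore_radius / 6.0), (n, 2))
    return np.column_stack([xy, z])


def _wrap_walker_path(b: _TrajectoryBuilder) -> np.ndarray:
    """Bulk ion diffusing through the periodic boundary (never in the slab)."""
    spec, rng = b.spec, b.rng
    lz = spec.box[2]
    wall = spec.leaflet_z + 2.0
    # ring coordinate zeta in [wall, lz - wall]; z = zeta (<= lz/2) or zeta - lz
    zeta = _reflective_walk(rng, lz / 2.0, wall, lz - wall, b.n_frames, spec.walk_sigma * 2.0)
    z = np.where(zeta <= lz / 2.0, zeta, zeta - lz)
    xy = b._walk_xy(np.array([0.0, 0.0]))
    return np.column_stack([xy, z])


def _confined_path(b: _TrajectoryBuilder, side: int) -> np.ndarray:
    spec, rng = b.spec, b.rng
    lz = spec.box[2]
    lo, hi = (spec.leaflet_z + 2.0, lz / 2 - 0.5) if side > 0 else (-(lz / 2 - 0.5), -(spec.leaflet_z + 2.0))
    start = rng.uniform(lo + 1, hi - 1)
    z = _reflective_walk(rng, start, lo, hi, b.n_frames, spec.walk_sigma)
    xy = b._walk_xy(rng.uniform([-spec.box[0] / 2, -spec.box[1] / 2],
                                [spec.box[0] / 2, spec.box[1] / 2]))
    return np.column_stack([xy, z])


def _contact_path(b: _TrajectoryBuilder, pc: ProgrammedContact) -> tuple[np.ndarray, int]:
    beacon = next((x for x in b.spec.beacons if x.label == pc.beacon_label), None)
    if beacon is None:
        raise ValueError(f"contact references unknown beacon {pc.beacon_label!r}")
    pos = np.asarray(beacon.position, dtype=float)
    n = b.n_frames
    n_contact = int(round(pc.occupancy * n))
    near = pos + np.array([3.0, 0.0, 0.0])
    far = pos + np.array([15.0, 0.0, 0.0])
    path = np.where(np.arange(n)[:, None] < n_contact, near, far)
    return path, n_contact


def _build_ions(b: _TrajectoryBuilder) -> tuple[list[LedgerCrossing], list[LedgerContact]]:
    spec = b.spec
    ledger_cross: list[LedgerCrossing] = []
    ledger_contacts: list[LedgerContact] = []
    species_info = {"NA": ("NA", +1), "CL": ("CLA", -1)}
    budgets = {"NA": spec.na_count, "CL": spec.cl_count}
    paths_by_species: dict[str, list[tuple[np.ndarray, dict]]] = {"NA": [], "CL": []}

    for c in spec.crossings:
        path, entry, exit_ = _crossing_path(b, c)
        f0 = int(np.searchsorted(b.times, c.start_time_ps))
        f1 = int(np.searchsorted(b.times, c.start_time_ps + c.transit_ps, side="right")) - 1
        paths_by_species[c.species].append(
            (path, {"crossing": (c, entry, exit_, (f0, max(f1, f0 + 4)))})
        )
    for pc in spec.contacts:
        path, n_contact = _contact_path(b, pc)
        paths_by_species[pc.species].append((path, {"contact": (pc, n_contact)}))
    for _ in range(spec.excursion_count):
        paths_by_species["NA"].append((_excursion_path(b), {}))

    for sp in ("NA", "CL"):
        remaining = budgets[sp] - len(paths_by_species[sp])
        n_wrap = int(round(remaining * spec.wrap_fraction))
        for i in range(remaining):
            if i < n_wrap:
                paths_by_species[sp].append((_wrap_walker_path(b), {}))
            else:
                side = 1 if (i % 2 == 0) else -1
                paths_by_species[sp].append((_confined_path(b, side), {}))

    for sp in ("NA", "CL"):
        resname, valence = species_info[sp]
        for path, meta in paths_by_species[sp]:
            resid = b.next_resid
            b.next_resid += 1
            idx = b.add_atom(
                path,
                name=sp,
                element=sp[0],
                residue_name=resname,
                residue_id=resid,
                role="ion",
                ion_species=sp,
                ion_valence=valence,
            )
            if "crossing" in meta:
                c, entry, exit_, window = meta["crossing"]
                ledger_cross.append(
                    LedgerCrossing(
                        atom_index=idx,
                        species=sp,
                        valence=valence,
                        direction=c.direction,
                        entry_frame=entry,
                        exit_frame=exit_,
                        window_frames=window,
                    )
                )
            if "contact" in meta:
                pc, n_contact = meta["contact"]
                ledger_contacts.append(
                    LedgerContact(
                        beacon_label=pc.beacon_label,
                        species=sp,
                        atom_index=idx,
                        contact_frames=n_contact,
                        occupancy=n_contact / b.n_frames,
                    )
                )
    return ledger_cross, ledger_contacts


def _build_waters(b: _TrajectoryBuilder) -> None:
    """Uniform waters in the bulk and pore regions, resampled each frame."""
    spec, rng = b.spec, b.rng
    if spec.water_count == 0:
        return
    lx, ly, lz = spec.box
    wall = spec.leaflet_z + 2.0
    cx, cy = spec.pore_center
    r = spec.pore_radius

    bulk_h = lz / 2.0 - wall
    v_bulk = lx * ly * bulk_h                     # one bulk slab
    band = spec.dewetted_band
    pore_h = 2.0 * wall - (0.0 if band is None else (band[1] - band[0]))
    v_pore = np.pi * r * r * pore_h
    vols = np.array([v_bulk, v_bulk, v_pore])
    probs = vols / vols.sum()

    n = b.n_frames
    w = spec.water_count
    region = rng.choice(3, size=(n, w), p=probs)
    u = rng.uniform(size=(n, w, 3))

    coords = np.empty((n, w, 3))
    coords[:, :, 0] = u[:, :, 0] * lx - lx / 2
    coords[:, :, 1] = u[:, :, 1] * ly - ly / 2
    m0, m1, m2 = region == 0, region == 1, region == 2
    z = coords[:, :, 2]
    z[m0] = wall + u[:, :, 2][m0] * bulk_h
    z[m1] = -wall - u[:, :, 2][m1] * bulk_h

    # pore waters: uniform in the cylinder, skipping the dewetted band
    n2 = int(m2.sum())
    theta = rng.uniform(0, 2 * np.pi, size=n2)
    rad = r * np.sqrt(rng.uniform(size=n2))
    frac = u[:, :, 2][m2] * pore_h
    if band is None:
        zp = -wall + frac
    else:
        lo_h = band[0] + wall                      # height below the band
        zp = np.where(frac < lo_h, -wall + frac, band[1] + (frac - lo_h))
    coords[:, :, 0][m2] = cx + rad * np.cos(theta)
    coords[:, :, 1][m2] = cy + rad * np.sin(theta)
    z[m2] = zp

    first_resid = b.next_resid
    for j in range(w):
        b.atoms.append(
            Atom(
                index=len(b.atoms),
                name="OH2",
                element="O",
                residue_name="TIP3",
                residue_id=first_resid + j,
                role="water",
            )
        )
    b.next_resid = first_resid + w
    b.water_block = coords


# ---------------------------------------------------------------------------
# preset catalogue

def _conducting_spec(seed: int, n_na: int, n_cl: int, name: str) -> ScenarioSpec:
    rng = np.random.default_rng(seed + 104729)
    duration_ns = 20.0
    crossings = []
    # at -0.5 V the field drives cations up and anions down (field-consistent)
    starts = np.sort(rng.uniform(500.0, duration_ns * 1000.0 - 3500.0, size=n_na + n_cl))
    for i, t0 in enumerate(starts):
        sp = "NA" if i < n_na else "CL"
        d = "up" if sp == "NA" else "down"
        crossings.append(ProgrammedCrossing(sp, d, float(t0), 2000.0))
    return ScenarioSpec(
        crossings=crossings,
        water_count=2000,
        duration_ns=duration_ns,
        stride_ps=20.0,
        voltage=-0.5,
        seed=seed,
        name=name,
    )


def preset_scenarios(seed: int = 0) -> dict[str, ScenarioSpec]:
    """Named scenario catalogue.

    * ``open-conducting`` — an open, conducting pore: 14 Na+ and 2 Cl-
      programmed crossings under -0.5 V, water throughout the pore.
    * ``open-conducting-17x3`` — the larger conducting run: 17 Na+ and 3 Cl-
      crossings under -0.5 V.
    * ``closed-hydrated-discontinuous`` — a hydrated but closed pore: water
      enters from both sides but a programmed dry band at |z| < 4 Å
      interrupts the column mid-membrane; no crossings.
    * ``scrambling`` — one lipid flips from the lower to the upper leaflet
      through the pore, transiting around t = 60 ns.
    """
    return {
        "open-conducting": _conducting_spec(seed, 14, 2, "open-conducting"),
        "open-conducting-17x3": _conducting_spec(seed + 1, 17, 3, "open-conducting-17x3"),
        "closed-hydrated-discontinuous": ScenarioSpec(
            water_count=2500,
            duration_ns=5.0,
            stride_ps=25.0,
            dewetted_band=(-4.0, 4.0),
            seed=seed + 2,
            name="closed-hydrated-discontinuous",
        ),
        "scrambling": ScenarioSpec(
            water_count=100,
            na_count=10,
            cl_count=10,
            duration_ns=100.0,
            stride_ps=100.0,
            flips=[ProgrammedFlip(time_ps=60_000.0, transit_ps=20_000.0, from_leaflet="lower")],
            seed=seed + 3,
            name="scrambling",
        ),
    }


def random_scenario(seed: int, duration_ns: float = 4.0, stride_ps: float = 20.0) -> ScenarioSpec:
    """A small randomized scenario for detector-validation sweeps.

    Randomizes crossing counts and directions, excursion ions and the share
    of wrap-walking bulk ions, all deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed + 7919)
    n_na = int(rng.integers(0, 5))
    n_cl = int(rng.integers(0, 4))
    dur_ps = duration_ns * 1000.0
    crossings = []
    for i in range(n_na + n_cl):
        sp = "NA" if i < n_na else "CL"
        d = "up" if rng.random() < 0.5 else "down"
        transit = float(rng.uniform(0.2, 0.35)) * dur_ps
        t0 = float(rng.uniform(0.0, dur_ps - transit - stride_ps))
        crossings.append(ProgrammedCrossing(sp, d, t0, transit))
    return ScenarioSpec(
        lipids_per_leaflet=16,
        na_count=10,
        cl_count=10,
        water_count=0,
        crossings=crossings,
        excursion_count=int(rng.integers(0, 3)),
        wrap_fraction=float(rng.uniform(0.2, 0.6)),
        duration_ns=duration_ns,
        stride_ps=stride_ps,
        seed=int(rng.integers(0, 2**31 - 1)),
        name=f"random-{seed}",
    )


def get_preset(name: str, seed: int = 0) -> ScenarioSpec:
    catalog = preset_scenarios(seed)
    if name not in catalog:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(catalog)}")
    return catalog[name]


def write_scenario(
    spec: ScenarioSpec,
    out_dir: str | Path,
    trajectory_format: str = "DCD",
) -> dict[str, Path]:
    """Generate a scenario and write topology, trajectory and ledger to disk."""
    from . import trajectory_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topology, traj, ledger = generate(spec)
    paths = {
        "topology": trajectory_io.write_topology(
            topology, traj.coordinates[0], traj.boxes[0], out / "system.gro"
        ),
        "trajectory": trajectory_io.write_trajectory(
            traj, out / f"trajectory.{trajectory_format.lower()}", trajectory_format
        ),
    }
    ledger_path = out / "ledger.json"
    ledger_path.write_text(json.dumps(ledger.to_dict(), indent=1))
    paths["ledger"] = ledger_path
    return paths
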