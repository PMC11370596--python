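"""Reading and writing topologies, trajectories, grids and event tables.

Standard formats (PDB/GRO/DCD/XTC/OpenDX) are handled through MDAnalysis and
GridDataFormats; a plain-text XYZ-with-box dialect is provided for
human-readable fixtures:

    <n_atoms>
    t=<time ps> box=<Lx> <Ly> <Lz>
    <atom name> <x> <y> <z>
    ... (repeated per frame)
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from gridData import Grid

from .model import Atom, Box, RoleMap, Topology, Trajectory

logger = logging.getLogger("memflux")

TOPOLOGY_FORMATS = ("PDB", "GRO")
TRAJECTORY_FORMATS = ("DCD", "XTC", "XYZ")


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_topology(path: str | Path, format: str | None = None, role_map: RoleMap | None = None) -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Roles are assigned purely from ``role_map`` (residue-name dictionary);
    unknown residue names get role ``other`` with a logged warning.  Partial
    charges default to 0 because neither format carries them; use
    :func:`apply_charge_overlay` to add charges from a PSF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in TOPOLOGY_FORMATS:
        raise ValueError(f"unsupported topology format {fmt!r} (use PDB or GRO)")
    role_map = role_map or RoleMap()

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt, to_guess=())
        except Exception as exc:  # noqa: BLE001 - surface parser diagnostics
            raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc

    atoms = []
    unknown: set[str] = set()
    for i, a in enumerate(u.atoms):
        resname = str(a.resname).strip()
        name = str(a.name).strip()
        role, species, valence, is_head = role_map.classify(resname, name)
        if role == "other":
            unknown.add(resname)
        try:
            chain = str(a.segid)
        except Exception:  # noqa: BLE001
            chain = ""
        atoms.append(
            Atom(
                index=i,
                name=name,
                element=_element_from_name(name),
                residue_name=resname,
                residue_id=int(a.resid),
                chain=chain,
                partial_charge=0.0,
                mass=0.0,
                role=role,
                ion_species=species,
                ion_valence=valence,
                is_headgroup=is_head,
            )
        )
    for rn in sorted(unknown):
        logger.warning("unknown residue name %r: assigned role 'other'", rn)
    return Topology(atoms)


def apply_charge_overlay(topology: Topology, psf_path: str | Path) -> Topology:
    """Overlay partial charges and masses from a PSF file onto ``topology``.

    Only the charge/mass columns of the PSF are consumed; connectivity is
    ignored.  Atom count and order must match.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(psf_path), to_guess=())
    if len(u.atoms) != topology.n_atoms:
        raise ValueError(
            f"PSF atom count {len(u.atoms)} does not match topology "
            f"({topology.n_atoms})"
        )
    return topology.with_charges(u.atoms.charges, u.atoms.masses)


def _read_xyz_text(path: Path) -> tuple[list[np.ndarray], list[float], list[Box], list[str]]:
    frames: list[np.ndarray] = []
    times: list[float] = []
    boxes: list[Box] = []
    names: list[str] = []
    lines = path.read_text().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {pos + 1}") from exc
        header = lines[pos + 1].split()
        kv = dict(item.split("=", 1) for item in header if "=" in item)
        t = float(kv.get("t", len(frames)))
        box_vals = [float(x) for x in (kv["box"].split(",") if "box" in kv else [])]
        if len(box_vals) != 3:
            raise ValueError(f"{path}: frame header at line {pos + 2} lacks box=Lx,Ly,Lz")
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            warnings.warn(f"{path}: truncated final frame dropped", stacklevel=2)
            break
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(body):
            parts = ln.split()
            frame_names.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        if not names:
            names = frame_names
        frames.append(coords)
        times.append(t)
        boxes.append(Box(*box_vals))
        pos += 2 + n
    return frames, times, boxes, names


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
    stride_ps: float | None = None,
) -> Trajectory:
    """Read a DCD/XTC/XYZ-text trajectory against a known topology.

    Times come from the file where present; otherwise frames are spaced by
    ``stride_ps`` (default 1 ps) starting at 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in TRAJECTORY_FORMATS:
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    if fmt == "XYZ":
        frames, times, boxes, _ = _read_xyz_text(path)
        if not frames:
            raise ValueError(f"{path}: no frames")
        coords = np.stack(frames)
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"trajectory atom count {coords.shape[1]} does not match topology "
                f"({topology.n_atoms})"
            )
        return Trajectory(topology, coords, np.asarray(times), boxes)

    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    reader_cls = DCDReader if fmt == "DCD" else XTCReader
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(path))
        if reader.n_atoms != topology.n_atoms:
            raise ValueError(
                f"trajectory atom count {reader.n_atoms} does not match topology "
                f"({topology.n_atoms})"
            )
        coords, times, boxes = [], [], []
        for ts in reader:
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time))
            dims = ts.dimensions
            if dims is None or dims[0] <= 0:
                raise ValueError(f"{path}: frame without box dimensions")
            if not np.allclose(dims[3:6], 90.0, atol=1e-3):
                raise ValueError("only orthorhombic boxes are supported")
            boxes.append(Box(float(dims[0]), float(dims[1]), float(dims[2])))
        reader.close()
    if not coords:
        raise ValueError(f"{path}: no frames")
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and np.any(np.diff(times_arr) <= 0):
        dt = stride_ps if stride_ps else 1.0
        times_arr = np.arange(len(coords)) * dt
    return Trajectory(topology, np.stack(coords), times_arr, boxes)


def _mda_universe_from(topology: Topology, trajectory: Trajectory | None = None):
    import MDAnalysis as mda

    n_res = len(np.unique(topology.residue_ids))
    resid_order, res_index = np.unique(topology.residue_ids, return_inverse=True)
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=n_res,
        atom_resindex=res_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.names])
    resnames = []
    for rid in resid_order:
        i = int(np.flatnonzero(topology.residue_ids == rid)[0])
        resnames.append(str(topology.residue_names[i]))
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resid_order.astype(int))
    return u


def write_topology(topology: Topology, coordinates: np.ndarray, box: Box, path: str | Path) -> Path:
    """Write a single-frame GRO file for ``topology`` at the given coordinates."""
    path = Path(path)
    u = _mda_universe_from(topology)
    u.atoms.positions = np.asarray(coordinates, dtype=np.float32)
    u.dimensions = [box.lx, box.ly, box.lz, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def write_trajectory(trajectory: Trajectory, path: str | Path, format: str | None = None) -> Path:
    """Write a trajectory as DCD, XTC or XYZ-text."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in TRAJECTORY_FORMATS:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if fmt == "XYZ":
        lines = []
        names = trajectory.topology.names
        for i in range(trajectory.n_frames):
            b = trajectory.boxes[i]
            lines.append(str(trajectory.n_atoms))
            lines.append(f"t={trajectory.times[i]:.6f} box={b.lx:.6f},{b.ly:.6f},{b.lz:.6f}")
            for name, (x, y, z) in zip(names, trajectory.coordinates[i]):
                lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
        path.write_text("\n".join(lines) + "\n")
        return path

    import MDAnalysis as mda

    u = _mda_universe_from(trajectory.topology)
    dt = trajectory.stride_ps or 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), trajectory.n_atoms, format=fmt, dt=dt, istart=0) as w:
            for i in range(trajectory.n_frames):
                b = trajectory.boxes[i]
                u.atoms.positions = trajectory.coordinates[i].astype(np.float32)
                u.dimensions = [b.lx, b.ly, b.lz, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = float(trajectory.times[i])
                u.trajectory.ts.frame = i
                w.write(u.atoms)
    return path


def write_grid(grid, path: str | Path, format: str = "DX") -> Path:
    """Persist a :class:`~memflux.fields.DensityGrid` as OpenDX or CSV."""
    path = Path(path)
    values = np.asarray(grid.values, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise ValueError(f"grid contains non-finite voxels at indices {bad[:10].tolist()}")
    fmt = format.upper()
    if fmt in ("DX", "OPENDX"):
        g = Grid(values, origin=np.asarray(grid.origin, dtype=float), delta=float(grid.voxel_size))
        g.export(str(path), file_format="dx")
    elif fmt == "CSV":
        nx, ny, nz = values.shape
        ii, jj, kk = np.meshgrid(range(nx), range(ny), range(nz), indexing="ij")
        df = pd.DataFrame(
            {
                "ix": ii.ravel(),
                "iy": jj.ravel(),
                "iz": kk.ravel(),
                "value": values.ravel(),
            }
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported grid format {format!r}")
    return path


def read_grid(path: str | Path):
    """Read an OpenDX grid back as (values, origin, voxel_size)."""
    g = Grid(str(path))
    delta = np.atleast_1d(np.asarray(g.delta, dtype=float))
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta.flat[0]):
        raise ValueError("anisotropic voxels are not supported")
    return np.asarray(g.grid, dtype=float), np.asarray(g.origin, dtype=float), float(delta.flat[0])


def write_events(events: Sequence, path: str | Path, kind: str | None = None) -> Path:
    """Write crossing or flip events as a TSV table, one row per event.

    All events must be of one dataclass type; columns follow the dataclass
    field order.  An empty list writes a header-only file (``kind`` selects
    which header; defaults to crossing columns).
    """
    from .permeation import CrossingEvent
    from .scrambling import FlipEvent

    path = Path(path)
    kinds = {"crossing": CrossingEvent, "flip": FlipEvent}
    if events:
        types = {type(e) for e in events}
        if len(types) > 1:
            raise ValueError("homogeneous event type required")
        cls = types.pop()
        if cls not in kinds.values():
            raise ValueError(f"unsupported event type {cls.__name__}")
    else:
        cls = kinds.get(kind or "crossing")
        if cls is None:
            raise ValueError(f"unknown event kind {kind!r}")
    cols = [f.name for f in dataclasses.fields(cls)]
    rows = [dataclasses.asdict(e) for e in events]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path
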