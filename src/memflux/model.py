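"""Internal data model for membrane trajectory analysis.

Conventions used throughout the package:

* lengths in angstrom (Å), times in picoseconds (ps), charges in
  elementary charges (e), masses in amu;
* atom indices are 0-based, residue ids are 1-based as read from files;
* only orthorhombic periodic boxes are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("memflux")

ROLES = ("protein", "lipid", "water", "ion", "other")

#: residue-name -> role dictionaries.  These cover the CHARMM/GROMACS names
#: of the usual suspects in a solvated bilayer system; the maps are plain
#: data so a caller can extend or replace them.
PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET
    PHE PRO SER THR TRP TYR VAL""".split()
)
WATER_RESNAMES = frozenset("TIP3 TIP4 HOH SOL WAT SPC OH2".split())
LIPID_RESNAMES = frozenset("POPC POPE POPS POPG DOPC DPPC DMPC".split())
#: lipid atom names treated as the headgroup reference atom (phosphate)
HEADGROUP_ATOM_NAMES = frozenset("P PO4 P8 P1".split())
#: residue name -> (species tag, signed valence)
ION_RESNAMES: Mapping[str, tuple[str, int]] = {
    "NA": ("NA", +1),
    "SOD": ("NA", +1),
    "CL": ("CL", -1),
    "CLA": ("CL", -1),
    "K": ("K", +1),
    "POT": ("K", +1),
    "CA": ("CA", +2),
    "CAL": ("CA", +2),
    "MG": ("MG", +2),
}


@dataclass(frozen=True)
class RoleMap:
    """Pure residue-name -> role mapping used when reading topologies."""

    protein: frozenset = PROTEIN_RESNAMES
    water: frozenset = WATER_RESNAMES
    lipid: frozenset = LIPID_RESNAMES
    ions: Mapping[str, tuple[str, int]] = field(default_factory=lambda: dict(ION_RESNAMES))
    headgroup_atoms: frozenset = HEADGROUP_ATOM_NAMES

    def classify(self, residue_name: str, atom_name: str) -> tuple[str, str | None, int, bool]:
        """Return (role, ion_species, valence, is_headgroup) for one atom."""
        rn = residue_name.upper()
        if rn in self.ions:
            species, valence = self.ions[rn]
            return "ion", species, valence, False
        if rn in self.water:
            return "water", None, 0, False
        if rn in self.lipid:
            return "lipid", None, 0, atom_name.upper() in self.headgroup_atoms
        if rn in self.protein:
            return "protein", None, 0, False
        return "other", None, 0, False


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str = ""
    partial_charge: float = 0.0
    mass: float = 0.0
    role: str = "other"
    ion_species: str | None = None
    ion_valence: int = 0
    is_headgroup: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if abs(self.partial_charge) > 4:
            raise ValueError(f"atom {self.index}: |partial_charge| > 4 e")
        if self.role == "ion" and not self.ion_species:
            raise ValueError(f"atom {self.index}: role=ion requires ion_species")
        if self.is_headgroup and self.role != "lipid":
            raise ValueError(f"atom {self.index}: is_headgroup implies role=lipid")


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box (Å)."""

    lx: float
    ly: float
    lz: float
    orthorhombic: bool = True

    def __post_init__(self) -> None:
        if not self.orthorhombic:
            raise ValueError("only orthorhombic boxes are supported")
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("box lengths must be positive")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)


class Topology:
    """An ordered collection of atoms partitioned into residues."""

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        idx = np.array([a.index for a in atoms])
        if len(atoms) and not np.array_equal(idx, np.arange(len(atoms))):
            raise ValueError("atom indices must be unique, contiguous and 0-based")
        self.atoms: list[Atom] = atoms
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_ids = np.array([a.residue_id for a in atoms], dtype=int)
        self.roles = np.array([a.role for a in atoms], dtype=object)
        self.charges = np.array([a.partial_charge for a in atoms], dtype=float)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.ion_species = np.array(
            [a.ion_species or "" for a in atoms], dtype=object
        )
        self.ion_valences = np.array([a.ion_valence for a in atoms], dtype=int)
        self.is_headgroup = np.array([a.is_headgroup for a in atoms], dtype=bool)
        self._validate_lipids()

    def _validate_lipids(self) -> None:
        lipid_resids = np.unique(self.residue_ids[self.roles == "lipid"])
        for rid in lipid_resids:
            mask = (self.residue_ids == rid) & (self.roles == "lipid")
            n_head = int(self.is_headgroup[mask].sum())
            if n_head != 1:
                raise ValueError(
                    f"lipid residue {rid} has {n_head} headgroup reference atoms "
                    "(exactly one required)"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(
        self,
        role: str | None = None,
        residue_ids: Sequence[int] | None = None,
        names: Sequence[str] | None = None,
        headgroup: bool | None = None,
        species: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Return 0-based atom indices matching all given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            mask &= self.roles == role
        if residue_ids is not None:
            mask &= np.isin(self.residue_ids, np.asarray(residue_ids))
        if names is not None:
            mask &= np.isin(self.names, np.asarray(names, dtype=object))
        if headgroup is not None:
            mask &= self.is_headgroup == headgroup
        if species is not None:
            mask &= np.isin(self.ion_species, np.asarray(species, dtype=object))
        return np.flatnonzero(mask)

    def with_charges(self, charges: np.ndarray, masses: np.ndarray | None = None) -> "Topology":
        """Return a copy with partial charges (and optionally masses) replaced."""
        charges = np.asarray(charges, dtype=float)
        if charges.shape != (self.n_atoms,):
            raise ValueError("charge array length mismatch")
        new_atoms = []
        for a, q in zip(self.atoms, charges):
            m = a.mass if masses is None else float(masses[a.index])
            new_atoms.append(replace(a, partial_charge=float(q), mass=m))
        return Topology(new_atoms)


@dataclass(frozen=True)
class Frame:
    """One stored configuration: time (ps), coordinates (Å, shape (N, 3)), box."""

    time: float
    coordinates: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        object.__setattr__(self, "coordinates", c)


class Trajectory:
    """An ordered sequence of frames over a fixed topology.

    Coordinates are held as one (n_frames, n_atoms, 3) float array; ``Frame``
    views are materialised on demand.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        times: np.ndarray,
        boxes: Sequence[Box] | Box,
    ):
        coordinates = np.asarray(coordinates, dtype=float)
        times = np.asarray(times, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coordinates.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coordinates.shape[1]} does not match "
                f"topology ({topology.n_atoms})"
            )
        if coordinates.shape[0] != len(times):
            raise ValueError("times length must equal number of frames")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if isinstance(boxes, Box):
            boxes = [boxes] * len(times)
        if len(boxes) != len(times):
            raise ValueError("one box per frame required")
        self.topology = topology
        self.coordinates = coordinates
        self.times = times
        self.boxes = list(boxes)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def stride_ps(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    @property
    def duration_ns(self) -> float:
        """Sampled duration in ns (one stride per stored interval)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[-1] - self.times[0]) / 1000.0

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.coordinates[i], self.boxes[i])

    @property
    def frames(self) -> Iterator[Frame]:
        return (self.frame(i) for i in range(self.n_frames))

    def __len__(self) -> int:
        return self.n_frames
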