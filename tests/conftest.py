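"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from memflux import synthetic_data as sd
from memflux.geometry import fit_membrane, wrap_displacement
from memflux.model import Atom, Box, Topology, Trajectory


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately simple and separate from the package)

def brute_force_crossing_counts(traj, membrane, buffer=5.0) -> Counter:
    """Per-frame scalar recount of transmembrane crossings (slab mode, dwell 1).

    A plain per-ion, per-frame python scan over committed bulk sides, used as
    the independent check on both the generator ledger and the detector.
    """
    axis = membrane.normal_axis
    top = traj.topology
    box_l = np.array([b.lengths[axis] for b in traj.boxes])
    up = membrane.upper_plane - membrane.midplane + buffer
    lo = membrane.lower_plane - membrane.midplane - buffer
    out: Counter = Counter()
    for i in top.select(role="ion"):
        z = wrap_displacement(traj.coordinates[:, i, axis] - membrane.midplane, box_l)
        committed = 0
        last_committed = -1
        for f in range(len(z)):
            s = 1 if z[f] > up[f] else (-1 if z[f] < lo[f] else 0)
            if s == 0:
                continue
            if committed == 0 or s == committed:
                committed = s
                last_committed = f
                continue
            between = z[last_committed + 1 : f]
            between_sides = [
                1 if zz > up[g] else (-1 if zz < lo[g] else 0)
                for g, zz in zip(range(last_committed + 1, f), between)
            ]
            if len(between_sides) and all(b == 0 for b in between_sides):
                out[(str(top.ion_species[i]), "up" if s == 1 else "down")] += 1
            committed = s
            last_committed = f
    return out


def direct_ewald_potential(positions, charges, box, probes, sigma, nmax=14):
    """Direct reciprocal-space Ewald sum for Gaussian charges (no FFT).

    Returns the periodic potential (reduced units: charge in e, length in Å,
    eps0 = 1) at arbitrary probe points, with the k=0 mode removed
    (neutralizing background).  Absolutely convergent because of the Gaussian
    form factor; ``nmax`` covers |n| <= nmax reciprocal vectors per axis.
    """
    box = np.asarray(box, dtype=float)
    volume = box.prod()
    ns = np.arange(-nmax, nmax + 1)
    kx, ky, kz = np.meshgrid(
        2 * np.pi * ns / box[0], 2 * np.pi * ns / box[1], 2 * np.pi * ns / box[2],
        indexing="ij",
    )
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    mask = k2 > 0
    kx, ky, kz, k2 = kx[mask], ky[mask], kz[mask], k2[mask]
    s = np.zeros(k2.shape, dtype=complex)
    for q, r in zip(charges, positions):
        s += q * np.exp(-1j * (kx * r[0] + ky * r[1] + kz * r[2]))
    s *= np.exp(-0.5 * sigma ** 2 * k2) / k2
    return np.array(
        [
            (s * np.exp(1j * (kx * p[0] + ky * p[1] + kz * p[2]))).sum().real / volume
            for p in np.atleast_2d(probes)
        ]
    )


def single_atom_trajectory(path_z, box=(20.0, 20.0, 60.0), stride_ps=10.0,
                           role="ion", species="NA", valence=1, xy=(0.0, 0.0)):
    """A 1-ion trajectory plus an 8+8-lipid static membrane for zone tests."""
    atoms = []
    paths = []
    n = len(path_z)
    resid = 1
    for sign in (1, -1):
        for k in range(8):
            x = -7.5 + 2.5 * k
            for name, is_head, z in (("P", True, sign * 19.0), ("C2", False, sign * 12.0)):
                atoms.append(
                    Atom(index=len(atoms), name=name, element=name[0],
                         residue_name="POPC", residue_id=resid, role="lipid",
                         is_headgroup=is_head)
                )
                paths.append(np.tile([x, sign * 5.0, z], (n, 1)))
            resid += 1
    kwargs = dict(role=role)
    if role == "ion":
        kwargs.update(ion_species=species, ion_valence=valence)
    atoms.append(
        Atom(index=len(atoms), name=species, element=species[0],
             residue_name="SOD" if species == "NA" else "CLA",
             residue_id=resid, **kwargs)
    )
    ion_path = np.column_stack(
        [np.full(n, xy[0]), np.full(n, xy[1]), np.asarray(path_z, dtype=float)]
    )
    paths.append(ion_path)
    coords = np.stack(paths, axis=1)
    times = np.arange(n) * stride_ps
    return Trajectory(Topology(atoms), coords, times, Box(*box))


# ---------------------------------------------------------------------------
# session-scoped scenario fixtures (generation is the expensive part)

@pytest.fixture(scope="session")
def preset_17x3():
    spec = sd.get_preset("open-conducting-17x3", seed=11)
    top, traj, ledger = sd.generate(spec)
    return spec, top, traj, ledger


@pytest.fixture(scope="session")
def preset_open():
    spec = sd.get_preset("open-conducting", seed=7)
    top, traj, ledger = sd.generate(spec)
    return spec, top, traj, ledger


@pytest.fixture(scope="session")
def preset_closed():
    spec = sd.get_preset("closed-hydrated-discontinuous", seed=7)
    top, traj, ledger = sd.generate(spec)
    return spec, top, traj, ledger


@pytest.fixture(scope="session")
def preset_scrambling():
    spec = sd.get_preset("scrambling", seed=7)
    top, traj, ledger = sd.generate(spec)
    return spec, top, traj, ledger


@pytest.fixture(scope="session")
def small_scenario():
    spec = sd.random_scenario(42)
    top, traj, ledger = sd.generate(spec)
    membrane = fit_membrane(traj)
    return spec, top, traj, ledger, membrane
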