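from collections import Counter

import numpy as np
import pytest

from conftest import brute_force_crossing_counts, single_atom_trajectory
from memflux import synthetic_data as sd
from memflux.geometry import define_pore, fit_membrane
from memflux.model import Trajectory
from memflux.permeation import (
    conductance,
    cumulative_crossings,
    detect_crossings,
    ion_residue_contacts,
    summarize_permeation,
)


class TestConductance:
    @pytest.mark.parametrize(
        "charge,duration,expected",
        [(20, 200.0, 32.0), (6, 200.0, 9.6), (16, 200.0, 25.6), (37, 480.0, 24.7)],
    )
    def test_voltage_clamp_counting_estimates(self, charge, duration, expected):
        """Gross transported charge over a run at 0.5 V gives the familiar pS values."""
        assert round(conductance(charge, 0.5, duration), 1) == expected
        assert round(conductance(charge, -0.5, duration), 1) == expected

    def test_zero_charge_and_zero_voltage(self):
        assert conductance(0, 0.5, 200.0) == 0.0
        with pytest.raises(ValueError, match="0 V"):
            conductance(5, 0.0, 200.0)

    def test_linearity_in_charge_and_time(self):
        base = conductance(7, 0.5, 123.0)
        assert conductance(14, 0.5, 123.0) == pytest.approx(2 * base, rel=1e-12)
        assert conductance(7, 0.5, 246.0) == pytest.approx(base / 2, rel=1e-12)


class TestDetectCrossings:
    def test_preset_17x3_matches_ledger(self, preset_17x3):
        spec, top, traj, ledger = preset_17x3
        mem = fit_membrane(traj)
        pore = define_pore({"center_xy": list(spec.pore_center),
                            "radius_A": spec.pore_radius}, membrane=mem)
        events = detect_crossings(traj, mem, pore)
        got = Counter((e.ion_species, e.direction) for e in events)
        assert got == Counter({("NA", "up"): 17, ("CL", "down"): 3})
        # every detected event lands inside its programmed transit window
        windows = sorted((c.atom_index, c.window_frames) for c in ledger.crossings)
        by_atom = dict(windows)
        for e in events:
            lo, hi = by_atom[e.atom_index]
            assert lo <= e.exit_frame <= hi + 1
            assert e.path_through_pore

    def test_excursion_returns_no_event(self):
        z = [30.0, 28, 20, 5, -10, -20, 5, 22, 28, 30, 31]
        traj = single_atom_trajectory(z)
        mem = fit_membrane(traj)
        # the single fast ion also trips the coarse-stride warning
        with pytest.warns(UserWarning, match="possible missed crossings"):
            assert detect_crossings(traj, mem, None, mode="slab") == []

    def test_periodic_teleport_rejected(self):
        # jumps straight between the bulk zones through the box boundary
        z = [28.0, 28, 29, -29, -28, -29, 29, 28, 29, -29]
        traj = single_atom_trajectory(z)
        mem = fit_membrane(traj)
        assert detect_crossings(traj, mem, None, mode="slab") == []

    def test_genuine_crossing_scores_once(self):
        z = [-29.0, -27, -20, -10, 0, 10, 20, 27, 29, 29]
        traj = single_atom_trajectory(z)
        mem = fit_membrane(traj)
        with pytest.warns(UserWarning, match="possible missed crossings"):
            ev = detect_crossings(traj, mem, None, mode="slab")
        assert len(ev) == 1 and ev[0].direction == "up"
        assert ev[0].entry_frame == 2 and ev[0].exit_frame == 7
        assert ev[0].exit_time > ev[0].entry_time

    def test_radial_mode_excludes_off_axis_paths(self):
        z = [-29.0, -27, -20, -10, 0, 10, 20, 27, 29, 29]
        traj = single_atom_trajectory(z, xy=(9.0, 0.0))  # outside an 8 Å pore
        mem = fit_membrane(traj)
        pore = define_pore({"center_xy": [0.0, 0.0], "radius_A": 8.0}, membrane=mem)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            assert detect_crossings(traj, mem, pore, mode="radial") == []
            slab = detect_crossings(traj, mem, pore, mode="slab")
        assert len(slab) == 1 and slab[0].path_through_pore is False

    def test_species_filter_must_match(self, small_scenario):
        _, _, traj, _, mem = small_scenario
        with pytest.raises(ValueError, match="matches no ions"):
            detect_crossings(traj, mem, None, species=["K"], mode="slab")

    def test_time_reversal_swaps_directions(self, small_scenario):
        spec, top, traj, ledger, mem = small_scenario
        ev = detect_crossings(traj, mem, None, mode="slab")
        rev = Trajectory(top, traj.coordinates[::-1].copy(), traj.times,
                         list(traj.boxes)[::-1])
        mem_r = fit_membrane(rev)
        ev_r = detect_crossings(rev, mem_r, None, mode="slab")
        fwd = Counter((e.ion_species, e.direction) for e in ev)
        back = Counter(
            (e.ion_species, "down" if e.direction == "up" else "up") for e in ev_r
        )
        assert fwd == back

    def test_stride_decimation_preserves_counts(self, preset_17x3):
        spec, top, traj, ledger = preset_17x3
        dec = Trajectory(top, traj.coordinates[::2].copy(), traj.times[::2],
                         list(traj.boxes)[::2])
        mem = fit_membrane(dec)
        pore = define_pore({"center_xy": [0, 0], "radius_A": spec.pore_radius},
                           membrane=mem)
        got = Counter(
            (e.ion_species, e.direction) for e in detect_crossings(dec, mem, pore)
        )
        assert got == Counter({("NA", "up"): 17, ("CL", "down"): 3})

    def test_detector_agrees_with_brute_force_recount(self, small_scenario):
        spec, top, traj, ledger, mem = small_scenario
        ev = detect_crossings(traj, mem, None, mode="slab")
        got = Counter((e.ion_species, e.direction) for e in ev)
        assert got == brute_force_crossing_counts(traj, mem)


class TestSummaries:
    def test_field_consistent_charge_and_backward_tally(self, preset_17x3):
        spec, top, traj, ledger = preset_17x3
        mem = fit_membrane(traj)
        pore = define_pore({"center_xy": [0, 0], "radius_A": spec.pore_radius},
                           membrane=mem)
        ev = detect_crossings(traj, mem, pore)
        res = summarize_permeation(ev, spec.voltage, 200.0)
        assert res.counts == {"CL": 3, "NA": 17}
        assert res.transported_charge == 20
        assert res.backward_events == 0
        assert res.conductance_pS_rounded == 32.0

    def test_cumulative_steps(self):
        from memflux.permeation import CrossingEvent

        events = [
            CrossingEvent(atom_index=i, ion_species="NA", ion_valence=1,
                          direction="up", entry_time=t - 5000, exit_time=t,
                          entry_frame=0, exit_frame=1, path_through_pore=True)
            for i, t in enumerate((10_000.0, 20_000.0, 30_000.0))
        ]
        cum = cumulative_crossings(events, 40.0, ["NA"])
        na = cum[cum.species == "NA"]
        assert list(na["count"]) == [0, 1, 2, 3, 3]
        assert list(na["time_ns"]) == [0.0, 10.0, 20.0, 30.0, 40.0]
        empty = cumulative_crossings([], 40.0, ["NA"])
        assert list(empty["count"]) == [0, 0]

    def test_cumulative_matches_per_frame_recount(self, preset_17x3):
        spec, top, traj, ledger = preset_17x3
        mem = fit_membrane(traj)
        ev = detect_crossings(traj, mem, None, mode="slab")
        cum = cumulative_crossings(ev, traj.duration_ns, ["NA", "CL"])
        # brute-force: count events with exit_time <= t at every frame time
        for s in ("NA", "CL"):
            series = cum[cum.species == s]
            for t_ns in np.linspace(0, traj.duration_ns, 7):
                expected = sum(
                    1 for e in ev if e.ion_species == s and e.exit_time / 1000.0 <= t_ns
                )
                val = series[series.time_ns <= t_ns]["count"].iloc[-1]
                assert val == expected


class TestContacts:
    def test_parked_ion_occupancy_matches_ledger(self):
        spec = sd.ScenarioSpec(
            water_count=0, na_count=4, cl_count=4, lipids_per_leaflet=16,
            duration_ns=2.0, seed=9,
            beacons=[sd.Beacon("R419", (0.0, 0.0, 27.0))],
            contacts=[sd.ProgrammedContact("R419", "CL", 0.5)],
        )
        top, traj, ledger = sd.generate(spec)
        series = ion_residue_contacts(traj, ["R419"], "CL", cutoff=4.0)
        assert series[0].occupancy == pytest.approx(ledger.contacts[0].occupancy)
        segs = series[0].dwell_segments
        assert len(segs) == 1 and segs[0][0] == 0

    def test_tiny_cutoff_gives_zero_occupancy(self):
        spec = sd.ScenarioSpec(
            water_count=0, na_count=4, cl_count=4, lipids_per_leaflet=16,
            duration_ns=1.0, seed=9,
            beacons=[sd.Beacon("R419", (0.0, 0.0, 27.0))],
            contacts=[sd.ProgrammedContact("R419", "CL", 0.5)],
        )
        _, traj, _ = sd.generate(spec)
        series = ion_residue_contacts(traj, ["R419"], "CL", cutoff=0.1)
        assert series[0].occupancy == 0.0

    def test_oscillating_ion_interleaves_two_beacons(self):
        # one ion alternating between two beacons in alternate frames
        n = 10
        spec = sd.ScenarioSpec(
            water_count=0, na_count=4, cl_count=4, lipids_per_leaflet=16,
            duration_ns=(n - 1) * 0.02, stride_ps=20.0, seed=9,
            beacons=[sd.Beacon("R419", (-8.0, 0.0, 27.0)),
                     sd.Beacon("R488", (8.0, 0.0, 27.0))],
        )
        top, traj, _ = sd.generate(spec)
        ion = top.select(role="ion", species=["CL"])[0]
        a = np.array([-8.0, 0.0, 27.0]) + [3.0, 0, 0]
        bpos = np.array([8.0, 0.0, 27.0]) + [3.0, 0, 0]
        traj.coordinates[:, ion] = np.where(
            (np.arange(traj.n_frames) % 2 == 0)[:, None], a, bpos
        )
        s1, s2 = ion_residue_contacts(traj, ["R419", "R488"], "CL", cutoff=4.0)
        assert s1.occupancy == pytest.approx(0.5)
        assert s2.occupancy == pytest.approx(0.5)
        assert not np.any(s1.contact & s2.contact)
        assert np.all(s1.contact | s2.contact)

    def test_unknown_residue_label(self, small_scenario):
        _, _, traj, _, _ = small_scenario
        with pytest.raises(ValueError, match="not found|unknown"):
            ion_residue_contacts(traj, ["R999"], "NA")


def test_pore_contact_residue_presets_are_usable():
    """The shipped channel annotation presets drive the contact analysis."""
    from memflux.permeation import PORE_CONTACT_RESIDUES

    assert PORE_CONTACT_RESIDUES["TMC4"] == ("R419", "R488", "R635")
    assert PORE_CONTACT_RESIDUES["TMC5"] == ("R641", "R736", "R659", "K549")
    labels = PORE_CONTACT_RESIDUES["TMC4"]
    spec = sd.ScenarioSpec(
        water_count=0, na_count=4, cl_count=4, lipids_per_leaflet=16,
        duration_ns=1.0, seed=12,
        beacons=[sd.Beacon(lbl, (8.0 * i - 8.0, 0.0, 27.0))
                 for i, lbl in enumerate(labels)],
        contacts=[sd.ProgrammedContact("R488", "CL", 0.4)],
    )
    top, traj, ledger = sd.generate(spec)
    series = ion_residue_contacts(traj, list(labels), "CL", cutoff=4.0)
    by_label = {s.residue_label: s.occupancy for s in series}
    assert by_label["R488"] == pytest.approx(ledger.contacts[0].occupancy)
    assert by_label["R635"] == 0.0
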