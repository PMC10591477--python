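"""Atom typing rules, interaction detection geometry, frequency aggregation
and state comparison."""

import numpy as np
import pytest
from scipy.stats import binom

from tndyn import synthetic
from tndyn.interactions import (
    ContactEvent,
    FrequencyTable,
    InteractionCutoffs,
    aggregate,
    assign_atom_types,
    compare_states,
    detect_interactions,
    heatmap_matrix,
    profile_trajectory,
)
from tndyn.structure_io import AtomRecord, Topology

from conftest import make_trajectory


def build_topology(residues):
    """residues: list of (subunit, resnum, resname, [(atom, element, xyz)])."""
    atoms, coords = [], []
    for su, resnum, resname, atom_list in residues:
        for name, el, xyz in atom_list:
            atoms.append(AtomRecord(name, el, su, resnum, resname, len(atoms)))
            coords.append(xyz)
    return Topology(atoms), np.array(coords, dtype=float)


def arg_residue(su, num, offset):
    ox, oy, oz = offset
    return (su, num, "ARG", [
        ("CA", "C", (ox, oy, oz)),
        ("NE", "N", (ox, oy, oz + 1.4)),
        ("NH1", "N", (ox, oy, oz + 2.6)),
        ("NH2", "N", (ox + 0.9, oy, oz + 2.2)),
    ])


def glu_residue(su, num, offset, oe1):
    ox, oy, oz = offset
    return (su, num, "GLU", [
        ("CA", "C", (ox, oy, oz)),
        ("OE1", "O", oe1),
        ("OE2", "O", (oe1[0] + 0.9, oe1[1], oe1[2] + 0.4)),
    ])


class TestAtomTyping:
    def test_arginine_guanidinium_group(self):
        top, _ = build_topology([arg_residue("A", 1, (0, 0, 0))])
        t = assign_atom_types(top)
        side = [i for i, n in enumerate(top.names) if n in ("NE", "NH1", "NH2")]
        assert all(t.charge_sign[i] == 1 for i in side)
        assert len({t.charge_group[i] for i in side}) == 1
        assert all(t.donor[i] for i in side)

    def test_phosphoserine_anionic_group(self):
        sep = ("A", 23, "SEP", [
            ("CA", "C", (0, 0, 0)),
            ("P", "P", (0, 0, 2.0)),
            ("O1P", "O", (0, 0, 3.4)),
            ("O2P", "O", (0.9, 0, 2.4)),
            ("O3P", "O", (-0.9, 0, 2.4)),
        ])
        top, _ = build_topology([sep])
        t = assign_atom_types(top)
        phos = [i for i, n in enumerate(top.names) if n in ("O1P", "O2P", "O3P")]
        assert all(t.charge_sign[i] == -1 for i in phos)
        assert len({t.charge_group[i] for i in phos}) == 1
        assert all(t.acceptor[i] for i in phos)

    def test_phenylalanine_ring(self):
        ring = [(n, "C", (np.cos(k), np.sin(k), 0.0))
                for k, n in zip(np.linspace(0, 5, 6),
                                ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))]
        top, _ = build_topology([("A", 1, "PHE", [("CA", "C", (0, 0, -2.0))] + ring)])
        t = assign_atom_types(top)
        assert (t.ring_id >= 0).sum() == 6

    def test_unknown_residue_vdw_only_with_warning(self):
        top, _ = build_topology([("A", 1, "XYZ", [("C1", "C", (0, 0, 0))])])
        with pytest.warns(UserWarning, match="XYZ"):
            t = assign_atom_types(top)
        assert not t.donor.any() and not t.acceptor.any()
        assert (t.charge_sign == 0).all()


class TestDetection:
    def _arg_glu(self, separation):
        nh1_z = 2.6
        top, X = build_topology([
            arg_residue("A", 1, (0, 0, 0)),
            glu_residue("A", 5, (separation + 10, 0, 0), (separation, 0, nh1_z)),
        ])
        # OE1 sits `separation` along x from NH1 at (0,0,2.6)... adjust:
        X[[i for i, n in enumerate(top.names) if n == "OE1"][0]] = [separation, 0, nh1_z]
        return top, X

    def test_salt_bridge_within_cutoff(self):
        top, X = self._arg_glu(3.0)
        events = detect_interactions(X, top, assign_atom_types(top))
        types = {e.interaction_type for e in events
                 if {e.res_a, e.res_b} == {("A", 1), ("A", 5)}}
        assert "ionic" in types

    def test_no_event_beyond_cutoff(self):
        top, X = self._arg_glu(6.5)
        events = detect_interactions(X, top, assign_atom_types(top))
        assert not any(
            e.interaction_type == "ionic"
            and {e.res_a, e.res_b} == {("A", 1), ("A", 5)}
            for e in events
        )

    def test_stacked_rings_aromatic(self):
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")

        def ring(z, su, num):
            pts = [(n, "C", (1.39 * np.cos(np.radians(60 * k)),
                             1.39 * np.sin(np.radians(60 * k)), z))
                   for k, n in enumerate(names)]
            return (su, num, "PHE", [("CA", "C", (0, 5.0, z))] + pts)

        top, X = build_topology([ring(0.0, "A", 1), ring(4.0, "A", 9)])
        t = assign_atom_types(top)
        # brute-force centroid check in the test itself
        ring1 = X[np.flatnonzero(t.ring_id == 0)].mean(0)
        ring2 = X[np.flatnonzero(t.ring_id == 1)].mean(0)
        assert np.linalg.norm(ring1 - ring2) == pytest.approx(4.0, abs=1e-9)
        events = detect_interactions(X, top, t)
        assert any(e.interaction_type == "aromatic" for e in events)

    def test_determinism(self, small_system):
        traj, _ = small_system
        t = assign_atom_types(traj.topology)
        e1 = detect_interactions(traj.coordinates[0], traj.topology, t)
        e2 = detect_interactions(traj.coordinates[0], traj.topology, t)
        assert e1 == e2

    def test_loosening_cutoffs_is_monotone(self, small_system):
        traj, _ = small_system
        t = assign_atom_types(traj.topology)
        tight = InteractionCutoffs()
        loose = InteractionCutoffs(hbond_dist=4.0, ionic_dist=5.0,
                                   aromatic_centroid_dist=6.5, vdw_margin=1.0)
        X = traj.coordinates[0]
        e_tight = {(e.res_a, e.res_b, e.interaction_type)
                   for e in detect_interactions(X, traj.topology, t, tight)
                   if e.interaction_type != "vdw"}
        e_loose = {(e.res_a, e.res_b, e.interaction_type)
                   for e in detect_interactions(X, traj.topology, t, loose)
                   if e.interaction_type != "vdw"}
        assert e_tight <= e_loose

    def test_residue_pair_canonical_symmetry(self, small_system):
        traj, _ = small_system
        t = assign_atom_types(traj.topology)
        for e in detect_interactions(traj.coordinates[0], traj.topology, t):
            assert e.res_a <= e.res_b


class TestAggregate:
    def test_percentage_scale(self):
        events = [ContactEvent(i, ("A", 1), ("A", 5), "ionic") for i in range(30000)]
        table = aggregate(events, 37500)
        assert table.lookup(("A", 1), ("A", 5), "ionic") == pytest.approx(80.0)

    def test_empty_table_zero_lookup(self):
        table = aggregate([], 100)
        assert len(table.table) == 0
        assert table.lookup(("A", 1), ("A", 2), "hbond") == 0.0

    def test_out_of_range_frame_errors(self):
        with pytest.raises(ValueError):
            aggregate([ContactEvent(10, ("A", 1), ("A", 5), "ionic")], 10)

    def test_planted_occupancy_within_binomial_ci(self):
        f, n = 0.25, 500
        spec = synthetic.SyntheticSpec(
            n_runs=1, frames_per_run=n, seed=21,
            planted_contacts=(synthetic.PlantedContact(("TnC", 95), ("TnC", 98), "ionic", f),),
        )
        traj, truth = synthetic.generate_trajectory(spec)
        table = profile_trajectory(traj)
        pct = table.lookup(("TnC", 95), ("TnC", 98), "ionic")
        count = round(pct * n / 100)
        lo, hi = binom.ppf([0.005, 0.995], n, f)
        assert lo <= count <= hi
        # and the measured count equals the recorded Bernoulli draws exactly
        key = next(iter(truth.contact_states))
        assert count == truth.contact_states[key].sum()


class TestCompareStates:
    def test_identical_states_zero_delta(self):
        ev = [ContactEvent(i, ("A", 1), ("A", 5), "ionic") for i in range(80)]
        t = aggregate(ev, 100)
        delta = compare_states(t, t)
        assert (delta.delta == 0).all()

    def test_appearing_contact_plus_80_points(self):
        t0 = aggregate([], 100)
        t1 = aggregate([ContactEvent(i, ("A", 1), ("A", 5), "ionic") for i in range(80)], 100)
        delta = compare_states(t0, t1)
        assert delta.delta.iloc[0] == pytest.approx(80.0)

    def test_planted_occupancy_shift(self):
        def system(f, seed):
            spec = synthetic.SyntheticSpec(
                n_runs=1, frames_per_run=400, seed=seed,
                planted_contacts=(
                    synthetic.PlantedContact(("TnC", 95), ("TnC", 98), "ionic", f),
                ),
            )
            traj, _ = synthetic.generate_trajectory(spec)
            return profile_trajectory(traj)

        delta = compare_states(system(0.6, 31), system(0.3, 32))
        row = delta[(delta.res_a == 95) & (delta.res_b == 98) & (delta.type == "ionic")]
        # -30 points within the binomial sampling band (99%, n=400 per state)
        assert row.delta.iloc[0] == pytest.approx(-30.0, abs=8.0)


class TestHeatmap:
    def test_empty_table_correct_shape(self):
        t = aggregate([], 10)
        m = heatmap_matrix(t, ("A", 1, 5), ("B", 1, 3), "ionic")
        assert m.shape == (5, 3)
        assert (m.to_numpy() == 0).all()

    def test_single_pair_single_cell(self):
        ev = [ContactEvent(i, ("A", 2), ("B", 3), "hbond") for i in range(5)]
        m = heatmap_matrix(aggregate(ev, 10), ("A", 1, 5), ("B", 1, 5), "hbond")
        assert (m.to_numpy() > 0).sum() == 1
        assert m.loc["A:2", "B:3"] == pytest.approx(50.0)

    def test_three_pair_pattern_hand_computed(self):
        ev = (
            [ContactEvent(i, ("A", 1), ("B", 1), "ionic") for i in range(10)]
            + [ContactEvent(i, ("A", 2), ("B", 3), "ionic") for i in range(5)]
            + [ContactEvent(0, ("A", 3), ("B", 2), "ionic")]
        )
        m = heatmap_matrix(aggregate(ev, 10), ("A", 1, 3), ("B", 1, 3), "ionic")
        expected = np.array([[100.0, 0, 0], [0, 0, 50.0], [0, 10.0, 0]])
        np.testing.assert_allclose(m.to_numpy(), expected)

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            heatmap_matrix(aggregate([], 10), ("A", 5, 1), ("B", 1, 3), "ionic")
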