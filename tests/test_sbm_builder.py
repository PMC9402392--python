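"""Dual-basin potential assembly, closed-form energies, analytic forces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostate_sbm.contact_map import ContactMap, ContactRecord
from twostate_sbm.sbm_builder import (
    DualGaussianContact,
    ModelParams,
    SpecificContact,
    build_topology,
    dual_gaussian_energy,
    excluded_volume_energy,
    export_gromacs,
    export_topology,
    import_topology,
    lj1012_energy,
    total_energy,
    forces,
)
from twostate_sbm.structure_io import Atom, ResidueRecord, Structure


def _bead_chain(coords):
    return Structure("A", [
        ResidueRecord(k + 1, "GLY", [Atom("CA", "C", np.asarray(c, float))])
        for k, c in enumerate(coords)
    ])


@pytest.fixture(scope="module")
def ten_bead_topology():
    rng = np.random.default_rng(7)
    coords = np.cumsum(rng.normal(0, 0.2, (10, 3)) + [0.3, 0, 0], axis=0)
    chain = _bead_chain(coords)
    cm = ContactMap([
        ContactRecord(1, 6, 0.9, 0.7, True, True, "common"),
        ContactRecord(2, 8, 0.8, 1.5, True, False, "open_specific"),
        ContactRecord(3, 9, 1.4, 0.6, False, True, "closed_specific"),
        ContactRecord(4, 10, 1.0, 1.2, True, False, "discarded"),
    ])
    params = ModelParams(eps_os=1.0, eps_cs=0.7)
    return chain, cm, build_topology(chain, cm, params)


class TestBuildTopology:
    def test_bonded_term_counts(self, ten_bead_topology):
        _, _, top = ten_bead_topology
        assert len(top.bonded.bond_idx) == 9
        assert len(top.bonded.angle_idx) == 8
        assert len(top.bonded.dihedral_idx) == 7

    def test_contact_term_counts(self, ten_bead_topology):
        _, _, top = ten_bead_topology
        assert len(top.dual_gaussian) == 1
        assert len(top.specific) == 2  # discarded contributes nothing

    def test_discarded_pair_falls_back_to_excluded_volume(self, ten_bead_topology):
        _, _, top = ten_bead_topology
        ev = {tuple(p) for p in top.ev_idx}
        assert (3, 9) in ev  # auth 4-10 -> beads 3-9, discarded record
        assert (0, 5) not in ev  # common contact pair (auth 1-6) is not EV
        assert all(j - i >= 4 for i, j in ev)

    def test_native_distances_assigned_per_class(self, ten_bead_topology):
        _, _, top = ten_bead_topology
        dg = top.dual_gaussian[0]
        assert (dg.r1, dg.r2) == (0.9, 0.7)
        by_pair = {(c.i, c.j): c for c in top.specific}
        assert by_pair[(1, 7)].sigma == 0.8  # open-specific at open distance
        assert by_pair[(2, 8)].sigma == 0.6  # closed-specific at closed distance
        assert by_pair[(2, 8)].strength == pytest.approx(0.7)

    def test_cth_scale_multiplies_only_tail_contacts(self, toy):
        base = build_topology(toy.open, toy.contacts,
                              ModelParams(cth_range=toy.cth_range))
        doubled = build_topology(toy.open, toy.contacts,
                                 ModelParams(cth_range=toy.cth_range,
                                             cth_scale=2.0))
        for a, b in zip(base.specific, doubled.specific):
            if a.is_closed:
                assert b.strength == a.strength
            else:  # every open-specific toy contact involves the tail
                assert b.strength == pytest.approx(2.0 * a.strength)

    def test_missing_residue_raises(self, ten_bead_topology):
        chain, _, _ = ten_bead_topology
        cm = ContactMap([ContactRecord(1, 99, 1.0, 1.0, True, True, "common")])
        with pytest.raises(KeyError, match="99"):
            build_topology(chain, cm, ModelParams())


class TestClosedForms:
    def test_dual_gaussian_minimum_at_each_native_distance(self):
        c = DualGaussianContact(0, 1, r1=0.9, r2=0.6, depth=1.3)
        assert dual_gaussian_energy(0.9, c) == pytest.approx(-1.3, abs=1e-12)
        assert dual_gaussian_energy(0.6, c) == pytest.approx(-1.3, abs=1e-12)

    def test_dual_gaussian_vanishes_far_away(self):
        c = DualGaussianContact(0, 1, r1=0.9, r2=0.6)
        assert abs(dual_gaussian_energy(9.0, c)) < 1e-6

    def test_dual_gaussian_repulsive_core(self):
        c = DualGaussianContact(0, 1, r1=0.9, r2=0.6)
        assert dual_gaussian_energy(0.05, c) > 1e6

    @given(st.floats(0.3, 3.0), st.floats(0.4, 2.0), st.floats(0.4, 2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dual_gaussian_swap_symmetry(self, r, r1, r2):
        a = DualGaussianContact(0, 1, r1=r1, r2=r2)
        b = DualGaussianContact(0, 1, r1=r2, r2=r1)
        assert dual_gaussian_energy(r, a) == pytest.approx(
            dual_gaussian_energy(r, b), rel=1e-12, abs=1e-12)

    def test_lj1012_minimum_depth_and_location(self):
        c = SpecificContact(0, 1, sigma=0.8, strength=1.7)
        assert lj1012_energy(0.8, c) == pytest.approx(-1.7, abs=1e-12)
        h = 1e-7
        deriv = (lj1012_energy(0.8 + h, c) - lj1012_energy(0.8 - h, c)) / (2 * h)
        assert abs(deriv) < 1e-4

    def test_lj1012_hand_computed_value(self):
        # r = sigma/1.2: 5*1.2^12 - 6*1.2^10
        c = SpecificContact(0, 1, sigma=0.6, strength=1.0)
        expected = 5 * 1.2 ** 12 - 6 * 1.2 ** 10
        assert lj1012_energy(0.5, c) == pytest.approx(expected, abs=1e-12)

    def test_excluded_volume_values(self):
        p = ModelParams(eps_ev=1.3)
        assert excluded_volume_energy(0.4, p) == pytest.approx(1.3, abs=1e-12)
        assert excluded_volume_energy(0.8, p) == pytest.approx(1.3 / 4096,
                                                               abs=1e-15)

    @pytest.mark.parametrize("fn,obj", [
        (dual_gaussian_energy, DualGaussianContact(0, 1, 0.9, 0.6)),
        (lj1012_energy, SpecificContact(0, 1, 0.8, 1.0)),
        (excluded_volume_energy, ModelParams()),
    ])
    def test_nonpositive_distance_rejected(self, fn, obj):
        with pytest.raises(ValueError):
            fn(-0.1, obj)


class TestTotalEnergy:
    def test_decomposition_sums_to_total(self, toy_topology, toy, rng):
        x = toy.open.ca_coords() + rng.normal(0, 0.05, (toy_topology.n_beads, 3))
        e = total_energy(toy_topology, x)
        parts = sum(v for k, v in e.items() if k != "total")
        assert e["total"] == pytest.approx(parts, abs=1e-10)

    def test_native_state_is_exact_minimum_of_its_terms(self, toy, toy_topology):
        e = total_energy(toy_topology, toy.open.ca_coords())
        assert e["bond"] == pytest.approx(0.0, abs=1e-18)
        assert e["angle"] == pytest.approx(0.0, abs=1e-18)
        assert e["dihedral"] == pytest.approx(0.0, abs=1e-18)
        n_common = len(toy_topology.dual_gaussian)
        n_os = sum(not c.is_closed for c in toy_topology.specific)
        assert e["dual_gaussian"] == pytest.approx(-n_common, abs=1e-9)
        assert e["specific_open"] == pytest.approx(-n_os, abs=1e-9)

    def test_eps_cs_scaling_is_exact(self, toy, rng):
        x = toy.closed.ca_coords() + rng.normal(0, 0.03, (len(toy.closed), 3))
        lam = 1.73
        e1 = total_energy(build_topology(toy.open, toy.contacts,
                                         ModelParams(eps_cs=1.0)), x)
        e2 = total_energy(build_topology(toy.open, toy.contacts,
                                         ModelParams(eps_cs=lam)), x)
        assert e2["specific_closed"] == pytest.approx(
            lam * e1["specific_closed"], rel=1e-12)
        assert e2["dual_gaussian"] == pytest.approx(e1["dual_gaussian"],
                                                    rel=1e-12)

    def test_nan_coordinate_rejected(self, toy_topology):
        x = np.zeros((toy_topology.n_beads, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            total_energy(toy_topology, x)


class TestForces:
    def test_matches_finite_differences(self, toy, toy_topology, rng):
        x = toy.open.ca_coords() + rng.normal(0, 0.01,
                                              (toy_topology.n_beads, 3))
        f = forces(toy_topology, x)
        h = 1e-6
        for i in range(0, toy_topology.n_beads, 7):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                fd = -(total_energy(toy_topology, xp)["total"]
                       - total_energy(toy_topology, xm)["total"]) / (2 * h)
                assert f[i, d] == pytest.approx(fd, abs=1e-5)

    def test_zero_net_force(self, toy, toy_topology, rng):
        x = toy.open.ca_coords() + rng.normal(0, 0.2,
                                              (toy_topology.n_beads, 3))
        f = forces(toy_topology, x)
        # translation invariance up to roundoff relative to the largest force
        atol = 1e-12 * np.abs(f).max() + 1e-10
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=atol)

    def test_native_state_forces_small(self, toy, toy_topology):
        # native coords sit at the exact minimum of every attractive term;
        # only the excluded-volume tail exerts a weak residual push
        f = forces(toy_topology, toy.open.ca_coords())
        assert np.abs(f).max() < 2.0


class TestExport:
    def test_native_json_roundtrip(self, toy_topology, tmp_path):
        path = tmp_path / "model.json"
        export_topology(toy_topology, path)
        back = import_topology(path)
        assert back.n_beads == toy_topology.n_beads
        assert back.auth_ids == toy_topology.auth_ids
        np.testing.assert_array_equal(back.bonded.bond_idx,
                                      toy_topology.bonded.bond_idx)
        np.testing.assert_allclose(back.bonded.dihedral_phi0,
                                   toy_topology.bonded.dihedral_phi0)
        assert back.dual_gaussian == toy_topology.dual_gaussian
        assert back.specific == toy_topology.specific
        np.testing.assert_array_equal(back.ev_idx, toy_topology.ev_idx)
        x = np.cumsum(np.full((toy_topology.n_beads, 3), 0.2), axis=0)
        assert total_energy(back, x) == total_energy(toy_topology, x)

    def test_gromacs_dialect_files(self, toy_topology, toy, tmp_path):
        top_path, gro_path = export_gromacs(toy_topology, tmp_path / "model",
                                            toy.open.ca_coords())
        gro_lines = gro_path.read_text().splitlines()
        assert len(gro_lines) == toy_topology.n_beads + 3
        top_text = top_path.read_text()
        bonds = [ln for ln in top_text.split("[ bonds ]")[1]
                 .split("[")[0].splitlines() if ln.strip()]
        assert len(bonds) == toy_topology.n_beads - 1

    def test_unknown_format_rejected(self, toy_topology, tmp_path):
        with pytest.raises(ValueError):
            export_topology(toy_topology, tmp_path / "x", format="amber")
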