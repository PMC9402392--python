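"""Reaction coordinates, Boltzmann-inversion PMFs, hysteretic state
assignment, salt bridges and the ε_CS tuning protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostate_sbm.cg_dynamics import KB, IntegratorParams
from twostate_sbm.sbm_builder import ModelParams
from twostate_sbm.structure_io import StructureError, ca_distance
from twostate_sbm.synthetic_data import make_rc_series, make_salt_bridge_fixture
from twostate_sbm.transition_analysis import (
    CLOSED,
    INTERMEDIATE,
    OPEN,
    RCSeries,
    TuningError,
    assign_states,
    basin_populations,
    count_transitions,
    fraction_formed,
    load_all_atom_frames,
    pmf,
    rc_series,
    salt_bridge_series,
    transition_stats,
    tune_epsilon_cs,
)


class TestRCSeries:
    def test_static_trajectory_constant_series(self, toy):
        frames = np.repeat(toy.open.ca_coords()[None], 5, axis=0)
        s = rc_series(frames, toy.open.auth_ids, *toy.rc_pair)
        native = ca_distance(toy.open, *toy.rc_pair)
        np.testing.assert_allclose(s.values, native)

    def test_planted_distances_recovered_exactly(self, rng):
        auth_ids = [1, 2, 3]
        planted = rng.uniform(0.5, 2.5, size=20)
        frames = np.zeros((20, 3, 3))
        frames[:, 2, 0] = planted
        s = rc_series(frames, auth_ids, 1, 3)
        np.testing.assert_allclose(s.values, planted, atol=1e-12)

    def test_missing_residue_raises(self, toy):
        with pytest.raises(KeyError):
            rc_series(np.zeros((1, len(toy.open), 3)), toy.open.auth_ids,
                      1, 10_000)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            RCSeries(np.array([1.0, -0.2]), np.arange(2))


class TestPmf:
    def test_uniform_series_is_flat(self, rng):
        n = 200_000
        s = rng.uniform(1.0, 2.0, n)
        profile = pmf(s, temperature=100.0, n_bins=20)
        p = 1.0 / 20
        # 3-sigma binomial bound propagated through -kT ln p
        bound = 3 * KB * 100.0 * np.sqrt((1 - p) / (n * p))
        assert profile.f.max() < 2 * bound

    def test_two_state_depth_difference_matches_planted_weights(self):
        series, _ = make_rc_series((0.8, 2.0), widths=(0.05, 0.05),
                                   weights=(0.7, 0.3), n=100_000, seed=4)
        profile = pmf(series, temperature=100.0, n_bins=60)
        kbt = KB * 100.0
        # F at each basin minimum; widths equal, so ΔF = -kBT ln(w2/w1)
        lo = profile.f[np.abs(profile.bin_centers - 0.8) < 0.15].min()
        hi = profile.f[np.abs(profile.bin_centers - 2.0) < 0.15].min()
        expected = -kbt * np.log(0.3 / 0.7)
        assert hi - lo == pytest.approx(expected, abs=0.15 * kbt * 3)

    def test_depth_difference_invariant_to_binning(self):
        series, _ = make_rc_series((0.8, 2.0), widths=(0.08, 0.08),
                                   weights=(0.5, 0.5), n=100_000, seed=8)
        deltas = []
        for n_bins in (20, 40, 80):
            profile = pmf(series, temperature=100.0, n_bins=n_bins)
            lo = profile.f[np.abs(profile.bin_centers - 0.8) < 0.2].min()
            hi = profile.f[np.abs(profile.bin_centers - 2.0) < 0.2].min()
            deltas.append(hi - lo)
        assert max(deltas) - min(deltas) < 0.3

    def test_min_shift_exact_and_empty_bins_dropped(self, rng):
        s = np.concatenate([rng.normal(1.0, 0.01, 500),
                            rng.normal(3.0, 0.01, 500)])
        profile = pmf(s, temperature=100.0, n_bins=50)
        assert profile.f.min() == 0.0
        assert (profile.counts > 0).all()

    def test_single_bin_warns(self):
        with pytest.warns(UserWarning, match="single bin"):
            pmf(np.full(100, 1.0), temperature=100.0, n_bins=10)


class TestStateAssignment:
    def test_alternating_series_counts_all_switches(self):
        series = np.array([2.3, 0.8] * 5)
        labels = assign_states(series, 1.8, 1.0)
        assert count_transitions(labels) == 9

    def test_series_inside_window_is_intermediate(self):
        labels = assign_states(np.full(50, 1.4), 1.8, 1.0)
        assert (labels == INTERMEDIATE).all()
        assert count_transitions(labels) == 0

    def test_hysteresis_keeps_previous_state(self):
        series = np.array([2.0, 1.5, 1.5, 0.9, 1.5, 2.0])
        labels = assign_states(series, 1.8, 1.0)
        np.testing.assert_array_equal(
            labels, [OPEN, OPEN, OPEN, CLOSED, CLOSED, OPEN])
        assert count_transitions(labels) == 2

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_bruteforce_automaton_replay(self, seed):
        rng = np.random.default_rng(seed)
        series = np.abs(np.cumsum(rng.normal(0, 0.2, 300)) + 1.4) + 0.05
        labels = assign_states(series, 1.8, 1.0)
        state, replay = INTERMEDIATE, []
        for d in series:
            if d > 1.8:
                state = OPEN
            elif d < 1.0:
                state = CLOSED
            replay.append(state)
        np.testing.assert_array_equal(labels, replay)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            assign_states(np.ones(3), 1.0, 1.8)

    def test_transition_count_invariant_under_reversal(self, rng):
        series = np.abs(np.cumsum(rng.normal(0, 0.3, 500))) + 0.5
        fwd = count_transitions(assign_states(series, 1.8, 1.0))
        rev = count_transitions(assign_states(series[::-1], 1.8, 1.0))
        assert fwd == rev

    def test_populations(self):
        labels = np.array([OPEN, OPEN, CLOSED, OPEN, INTERMEDIATE])
        pops = basin_populations(labels)
        assert pops == {"open": 0.75, "closed": 0.25}
        assert count_transitions(labels) == 2
        assert basin_populations(np.array([OPEN] * 4)) == {"open": 1.0,
                                                           "closed": 0.0}


class TestSaltBridge:
    def test_planted_distance_and_formation(self):
        frames = make_salt_bridge_fixture([0.35])
        series = salt_bridge_series(frames, 10, 20)
        assert series[0] == pytest.approx(0.35, abs=1e-3)
        assert fraction_formed(series, cutoff=0.5) == 1.0

    def test_beyond_cutoff_not_formed(self):
        series = salt_bridge_series(make_salt_bridge_fixture([0.6]), 10, 20)
        assert fraction_formed(series, cutoff=0.5) == 0.0

    def test_matches_bruteforce_all_pairs_minimum(self):
        frames = make_salt_bridge_fixture([0.42, 0.55, 0.91])
        series = salt_bridge_series(frames, 10, 20)
        for t, s in enumerate(frames):
            asp, lys = s.residue(10), s.residue(20)
            brute = min(
                np.linalg.norm(o.position - n.position)
                for o in asp.atoms if o.name in ("OD1", "OD2")
                for n in lys.atoms if n.name == "NZ")
            assert series[t] == pytest.approx(brute, abs=1e-12)

    def test_argument_order_symmetric(self):
        frames = make_salt_bridge_fixture([0.4, 0.7])
        np.testing.assert_allclose(salt_bridge_series(frames, 10, 20),
                                   salt_bridge_series(frames, 20, 10))

    def test_calpha_only_input_refused(self, toy):
        with pytest.raises(StructureError, match="acidic"):
            salt_bridge_series([toy.open], 1, 5)

    def test_missing_sidechain_atoms_named(self):
        frames = make_salt_bridge_fixture([0.4])
        frames[0].residue(20).atoms = [
            a for a in frames[0].residue(20).atoms if a.name != "NZ"]
        with pytest.raises(StructureError, match="NZ"):
            salt_bridge_series(frames, 10, 20)


class TestAllAtomIngestion:
    def _write_multimodel(self, frames, path, tmp_path):
        from twostate_sbm.structure_io import write_structure

        blocks = []
        for m, frame in enumerate(frames, 1):
            tmp = tmp_path / f"_f{m}.pdb"
            write_structure(frame, tmp)
            atoms = [ln for ln in tmp.read_text().splitlines()
                     if ln.startswith(("ATOM", "HETATM"))]
            blocks.append(f"MODEL     {m:4d}\n" + "\n".join(atoms) + "\nENDMDL")
        path.write_text("\n".join(blocks) + "\nEND\n")

    def test_multimodel_pdb_roundtrip_preserves_salt_bridge(self, tmp_path):
        schedule = [0.4, 0.75]
        frames = make_salt_bridge_fixture(schedule)
        path = tmp_path / "traj.pdb"
        self._write_multimodel(frames, path, tmp_path)
        loaded = load_all_atom_frames(path)
        assert len(loaded) == 2
        series = salt_bridge_series(loaded, 10, 20)
        np.testing.assert_allclose(series, schedule, atol=2e-3)

    def test_xtc_with_topology(self, tmp_path):
        import mdtraj.formats as fmts

        from twostate_sbm.structure_io import write_structure

        schedule = [0.45, 0.6, 0.9]
        frames = make_salt_bridge_fixture(schedule)
        top_pdb = tmp_path / "top.pdb"
        write_structure(frames[0], top_pdb)
        coords = np.array([[a.position for r in f.residues for a in r.atoms]
                           for f in frames], dtype=np.float32)
        xtc = tmp_path / "traj.xtc"
        with fmts.XTCTrajectoryFile(str(xtc), "w") as fh:
            fh.write(coords)
        loaded = load_all_atom_frames(xtc, topology_path=top_pdb)
        series = salt_bridge_series(loaded, 10, 20)
        np.testing.assert_allclose(series, schedule, atol=2e-3)

    def test_binary_without_topology_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="topology"):
            load_all_atom_frames(tmp_path / "x.xtc")


class TestTuneEpsilonCs:
    def test_degenerate_criteria_accept_first_point(self, toy):
        base = ModelParams(eps_os=1.0, cth_range=toy.cth_range)
        p = IntegratorParams(n_steps=2000, save_every=1000, seed=0)
        res = tune_epsilon_cs(toy.open, toy.contacts, base, p,
                              [0.5, 0.8, 1.1], toy.rc_pair, 1.57, 1.2,
                              min_transitions=0, population_window=(0.0, 1.0))
        assert res.eps_cs == 0.5
        assert res.report[0]["qualifies"]

    def test_unreachable_criteria_raise_with_report(self, toy):
        base = ModelParams(eps_os=1.0, cth_range=toy.cth_range)
        p = IntegratorParams(n_steps=2000, save_every=1000, seed=0)
        with pytest.raises(TuningError) as err:
            tune_epsilon_cs(toy.open, toy.contacts, base, p, [0.5, 0.8],
                            toy.rc_pair, 1.57, 1.2, min_transitions=999)
        assert len(err.value.report) == 2
        assert all("n_transitions" in row for row in err.value.report)

    def test_grid_must_ascend(self, toy):
        with pytest.raises(ValueError):
            tune_epsilon_cs(toy.open, toy.contacts, ModelParams(),
                            IntegratorParams(n_steps=100), [1.0, 0.5],
                            toy.rc_pair, 1.57, 1.2)


def test_transition_stats_bundles_everything():
    series = np.array([2.3, 0.8, 2.3, 1.4])
    stats = transition_stats(series, 1.8, 1.0)
    assert stats.n_transitions == 2
    assert stats.populations["open"] == pytest.approx(3 / 4)
    assert stats.open_threshold == 1.8
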