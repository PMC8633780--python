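import numpy as np
import pytest
from scipy.spatial.distance import pdist

from flexor.enm import build_enm, lowest_modes, trivial_modes
from flexor.fixtures import ideal_peptide
from flexor.geosim import (
    ConstraintTargets,
    Ensemble,
    GeoSimConfig,
    constraint_targets,
    max_violation,
    project_mode,
    relax_geometry,
    run_geosim,
)
from flexor.interactions import build_network


@pytest.fixture(scope="module")
def dimer_system(dimer_h):
    enm_net = build_enm(dimer_h)
    net = build_network(dimer_h, cutoff=-4.0)
    return dimer_h, enm_net, net


def _bare_targets(eq_pairs, eq_targets, n_atoms):
    return ConstraintTargets(
        eq_pairs=np.array(eq_pairs, dtype=int).reshape(-1, 2),
        eq_targets=np.array(eq_targets, dtype=float),
        ub_pairs=np.empty((0, 2), dtype=int),
        ub_targets=np.empty(0),
        excluded={(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)},
        radii=np.full(n_atoms, 1.7),
        steric_factor=0.85,
    )


class TestConstraintTargets:
    def test_peptide_bond_is_equality_at_crystal_value(self):
        s = ideal_peptide(["ALA", "ALA"])
        net = build_network(s, cutoff=-4.0)
        targets = constraint_targets(s, net)
        index = s.atom_index()
        ci = index[("A", 1, "", "C")]
        nj = index[("A", 2, "", "N")]
        pair = (min(ci, nj), max(ci, nj))
        row = np.where((targets.eq_pairs == pair).all(axis=1))[0]
        assert len(row) == 1
        d = np.linalg.norm(s.atoms[ci].position - s.atoms[nj].position)
        assert targets.eq_targets[row[0]] == pytest.approx(d, abs=1e-12)

    def test_covalent_pairs_excluded_from_sterics(self, dimer_system):
        s, _, net = dimer_system
        targets = constraint_targets(s, net)
        for c in net.constraints:
            pair = (min(c.atom_i, c.atom_j), max(c.atom_i, c.atom_j))
            assert pair in targets.excluded

    def test_tether_pair_gets_upper_bound_at_crystal_distance(self, dimer_system):
        s, _, net = dimer_system
        targets = constraint_targets(s, net)
        tether = net.by_kind("tether")[0]
        pair = (min(tether.atom_i, tether.atom_j),
                max(tether.atom_i, tether.atom_j))
        row = np.where((targets.ub_pairs == pair).all(axis=1))[0]
        assert len(row) == 1
        assert targets.ub_targets[row[0]] == pytest.approx(tether.distance,
                                                           abs=1e-9)

    def test_input_structure_satisfies_its_own_targets(self, dimer_system):
        s, _, net = dimer_system
        targets = constraint_targets(s, net)
        assert max_violation(s.coord_array(), targets) <= 1e-9


class TestRelaxGeometry:
    def test_satisfied_input_returned_unchanged_zero_sweeps(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        targets = _bare_targets([[0, 1]], [1.5], 2)
        out, sweeps, worst = relax_geometry(coords, targets)
        assert sweeps == 0
        np.testing.assert_array_equal(out, coords)
        assert worst == 0.0

    def test_single_stretched_bond_one_sweep_split_correction(self):
        coords = np.array([[0.0, 0, 0], [1.8, 0, 0]])
        targets = _bare_targets([[0, 1]], [1.5], 2)
        out, sweeps, worst = relax_geometry(coords, targets)
        assert sweeps == 1
        assert worst <= 0.1
        np.testing.assert_allclose(out[0], [0.15, 0, 0], atol=1e-12)
        np.testing.assert_allclose(out[1], [1.65, 0, 0], atol=1e-12)

    def test_contradictory_targets_flagged_unrestorable(self):
        # triangle violating the triangle inequality can never satisfy all
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0.5]])
        targets = _bare_targets([[0, 1], [1, 2], [0, 2]], [1.0, 1.0, 5.0], 3)
        _, _, worst = relax_geometry(coords, targets)
        assert worst > 0.1


class TestProjectMode:
    def test_translation_mode_moves_every_atom_identically(self, dimer_system):
        s, enm_net, _ = dimer_system
        tmode = trivial_modes(enm_net)[0]
        bias = project_mode(tmode, s, enm_net, step_scale=0.1)
        assert np.abs(bias - bias[0]).max() < 1e-12

    def test_bias_norm_equals_step_scale(self, dimer_system):
        s, enm_net, _ = dimer_system
        mode = lowest_modes(enm_net, 1)[0]
        bias = project_mode(mode, s, enm_net, step_scale=0.1)
        assert np.linalg.norm(bias) == pytest.approx(0.1, abs=1e-12)

    def test_antiparallel_is_negated(self, dimer_system):
        s, enm_net, _ = dimer_system
        mode = lowest_modes(enm_net, 1)[0]
        fwd = project_mode(mode, s, enm_net, direction="parallel")
        bwd = project_mode(mode, s, enm_net, direction="antiparallel")
        np.testing.assert_array_equal(bwd, -fwd)


class TestRunGeosim:
    def test_translation_run_displaces_50A_conserving_geometry(self, dimer_system):
        s, enm_net, net = dimer_system
        tmode = trivial_modes(enm_net)[0]
        ens = run_geosim(s, tmode, GeoSimConfig(), enm_net=enm_net, net=net)
        assert ens.steps_completed == 500
        assert ens.halt_reason == "max_steps"
        assert len(ens.frames) == 11  # frame 0 + every 50th step
        disp = ens.frames[-1] - ens.frames[0]
        assert np.linalg.norm(disp) == pytest.approx(50.0, abs=1e-9)
        assert np.abs(pdist(ens.frames[-1]) - pdist(ens.frames[0])).max() < 1e-9

    def test_every_frame_within_tolerance(self, dimer_system):
        s, enm_net, net = dimer_system
        mode = lowest_modes(enm_net, 1)[0]
        cfg = GeoSimConfig(max_steps=150, frame_interval=25)
        ens = run_geosim(s, mode, cfg, enm_net=enm_net, net=net)
        targets = constraint_targets(s, net)
        for frame in ens.frames:
            assert max_violation(frame, targets) <= cfg.tolerance

    def test_bit_deterministic(self, dimer_system):
        s, enm_net, net = dimer_system
        mode = lowest_modes(enm_net, 1)[0]
        cfg = GeoSimConfig(max_steps=60, frame_interval=20)
        a = run_geosim(s, mode, cfg, enm_net=enm_net, net=net)
        b = run_geosim(s, mode, cfg, enm_net=enm_net, net=net)
        assert len(a.frames) == len(b.frames)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_frame_count_contract(self, dimer_system):
        s, enm_net, net = dimer_system
        mode = lowest_modes(enm_net, 1)[0]
        cfg = GeoSimConfig(max_steps=90, frame_interval=20)
        ens = run_geosim(s, mode, cfg, enm_net=enm_net, net=net)
        assert ens.steps_completed <= cfg.max_steps
        assert len(ens.frames) == ens.steps_completed // cfg.frame_interval + 1

    def test_run_log_fields(self, dimer_system):
        s, enm_net, net = dimer_system
        mode = lowest_modes(enm_net, 1)[0]
        cfg = GeoSimConfig(max_steps=40, frame_interval=40,
                           direction="antiparallel")
        ens = run_geosim(s, mode, cfg, enm_net=enm_net, net=net)
        log = ens.run_log()
        assert log["mode_index"] == 7
        assert log["direction"] == "antiparallel"
        assert log["halt_reason"] in ("max_steps", "geometry_unrestorable")
        assert len(log["frame_max_violation"]) == log["n_frames"]


def test_config_validation():
    with pytest.raises(ValueError):
        GeoSimConfig(step_scale=-0.1)
    with pytest.raises(ValueError):
        GeoSimConfig(frame_interval=600, max_steps=500)


def test_ensemble_write_roundtrip(tmp_path, dimer_system):
    s, enm_net, net = dimer_system
    mode = lowest_modes(enm_net, 1)[0]
    cfg = GeoSimConfig(max_steps=20, frame_interval=10)
    ens = run_geosim(s, mode, cfg, enm_net=enm_net, net=net)
    path = tmp_path / "ens.pdb"
    ens.write(path)
    from flexor.structure_io import read_ensemble
    frames = read_ensemble(path)
    assert len(frames) == len(ens.frames)
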