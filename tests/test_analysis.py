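import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flexor._geometry import rotation_about_axis
from flexor.analysis import (
    bfactor_profile,
    composition_census,
    interface_area,
    kabsch_rmsd,
    paired_ca_coords,
    rmsf,
    sasa,
    total_sasa,
)
from flexor.fixtures import ideal_helix, noisy_ensemble
from flexor.structure_io import AtomRecord, RegionSelection, Structure


def _atoms(specs):
    s = Structure(title="mini")
    for k, (name, element, resname, chain, resnum, xyz) in enumerate(specs):
        s.atoms.append(AtomRecord(
            serial=k + 1, name=name, element=element, alt_loc="",
            residue_name=resname, chain_id=chain, residue_number=resnum,
            insertion_code="", position=np.array(xyz, dtype=float)))
    return s


class TestKabschRmsd:
    def test_identical_coordinates_zero(self, helix20):
        c = helix20.coord_array()
        assert kabsch_rmsd(c, c) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_rigid_transform(self, helix20):
        c = helix20.coord_array()
        rot = Rotation.from_euler("xyz", [90, 0, 30], degrees=True)
        assert kabsch_rmsd(c, rot.apply(c) + [10, -4, 2]) == pytest.approx(
            0.0, abs=1e-8)

    def test_symmetric(self, helix20):
        rng = np.random.default_rng(0)
        a = helix20.coord_array()
        b = a + rng.normal(0, 0.3, a.shape)
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-10)

    def test_dimer_chains_near_identical(self, dimer):
        a, b = paired_ca_coords(dimer, "A", "B")
        # chains differ only by the 0.005 A jitter and sequence differences
        assert kabsch_rmsd(a, b) < 0.05

    def test_length_mismatch_reported(self):
        with pytest.raises(ValueError, match="pair"):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestRmsf:
    def test_identical_frames_zero(self, helix20):
        ens = noisy_ensemble(helix20, 0.0, 5, seed=0)
        assert rmsf(ens).rmsf.max() == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_atom_closed_form(self, helix20):
        base = helix20.coord_array()
        f2 = base.copy()
        ca_idx = [i for i, a in enumerate(helix20.atoms) if a.name == "CA"]
        f2[ca_idx[10]] += [2.0, 0, 0]  # one CA displaced by 2d with d = 1
        from flexor.geosim import Ensemble
        ens = Ensemble(structure=helix20, frames=[base, f2],
                       steps_completed=0, halt_reason="max_steps")
        stats = rmsf(ens, superpose=False)
        assert stats.rmsf[10] == pytest.approx(1.0, abs=1e-12)
        others = np.delete(stats.rmsf, 10)
        assert others.max() == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_noise_matches_closed_form(self, helix20):
        sigma, n = 0.5, 1000
        ens = noisy_ensemble(helix20, sigma, n, seed=1)
        stats = rmsf(ens, superpose=False)
        expected = sigma * np.sqrt(3.0 * (n - 1) / n)
        assert stats.rmsf.mean() == pytest.approx(expected, rel=0.05)

    def test_invariant_under_global_rigid_transform(self, helix20):
        ens = noisy_ensemble(helix20, 0.3, 20, seed=2)
        ref = rmsf(ens).rmsf
        rot = rotation_about_axis(np.array([0.0, 1.0, 1.0]), 45.0)
        from flexor.geosim import Ensemble
        moved = Ensemble(structure=helix20,
                         frames=[f @ rot.T + [7, 8, 9] for f in ens.frames],
                         steps_completed=0, halt_reason="max_steps")
        np.testing.assert_allclose(rmsf(moved).rmsf, ref, atol=1e-9)

    def test_single_frame_rejected(self, helix20):
        ens = noisy_ensemble(helix20, 0.1, 1, seed=0)
        with pytest.raises(ValueError):
            rmsf(ens)


class TestBFactorProfile:
    def test_uniform_bfactors_fold_one(self):
        s = ideal_helix(20, b_factors=[10.0] * 20)
        prof = bfactor_profile(s, RegionSelection("A", 1, 20))
        assert prof.normalized_fold == pytest.approx(1.0, abs=1e-12)

    def test_hot_region_fold(self):
        b = [10.0] * 20
        for i in range(5, 10):
            b[i] = 30.0
        s = ideal_helix(20, b_factors=b)
        prof = bfactor_profile(s, RegionSelection("A", 6, 10))
        assert prof.overall_mean == pytest.approx(15.0)
        assert prof.region_mean == pytest.approx(30.0)
        assert prof.normalized_fold == pytest.approx(2.0)

    def test_empty_region_raises(self, helix20):
        with pytest.raises(ValueError):
            bfactor_profile(helix20, RegionSelection("Z", 1, 5))


class TestSasa:
    def test_isolated_atom_sphere_area(self):
        s = _atoms([("C", "C", "ALA", "A", 1, (0, 0, 0))])
        area = sasa(s)[0]
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_far_separated_atoms_additive(self):
        s = _atoms([("C", "C", "ALA", "A", 1, (0, 0, 0)),
                    ("S", "S", "MET", "A", 9, (50, 0, 0))])
        areas = sasa(s)
        expected = 4 * np.pi * np.array([(1.7 + 1.4) ** 2, (1.8 + 1.4) ** 2])
        np.testing.assert_allclose(areas, expected, rtol=0.01)

    def test_buried_atom_zero(self):
        # central atom caged by a shell of neighbours: no probe access
        import flexor.analysis as an
        shell = []
        golden = np.pi * (3 - np.sqrt(5))
        for k in range(32):
            z = 1 - 2 * (k + 0.5) / 32
            r = np.sqrt(1 - z * z)
            th = golden * k
            shell.append(3.2 * np.array([r * np.cos(th), r * np.sin(th), z]))
        specs = [("C", "C", "ALA", "A", 1, (0.0, 0, 0))]
        specs += [("C", "C", "ALA", "A", 2 + k, tuple(p))
                  for k, p in enumerate(shell)]
        s = _atoms(specs)
        assert an.sasa(s)[0] == pytest.approx(0.0, abs=1e-9)

    def test_sampling_convergence(self, helix20):
        full = total_sasa(helix20, samples_per_atom=960)
        half = total_sasa(helix20, samples_per_atom=480)
        assert abs(full - half) / full < 0.005

    def test_unknown_element_listed(self):
        s = _atoms([("FE", "FE", "HEM", "A", 1, (0, 0, 0))])
        with pytest.raises(ValueError, match="FE"):
            sasa(s)


class TestInterfaceArea:
    def test_disjoint_chains_zero(self):
        s = _atoms([("CA", "C", "ALA", "A", 1, (0, 0, 0)),
                    ("CA", "C", "ALA", "B", 1, (60, 0, 0))])
        assert interface_area(s, "A", "B") == pytest.approx(0.0, abs=1.0)

    def test_symmetric_and_positive_for_dimer(self, dimer):
        ab = interface_area(dimer, "A", "B")
        ba = interface_area(dimer, "B", "A")
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab > 50.0

    def test_missing_chain_raises(self, dimer):
        with pytest.raises(ValueError):
            interface_area(dimer, "A", "Z")


class TestCompositionCensus:
    def test_polyala(self):
        c = composition_census(["ALA"] * 20)
        assert c["counts"] == {"ALA": 20}
        assert c["fraction_charged"] == 0.0

    def test_dimer_chains(self, dimer):
        a = composition_census(dimer, "A")
        assert a["acidic"] == 1 and a["basic_kr"] == 0
        b = composition_census(dimer, "B")
        assert b["acidic"] == 0 and b["basic_kr"] == 1
        assert a["source"] == "seqres"

    def test_seqres_counts_dominate_observed(self, dimer):
        truncated = dimer.copy()
        truncated.atoms = [a for a in truncated.atoms
                           if not (a.chain_id == "A" and a.residue_number <= 2)]
        seqres = composition_census(truncated, "A", sequence_source="seqres")
        observed = composition_census(truncated, "A",
                                      sequence_source="observed")
        for res, n_obs in observed["counts"].items():
            assert seqres["counts"].get(res, 0) >= n_obs
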