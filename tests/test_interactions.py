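import numpy as np
import pytest

from flexor._geometry import rotation_about_axis
from flexor.fixtures import ideal_peptide, two_helix_dimer
from flexor.interactions import (
    KIND_COVALENT_LOCKED,
    KIND_COVALENT_ROTATABLE,
    InteractionParams,
    build_network,
    count_salt_bridges,
    detect_covalent,
    detect_polar,
    detect_tethers,
    mayo_energy,
    read_constraints_tsv,
    write_constraints_tsv,
)
from flexor.structure_io import AtomRecord, Structure, add_polar_hydrogens


def _mini_structure(atom_specs):
    """Structure from (name, element, resname, chain, resnum, xyz) tuples."""
    s = Structure(title="mini")
    for k, (name, element, resname, chain, resnum, xyz) in enumerate(atom_specs):
        s.atoms.append(AtomRecord(
            serial=k + 1, name=name, element=element, alt_loc="",
            residue_name=resname, chain_id=chain, residue_number=resnum,
            insertion_code="", position=np.array(xyz, dtype=float)))
    return s


class TestCovalent:
    def test_dialanine_has_one_locked_peptide_bond(self):
        s = ideal_peptide(["ALA", "ALA"])
        cov = detect_covalent(s)
        peptide = [c for c in cov
                   if {s.atoms[c.atom_i].name, s.atoms[c.atom_j].name} == {"C", "N"}
                   and s.atoms[c.atom_i].residue_number
                   != s.atoms[c.atom_j].residue_number]
        assert len(peptide) == 1
        assert peptide[0].kind == KIND_COVALENT_LOCKED

    def test_phe_ring_bonds_all_locked(self):
        s = ideal_peptide(["ALA", "PHE", "ALA", "ALA"])
        cov = detect_covalent(s)
        ring = {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
        ring_bonds = [c for c in cov
                      if s.atoms[c.atom_i].name in ring
                      and s.atoms[c.atom_j].name in ring]
        assert len(ring_bonds) == 6
        assert all(c.kind == KIND_COVALENT_LOCKED for c in ring_bonds)

    def test_disulfide_detected_at_2_05(self):
        s = _mini_structure([
            ("CB", "C", "CYS", "A", 1, (0, 0, 0)),
            ("SG", "S", "CYS", "A", 1, (1.8, 0, 0)),
            ("CB", "C", "CYS", "A", 10, (5.65, 0, 0)),
            ("SG", "S", "CYS", "A", 10, (3.85, 0, 0)),
        ])
        cov = detect_covalent(s)
        ss = [c for c in cov if s.atoms[c.atom_i].name == "SG"
              and s.atoms[c.atom_j].name == "SG"]
        assert len(ss) == 1
        assert ss[0].kind == KIND_COVALENT_ROTATABLE

    def test_hydrogens_locked_to_parent(self, helix20_h):
        cov = detect_covalent(helix20_h)
        h_bonds = [c for c in cov
                   if "H" in (helix20_h.atoms[c.atom_i].element,
                              helix20_h.atoms[c.atom_j].element)]
        assert len(h_bonds) == 19
        assert all(c.kind == KIND_COVALENT_LOCKED for c in h_bonds)


class TestTethers:
    def test_helix_backbone_has_no_tethers(self, helix20):
        assert detect_tethers(helix20) == []

    def test_far_cb_pair_not_tethered(self):
        s = _mini_structure([
            ("CB", "C", "ALA", "A", 1, (0, 0, 0)),
            ("CB", "C", "ALA", "A", 9, (6.0, 0, 0)),
        ])
        assert detect_tethers(s) == []

    def test_shortest_contact_rule_single_tether_per_pair(self):
        # two Leu side chains with several C..C contacts: only closest kept
        s = _mini_structure([
            ("CD1", "C", "LEU", "A", 1, (0, 0, 0)),
            ("CD2", "C", "LEU", "A", 1, (0.8, 1.2, 0)),
            ("CD1", "C", "LEU", "A", 9, (3.8, 0, 0)),
            ("CD2", "C", "LEU", "A", 9, (3.6, 1.2, 0)),
        ])
        teth = detect_tethers(s)
        assert len(teth) == 1
        assert teth[0].distance == pytest.approx(
            np.linalg.norm([3.6 - 0.8, 0, 0]), abs=1e-6)

    def test_sequence_separation_gate(self):
        s = _mini_structure([
            ("CB", "C", "ALA", "A", 1, (0, 0, 0)),
            ("CB", "C", "ALA", "A", 3, (3.5, 0, 0)),
        ])
        assert detect_tethers(s) == []  # |i-j| = 2 is excluded
        s2 = _mini_structure([
            ("CB", "C", "ALA", "A", 1, (0, 0, 0)),
            ("CB", "C", "ALA", "B", 1, (3.5, 0, 0)),
        ])
        assert len(detect_tethers(s2)) == 1  # different chains always eligible

    def test_rigid_motion_invariance(self, dimer_h):
        base = detect_tethers(dimer_h)
        moved = dimer_h.copy()
        rot = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 37.0)
        moved.set_coords(dimer_h.coord_array() @ rot.T + np.array([5, -3, 11.0]))
        after = detect_tethers(moved)
        assert [(c.atom_i, c.atom_j) for c in base] == \
            [(c.atom_i, c.atom_j) for c in after]


class TestPolar:
    def test_mayo_well_minimum(self):
        p = InteractionParams()
        assert mayo_energy(2.8, 180.0, p) == pytest.approx(-8.0, abs=1e-12)

    def test_energy_clamped_to_floor(self):
        p = InteractionParams()
        assert mayo_energy(2.8, 180.0,
                           InteractionParams(mayo_well_depth=15.0)) == -10.0
        assert mayo_energy(1.5, 180.0, p) == 0.0  # repulsive region clamps to 0

    def test_helix_ladder_detected(self, helix20_h):
        polar = detect_polar(helix20_h)
        assert len(polar) >= 16
        backbone = [c for c in polar
                    if helix20_h.atoms[c.atom_i].name == "O"
                    and helix20_h.atoms[c.atom_j].name == "N"
                    or helix20_h.atoms[c.atom_i].name == "N"
                    and helix20_h.atoms[c.atom_j].name == "O"]
        assert len(backbone) >= 16
        offsets = {abs(helix20_h.atoms[c.atom_i].residue_number
                       - helix20_h.atoms[c.atom_j].residue_number)
                   for c in backbone}
        assert offsets == {4}

    def test_donor_acceptor_distance_gate(self):
        # linear N-H...O at donor-acceptor 3.7 A: outside the gate
        s = _mini_structure([
            ("N", "N", "ALA", "A", 1, (0, 0, 0)),
            ("H", "H", "ALA", "A", 1, (1.0, 0, 0)),
            ("O", "O", "ALA", "A", 9, (3.7, 0, 0)),
        ])
        assert detect_polar(s) == []

    def test_ideal_linear_geometry_scores_well_depth(self):
        s = _mini_structure([
            ("N", "N", "ALA", "A", 1, (0, 0, 0)),
            ("H", "H", "ALA", "A", 1, (1.0, 0, 0)),
            ("O", "O", "ALA", "A", 9, (2.8, 0, 0)),
        ])
        polar = detect_polar(s)
        assert len(polar) == 1
        assert polar[0].energy == pytest.approx(-8.0, abs=1e-9)

    def test_salt_bridge_pinned_energy(self, dimer_h):
        polar = detect_polar(dimer_h)
        sb = [c for c in polar if c.is_salt_bridge]
        assert len(sb) == 1
        assert sb[0].energy == -10.0
        names = {dimer_h.atoms[sb[0].atom_i].name,
                 dimer_h.atoms[sb[0].atom_j].name}
        assert names <= {"OD1", "OD2", "NZ"}


class TestSaltBridgeCensus:
    def test_pair_inside_cutoff_counts_once(self):
        s = _mini_structure([
            ("OD1", "O", "ASP", "A", 1, (0, 0, 0)),
            ("OD2", "O", "ASP", "A", 1, (1.0, 1.0, 0)),
            ("NZ", "N", "LYS", "A", 9, (3.0, 0, 0)),
        ])
        assert count_salt_bridges(s) == 1

    def test_pair_outside_cutoff(self):
        s = _mini_structure([
            ("OD1", "O", "ASP", "A", 1, (0, 0, 0)),
            ("NZ", "N", "LYS", "A", 9, (4.5, 0, 0)),
        ])
        assert count_salt_bridges(s) == 0
        assert count_salt_bridges(s, cutoff=5.0) == 1

    def test_selection_restricts_both_residues(self, dimer_h):
        # the only salt bridge is inter-chain
        assert count_salt_bridges(dimer_h) == 1
        assert count_salt_bridges(dimer_h, "A") == 0
        assert count_salt_bridges(dimer_h, "B") == 0

    def test_histidine_counts_as_basic(self):
        s = _mini_structure([
            ("OE1", "O", "GLU", "A", 1, (0, 0, 0)),
            ("NE2", "N", "HIS", "A", 9, (3.2, 0, 0)),
        ])
        assert count_salt_bridges(s) == 1


class TestNetwork:
    def test_polar_filter_is_monotone(self, dimer_h):
        weak = build_network(dimer_h, cutoff=-1.0)
        strong = build_network(dimer_h, cutoff=-4.0)
        weak_pairs = {c.pair() for c in weak.by_kind("polar")}
        strong_pairs = {c.pair() for c in strong.by_kind("polar")}
        assert strong_pairs <= weak_pairs

    def test_polar_count_non_increasing_over_cutoffs(self, dimer_h):
        counts = [len(build_network(dimer_h, cutoff=c).by_kind("polar"))
                  for c in (-0.0, -2.0, -4.0, -6.0, -8.0, -10.0)]
        assert counts == sorted(counts, reverse=True)

    def test_bar_assignment_per_regime(self, dimer_h):
        for regime, tb in (("ambient", 2), ("cold", 1)):
            net = build_network(dimer_h, cutoff=-1.0, regime=regime)
            bars = {c.kind: c.bars for c in net.constraints}
            assert bars["covalent_locked"] == 6
            assert bars["covalent_rotatable"] == 5
            assert bars["polar"] == 5
            assert all(c.bars == tb for c in net.by_kind("tether"))

    def test_every_polar_respects_cutoff(self, dimer_h):
        net = build_network(dimer_h, cutoff=-4.0)
        assert all(c.energy <= -4.0 for c in net.by_kind("polar"))

    def test_no_polar_atoms_degenerate(self):
        s = _mini_structure([
            ("CB", "C", "ALA", "A", 1, (0, 0, 0)),
            ("CB", "C", "ALA", "A", 9, (3.5, 0, 0)),
        ])
        for cutoff in (-0.0, -5.0):
            net = build_network(s, cutoff=cutoff)
            assert {c.kind for c in net.constraints} == {"tether"}

    def test_positive_cutoff_rejected(self, dimer_h):
        with pytest.raises(ValueError):
            build_network(dimer_h, cutoff=1.0)

    def test_constraints_tsv_roundtrip(self, tmp_path, dimer_h):
        net = build_network(dimer_h, cutoff=-1.0)
        path = tmp_path / "constraints.tsv"
        write_constraints_tsv(dimer_h, net.constraints, path)
        back = read_constraints_tsv(dimer_h, path)
        assert [(c.kind, c.pair(), c.bars) for c in back] == \
            [(c.kind, c.pair(), c.bars) for c in net.constraints]
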