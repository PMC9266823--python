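"""Distance descriptors: d_SB, interfaces, H-bonds, bridges, turns, Kabsch."""

import numpy as np
import pytest

from conftest import random_rigid_motion
from sstbind import synthetic_data as sd
from sstbind.geometry import (
    DsbSpec,
    beta_turns,
    dsb,
    hbonds,
    interface_residues,
    kabsch_superpose,
    salt_bridges,
    water_bridges,
)
from sstbind.structio import Atom, Complex, SelectionError, Structure, select


def _mini_complex(pairs):
    """Complex from (name, resname, resid, chain, xyz) tuples."""
    atoms = [Atom(i + 1, n, n[0], rn, ri, ch, xyz) for i, (n, rn, ri, ch, xyz) in enumerate(pairs)]
    return Complex(Structure(atoms), receptor_chains={"R"}, ligand_chains={"L"})


class TestDsb:
    def test_programmed_distance(self):
        cplx = _mini_complex(
            [("NZ", "LYS", 9, "L", (0, 0, 0)), ("CG", "ASP", 126, "R", (3, 0, 0))]
        )
        assert dsb(cplx) == pytest.approx(3.0)

    def test_internal_mode_fixture(self, toy_receptor, sst_peptide):
        receptor, _ = toy_receptor
        peptide, _ = sst_peptide
        posed = sd.pose_ligand(peptide, receptor, dsb_target=3.0)
        st = Structure([a for a in receptor.atoms] + [a for a in posed.atoms])
        cplx = Complex(st, {"R"}, {"L"})
        value = dsb(cplx)
        assert value <= 4.0
        # agrees with direct coordinate arithmetic
        nz = st.atoms[st.atom_index("L", 9, "NZ")].coords
        cg = st.atoms[st.atom_index("R", 126, "CG")].coords
        assert value == pytest.approx(float(np.linalg.norm(nz - cg)), abs=1e-12)

    def test_absent_resid_raises(self, posed_complex):
        with pytest.raises(SelectionError):
            dsb(posed_complex, DsbSpec(receptor_resid=999))


class TestInterfaceResidues:
    def test_constructed_single_residue(self):
        cplx = _mini_complex(
            [
                ("CA", "ALA", 1, "R", (3.0, 0, 0)),
                ("CA", "GLY", 2, "R", (5.0, 0, 0)),
                ("CA", "LYS", 1, "L", (0, 0, 0)),
            ]
        )
        hits = interface_residues(cplx, cutoff=3.5)
        assert [(h[1], h[2]) for h in hits] == [(1, "ALA")]
        assert hits[0][3] == pytest.approx(3.0)

    def test_tiny_cutoff_empty(self, posed_complex):
        assert interface_residues(posed_complex, cutoff=0.5) == []

    def test_monotone_in_cutoff_and_matches_brute_force(self, posed_complex):
        small = {(h[0], h[1]) for h in interface_residues(posed_complex, cutoff=3.5)}
        large = {(h[0], h[1]) for h in interface_residues(posed_complex, cutoff=4.5)}
        assert small <= large
        # brute force over all heavy-atom pairs
        st = posed_complex.structure
        rec = posed_complex.receptor_indices(heavy_only=True)
        lig = posed_complex.ligand_indices(heavy_only=True)
        expected = set()
        for i in rec:
            for j in lig:
                if np.linalg.norm(st.atoms[i].coords - st.atoms[j].coords) <= 4.5:
                    expected.add((st.atoms[i].chain, st.atoms[i].resid))
        assert large == expected


class TestHBonds:
    def test_n_o_pair_at_2p9(self):
        cplx = _mini_complex(
            [("N", "GLY", 1, "R", (0, 0, 0)), ("O", "GLY", 1, "L", (2.9, 0, 0))]
        )
        found = hbonds(cplx.structure)
        assert len(found) == 1
        assert found[0].distance == pytest.approx(2.9)

    def test_carbon_is_not_a_partner(self):
        cplx = _mini_complex(
            [("C", "GLY", 1, "R", (0, 0, 0)), ("O", "GLY", 1, "L", (2.9, 0, 0))]
        )
        assert hbonds(cplx.structure) == []

    def test_count_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(19)
        elements = ["N", "O", "S", "C"]
        atoms = []
        for i in range(50):
            el = elements[rng.integers(0, 4)]
            atoms.append(
                Atom(i + 1, f"{el}{i}", el, "RES", i + 1, "A", rng.uniform(0, 12, 3))
            )
        st = Structure(atoms)
        found = hbonds(st, max_da=3.5)
        expected = 0
        for i in range(50):
            for j in range(i + 1, 50):
                if atoms[i].element not in "NOS" or atoms[j].element not in "NOS":
                    continue
                d = np.linalg.norm(atoms[i].coords - atoms[j].coords)
                if d <= 3.5 and not (atoms[i].resid == atoms[j].resid and d < 1.8):
                    expected += 1
        assert len(found) == expected

    def test_subset_under_larger_cutoff(self, posed_complex):
        st = posed_complex.structure
        tight = {(h.donor, h.acceptor) for h in hbonds(st, max_da=3.0)}
        loose = {(h.donor, h.acceptor) for h in hbonds(st, max_da=3.5)}
        assert tight <= loose


class TestSaltBridges:
    def test_lys_asp_bridge(self):
        cplx = _mini_complex(
            [
                ("NZ", "LYS", 1, "L", (0, 0, 0)),
                ("OD1", "ASP", 2, "R", (2.8, 0, 0)),
            ]
        )
        bridges = salt_bridges(cplx)
        assert len(bridges) == 1
        assert bridges[0][2] == pytest.approx(2.8)

    def test_beyond_cutoff_empty(self):
        cplx = _mini_complex(
            [
                ("NZ", "LYS", 1, "L", (0, 0, 0)),
                ("OD1", "ASP", 2, "R", (5.5, 0, 0)),
            ]
        )
        assert salt_bridges(cplx) == []

    def test_external_mode_backbone_o_to_arg(self):
        # ligand backbone carbonyl near a receptor arginine guanidinium
        cplx = _mini_complex(
            [
                ("NH1", "ARG", 188, "R", (0, 0, 0)),
                ("NE", "ARG", 188, "R", (-1.2, 0.5, 0)),
                ("O", "THR", 12, "L", (3.1, 0, 0)),
                ("CA", "THR", 12, "L", (4.8, 1.2, 0)),
            ]
        )
        bridges = salt_bridges(cplx)
        assert len(bridges) == 1
        basic, acidic, d = bridges[0]
        assert basic[:2] == ("R", 188)
        assert acidic[2] == "backbone-O"
        assert d == pytest.approx(3.1)

    def test_two_residue_energy_fixture_has_one_bridge(self):
        pc = sd.make_energy_fixture("two_residue")
        bridges = salt_bridges(pc.complex)
        assert len(bridges) == 1
        assert bridges[0][0][:2] == ("L", 9)
        assert bridges[0][1][:2] == ("R", 126)


class TestWaterBridges:
    def test_intermediate_fixture_has_three_bridges(self, intermediate_fixture):
        cplx, manifest = intermediate_fixture
        lig = select(cplx.structure, manifest.ground_truth["ligand_sel"])
        rec = select(cplx.structure, manifest.ground_truth["receptor_sel"])
        bridges = water_bridges(cplx, lig, rec)
        assert len(bridges) == 3
        assert sorted(b.water[1] for b in bridges) == manifest.ground_truth["bridge_water_resids"]

    def test_decoys_excluded(self, intermediate_fixture):
        cplx, manifest = intermediate_fixture
        lig = select(cplx.structure, manifest.ground_truth["ligand_sel"])
        rec = select(cplx.structure, manifest.ground_truth["receptor_sel"])
        bridge_resids = {b.water[1] for b in water_bridges(cplx, lig, rec)}
        decoy_resids = {404, 405}
        assert bridge_resids.isdisjoint(decoy_resids)

    def test_component_hbonds_pass_criterion(self, intermediate_fixture):
        cplx, manifest = intermediate_fixture
        lig = select(cplx.structure, manifest.ground_truth["ligand_sel"])
        rec = select(cplx.structure, manifest.ground_truth["receptor_sel"])
        for b in water_bridges(cplx, lig, rec, max_da=3.5):
            assert b.ligand_hbond.distance <= 3.5
            assert b.receptor_hbond.distance <= 3.5

    def test_waterless_complex_empty(self, posed_complex):
        assert water_bridges(posed_complex) == []

    def test_one_sided_water_excluded(self):
        cplx = _mini_complex(
            [
                ("NZ", "LYS", 9, "L", (0, 0, 0)),
                ("OD1", "ASP", 126, "R", (20, 0, 0)),
                ("O", "HOH", 401, "W", (2.8, 0, 0)),  # ligand side only
            ]
        )
        assert water_bridges(cplx) == []


class TestBetaTurns:
    def test_fwkt_turn_detected(self, sst_peptide):
        peptide, _ = sst_peptide
        turns = beta_turns(peptide, "L")
        assert [t.start_resid for t in turns] == [7]
        assert turns[0].ca_distance <= 7.0

    def test_extended_strand_empty(self):
        atoms = [
            Atom(i + 1, "CA", "C", "GLY", i + 1, "A", (3.5 * i, 0, 0)) for i in range(6)
        ]
        assert beta_turns(Structure(atoms), "A") == []

    def test_ideal_alpha_helix_excluded(self):
        # ideal helix: rise 1.5 Å, 100° per residue, radius 2.3 Å
        atoms = []
        for i in range(10):
            th = np.deg2rad(100 * i)
            atoms.append(
                Atom(i + 1, "CA", "C", "ALA", i + 1, "A", (2.3 * np.cos(th), 2.3 * np.sin(th), 1.5 * i))
            )
        st = Structure(atoms)
        # helical i,i+3 distances are ~5.5 Å (below 7) but the helix filter removes them
        assert beta_turns(st, "A") == []

    def test_short_chain_empty(self):
        atoms = [Atom(i + 1, "CA", "C", "GLY", i + 1, "A", (3.8 * i, 0, 0)) for i in range(3)]
        assert beta_turns(Structure(atoms), "A") == []


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(0, 10, (8, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)

    def test_recovers_90_degree_rotation(self):
        pts = np.random.default_rng(1).uniform(0, 10, (12, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ Rz.T
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, Rz, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_copy_rmsd_matches_direct_recomputation(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 20, (50, 3))
        R0, t0 = random_rigid_motion(rng)
        noisy = pts @ R0.T + t0 + rng.normal(0, 0.1, (50, 3))
        R, t, rmsd = kabsch_superpose(pts, noisy)
        assert 0.05 <= rmsd <= 0.2
        moved = pts @ R.T + t
        direct = float(np.sqrt(((moved - noisy) ** 2).sum(axis=1).mean()))
        assert rmsd == pytest.approx(direct, rel=1e-12)
        # optimality: no worse than the untransformed pair
        untrans = float(np.sqrt(((pts - noisy) ** 2).sum(axis=1).mean()))
        assert rmsd <= untrans

    def test_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def test_descriptors_invariant_under_rigid_motion(intermediate_fixture):
    cplx, manifest = intermediate_fixture
    lig = select(cplx.structure, manifest.ground_truth["ligand_sel"])
    rec = select(cplx.structure, manifest.ground_truth["receptor_sel"])
    base_dsb = dsb(cplx)
    base_iface = interface_residues(cplx, cutoff=4.0)
    base_hb = hbonds(cplx.structure, max_da=3.5)
    base_wb = water_bridges(cplx, lig, rec)
    rng = np.random.default_rng(2024)
    for _ in range(3):
        R, t = random_rigid_motion(rng)
        moved = cplx.structure.with_coords(cplx.structure.coords @ R.T + t)
        mc = Complex(moved, cplx.receptor_chains, cplx.ligand_chains)
        assert dsb(mc) == pytest.approx(base_dsb, abs=1e-9)
        iface = interface_residues(mc, cutoff=4.0)
        assert [(h[0], h[1], h[2]) for h in iface] == [(h[0], h[1], h[2]) for h in base_iface]
        assert np.allclose([h[3] for h in iface], [h[3] for h in base_iface], atol=1e-9)
        hb = hbonds(mc.structure, max_da=3.5)
        assert {(h.donor, h.acceptor) for h in hb} == {(h.donor, h.acceptor) for h in base_hb}
        wb = water_bridges(mc, lig, rec)
        assert {b.water for b in wb} == {b.water for b in base_wb}
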