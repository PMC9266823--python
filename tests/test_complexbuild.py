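"""Seed-and-grow construction, ligand transplantation, clashes, relaxation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from sstbind import synthetic_data as sd
from sstbind.complexbuild import (
    GrowSpec,
    detect_clashes,
    grow_peptide,
    relax,
    transplant_ligand,
)
from sstbind.energetics import ParamStructure, ParameterizedComplex
from sstbind.geometry import DsbSpec
from sstbind.structio import Atom, Complex, Structure


@pytest.fixture(scope="module")
def growth_setup(toy_receptor, sst_peptide_open):
    receptor, _ = toy_receptor
    posed = sd.pose_ligand(sst_peptide_open, receptor, dsb_target=5.5)
    seed = Structure([a for a in posed.atoms if 7 <= a.resid <= 10])
    return receptor, seed


@pytest.fixture(scope="module")
def grown_models(growth_setup):
    receptor, seed = growth_setup
    spec = GrowSpec(
        sequence=sd.SST_SEQUENCE, seed_start=7, seed_end=10, disulfide_pairs=[(3, 14)]
    )
    return grow_peptide(receptor, seed, spec, n_models=10, seed_rng=42), seed


class TestGrowPeptide:
    def test_frozen_seed_preserved(self, grown_models):
        results, seed = grown_models
        for res in results:
            st = res.complex.structure
            for a in seed.atoms:
                b = st.atoms[st.atom_index(a.chain, a.resid, a.name)]
                assert np.allclose(a.coords, b.coords, atol=1e-6)

    def test_full_sequence_grown_with_connectivity(self, grown_models):
        results, _seed = grown_models
        for res in results:
            st = res.complex.structure
            assert len(st.residues("L")) == 14
            for i in range(1, 14):
                c = st.atoms[st.atom_index("L", i, "C")].coords
                n = st.atoms[st.atom_index("L", i + 1, "N")].coords
                assert abs(float(np.linalg.norm(c - n)) - 1.33) <= 0.2

    def test_disulfide_restraint_closes_in_some_model(self, grown_models):
        results, _seed = grown_models
        ss = [res.ss_distances[(3, 14)] for res in results]
        assert all(np.isfinite(ss))
        assert min(ss) <= 2.5

    def test_determinism_same_seed(self, growth_setup):
        receptor, seed = growth_setup
        spec = GrowSpec(sequence=sd.SST_SEQUENCE, seed_start=7, seed_end=10)
        r1 = grow_peptide(receptor, seed, spec, n_models=2, seed_rng=5)
        r2 = grow_peptide(receptor, seed, spec, n_models=2, seed_rng=5)
        for a, b in zip(r1, r2):
            assert np.allclose(a.complex.structure.coords, b.complex.structure.coords)
            assert a.e_inter == b.e_inter

    def test_dsb_restraint_on_k9_seed(self, toy_receptor, sst_peptide_open):
        """The restrained-growth setup: a lone K9 seed at the observed minimum
        d_SB, full peptide grown around it with a 5 Å target."""
        receptor, _ = toy_receptor
        posed = sd.pose_ligand(sst_peptide_open, receptor, dsb_target=5.2)
        seed = Structure([a for a in posed.atoms if a.resid == 9])
        spec = GrowSpec(
            sequence=sd.SST_SEQUENCE, seed_start=9, seed_end=9,
            dsb_spec=DsbSpec(), dsb_target=5.0,
        )
        results = grow_peptide(receptor, seed, spec, n_models=5, seed_rng=3)
        best = min(results, key=lambda r: abs(r.dsb - 5.0))
        assert abs(best.dsb - 5.0) <= 1.0
        for res in results:
            assert len(res.complex.structure.residues("L")) == 14

    def test_dsb_restraint_pulls_versus_unrestrained(self, toy_receptor, sst_peptide_open):
        receptor, _ = toy_receptor
        posed = sd.pose_ligand(sst_peptide_open, receptor, dsb_target=9.0)
        seed = Structure([a for a in posed.atoms if 12 <= a.resid <= 14])
        common = dict(sequence=sd.SST_SEQUENCE, seed_start=12, seed_end=14, dsb_spec=DsbSpec())
        free = grow_peptide(receptor, seed, GrowSpec(**common), n_models=4, seed_rng=7)
        held = grow_peptide(
            receptor, seed, GrowSpec(**common, dsb_target=5.0), n_models=4, seed_rng=7
        )
        assert min(r.dsb for r in held) < min(r.dsb for r in free)

    def test_seed_span_validation(self, growth_setup):
        receptor, seed = growth_setup
        with pytest.raises(ValueError):
            GrowSpec(sequence="AGC", seed_start=7, seed_end=10)
        with pytest.raises(ValueError, match="disulfide"):
            GrowSpec(sequence=sd.SST_SEQUENCE, seed_start=7, seed_end=10, disulfide_pairs=[(4, 14)])
        bad = GrowSpec(sequence=sd.SST_SEQUENCE, seed_start=1, seed_end=4)
        with pytest.raises(ValueError, match="seed resids"):
            grow_peptide(receptor, seed, bad)


class TestTransplant:
    MAPPING = [(101, 101), (105, 105), (110, 110), (115, 115)]

    def _source(self, toy_receptor, sst_peptide):
        receptor, _ = toy_receptor
        peptide, _ = sst_peptide
        posed = sd.pose_ligand(peptide, receptor, dsb_target=5.5)
        st = Structure([a for a in receptor.atoms] + [a for a in posed.atoms])
        return Complex(st, {"R"}, {"L"}), receptor, posed

    def test_identity_between_receptor_copies(self, toy_receptor, sst_peptide):
        src, receptor, posed = self._source(toy_receptor, sst_peptide)
        out = transplant_ligand(src, receptor.copy(), self.MAPPING)
        lig = np.array([a.coords for a in out.structure.atoms if a.chain == "L"])
        assert np.allclose(lig, posed.coords, atol=1e-9)

    def test_rigid_motion_consistency(self, toy_receptor, sst_peptide):
        src, receptor, posed = self._source(toy_receptor, sst_peptide)
        th = np.deg2rad(45)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        t = np.array([1.0, -2.0, 3.0])
        target = receptor.with_coords(receptor.coords @ R.T + t)
        out = transplant_ligand(src, target, self.MAPPING)
        lig = np.array([a.coords for a in out.structure.atoms if a.chain == "L"])
        assert np.allclose(lig, posed.coords @ R.T + t, atol=1e-9)

    def test_intra_ligand_distances_preserved(self, toy_receptor, sst_peptide):
        src, receptor, posed = self._source(toy_receptor, sst_peptide)
        rng = np.random.default_rng(4)
        from conftest import random_rigid_motion

        R, t = random_rigid_motion(rng)
        target = receptor.with_coords(receptor.coords @ R.T + t)
        out = transplant_ligand(src, target, self.MAPPING)
        lig = np.array([a.coords for a in out.structure.atoms if a.chain == "L"])
        assert np.abs(pdist(lig) - pdist(posed.coords)).max() < 1e-9
        assert len(detect_clashes(out)) == len(detect_clashes(src))

    def test_missing_mapping_atom_raises(self, toy_receptor, sst_peptide):
        src, receptor, _posed = self._source(toy_receptor, sst_peptide)
        with pytest.raises(KeyError, match="999"):
            transplant_ligand(src, receptor.copy(), [(101, 101), (105, 105), (999, 110)])
        with pytest.raises(ValueError):
            transplant_ligand(src, receptor.copy(), [(101, 101)])


class TestDetectClashes:
    def test_non_overlapping_empty(self, posed_complex):
        assert detect_clashes(posed_complex, cutoff=0.8) == []

    def test_pair_at_1p5(self):
        atoms = [
            Atom(1, "CA", "C", "GLY", 1, "R", (0, 0, 0)),
            Atom(2, "CA", "C", "GLY", 1, "L", (1.5, 0, 0)),
        ]
        clashes = detect_clashes(Complex(Structure(atoms), {"R"}, {"L"}))
        assert len(clashes) == 1
        assert clashes[0][2] == pytest.approx(1.5)

    def test_matches_brute_force(self, posed_complex):
        got = detect_clashes(posed_complex, cutoff=5.0)
        st = posed_complex.structure
        expected = 0
        for i in posed_complex.receptor_indices(heavy_only=True):
            for j in posed_complex.ligand_indices(heavy_only=True):
                if np.linalg.norm(st.atoms[i].coords - st.atoms[j].coords) < 5.0:
                    expected += 1
        assert len(got) == expected


class TestRelax:
    def _shifted_pair(self, dz=5.0):
        pc = sd.make_energy_fixture("two_residue")
        st = pc.structure
        lig = [i for i, a in enumerate(st.atoms) if a.chain == "L"]
        xyz = st.coords
        xyz[lig] += np.array([0.0, 0.0, dz])
        st2 = st.with_coords(xyz)
        return (
            ParameterizedComplex(
                complex=Complex(st2, {"R"}, {"L"}),
                params=ParamStructure(st2, pc.params.q.copy(), pc.params.eps.copy(), pc.params.rmin2.copy()),
            ),
            lig,
        )

    def test_salt_bridge_pair_attracts(self):
        pc, lig = self._shifted_pair()
        st0 = pc.structure
        d0 = np.linalg.norm(
            st0.atoms[st0.atom_index("L", 9, "NZ")].coords
            - st0.atoms[st0.atom_index("R", 126, "OD1")].coords
        )
        result = relax(pc, mobile=lig, max_steps=150, step=0.1)
        st1 = result.complex.structure
        d1 = np.linalg.norm(
            st1.atoms[st1.atom_index("L", 9, "NZ")].coords
            - st1.atoms[st1.atom_index("R", 126, "OD1")].coords
        )
        assert d1 < d0
        assert result.trace[-1] < result.trace[0]
        # receptor never moved
        rec_rows = [i for i, a in enumerate(st0.atoms) if a.chain == "R"]
        assert np.allclose(st1.coords[rec_rows], st0.coords[rec_rows])

    def test_trace_never_increases(self):
        pc, lig = self._shifted_pair(dz=3.0)
        result = relax(pc, mobile=lig, max_steps=100, step=0.1)
        assert all(b <= a for a, b in zip(result.trace, result.trace[1:]))

    def test_lj_dimer_at_minimum_stops_immediately(self):
        pc = sd.make_energy_fixture("lj_dimer")
        result = relax(pc, mobile=[1], max_steps=50, step=0.05)
        assert result.n_steps <= 1
        assert np.allclose(result.complex.structure.coords, pc.structure.coords, atol=0.05)

    def test_zero_max_steps_is_identity(self):
        pc = sd.make_energy_fixture("lj_dimer")
        result = relax(pc, mobile=[1], max_steps=0)
        assert np.allclose(result.complex.structure.coords, pc.structure.coords)

    def test_empty_mobile_raises(self):
        pc = sd.make_energy_fixture("lj_dimer")
        with pytest.raises(ValueError):
            relax(pc, mobile=[])
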