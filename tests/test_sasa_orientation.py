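"""SASA quadrature correctness and the lipid/solvent accessibility split."""

import numpy as np
import pytest

from memtrap.sasa_orientation import (
    accessibility_split,
    golden_spiral_points,
    mean_sasa,
    sasa,
    topology_agreement,
)
from memtrap.synthetic_data import SimSpec, gen_membrane_complex
from tests.conftest import bead_model


def sphere_area(r):
    return 4.0 * np.pi * r * r


class TestGoldenSpiral:
    def test_points_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)

    def test_near_uniform_moments(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(pts.mean(axis=0), 0.0, atol=1e-3)


class TestSasaCore:
    def test_isolated_sphere_closed_form(self):
        m = bead_model([[0.0, 0.0, 0.0]])
        p = sasa(m, probe_radius=0.14, n_points=960)
        assert p.total() == pytest.approx(sphere_area(0.34), rel=1e-12)

    def test_quadrature_too_coarse(self):
        m = bead_model([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="coarse"):
            sasa(m, n_points=16)

    def test_two_sphere_cap_oracle(self):
        """Two equal overlapping spheres: exposed area per sphere equals
        4 pi R^2 minus the spherical cap 2 pi R (R - d/2)."""
        R = 0.34
        for d in (0.20, 0.40, 0.60):
            m = bead_model([[0, 0, 0], [d, 0, 0]])
            p = sasa(m, probe_radius=0.14, n_points=960)
            exact = sphere_area(R) - 2 * np.pi * R * (R - d / 2)
            np.testing.assert_allclose(p.atom_areas, exact, rtol=0.02)

    def test_buried_atom_zero_area(self):
        # central atom caged by a dense shell of larger neighbors
        shell = golden_spiral_points(60) * 0.25
        m = bead_model(np.vstack([[0, 0, 0], shell]),
                       radii=[0.1] + [0.2] * 60)
        p = sasa(m, probe_radius=0.0, n_points=960)
        assert p.atom_areas[0] == 0.0

    def test_duplicate_atoms_deduplicated(self):
        m = bead_model([[0, 0, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="duplicate"):
            p = sasa(m, probe_radius=0.14, n_points=960)
        assert p.total() == pytest.approx(sphere_area(0.34), rel=1e-12)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(8)
        xyz = rng.uniform(0, 1.2, size=(40, 3))
        m1 = bead_model(xyz)
        # random rotation via QR, plus a translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m2 = bead_model(xyz @ q.T + np.array([3.0, -2.0, 5.0]))
        a1 = sasa(m1, probe_radius=0.14, n_points=960).total()
        a2 = sasa(m2, probe_radius=0.14, n_points=960).total()
        assert a2 == pytest.approx(a1, rel=0.005)

    def test_occluder_monotonicity(self):
        rng = np.random.default_rng(9)
        xyz = rng.uniform(0, 1.0, size=(15, 3))
        base = sasa(bead_model(xyz), probe_radius=0.14, n_points=960)
        more = np.vstack([xyz, rng.uniform(0, 1.0, size=(5, 3))])
        grown = sasa(bead_model(more), probe_radius=0.14, n_points=960)
        assert np.all(grown.atom_areas[:15] <= base.atom_areas + 1e-12)

    def test_quadrature_convergence(self):
        rng = np.random.default_rng(10)
        xyz = rng.uniform(0, 1.0, size=(30, 3))
        m = bead_model(xyz)
        a960 = sasa(m, probe_radius=0.14, n_points=960).total()
        a3840 = sasa(m, probe_radius=0.14, n_points=3840).total()
        assert a960 == pytest.approx(a3840, rel=0.01)

    def test_rejection_sampling_oracle(self):
        """Independent Monte-Carlo SASA: 1e5 random surface points per atom,
        rejecting those inside any neighbor. Agreement within 2%."""
        rng = np.random.default_rng(12)
        n_atoms = 50
        xyz = rng.uniform(0, 1.4, size=(n_atoms, 3))
        radii = rng.uniform(0.15, 0.25, size=n_atoms)
        m = bead_model(xyz, radii=radii)
        probe = 0.14
        got = sasa(m, probe_radius=probe, n_points=960)

        R = radii + probe
        oracle = np.zeros(n_atoms)
        n_mc = 100_000
        for i in range(n_atoms):
            v = rng.normal(size=(n_mc, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = xyz[i] + R[i] * v
            exposed = np.ones(n_mc, dtype=bool)
            for j in range(n_atoms):
                if j == i:
                    continue
                d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
                exposed &= d2 >= R[j] ** 2
            oracle[i] = exposed.mean() * sphere_area(R[i])
        np.testing.assert_allclose(got.total(), oracle.sum(), rtol=0.02)

    def test_independent_library_cross_check(self):
        """Cross-check against biotite's Shrake-Rupley on a random cluster."""
        import biotite.structure as struc

        rng = np.random.default_rng(21)
        n = 30
        xyz_nm = rng.uniform(0, 1.2, size=(n, 3))
        radii = np.full(n, 0.17)
        m = bead_model(xyz_nm, radii=radii)
        mine = sasa(m, probe_radius=0.14, n_points=960).total()

        atoms = struc.AtomArray(n)
        atoms.coord = xyz_nm * 10.0          # biotite works in Angstrom
        atoms.res_id = np.arange(1, n + 1)
        atoms.atom_name = np.array(["C"] * n)
        atoms.res_name = np.array(["UNK"] * n)
        atoms.chain_id = np.array(["A"] * n)
        atoms.element = np.array(["C"] * n)
        ref = struc.sasa(atoms, probe_radius=1.4, point_number=960,
                         vdw_radii="Single").sum() / 100.0   # A^2 -> nm^2
        assert mine == pytest.approx(ref, rel=0.02)


class TestAccessibilitySplit:
    def test_null_membrane(self):
        rng = np.random.default_rng(13)
        xyz = rng.uniform(0, 2.0, size=(10, 3))
        m = bead_model(xyz)
        p = sasa(m, probe_radius=0.14, n_points=960)
        split = accessibility_split(p, p)
        assert all(v == 0.0 for v in split.lipid_area.values())
        assert set(split.preference.values()) <= {"solvent", "buried"}

    def test_contact_residues_lipid_preferring(self):
        spec = SimSpec(seed=77)
        alone, cplx, contacts = gen_membrane_complex(spec)
        kwargs = dict(probe_radius=0.0, n_points=960, radius_augment=0.21)
        pa = sasa(alone, subset=["peptide"], **kwargs)
        pc = sasa(cplx, subset=["peptide"], **kwargs)
        split = accessibility_split(pa, pc)
        assert split.residues("lipid") == contacts
        assert split.residues("solvent") == set(range(1, 38)) - contacts

    def test_sandwiched_residue_buried(self):
        # one bead fully enclosed between two tight slabs of beads
        cage = golden_spiral_points(80) * 0.3
        m_alone = bead_model([[0.0, 0.0, 0.0]], radii=[0.1])
        m_cplx = bead_model(
            np.vstack([[0.0, 0.0, 0.0], cage]),
            radii=[0.1] + [0.25] * 80,
            groups=["peptide"] + ["membrane"] * 80,
            residue_index=[1] + list(range(1001, 1081)),
        )
        pa = sasa(m_alone, subset=["peptide"], probe_radius=0.0, n_points=960)
        pc = sasa(m_cplx, subset=["peptide"], probe_radius=0.0, n_points=960)
        split = accessibility_split(pa, pc)
        assert split.preference[1] == "lipid" or split.preference[1] == "buried"
        assert split.solvent_area[1] == pytest.approx(0.0, abs=1e-9)

    def test_parameter_mismatch_rejected(self):
        m = bead_model([[0.0, 0.0, 0.0]])
        p1 = sasa(m, probe_radius=0.14, n_points=960)
        p2 = sasa(m, probe_radius=0.0, n_points=960)
        with pytest.raises(ValueError, match="parameter mismatch"):
            accessibility_split(p1, p2)

    def test_residue_support_mismatch_rejected(self):
        p1 = sasa(bead_model([[0.0, 0.0, 0.0]]), n_points=960)
        p2 = sasa(bead_model([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]), n_points=960)
        with pytest.raises(ValueError, match="support"):
            accessibility_split(p1, p2)

    def test_complex_never_exceeds_alone(self):
        spec = SimSpec(seed=5)
        alone, cplx, _ = gen_membrane_complex(spec)
        kwargs = dict(probe_radius=0.0, n_points=960, radius_augment=0.21)
        pa = sasa(alone, subset=["peptide"], **kwargs)
        pc = sasa(cplx, subset=["peptide"], **kwargs)
        for ri in pa.residue_areas:
            assert pc.residue_areas[ri] <= pa.residue_areas[ri] + 1e-9


class TestMeanSasa:
    def test_average_over_snapshots(self):
        m1 = bead_model([[0.0, 0.0, 0.0]])
        m2 = bead_model([[0.0, 0.0, 0.0], [0.45, 0.0, 0.0]],
                        residue_index=[1, 2])
        p1 = sasa(m1, probe_radius=0.14, n_points=960)
        p2 = sasa(m2, probe_radius=0.14, n_points=960)
        avg = mean_sasa([p1, p1])
        assert avg.residue_areas[1] == pytest.approx(p1.residue_areas[1])
        avg2 = mean_sasa([p1, p2])
        expect = 0.5 * (p1.residue_areas[1] + p2.residue_areas[1])
        assert avg2.residue_areas[1] == pytest.approx(expect)


class TestTopologyAgreement:
    @staticmethod
    def _call(membrane):
        from memtrap.probe_topology import TopologyCall
        labels = {i: ("membrane" if i in membrane else "unclassified")
                  for i in range(1, 38)}
        return TopologyCall(labels=labels, evidence={})

    @staticmethod
    def _split(lipid):
        from memtrap.sasa_orientation import AccessibilitySplit
        return AccessibilitySplit(
            solvent_area={i: 1.0 for i in range(1, 38)},
            lipid_area={i: (2.0 if i in lipid else 0.0) for i in range(1, 38)},
            preference={i: ("lipid" if i in lipid else "solvent")
                        for i in range(1, 38)},
        )

    def test_nested_sets_full_overlap(self):
        rep = topology_agreement(self._call({11, 12, 17, 18}),
                                 self._split({11, 12, 13, 17, 18, 19}))
        assert rep.both == {11, 12, 17, 18}
        assert rep.overlap_coefficient == pytest.approx(1.0)

    def test_disjoint_sets(self):
        rep = topology_agreement(self._call({1, 2}), self._split({30, 31}))
        assert rep.overlap_coefficient == 0.0
        assert rep.both == set()

    def test_identical_sets(self):
        rep = topology_agreement(self._call({5, 6, 7}), self._split({5, 6, 7}))
        assert rep.overlap_coefficient == pytest.approx(1.0)
        assert rep.nmr_only == set() and rep.sasa_only == set()

    def test_counts_partition_support(self):
        rep = topology_agreement(self._call({1, 2, 3}), self._split({3, 4}))
        assert sum(rep.counts().values()) == 37

    def test_empty_nmr_set_flagged(self):
        rep = topology_agreement(self._call(set()), self._split({3, 4}))
        assert rep.undefined
        assert rep.overlap_coefficient is None
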