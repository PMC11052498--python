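import numpy as np
import pytest
from rdkit import Chem

from qsarkit.chem import atom_parameters, embed_3d, gasteiger_charges
from qsarkit.fields import (
    COMFA_PROBE,
    ComfaFieldTransformer,
    ComsiaFieldTransformer,
    FieldBlock,
    LatticeSpec,
    align_to_scaffold,
    build_lattice,
    comfa_fields,
    comsia_fields,
    filter_columns,
)

CARBON = {"radius": np.array([1.70]), "epsilon": np.array([0.107]),
          "charge": np.array([0.0]), "hydrophobicity": np.array([0.2]),
          "donor": np.array([0.0]), "acceptor": np.array([0.0])}


class TestLattice:
    def test_single_atom_box(self):
        lat = build_lattice([np.zeros((1, 3))], spacing=2.0, margin=4.0)
        assert np.allclose(lat.axes()[0], [-4, -2, 0, 2, 4])
        assert lat.n_points == 125

    def test_two_atom_box(self):
        lat = build_lattice([np.array([[0., 0, 0], [2., 0, 0]])])
        assert lat.dims == (6, 5, 5) and lat.n_points == 150

    def test_minimum_two_points_per_axis(self):
        lat = build_lattice([np.zeros((1, 3))], spacing=100.0, margin=1.0)
        assert all(d == 2 for d in lat.dims)

    def test_no_coordinates_rejected(self):
        with pytest.raises(ValueError):
            build_lattice([])


class TestAlignment:
    def test_self_alignment_rmsd_zero(self, rng):
        tpl = rng.normal(size=(6, 3))
        _, rmsd = align_to_scaffold(tpl, tpl, [(i, i) for i in range(6)])
        assert rmsd < 1e-12

    def test_translation_removed(self, rng):
        tpl = rng.normal(size=(5, 3))
        moved = tpl + np.array([3.0, -1.0, 7.0])
        aligned, rmsd = align_to_scaffold(moved, tpl, [(i, i) for i in range(5)])
        assert rmsd < 1e-10 and np.abs(aligned - tpl).max() < 1e-10

    def test_rotation_recovered(self, rng):
        tpl = rng.normal(size=(7, 3))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = tpl @ R.T + 2.5
        aligned, rmsd = align_to_scaffold(moved, tpl, [(i, i) for i in range(7)])
        assert np.abs(aligned - tpl).max() < 1e-8

    def test_too_few_atoms_rejected(self, rng):
        tpl = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            align_to_scaffold(tpl, tpl, [(0, 0), (1, 1)])

    def test_collinear_template_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            align_to_scaffold(line, line, [(i, i) for i in range(3)])


class TestComfa:
    def test_zero_charges_zero_electrostatics(self):
        lat = LatticeSpec(origin=(2, 0, 0), spacing=2.0, dims=(3, 2, 2))
        _, elec, _ = comfa_fields(np.zeros((1, 3)), CARBON, lat)
        assert np.allclose(elec, 0.0)

    def test_lennard_jones_minimum_at_contact_distance(self):
        Rj = COMFA_PROBE.vdw_radius + 1.70
        lat = LatticeSpec(origin=(Rj, 0, 0), spacing=2.0, dims=(2, 2, 2))
        steric, _, _ = comfa_fields(np.zeros((1, 3)), CARBON, lat)
        assert steric[0] == pytest.approx(-np.sqrt(0.107 * COMFA_PROBE.epsilon))

    def test_coincident_point_clamped_and_flagged(self):
        lat = LatticeSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        steric, _, singular = comfa_fields(np.zeros((1, 3)), CARBON, lat)
        assert steric[0] == 30.0 and singular == [0]

    def test_clamping_bound_is_exact(self, random_mols):
        tf = ComfaFieldTransformer()
        mols = [embed_3d(m) for m in random_mols[:5]]
        block = tf.fit(mols).transform(mols)
        assert np.abs(block.matrix).max() <= 30.0

    def test_rigid_motion_invariance(self, rng):
        # rigidly moving the molecule and realigning it onto the template
        # leaves both field families unchanged; pure translations of
        # molecule + lattice are exactly representable and tested directly
        coords = rng.normal(size=(5, 3)) * 2
        params = {k: rng.uniform(0.1, 1.0, size=5) if k != "radius" else np.full(5, 1.6)
                  for k in CARBON}
        lat = build_lattice([coords])
        s1, e1, _ = comfa_fields(coords, params, lat)
        c1 = comsia_fields(coords, params, lat)

        shift = np.array([1.0, -2.0, 0.5])
        lat_t = LatticeSpec(origin=tuple(np.asarray(lat.origin) + shift),
                            spacing=lat.spacing, dims=lat.dims)
        s2, e2, _ = comfa_fields(coords + shift, params, lat_t)
        assert np.abs(s1 - s2).max() < 1e-8 and np.abs(e1 - e2).max() < 1e-8

        th = 0.6
        R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        moved = coords @ R.T + shift
        realigned, rmsd = align_to_scaffold(moved, coords, [(i, i) for i in range(5)])
        assert rmsd < 1e-10
        s3, e3, _ = comfa_fields(realigned, params, lat)
        c3 = comsia_fields(realigned, params, lat)
        assert np.abs(s1 - s3).max() < 1e-8 and np.abs(e1 - e3).max() < 1e-8
        for p in "SEHDA":
            assert np.abs(c1[p] - c3[p]).max() < 1e-8


class TestComsia:
    def test_value_at_atom_position_closed_form(self):
        lat = LatticeSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        f = comsia_fields(np.zeros((1, 3)), CARBON, lat)
        assert f["S"][0] == pytest.approx(-(1.70 ** 3))
        assert f["H"][0] == pytest.approx(-0.2)

    def test_two_atoms_additive(self, rng):
        lat = LatticeSpec(origin=(-2, -2, -2), spacing=2.0, dims=(4, 4, 4))
        c1, c2 = rng.normal(size=(1, 3)), rng.normal(size=(1, 3))
        both = np.vstack([c1, c2])
        params2 = {k: np.repeat(v, 2) for k, v in CARBON.items()}
        f12 = comsia_fields(both, params2, lat)
        f1 = comsia_fields(c1, CARBON, lat)
        f2 = comsia_fields(c2, CARBON, lat)
        for p in "SEHDA":
            assert np.abs(f12[p] - (f1[p] + f2[p])).max() < 1e-9

    def test_gaussian_monotone_decay(self):
        lat = LatticeSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        vals = [abs(comsia_fields(np.array([[d, 0, 0]]), CARBON, lat)["S"][0])
                for d in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_for_positive_weights(self, random_mols):
        tf = ComsiaFieldTransformer(properties=("S", "D", "A"))
        mols = [embed_3d(m) for m in random_mols[:3]]
        block = tf.fit(mols).transform(mols)
        assert (block.matrix <= 0).all()


class TestAtomParameters:
    def test_methane_carbon_nearly_neutral(self):
        q = gasteiger_charges(Chem.MolFromSmiles("C"))
        assert abs(q[0]) < 0.1

    def test_water_oxygen_is_donor_and_acceptor(self):
        p = atom_parameters(Chem.MolFromSmiles("O"))
        assert p["donor"][0] == 1.0 and p["acceptor"][0] == 1.0

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccncc1", "CC(=O)[O-]", "C[NH3+]"])
    def test_total_charge_conserved(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        total = sum(a.GetFormalCharge() for a in mol.GetAtoms())
        assert gasteiger_charges(mol).sum() == pytest.approx(total, abs=1e-6)

    def test_unknown_element_reported(self):
        with pytest.raises(KeyError, match="Se"):
            atom_parameters(Chem.MolFromSmiles("[Se]"))


class TestColumnFilter:
    def test_constant_column_removed(self):
        block = FieldBlock(np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]]),
                           [("S", 0), ("S", 1)])
        out = filter_columns(block, 1e-9)
        assert out.matrix.shape == (3, 1) and out.columns == [("S", 1)]

    def test_zero_sigma_is_identity(self):
        block = FieldBlock(np.ones((3, 2)), [("S", 0), ("S", 1)])
        out = filter_columns(block, 0.0)
        assert out.matrix.shape == (3, 2)

    def test_threshold_on_toy_sds(self):
        # columns with sd 0 and 1 -> min_sigma 0.5 keeps exactly one
        block = FieldBlock(np.array([[5.0, -1.0], [5.0, 0.0], [5.0, 1.0]]),
                           [("E", 0), ("E", 1)])
        out = filter_columns(block, 0.5)
        assert out.columns == [("E", 1)]

    def test_all_removed_is_error(self):
        block = FieldBlock(np.ones((3, 2)), [("S", 0), ("S", 1)])
        with pytest.raises(ValueError):
            filter_columns(block, 0.5)
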