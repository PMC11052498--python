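import numpy as np
import pytest
from rdkit import Chem

from qsarkit.rgroup import (
    Fragment,
    RGroupCutSpec,
    TopomerFieldModel,
    assemble,
    assemble_and_predict,
    cut_rgroups,
    fragment_distance,
    fragment_field_vector,
    group_contributions,
    screen_library,
)
from qsarkit.synthetic import DEFAULT_SCAFFOLD, default_series_spec, generate_rgroup_series

THREE_CUT = RGroupCutSpec(DEFAULT_SCAFFOLD)
ONE_CUT = RGroupCutSpec("[*:1]c1ccccc1")


class TestCutting:
    def test_single_cut_two_parts(self):
        dec = cut_rgroups("CCc1ccccc1", ONE_CUT)
        assert list(dec.fragments) == ["Ra"]
        assert dec.fragments["Ra"].canonical() == Chem.CanonSmiles("*CC")

    def test_three_cut_partition_is_exhaustive_and_disjoint(self):
        smi = "Cc1nc2ccc(Cl)cc2nc1N"
        dec = cut_rgroups(smi, THREE_CUT)
        mol = Chem.MolFromSmiles(smi)
        core = set(dec.core_atoms)
        frag_sets = [set(v) for v in dec.fragment_atoms.values()]
        all_atoms = core.union(*frag_sets)
        assert all_atoms == set(range(mol.GetNumAtoms()))
        for i, a in enumerate(frag_sets):
            assert not a & core
            for b in frag_sets[i + 1:]:
                assert not a & b

    def test_hydrogen_position(self):
        dec = cut_rgroups("c1ccc2nc(C)c([H])nc2c1".replace("([H])", ""), THREE_CUT)
        assert dec.fragments["Ra"].is_hydrogen()

    def test_no_match_is_error(self):
        with pytest.raises(ValueError, match="exactly once"):
            cut_rgroups("CCO", THREE_CUT)

    def test_multiple_matches_is_error(self):
        # biphenyl: the single-ring scaffold matches both rings
        with pytest.raises(ValueError, match="exactly once"):
            cut_rgroups("c1ccc(-c2ccccc2)cc1", ONE_CUT)

    def test_reassembly_round_trip_on_random_series(self):
        spec = default_series_spec(n=40, noise_sd=0.0, seed=11)
        cset, _ = generate_rgroup_series(spec)
        for record in cset:
            dec = cut_rgroups(record.smiles, THREE_CUT)
            rebuilt = assemble(THREE_CUT, dec.fragments)
            assert Chem.MolToSmiles(rebuilt) == Chem.CanonSmiles(record.smiles)


class TestContributions:
    def test_zero_coefficients_zero_contributions(self):
        out = group_contributions(np.zeros(6), 1.0, np.ones(6), ["core"] * 3 + ["Ra"] * 3)
        assert all(c.value == 0.0 for c in out)

    def test_decomposition_identity_on_random_models(self, rng):
        for _ in range(100):
            m = rng.integers(4, 20)
            coef = rng.normal(size=m)
            x = rng.normal(size=m)
            labels = rng.choice(["core", "Ra", "Rb", "Rc"], size=m).tolist()
            out = group_contributions(coef, 0.7, x, labels)
            total = 0.7 + sum(c.value for c in out)
            assert total == pytest.approx(float(coef @ x + 0.7), abs=1e-9)

    def test_unassigned_column_rejected(self):
        with pytest.raises(ValueError, match="unassigned"):
            group_contributions(np.ones(2), 0.0, np.ones(2), ["Ra", ""])


class TestFragmentDistance:
    def test_identity_is_zero(self):
        assert fragment_distance(Fragment("*CC"), Fragment("*CC")) == 0.0

    def test_symmetry(self):
        pairs = [("*C", "*CC"), ("*Cl", "*c1ccccc1"), ("*N", "*OC")]
        for a, b in pairs:
            assert fragment_distance(Fragment(a), Fragment(b)) == pytest.approx(
                fragment_distance(Fragment(b), Fragment(a)), abs=1e-12)

    def test_matches_independent_field_difference(self):
        """Methyl vs ethyl against a directly coded standardized difference."""
        from qsarkit.rgroup import FRAGMENT_LATTICE

        f1, f2 = Fragment("*C"), Fragment("*CC")
        v1 = fragment_field_vector(f1)
        v2 = fragment_field_vector(f2)
        m = FRAGMENT_LATTICE.n_points
        total = 0.0
        for lo, hi in ((0, m), (m, 2 * m)):
            pooled = np.concatenate([v1[lo:hi], v2[lo:hi]]).std()
            if pooled > 0:
                total += np.sum(((v1[lo:hi] - v2[lo:hi]) / pooled) ** 2)
        assert fragment_distance(f1, f2) == pytest.approx(np.sqrt(total), abs=1e-12)

    def test_hydrogen_fragment_has_empty_field(self):
        assert not fragment_field_vector(Fragment("*[H]")).any()


@pytest.fixture(scope="module")
def fitted_model():
    spec = default_series_spec(n=60, noise_sd=0.0, seed=5)
    cset, choices = generate_rgroup_series(spec, build_structures=False)
    model = TopomerFieldModel(spec.positions(), n_components=9)
    model.fit(choices, np.asarray(cset.activities()))
    return spec, choices, model


class TestScreening:
    def test_query_included_at_distance_zero(self, fitted_model):
        spec, _, model = fitted_model
        lib = spec.libraries["Rc"]
        rows = screen_library(lib, lib[2], model, "Rc")
        me = [r for r in rows if r["smiles"] == lib[2].canonical()]
        assert me and me[0]["distance"] == 0.0

    def test_min_contribution_above_all_gives_empty(self, fitted_model):
        spec, _, model = fitted_model
        lib = spec.libraries["Rc"]
        assert screen_library(lib, lib[0], model, "Rc", min_contribution=1e6) == []

    def test_empty_library_is_empty_not_error(self, fitted_model):
        _, _, model = fitted_model
        assert screen_library([], Fragment("*C"), model, "Rc") == []

    def test_ranking_matches_exhaustive_sort_oracle(self, fitted_model):
        spec, _, model = fitted_model
        lib = [Fragment(s) for s in
               ["*C", "*CC", "*CCC", "*N", "*O", "*Cl", "*F", "*C(C)C", "*OC",
                "*CO", "*C#N", "*c1ccccc1", "*Cc1ccccc1", "*CN", "*C(=O)C",
                "*C(=O)N", "*S", "*CF", "*CCl", "*CCN"]]
        query = Fragment("*CC")
        rows = screen_library(lib, query, model, "Rb")
        oracle = sorted(
            [{"smiles": f.canonical(),
              "distance": fragment_distance(query, f, model.lattice),
              "contribution": model.contribution("Rb", f)} for f in lib],
            key=lambda r: (-r["contribution"], r["distance"], r["smiles"]))
        assert [r["smiles"] for r in rows] == [r["smiles"] for r in oracle]

    def test_deterministic_order_across_calls(self, fitted_model):
        spec, _, model = fitted_model
        lib = spec.libraries["Ra"]
        a = screen_library(lib, lib[0], model, "Ra")
        b = screen_library(lib, lib[0], model, "Ra")
        assert [(r["smiles"], r["contribution"]) for r in a] == \
               [(r["smiles"], r["contribution"]) for r in b]


class TestAssembleAndPredict:
    def test_template_round_trip_prediction_identity(self, fitted_model):
        spec, choices, model = fitted_model
        choice = choices[0]
        mol, pred, contribs = assemble_and_predict(RGroupCutSpec(spec.scaffold),
                                                   choice, model)
        direct = model.predict([choice])[0]
        assert pred == pytest.approx(direct, abs=1e-9)
        assert pred == pytest.approx(model.intercept_ + sum(c.value for c in contribs),
                                     abs=1e-12)

    def test_swap_changes_by_contribution_difference(self, fitted_model):
        spec, choices, model = fitted_model
        choice = dict(choices[0])
        f_old = choice["Rc"]
        f_new = next(f for f in spec.libraries["Rc"]
                     if f.canonical() != f_old.canonical())
        _, pred_old, _ = assemble_and_predict(RGroupCutSpec(spec.scaffold), choice, model)
        choice["Rc"] = f_new
        _, pred_new, _ = assemble_and_predict(RGroupCutSpec(spec.scaffold), choice, model)
        expected = model.contribution("Rc", f_new) - model.contribution("Rc", f_old)
        assert pred_new - pred_old == pytest.approx(expected, abs=1e-9)

    def test_best_candidate_is_true_optimum_on_noiseless_series(self, fitted_model):
        from itertools import product

        spec, _, model = fitted_model
        combos = [dict(zip(spec.positions(), c))
                  for c in product(*[spec.libraries[p] for p in spec.positions()])]
        preds = model.predict(combos)
        truths = [spec.true_activity(c) for c in combos]
        assert int(np.argmax(preds)) == int(np.argmax(truths))

    def test_valence_violation_reported(self):
        spec = RGroupCutSpec("[*:1]C(C)(C)C")
        with pytest.raises(ValueError, match="valence"):
            assemble(spec, {"Ra": Fragment("*=O")})
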