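"""CATS2D descriptors: typing rules, pair counting, filtering, LOO models."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

import odorspace as od
from odorspace.chem import (
    Cats2DVectorizer,
    DescriptorFilter,
    Molecule,
    assign_pharmacophore_types,
    cats2d,
    final_odor_fixture_path,
    load_smiles_file,
    loo_classify,
)


class TestTyping:
    def test_pure_carbon_is_lipophilic(self):
        types = assign_pharmacophore_types("CC")
        assert types == [{"L"}, {"L"}]

    def test_butanol_rule_table(self):
        # O: donor (has H) and acceptor; C1-C3 lipophilic; C4 touches O -> untyped
        types = assign_pharmacophore_types("CCCCO")
        assert types[:3] == [{"L"}, {"L"}, {"L"}]
        assert types[3] == set()
        assert types[4] == {"D", "A"}

    def test_acetate_anion_negative(self):
        mol = Chem.MolFromSmiles("CC([O-])=O")
        types = assign_pharmacophore_types(mol)
        charged = [t for a, t in zip(mol.GetAtoms(), types) if a.GetFormalCharge() < 0]
        assert charged and all("N" in t for t in charged)

    def test_carboxylic_acid_oxygen_is_acidic(self):
        mol = Chem.MolFromSmiles("CC(=O)O")
        types = assign_pharmacophore_types(mol)
        hydroxyl = [
            t
            for a, t in zip(mol.GetAtoms(), types)
            if a.GetSymbol() == "O" and a.GetTotalNumHs() == 1
        ]
        assert hydroxyl == [{"D", "A", "N"}]

    def test_amine_nitrogen_is_positive_but_amide_is_not(self):
        amine = Chem.MolFromSmiles("CCN")
        t_amine = assign_pharmacophore_types(amine)
        assert "P" in t_amine[2]
        amide = Chem.MolFromSmiles("CC(=O)N")
        t_amide = assign_pharmacophore_types(amide)
        assert "P" not in t_amide[3]

    def test_unparseable_smiles_raises(self):
        with pytest.raises(ValueError):
            assign_pharmacophore_types("not_a_smiles")
        with pytest.raises(ValueError):
            assign_pharmacophore_types("CC.CC")  # disconnected


class TestCats2d:
    def test_cross_mode_has_90_descriptors(self):
        names = Cats2DVectorizer(pair_mode="cross").feature_names()
        assert len(names) == 90
        assert len({n.split("_")[2] for n in names}) == 10
        assert len({n.split("_")[1] for n in names}) == 9
        assert "CATS2D_06_AL" in names

    def test_full_mode_has_135_descriptors(self):
        names = Cats2DVectorizer(pair_mode="full").feature_names()
        assert len(names) == 135
        assert "CATS2D_02_LL" in names

    def test_butanol_counts_match_hand_enumeration(self):
        # CCCCO: L at C1-C3, O is D+A; graph distances O-C3=2, O-C2=3, O-C1=4
        v = cats2d("CCCCO", pair_mode="full")
        assert v["CATS2D_02_DL"] == 1
        assert v["CATS2D_03_DL"] == 1
        assert v["CATS2D_04_DL"] == 1
        assert v["CATS2D_01_LL"] == 2
        assert v["CATS2D_02_LL"] == 1
        # acceptor mirrors donor (same oxygen), plus the D/A co-location at 0
        assert v["CATS2D_02_AL"] == 1 and v["CATS2D_03_AL"] == 1 and v["CATS2D_04_AL"] == 1
        assert v["CATS2D_00_AD"] == 1
        assert v.sum() == 10

    def test_untyped_molecule_gives_zero_vector(self):
        # silane: no C/S/O/N, no charges -> nothing is typed
        v = cats2d("[SiH4]")
        assert (v == 0).all()

    def test_atom_order_invariance(self):
        a = cats2d("CC/C=C\\CCO", pair_mode="full")
        # same molecule, different atom ordering (canonicalized string)
        b = cats2d(Chem.MolToSmiles(Chem.MolFromSmiles("CC/C=C\\CCO")), pair_mode="full")
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
        c = cats2d("OCC/C=C\\CC", pair_mode="full")  # written from the hydroxyl end
        np.testing.assert_array_equal(a.to_numpy(), c.to_numpy())

    def test_pairwise_counts_match_brute_force(self):
        """Sum per (pair, distance) equals exhaustive typed-pair enumeration."""
        for smiles in ("CCCCO", "CC(C)C(=O)O", "Cc1ccc(O)cc1", "CSCCC=O"):
            mol = Chem.MolFromSmiles(smiles)
            types = assign_pharmacophore_types(mol)
            dist = Chem.GetDistanceMatrix(mol)
            v = cats2d(mol, pair_mode="full")
            brute = {}
            n = mol.GetNumAtoms()
            for i in range(n):
                for j in range(i, n):
                    d = int(dist[i, j])
                    if d > 8:
                        continue
                    if i == j:
                        from itertools import combinations

                        for t1, t2 in combinations(sorted(types[i]), 2):
                            brute[("".join(sorted((t1, t2))), 0)] = (
                                brute.get(("".join(sorted((t1, t2))), 0), 0) + 1
                            )
                    else:
                        for t1 in types[i]:
                            for t2 in types[j]:
                                key = ("".join(sorted((t1, t2))), d)
                                brute[key] = brute.get(key, 0) + 1
            for (pair, d), count in brute.items():
                assert v[f"CATS2D_{d:02d}_{pair}"] == count, (smiles, pair, d)
            assert v.sum() == sum(brute.values())

    def test_fixture_descriptor_matrix(self):
        mols = load_smiles_file(final_odor_fixture_path())
        assert len(mols) == 11
        labels = pd.Series({m.name: m.class_label for m in mols})
        assert labels.value_counts()["distinctive"] == 4
        assert labels.value_counts()["nondistinctive"] == 7
        desc = Cats2DVectorizer().transform(mols)
        assert desc.shape == (11, 90)
        assert (desc.to_numpy() >= 0).all()
        assert (desc.to_numpy() == desc.to_numpy().astype(int)).all()


class TestDescriptorFilter:
    def _matrix(self, seed=5, n=12, p=8):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"d{i}" for i in range(p)]
        )

    def test_constant_column_removed(self):
        X = self._matrix()
        X["const"] = 3.0
        out = od.filter_descriptors(X)
        assert "const" not in out.columns

    def test_duplicated_column_drops_exactly_one(self):
        X = self._matrix()
        X["dup"] = X["d0"]
        out = od.filter_descriptors(X)
        assert ("d0" in out.columns) != ("dup" in out.columns)

    def test_no_high_correlation_survives(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 1))
        X = pd.DataFrame(
            np.hstack([base + 0.1 * rng.normal(size=(20, 4)), rng.normal(size=(20, 4))]),
            columns=[f"c{i}" for i in range(8)],
        )
        out = od.filter_descriptors(X, cor_max=0.75)
        corr = out.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.75 + 1e-12

    def test_matches_brute_force_oracle(self):
        """Surviving set equals an independent reapplication of both rules."""
        rng = np.random.default_rng(5)
        X = self._matrix(seed=5, n=15, p=10)
        X["low_var"] = 0.01 * rng.normal(size=15)
        X["near_dup"] = X["d1"] + 0.01 * rng.normal(size=15)
        out = od.filter_descriptors(X, var_min=0.2, cor_max=0.75)

        cols = [c for c in X.columns if X[c].var(ddof=1) >= 0.2]
        while True:
            sub = X[cols].corr().abs()
            np.fill_diagonal(sub.to_numpy(), 0.0)
            if sub.to_numpy().max() <= 0.75:
                break
            mx = sub.to_numpy().max()
            pair = None
            for a in sub.index:
                hits = sub.loc[a][np.isclose(sub.loc[a], mx)]
                if len(hits):
                    pair = (a, sorted(hits.index)[0])
                    break
            a, b = pair
            drop = a if sub.loc[a].mean() >= sub.loc[b].mean() else b
            cols = [c for c in cols if c != drop]
        assert list(out.columns) == cols

    def test_everything_removed_raises(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            od.filter_descriptors(X)


class TestLooClassify:
    def _separable(self, n_per_class=6, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(2 * n_per_class, 3)),
            columns=[f"d{i}" for i in range(3)],
        )
        labels = pd.Series(
            ["distinctive"] * n_per_class + ["nondistinctive"] * n_per_class,
            index=X.index,
        )
        X["sep"] = [5.0] * n_per_class + [-5.0] * n_per_class
        return X, labels

    @pytest.mark.parametrize("model", ["forest", "bagged_trees"])
    def test_separable_toy_perfect_auc(self, model):
        X, labels = self._separable()
        res = loo_classify(X, labels, model=model, n_trees=100, random_state=1)
        assert res.auc == pytest.approx(1.0)
        assert res.importance.idxmax() == "sep"

    def test_two_per_class_auc_is_defined(self):
        X, labels = self._separable(n_per_class=2)
        res = loo_classify(X, labels, n_trees=50, random_state=2)
        assert 0.0 <= res.auc <= 1.0

    def test_single_class_rejected(self):
        X, labels = self._separable()
        with pytest.raises(ValueError):
            loo_classify(X, pd.Series("distinctive", index=X.index))

    def test_permutation_destroys_separation(self):
        """Shuffled labels lose the perfect separation of the toy."""
        X, labels = self._separable()
        rng = np.random.default_rng(7)
        aucs = [
            loo_classify(
                X, labels, permute=True, n_trees=50,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).auc
            for _ in range(10)
        ]
        assert float(np.mean(aucs)) < 0.9
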