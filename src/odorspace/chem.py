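"""CATS2D pharmacophore-pair descriptors and odor-set classification.

CATS2D (Chemically Advanced Template Search, topological variant) describes a
molecule by counting pairs of pharmacophore-typed heavy atoms at each
shortest-path bond distance.  Five atom types are used — L (lipophilic),
A (hydrogen-bond acceptor), D (hydrogen-bond donor), N (negatively charged or
acidic), P (positively charged or basic amine) — and distances 0..8 bonds.

Two pair enumerations are provided.  ``pair_mode="cross"`` (default) uses the
ten cross-type pairs (the n(n-1)/2 = 10 combinations of five types), giving
10 x 9 = 90 descriptors; ``pair_mode="full"`` adds the five same-type pairs
(LL, AA, ...), giving 135.  The classic 90-descriptor convention presumes
cross-type pairs only, yet same-type descriptors such as CATS2D_02_LL are
established names — both enumerations are kept because the two conventions
cannot be reconciled (see docs/methods.md).

The classification stage filters descriptors by variance and pairwise
correlation and evaluates tree ensembles (random forest or bagged CART) by
leave-one-out cross-validation with a label-permutation negative control.

The pharmacophore typing rule table is a declared dialect of the classic
CATS conventions (the descriptor engines in commercial packages do not
publish theirs); it is visible and overridable via :data:`TYPE_RULES`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "Molecule",
    "assign_pharmacophore_types",
    "Cats2DVectorizer",
    "cats2d",
    "DescriptorFilter",
    "filter_descriptors",
    "LOOResult",
    "loo_classify",
    "load_smiles_file",
    "final_odor_fixture_path",
]

TYPES = ("A", "D", "L", "N", "P")
CROSS_PAIRS = tuple("".join(p) for p in combinations(TYPES, 2))  # 10
ALL_PAIRS = tuple(sorted(CROSS_PAIRS + tuple(t + t for t in TYPES)))  # 15

_ACIDIC_O_SMARTS = [
    Chem.MolFromSmarts("[OX2H1][CX3](=O)"),  # carboxylic acid OH
    Chem.MolFromSmarts("[OX2H1][SX4](=O)(=O)"),  # sulfonic acid OH
    Chem.MolFromSmarts("[OX2H1][PX4](=O)"),  # phosphate / phosphonic OH
]
_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class Molecule:
    """A named odorant structure, optionally with a class label."""

    name: str
    smiles: str
    class_label: str | None = None  # "distinctive" / "nondistinctive"

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {self.name!r}: {self.smiles!r}")
        if mol.GetNumHeavyAtoms() < 1:
            raise ValueError(f"{self.name!r} has no heavy atoms")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ValueError(f"{self.name!r} is a disconnected structure")
        return mol


def _is_amine_nitrogen(atom: Chem.Atom) -> bool:
    """sp3 nitrogen of an amine: neutral, not amide/amidine-adjacent."""
    if atom.GetSymbol() != "N" or atom.GetFormalCharge() != 0:
        return False
    if atom.GetHybridization() != Chem.HybridizationType.SP3:
        return False
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() == "C":
            for bond in nb.GetBonds():
                other = bond.GetOtherAtom(nb)
                if bond.GetBondType() == Chem.BondType.DOUBLE and other.GetSymbol() in (
                    "O",
                    "N",
                ):
                    return False  # amide / amidine nitrogen is not basic
    return True


def _rule_donor(atom: Chem.Atom, mol: Chem.Mol, acidic_o: set[int]) -> bool:
    return atom.GetSymbol() in ("O", "N") and atom.GetTotalNumHs() >= 1


def _rule_acceptor(atom: Chem.Atom, mol: Chem.Mol, acidic_o: set[int]) -> bool:
    if atom.GetSymbol() == "O":
        return True
    return (
        atom.GetSymbol() == "N"
        and atom.GetTotalNumHs() == 0
        and atom.GetFormalCharge() <= 0
    )


def _rule_positive(atom: Chem.Atom, mol: Chem.Mol, acidic_o: set[int]) -> bool:
    return atom.GetFormalCharge() > 0 or _is_amine_nitrogen(atom)


def _rule_negative(atom: Chem.Atom, mol: Chem.Mol, acidic_o: set[int]) -> bool:
    return atom.GetFormalCharge() < 0 or atom.GetIdx() in acidic_o


def _rule_lipophilic(atom: Chem.Atom, mol: Chem.Mol, acidic_o: set[int]) -> bool:
    if atom.GetSymbol() not in ("C", "S"):
        return False
    return all(
        nb.GetSymbol() in ("C", "S") or nb.GetSymbol() in _HALOGENS
        for nb in atom.GetNeighbors()
    )


#: Pharmacophore typing rules, applied per heavy atom; override to change dialect.
TYPE_RULES = {
    "D": _rule_donor,
    "A": _rule_acceptor,
    "P": _rule_positive,
    "N": _rule_negative,
    "L": _rule_lipophilic,
}


def assign_pharmacophore_types(mol: Molecule | Chem.Mol | str) -> list[set[str]]:
    """Type-set per heavy atom (atom order of the rdkit molecule)."""
    if isinstance(mol, Molecule):
        rdmol = mol.to_rdkit()
    elif isinstance(mol, str):
        rdmol = Molecule(name=mol, smiles=mol).to_rdkit()
    else:
        rdmol = mol
    acidic_o: set[int] = set()
    for patt in _ACIDIC_O_SMARTS:
        for match in rdmol.GetSubstructMatches(patt):
            acidic_o.add(match[0])  # first SMARTS atom is the hydroxyl oxygen
    out: list[set[str]] = []
    for atom in rdmol.GetAtoms():
        types = {t for t, rule in TYPE_RULES.items() if rule(atom, rdmol, acidic_o)}
        out.append(types)
    return out


class Cats2DVectorizer(TransformerMixin, BaseEstimator):
    """Count pharmacophore-typed atom pairs per topological distance.

    ``transform`` accepts a sequence of :class:`Molecule`, SMILES strings or
    rdkit molecules and returns a DataFrame whose columns are Dragon-style
    descriptor names ``CATS2D_{distance:02d}_{pair}``.  Two types carried by
    one atom count as a pair at distance 0.
    """

    def __init__(self, max_distance: int = 8, pair_mode: str = "cross"):
        self.max_distance = max_distance
        self.pair_mode = pair_mode

    @property
    def pairs_(self) -> tuple[str, ...]:
        if self.pair_mode == "cross":
            return CROSS_PAIRS
        if self.pair_mode == "full":
            return ALL_PAIRS
        raise ValueError("pair_mode must be 'cross' or 'full'")

    def feature_names(self) -> list[str]:
        return [
            f"CATS2D_{d:02d}_{pair}"
            for pair in sorted(self.pairs_)
            for d in range(self.max_distance + 1)
        ]

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        names = []
        for i, m in enumerate(X):
            if isinstance(m, Molecule):
                rdmol, name = m.to_rdkit(), m.name
            elif isinstance(m, str):
                rdmol, name = Molecule(name=m, smiles=m).to_rdkit(), m
            else:
                rdmol, name = m, f"mol_{i}"
            rows.append(self._one(rdmol))
            names.append(name)
        return pd.DataFrame(rows, index=names, columns=self.feature_names())

    def _one(self, rdmol: Chem.Mol) -> dict[str, int]:
        pairs = set(self.pairs_)
        counts = {name: 0 for name in self.feature_names()}
        types = assign_pharmacophore_types(rdmol)
        dist = Chem.GetDistanceMatrix(rdmol)
        if np.any(~np.isfinite(dist)):
            raise ValueError("topological distances undefined on a disconnected graph")
        typed = [i for i, t in enumerate(types) if t]
        for idx, i in enumerate(typed):
            # same atom, distinct types -> distance 0
            for t1, t2 in combinations(sorted(types[i]), 2):
                pair = "".join(sorted((t1, t2)))
                if pair in pairs:
                    counts[f"CATS2D_00_{pair}"] += 1
            for j in typed[idx + 1 :]:
                d = int(dist[i, j])
                if d > self.max_distance:
                    continue
                for t1 in types[i]:
                    for t2 in types[j]:
                        pair = "".join(sorted((t1, t2)))
                        if pair in pairs:
                            counts[f"CATS2D_{d:02d}_{pair}"] += 1
        return counts


def cats2d(
    mol: Molecule | Chem.Mol | str, max_distance: int = 8, pair_mode: str = "cross"
) -> pd.Series:
    """CATS2D vector of one molecule (90 entries in paper mode)."""
    vec = Cats2DVectorizer(max_distance=max_distance, pair_mode=pair_mode).transform([mol])
    return vec.iloc[0]


class DescriptorFilter(TransformerMixin, BaseEstimator):
    """Variance then correlation pruning of a descriptor matrix.

    Columns with sample variance below ``var_min`` are dropped first.  Then,
    while any remaining pair has |Pearson r| > ``cor_max``, the pair with the
    largest |r| is taken (ties: lexicographic column order) and the member
    with the larger mean absolute correlation to everything else is removed.
    Deterministic; mirrors the usual greedy correlation-filter convention.
    """

    def __init__(self, var_min: float = 0.2, cor_max: float = 0.75):
        self.var_min = var_min
        self.cor_max = cor_max

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("descriptor filtering needs at least two molecules")
        keep = [c for c in X.columns if X[c].var(ddof=1) >= self.var_min]
        dropped_var = [c for c in X.columns if c not in keep]
        dropped_cor: list = []
        cols = list(keep)
        if cols:
            corr = X[cols].corr().abs()
            np.fill_diagonal(corr.to_numpy(), 0.0)
            while True:
                if corr.size == 0:
                    break
                max_r = corr.to_numpy().max() if len(corr) else 0.0
                if not len(corr) or max_r <= self.cor_max:
                    break
                # lexicographically first pair attaining the maximum
                pair = None
                for a in corr.index:
                    row = corr.loc[a]
                    hits = row[np.isclose(row, max_r)]
                    if len(hits):
                        pair = (a, sorted(hits.index)[0])
                        break
                a, b = pair
                mean_a = corr.loc[a].mean()
                mean_b = corr.loc[b].mean()
                drop = a if (mean_a > mean_b or (mean_a == mean_b and a >= b)) else b
                dropped_cor.append(drop)
                corr = corr.drop(index=drop, columns=drop)
            cols = [c for c in cols if c not in dropped_cor]
        if not cols:
            raise ValueError(
                "all descriptors removed "
                f"(variance < {self.var_min}: {len(dropped_var)}, "
                f"correlation > {self.cor_max}: {len(dropped_cor)})"
            )
        self.kept_ = cols
        self.dropped_variance_ = dropped_var
        self.dropped_correlation_ = dropped_cor
        return self

    def transform(self, X) -> pd.DataFrame:
        return pd.DataFrame(X)[self.kept_]


def filter_descriptors(
    matrix: pd.DataFrame, var_min: float = 0.2, cor_max: float = 0.75
) -> pd.DataFrame:
    """Functional wrapper over :class:`DescriptorFilter`."""
    return DescriptorFilter(var_min=var_min, cor_max=cor_max).fit_transform(matrix)


@dataclass
class LOOResult:
    """Leave-one-out evaluation: AUC, fold-averaged importance, LOO scores."""

    auc: float
    importance: pd.Series
    scores: pd.Series


def _make_model(model: str, n_trees: int, seed: int):
    if model == "forest":
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )
    if model == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=n_trees,
            random_state=seed,
        )
    raise ValueError("model must be 'forest' or 'bagged_trees'")


def _bagging_importance(clf: BaggingClassifier, n_features: int) -> np.ndarray:
    imps = np.zeros(n_features)
    for tree in clf.estimators_:
        imps += tree.feature_importances_
    return imps / len(clf.estimators_)


def loo_classify(
    matrix: pd.DataFrame,
    labels: pd.Series,
    model: str = "forest",
    permute: bool = False,
    n_trees: int = 500,
    random_state: int = 0,
) -> LOOResult:
    """Leave-one-out AUC and importance of a tree ensemble on the odor sets.

    Each molecule is held out once; the ensemble fit on the rest scores it.
    AUC-ROC is computed over the collected held-out scores.  ``permute=True``
    shuffles the labels once before the full LOO cycle (negative control).
    """
    X = pd.DataFrame(matrix)
    y = pd.Series(labels).reindex(X.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("leave-one-out classification needs two classes")
    if y.value_counts().min() < 2:
        raise ValueError("need at least two molecules per class")
    rng = np.random.default_rng(random_state)
    if permute:
        y = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    pos = classes[-1] if "distinctive" not in classes else "distinctive"
    scores = {}
    imp_sum = np.zeros(X.shape[1])
    for holdout in X.index:
        rest = X.index != holdout
        clf = _make_model(model, n_trees, seed=int(rng.integers(0, 2**31 - 1)))
        clf.fit(X[rest].to_numpy(dtype=float), y[rest].to_numpy())
        if isinstance(clf, BaggingClassifier):
            imp_sum += _bagging_importance(clf, X.shape[1])
        else:
            imp_sum += clf.feature_importances_
        proba = clf.predict_proba(X.loc[[holdout]].to_numpy(dtype=float))[0]
        scores[holdout] = float(proba[list(clf.classes_).index(pos)])
    score_series = pd.Series(scores).reindex(X.index)
    y_bin = (y == pos).astype(int)
    auc = float(roc_auc_score(y_bin.to_numpy(), score_series.to_numpy()))
    return LOOResult(
        auc=auc,
        importance=pd.Series(imp_sum / len(X), index=X.columns),
        scores=score_series,
    )


def load_smiles_file(path: str | Path) -> list[Molecule]:
    """Read a name<TAB>smiles[<TAB>label] file; '#' lines are comments."""
    mols = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected name<TAB>smiles[<TAB>label]")
        name, smiles = parts[0], parts[1]
        label = parts[2] if len(parts) > 2 and parts[2] else None
        mols.append(Molecule(name=name, smiles=smiles, class_label=label))
    return mols


def final_odor_fixture_path() -> Path:
    """Packaged SMILES fixture of the 11 consensus odors with their labels."""
    return Path(__file__).parent / "data" / "final_odors.smi"
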