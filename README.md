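# odorspace

Analysis of how the perceptual space of odors changes with olfactory loss.

People with a reduced sense of smell (hyposmia) do not simply perceive odors
more weakly — the *structure* of their perception shifts. Ratings of
familiarity and intensity, which track olfactory function, fade, while
trigeminally mediated sensations (pain, temperature, irritation) persist.
`odorspace` implements a two-arm analysis that identifies which of seven
perceptual properties (edibility, intensity, irritation, temperature,
familiarity, hedonics, painfulness) and which of 40 odorants discriminate
normosmic from hyposmic raters, plus a chemoinformatics stage probing whether
the resulting odor sets differ chemically. Because the underlying clinical
cohort is not publicly deposited, the package ships a synthetic-cohort
generator that reproduces the study design (146 subjects over 4 odor sets,
10 odors/set, 7 properties, 2 ratings each on a 1–5 grade scale) with
controllable planted diagnosis effects, so every stage is testable.

## The method

**Data preparation.** Subjects with fewer than two thirds of their required
ratings are excluded; remaining gaps are filled by k-nearest-neighbor
imputation (k = 3, distance-weighted, within the subject's own odor set).
Two matrices result: the block-diagonal subject × (odor, property) feature
matrix *X* (146 × 280: each subject rated only their own set's 70 cells) and
the diagnosis-stratified mean-profile matrix (80 × 7: 40 odors × 2 diagnoses).

**Unsupervised arm.** PCA of the centered, unscaled 80 × 7 profile matrix.
For each odor, the Euclidean distance between its normosmic and hyposmic
projections on the PC1 × PC2 plane measures how differently the two groups
perceive it. A computed ABC analysis of these distances categorizes odors
into distinctive (set A), intermediate (B) and non-distinctive (C).

**ABC analysis.** Sorting positive values descending, the cumulative curve
point *i* is (i/n, Σ≤i / Σ). The A|B limit is the point closest to the ideal
(0, 1); the B|C limit is the break-even point, the last segment with slope ≥ 1
(value ≥ mean). Set A holds "the few most important" items.

**Supervised arm.** 1000 Monte-Carlo runs (here scaled down) of a random
forest (1000 trees, mtry = round(0.5·√d) = 8, ≤ 7 leaf nodes) mapping *X*
onto the diagnosis, trained on stratified two-thirds subsets and scored by
AUC-ROC on the held-out third. Per run, per feature: Gini importance and the
−log *p* of a Wilcoxon–Mann–Whitney test between diagnoses on the training
subjects. Both run-averaged 40 × 7 matrices are rank-transformed and
multiplied — the rank product is a logical AND: a cell counts only if the
forest relies on it *and* it shows a large group difference. ABC set A of the
rank products gives the most relevant (odor, property) cells; inverting both
rankings gives the least relevant ones. Training on permuted labels provides
the guessing-level control.

**Consensus.** Odors claimed exclusively by the most-relevant (resp. least-
relevant) selection are intersected with the unsupervised distinctive (resp.
non-distinctive) categories, yielding the final odor sets.

**Chemoinformatics.** Each odorant's CATS2D descriptor vector counts
pharmacophore-typed atom pairs — L (lipophilic), A (acceptor), D (donor),
N (negative/acidic), P (positive/basic) — at topological distances 0–8
(10 pair types × 9 distances = 90 descriptors). After variance (< 0.2) and
correlation (> 0.75) filtering, random-forest and bagged-CART models are
evaluated by leave-one-out cross-validation with a label-permutation control.

## Worked example

```python
import odorspace as od

design = od.CohortDesign(seed=1)      # 146 subjects, 4 sets, 10 odors, 7 properties
effect = od.EffectSpec(shift=-1.0)    # hyposmic rate familiarity+intensity 1 grade lower
cfg = od.RunConfig(n_runs=100, n_trees=100, seed=1)

result = od.run_pipeline(design, effect, cfg, with_permuted_control=True)

sel = result.selection
print(f"feature matrix: {result.features.X.shape[0]} x {result.features.X.shape[1]}")
print(f"mean profiles:  {result.profiles.values.shape[0]} x {result.profiles.values.shape[1]}")
evr = result.projection.explained_variance_fraction
print(f"PC1+PC2 explained variance: {100 * evr.iloc[:2].sum():.1f}%")
print(f"held-out AUC median: {100 * sel.auc_median:.1f}% "
      f"(95% CI {100 * sel.auc_ci95[0]:.1f}-{100 * sel.auc_ci95[1]:.1f}%)")
print(f"permuted-label AUC median: {100 * sel.auc_permuted_median:.1f}%")
print("most discriminating properties:",
      ", ".join(f"{p} ({n})" for p, n in sel.property_tally_most.most_common(3)))
```

Output:

```
feature matrix: 146 x 280
mean profiles:  80 x 7
PC1+PC2 explained variance: 45.5%
held-out AUC median: 91.0% (95% CI 87.1-95.7%)
permuted-label AUC median: 41.6%
most discriminating properties: intensity (35), familiarity (33), painfulness (8)
```

The forest separates the diagnoses far above chance on held-out subjects
(91% vs 42% with permuted training labels), and the rank-product selection
correctly singles out the two planted properties: intensity and familiarity
lead the most-relevant tally by a wide margin. On this synthetic cohort the
two retained components carry 45.5% of the profile variance — lower than on
clinical data, where property ratings are strongly inter-correlated, because
the generator draws each (odor, property) baseline independently.

A shell workflow covering the same steps:

```bash
odorspace simulate --seed 1 --out cohort.csv
odorspace prepare --in cohort.csv --out matrix.csv --profiles profiles.csv
odorspace unsupervised --profiles profiles.csv --out-dir unsup/
odorspace supervised --matrix matrix.csv --runs 100 --trees 100 --seed 1 --out-dir sup/
odorspace consensus --supervised sup/selection.json --unsupervised unsup/categories.json --out consensus.json
odorspace cats2d --smiles src/odorspace/data/final_odors.smi --out desc.csv
```

## Layout

| Module | Contents |
| --- | --- |
| `odorspace.cohort` | study design, synthetic cohort generator, CSV I/O |
| `odorspace.prepare` | completeness filter, kNN imputation, feature/profile matrices |
| `odorspace.abc_analysis` | computed ABC item categorization |
| `odorspace.unsupervised` | `ProfilePCA`, paired distances, odor categorization |
| `odorspace.supervised` | `MonteCarloRelevance`, stratified splits, rank-product selection |
| `odorspace.consensus` | exclusive sets and arm intersection |
| `odorspace.chem` | pharmacophore typing, `Cats2DVectorizer`, `DescriptorFilter`, LOO models |
| `odorspace.pipeline` | end-to-end `run_pipeline` |
| `odorspace.cli` | `odorspace` command-line interface |

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
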