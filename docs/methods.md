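# Methods

This note records the models, parameter choices and numerical conventions
behind `odorspace`, and what the synthetic-cohort experiments do and do not
establish about clinical data.

## Synthetic cohort model

The generator emulates the study design: 146 subjects split over four odor
sets of 38/33/42/33 subjects (8/9/17/8 hyposmic), 10 odors per set, 7
perceptual properties, 2 ratings per odor × property, grades 1–5.

Each rating is drawn from a latent Gaussian model

```
grade = clip(round(b[odor, property] + shift · 1[hyposmic & affected] + ε), 1, 5)
```

with baseline `b ~ U(2, 4)` drawn once per (odor, property) and rating noise
`ε ~ N(0, noise_sd)`. Defaults, chosen once:

* `shift = −1.0` grade on familiarity and intensity (hyposmic minus
  normosmic) — the direction and the two properties match the finding the
  pipeline is meant to recover; the magnitude is one grade step, the smallest
  interpretable effect on a five-point scale.
* `noise_sd = 1.0` grade — one scale step of rating noise, a realistic
  within-rater variability for five-point odor ratings.
* `missing_rate = 0.05` — clinical completeness was high (median ≈ 94%);
  each subject loses `floor(0.05 · 140) = 7` cells uniformly at random, so
  default subjects never cross the one-third exclusion threshold. Incomplete
  subjects for filter tests are constructed explicitly.
* Baselines `U(2, 4)` keep one grade of headroom on each side so a ±1 shift
  is not annihilated by clipping.

Two consequences worth knowing. First, rounding and clipping attenuate the
latent shift: a −1.0 latent shift appears as a −0.83 to −0.91 observed mean
difference (measured by direct averaging over 1000 simulated subjects).
Second, because baselines are drawn independently per (odor, property), the
seven properties are uncorrelated across odors; clinical rating profiles are
strongly inter-correlated, which is why PCA on real data concentrates ~85% of
variance in two components while the synthetic profiles yield ~45%. Passing
tests on synthetic cohorts therefore demonstrate that the machinery recovers
planted effects under honest noise — not that clinical effect sizes or
variance structure are reproduced.

The null model (`shift = 0`) makes the diagnosis groups exchangeable by
construction and is used for the chance-level controls.

## Preparation

Subjects with < 2/3 of their 140 required ratings are excluded (threshold
applied per subject). Imputation is k-nearest neighbors with k = 3 within
the subject's own odor set: neighbor distance is Euclidean over mutually
observed cells scaled by overlap size, imputed values are distance-weighted
neighbor means with a column-mean fallback when no neighbor overlaps
(scikit-learn's `KNNImputer` provides exactly these semantics). Observed
values are never altered, and imputation of a complete cohort is the
identity. Distances are computed on raw grades, not standardized ones — all
columns share the 1–5 scale. Repetitions are collapsed by arithmetic mean
when building the feature matrix; column order is (set, odor design order,
canonical property order). Out-of-block cells are structurally absent (NaN),
never zero.

## ABC analysis

The implementation is purely discrete: values sorted descending, curve point
`i` at (i/n, cumsum_i/total), plus the origin. The A|B limit is the curve
point minimizing Euclidean distance to (0, 1) (first index on ties, with a
1e-12 tolerance so exact geometric ties — e.g. all-equal inputs — do not
depend on cumsum rounding). The B|C limit is the break-even point: the last
segment with slope ≥ 1, equivalently the last value ≥ the mean; if it
precedes the A|B limit, set B is empty. No smoothing or interpolation is
applied, so the partition needs no bandwidth choice and is exactly
reproducible; an independent brute-force oracle verifies it exhaustively for
all inputs of length ≤ 8 over {1, 2, 3}.

A geometric property with practical consequences: for flat (near-uniform)
value distributions the Pareto point lands at roughly one third of the items,
so ABC set A of 280 rank products contains ~95 cells when most cells are
noise. Selection sharpness is a property of the value distribution, not a
tunable of the partition.

## Unsupervised arm

PCA is computed on the centered, unscaled profile matrix; all components are
kept for the variance accounting (fractions sum to 1) and `n_components = 2`
(a parameter) select the plane for scores and distances. Component signs are
fixed by making each component's largest-magnitude loading positive. Property
contributions are squared loadings normalized to 100% per component. Paired
odor distances are taken on the retained plane (full-space distances are one
keyword away but not the default). Exact zero distances are jittered by
machine epsilon before ABC partitioning, which maps A → distinctive,
B → intermediate, C → non-distinctive.

## Supervised arm

Per Monte-Carlo run: a stratified two-thirds training split, a random forest
(`n_trees`, `mtry = round(0.5·√d)`, `max_leaf_nodes = 7`), Gini importance per
feature, two-sided Wilcoxon–Mann–Whitney −log *p* (natural log, normal
approximation with tie and continuity correction) per feature over the
training subjects of the feature's odor set, and AUC-ROC on the held-out
third. Features with no variance in a run contribute importance 0 and p = 1.
Run-level seeds are spawned from one master seed, so results are reproducible
and independent of execution order.

Stratification is proportional per (diagnosis × odor set) stratum by default.
A `balanced` mode draws the same number from every stratum (two thirds of the
smallest, i.e. training sets of 5 × 8 strata) so that no odor set dominates
by size; it improves the ranking of planted cells but trains on only 40
subjects. Two facts about the proportional default, measured on null cohorts:
the pooled held-out AUC has a mild optimistic bias (median ≈ 0.56, not 0.50)
because hyposmic base rates differ between odor sets and a forest can exploit
set membership encoded by the block structure; the permuted-label control
shows the same effect in attenuated form. Both stay inside the [0.40, 0.60]
chance band used by the tests.

The single forest sees out-of-block cells as a constant sentinel (0, outside
the grade scale), which makes them useless as split variables; a per-set
forest mode (`block_mode="per_set"`) is available instead.

Rank products use ascending average ranks (largest value → largest rank);
the least-relevant direction inverts both rankings before multiplying. Cells
claimed by ABC set A of both directions are removed from both and logged.

## Consensus

Odors appearing only in the most-relevant (resp. least-relevant) odor lists
form the supervised-exclusive sets; intersection with the unsupervised
categories yields the finals. Overlap fractions are reported with the
supervised-exclusive set as denominator and `null` when it is empty.

On planted-subset cohorts (a −1 grade shift on familiarity + intensity of 8
designated odors), per-seed final distinctive sets are small — typically 2–3
odors, of which ~2 are planted. This is a structural consequence of the two
preceding facts: ABC set A of near-uniform rank products is large (~95
cells), so every planted odor has a high chance (~0.9) that one of its five
unaffected properties lands in the least-relevant set A, which removes the
odor in the exclusivity step. Enrichment of the consensus sets for planted
odors is therefore assessed by pooling hits over five seeds against the exact
convolution of per-seed hypergeometric nulls; the pooled test is decisive
(p ≈ 1e-4 or smaller) while single-seed significance is out of reach at such
set sizes (two hits in a two-odor set gives p = 0.036 at best).

## CATS2D stage

Pharmacophore typing is a declared rule table (the descriptor engines used
historically do not publish theirs): D = O/N bearing hydrogen; A = any O, or
N without hydrogen and without positive charge; P = positive formal charge or
sp3 amine nitrogen (amide/amidine excluded); N = negative formal charge or
the hydroxyl oxygen of carboxylic/sulfonic/phosphoric groups; L = C or S
whose heavy neighbors are only C, S or halogens. Atoms may carry several
types; two types on one atom count as a pair at distance 0.

Two pair enumerations exist because the two historical conventions cannot be
reconciled: `pair_mode="cross"` (default) uses the 10 cross-type pairs
(n(n−1)/2 with n = 5), giving the classic 90-descriptor count, but contains
no same-type pair such as LL; `pair_mode="full"` uses all 15 unordered pairs
(135 descriptors) and is the mode in which LL-type counts are defined. Counts are raw (no occupancy scaling); distances
are shortest-path bond counts from RDKit, capped at 8.

Descriptor filtering drops columns with sample variance < 0.2 (ddof = 1),
then greedily resolves each remaining pair with |Pearson r| > 0.75 by
removing the member with the larger mean absolute correlation (ties:
lexicographic), recomputing after every removal — deterministic by
construction.

Leave-one-out evaluation pools the held-out scores of all n fits into one
AUC. A caveat documented here because it surprises: under label permutation
with n = 11 and a 4/7 class split, the pooled-LOO AUC null is *not* centered
at 0.5 but near 0.35 — removing a sample biases the training majority against
its class, a well-known pessimism of leave-one-out at small n. The
permutation control tests therefore check that the distribution's center lies
in a wide chance band [0.3, 0.7] rather than asserting 0.5. The packaged
odorant structures (`data/final_odors.smi`) carry their consensus class
labels; on these 11 real structures the LOO AUC is reported as computed, with
no claim that the class boundary is chemically learnable at this sample size.

## Problem sizes

Tests and the acceptance script run the Monte-Carlo loop at 100 runs × 100
trees (60 runs per seed for the five-seed subset-recovery experiment) and the
chemistry permutation control at 200 cycles × 10 trees; `RunConfig` defaults
remain the study-scale 1000 × 1000. All randomness flows from explicit seeds;
identical seeds give byte-identical cohorts and identical pipeline results.

## Known limitations

* The generator plants homogeneous shifts; it does not model per-odor effect
  heterogeneity, cultural modulation of familiarity/hedonics, subject-level
  rating styles, or correlated property baselines.
* The proportional-stratification AUC carries the set-base-rate lift
  described above; use `balanced=True` when an unbiased null is more
  important than per-feature power.
* ABC set sizes on noise-dominated rank products are large by geometry;
  downstream exclusivity steps inherit that breadth.
* The pharmacophore rule table is one reasonable dialect; descriptors from
  other engines will differ in detail.
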