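# Methods

## Pair classification model

Drug–protein pairs are classified by a linear score f(D,P) = wᵀΦ(D,P) over a
binary pair descriptor. The tensor product descriptor places a 1 at position
k = i·N + j exactly when the drug carries feature i and the protein carries
feature j (row-major by drug feature); the combined descriptor appends the
raw drug and protein vectors after the tensor block. `DescriptorSpec` owns
this layout, so any weight position decodes back to named features and saved
models remain portable. Designs are materialised sparsely and only for
requested pairs: with realistic dimensions (e.g. 1179 side effects × 476
domains ≈ 5.6·10⁵ positions) a dense design over all pairs is not feasible,
but each pair's support is only |Φ(D)|₀·|Φ(P)|₀ (+ the two profile supports
for combined descriptors).

Weights minimise R(w) + C·Σ log(1 + exp(−y·wᵀΦ)), with R the L1 norm or the
*squared* L2 norm (sum of squared values, no ½ factor). The optimisation is
delegated to liblinear, whose primal forms are ‖w‖₁ + C_s·loss and
½wᵀw + C_s·loss; the mapping (L1: C_s = C, L2: C_s = C/2) is applied
internally and recorded in `fit_metadata`, so reported (penalty, C) always
refer to the objective above. Solver defaults: tolerance 1e-4 (liblinear's
native stopping rule), iteration budget 100 — overruns are recorded in
`fit_metadata["converged"]` rather than raised, which matters only deep into
the large-C end of the grid where models are dense and CV AUC is already
declining. L1 weights below 1e-8 in magnitude are truncated to exact zeros
(threshold recorded); L2 nonzero counts use the same threshold so sparsity
comparisons are like for like.

**Intercept.** The objective has no bias term and the default fit has none;
an opt-in `intercept` flag exists. This is not
cosmetic: with ~95% negative pairs and no intercept, the loss pushes every
frequently occurring descriptor cell negative, and rankings partly reflect a
pair's descriptor support size rather than the planted signal (on a strongly
planted synthetic dataset, pooled pair-wise AUC moves from ≈0.57 without an
intercept to ≈0.97 with one). Analyses that care about ranking quality
should consider the flag; analyses that must match the bias-free objective
above should leave it off.

**Regularization path.** C is chosen from the fixed grid
(10⁻⁴, 10⁻³, …, 10⁴) by cross-validated pooled AUC, with ties broken toward
the smaller C (the sparser model). Selection is non-nested: it reuses the
same folds as the reported experiment. Under the blockwise protocol the
selection AUC pools the three test categories' scores, since no single
category is privileged a priori.

## Feature extraction and prediction

Pharmacogenomic features are the positively weighted tensor-block positions,
decoded to (side effect, domain) pairs; drug-/protein-block weights of
combined models describe single entities and are never features, and
negative weights are discarded rather than reported as anti-associations.
Method comparisons use (side effect, domain) identity only. Novel
predictions score every pair outside the known-positive set and return the
top k by score, ties broken by (drug, protein) ID so output is
deterministic.

## Cross-validation protocols

*Pair-wise*: all n_D·n_P pairs are partitioned into 5 folds; each fold is
scored by a model trained on the other four. *Block-wise*: drugs and
proteins are partitioned independently into 5 folds each (separate
sub-streams of the master seed); round t trains on (non-t drugs × non-t
proteins) and scores TestDrug-TrainProtein, TrainDrug-TestProtein and
TestDrug-TestProtein blocks. With this pairing each pair lands in a category
at most once over the run, and the TestDrug-TestProtein pool covers the
~1/5 of pairs whose drug and protein share a fold index — a small pool whose
AUC consequently carries sampling noise of roughly ±0.05 at the default
synthetic scale; see Limitations. Reported AUCs are *pooled* (one
Mann–Whitney AUC over all held-out scores per category, ties counted ½),
not means of per-fold AUCs; a mean-of-folds option exists for sensitivity
checks.

## Benchmark construction

Drugs are clustered by average linkage on Tanimoto similarity of their
fingerprints. The implementation is a direct Lance–Williams update on the
similarity matrix with a deterministic tie rule (highest mean cross-pair
similarity first; ties go to the lexicographically smallest pair of minimum
member IDs) because similarity ties are common with binary fingerprints and
reproducible dendrograms are required. Cutting at threshold t applies all
merges with similarity ≥ t; each surviving cluster contributes one
representative — the member with the most known interactions, ties by ID —
chosen to retain the most informative drugs. The default sweep 0.2…1.0 by
0.1 yields nine benchmarks of decreasing chemical redundancy; proteins are
kept in full. A benchmark retaining fewer drugs than the fold count triggers
a warning rather than an error, since very permissive thresholds can
legitimately collapse a library into a handful of clusters.

## Synthetic data generator

The generator emulates the statistical shape of a curated interaction
dataset at desk scale. Defaults: 80 drugs × 60 proteins, M = 30 side
effects, N = 20 domains, 64 fingerprint bits, K = 5 planted (side effect,
domain) pairs with effect size β = 4, label-noise rate 0.01, and an
intercept b calibrated by root finding so the mean interaction probability
is 5%. Labels are drawn from Pr(y=+1) = σ(Σ_planted β·dᵢpⱼ + b) and then
flipped at the noise rate. Profile densities (side effects 0.15, domains
0.10) were set to put a handful of on-bits in each profile — matching the
*per-entity on-bit counts* of real side-effect and domain annotations once
dimensions are scaled down, which is what determines tensor support sizes.
Fingerprints model lead-series redundancy: 8 series, one random base pattern
each (density 0.30), members flip each bit independently at 0.05, so
within-series Tanimoto similarity is high and the benchmark clustering has
structure to remove. All draws come from independent sub-streams of one
master seed, so adding a component never perturbs earlier draws.

What the generator does **not** emulate: entity-level interaction
propensities (hub proteins, promiscuous drugs), correlation between a
drug's chemistry and its side effects or targets (lead-series twins share
fingerprints only, not side-effect profiles), and PFAM co-occurrence
structure. Consequently the planted signal is purely feature-mediated and
transfers fully to held-out drugs and proteins: block-wise CV is only
mildly harder than pair-wise here (smaller training set), whereas on real
data the gap is large. Passing tests on this generator certify the
machinery and the recoverability of feature-mediated signal, not cold-start
difficulty on real pharmacology data.

## Numerical and design choices

- AUC is computed by the rank-based Mann–Whitney formula (average ranks for
  ties), which is exactly the pair-counting definition, rather than a
  trapezoidal ROC integral.
- Negatives are the complement of the positive list — a dataset-level
  convention, not an option.
- Feature-name order for pair-list inputs is lexicographic; all exported
  rankings break weight ties by (side effect, domain) lexicographic order;
  edge-list weights print with 4 decimals.
- Fold sizes differ by at most one; fold assignment, fits and all outputs
  are reproducible from the seed alone.
- Tanimoto of two empty fingerprints is defined as 0 with a warning.
- Degenerate fits (single-class training labels) raise with the offending
  fold named.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the default scale above (4 800 pairs, 600 tensor positions) and smaller;
full grid selection with 5-fold CV over nine C values completes in well
under a minute per dataset on one core.

## Known limitations

- The pair-wise/block-wise AUC *ordering* on the default synthetic family is
  a weak effect (mean ≈ +0.02–0.05 pooled AUC in pair-wise CV's favour)
  relative to the TestDrug-TestProtein pool's sampling noise, for the
  generator-design reasons above; single-seed comparisons of the two
  protocols are not reliable at this scale.
- liblinear's coordinate-descent path at very large C (≥10³) on the L1
  objective can exhaust the iteration budget; such fits are flagged in
  `fit_metadata` and occur only where the grid search has already passed the
  AUC optimum.
- No enrichment statistics are attached to features; weights are reported
  raw.
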