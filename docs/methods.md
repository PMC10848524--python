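# Methods

## Problem and model

`mlocpred` predicts the subcellular locale of an mRNA — one of
Cytoplasm, ER (endoplasmic reticulum), ExR (extracellular region),
Mitochondria or Nucleus — from the transcript sequence alone, written in
the DNA alphabet (U is mapped to T on input). A *single* multiclass
classifier serves all five classes; this unified design contrasts with
one-vs-rest schemes that train one binary model per locale and is
cheaper to tune, store and deploy.

The pipeline is: encode → cleanse → normalize → fit → evaluate.

## Feature encoders

Seven descriptor groups are concatenated in a fixed order (KMER, PSEKNC,
PSEEIIP, DPCP, TPCP, ZC48, ZC144), giving 6122 columns in total. All
encoders are pure functions of the sequence.

**k-mer composition (1360).** For k = 2..5, each of the 4^k oligomers
contributes N_i / L, the overlapping-window count over the sequence
length (16 + 64 + 256 + 1024 = 1360 features). Dividing by L rather
than by the window count L − k + 1 is the package default; a
`per_window` mode is available. Consequence of the default: each k-block
sums to (L − k + 1)/L, not to 1 — this is asserted by tests.

**PseKNC (1370).** Type-1 pseudo k-tuple nucleotide composition: the
four composition tiers for k = 2..5 (each tier normalized per window)
followed by one shared tier of λ = 10 sequence-order correlation
factors. Factor θ_j is the mean over all dinucleotide pairs at lag j of
the mean squared difference of six standardized dinucleotide structural
scales (rise, roll, shift, slide, tilt, twist). The full vector is
jointly normalized by (4 + w·Σθ) with weight w = 0.1, so it sums to 1.
λ, w and the scale set are configurable; the defaults give the
contractual 1360 + 10 = 1370 dimensions. Sequences shorter than λ + 2
nucleotides are rejected.

**Z-curve, phase-independent (48).** For each dinucleotide prefix LM,
trinucleotide frequencies p(LMA..LMT), normalized by the total window
count L − 2, are projected onto three axes:

    x_LM = (p(LMA) + p(LMG)) − (p(LMC) + p(LMT))   purine vs pyrimidine
    y_LM = (p(LMA) + p(LMC)) − (p(LMG) + p(LMT))   amino vs keto
    z_LM = (p(LMA) + p(LMT)) − (p(LMC) + p(LMG))   weak vs strong H-bond

16 prefixes × 3 components = 48 features, each in [−1, 1]. The map is
invertible given the prefix marginals — the test suite reconstructs the
trinucleotide frequencies from (x, y, z) and checks them against direct
counting to 1e-12.

**Z-curve, codon-phase-specific (144).** The same projection computed
separately for the three codon phases; phase p ∈ {1, 2, 3} collects
windows whose start index ≡ p − 1 (mod 3), with frequencies normalized
within each phase. Phase indexing by window-start modulus is a package
decision; the per-phase window counts partition L − 2 and differ by at
most 1.

**PseEIIP (64).** Each trinucleotide xyz scores
(EIIP_x + EIIP_y + EIIP_z) · f_xyz with the standard electron-ion
interaction pseudopotential constants (A 0.1260, C 0.1340, G 0.0806,
T 0.1335), shipped as a CSV resource and overridable.

**DPCP (2368) / TPCP (768).** Di-/trinucleotide frequency times a
tabulated physicochemical scale value: 16 × 148 and 64 × 12 features in
oligo-major order. The bundled scale tables are deterministic
*synthetic stand-ins* (z-scored per scale; filenames carry
`_synthetic`): the published 148- and 12-scale collections are not
reproduced here, and only the table shapes — hence the feature
dimensions — are treated as contracts. Users with the real tables can
load them with `load_property_table` and pass them to the encoders.

## Cleansing and normalization

Two mutually exclusive reduction paths:

1. **Filtering path (default).** Drop constant columns; then scan
   columns in their fixed block order and drop any column whose absolute
   Pearson correlation with an *earlier kept* column exceeds 0.98;
   finally z-score with training-set statistics (sample SD, ddof = 1).
   Absolute correlation is used because strongly anti-correlated
   descriptor pairs are as redundant as positively correlated ones. The
   scan order makes the rule deterministic and means the earlier group
   in the canonical order (e.g. k-mer before the physicochemical
   blocks) survives a collinear tie.
2. **PCA path.** Drop constant columns, z-score, then keep the smallest
   number of leading principal components reaching 95% cumulative
   explained variance.

Inside cross-validation both the selection and the normalizer are
refitted on the training folds only; applying training statistics to
held-out rows is the only place test data meets the fitted pipeline.

## Classifier suite

Families: two gradient-boosted tree variants (`gbdt_lgbm` = LightGBM,
`gbdt_xgb` = XGBoost histogram trees), `decision_tree`, `gaussian_nb`,
`mlp`, and `stack`. The stacking fusion trains the two boosters as
members and a multinomial logistic regression (config-replaceable) on
their out-of-fold class probabilities, produced by stratified 5-fold
splitting so the meta-learner never sees leakage. Hyperparameter search
is exhaustive over a declared grid, scored by stratified k-fold mean
accuracy (macro-F1 selectable), with ties broken by enumeration order.
All stochastic components take an explicit seed (default 42); boosters
run single-threaded for reproducibility. A `feature_subset`
hyperparameter restricts a member to given columns, used for ablations
and for constructing deliberately complementary stacking members in
tests.

## Evaluation protocol

Two experiment shapes: a stratified holdout with five-sixths of each
class for training and the remaining sixth for testing (per-class test
count = round(n_c / 6)), and stratified 5-fold CV with the full
pipeline refit per fold. The 5×5 confusion matrix is collapsed per
class into one-vs-rest counts, from which

    Pr = TP/(TP+FP)   Sn = TP/(TP+FN)   Sp = TN/(FP+TN)
    Acc = (TP+TN)/n   F1 = 2·Pr·Sn/(Pr+Sn)

A zero denominator yields 0 with a warning — a live path for rare
classes with no predicted positives. CV metrics pool the counts over
folds before applying the formulas (more stable for small classes than
averaging per-fold ratios); per-fold rows are retained. The macro
average is the unweighted mean over the five class rows; tables round to
2 dp for display while machine output keeps full precision.

## Synthetic data

The generator emulates a five-class labeled mRNA corpus: i.i.d.
background sequence with per-class GC content, planted motifs inserted
at uniform random positions at a configurable per-sequence rate
(integer part guaranteed, fractional part Bernoulli), and an optional
per-codon-position nucleotide bias. Default class proportions follow a
realistic benchmark imbalance (Cytoplasm 42.8%, ER 9.6%, ExR 5.7%,
Mitochondria 2.8%, Nucleus 39.1%), so rare-class code paths
(zero-division conventions, small CV folds) are exercised. The default
profiles plant poly-A runs (Nucleus, ExR), CG-rich words (ER, Nucleus),
AT-rich words (Cytoplasm, ExR), and give Mitochondria a codon-position
skew so the phase-specific Z-curve block carries its signal; a
`separable` variant strengthens all signals for end-to-end recovery
checks, and a `null` variant uses one identical profile for all classes.

What passing tests show — and don't. Recovery of planted signals
demonstrates that the encoders expose the relevant composition
statistics and that the pipeline is leak-free and wired correctly; it
does not demonstrate accuracy on real transcripts, which carry gene
structure, homology structure and label noise the i.i.d. generator does
not model. The null variant guards against the converse failure: with
no true signal, held-out balanced accuracy stays at chance (0.2).

## Numerical choices and problem sizes

- Sequence lengths default to 150–400 nt; encoder minimums are 5 nt
  (k-mer), λ + 2 = 12 nt (PseKNC).
- Collinearity uses population correlation computed from standardized
  columns, clipped to [−1, 1]; normalization uses sample SD (ddof = 1).
- Argmax label ties break by canonical class order (alphabetical).
- Probability rows from float32 backends are renormalized to sum to 1.
- The planted-signal benchmark runs at 200 sequences/class (1000 total,
  ~6122 raw features), which keeps a full pipeline fit around a minute
  on one core while leaving the rare-class paths realistic at a 1/6
  holdout.

## Known limitations

- The bundled DPCP/TPCP/PseKNC property tables are synthetic stand-ins;
  absolute feature values in those groups are not comparable with
  published descriptor implementations, though shapes and the
  frequency-times-scale construction are.
- No homology reduction, multi-locale handling, or real-data ingestion
  beyond FASTA + label tables.
- Probabilities are not calibrated; SHAP-style attributions are out of
  scope (a model-native feature-importance accessor is provided).
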