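# Methods

This note records the statistical procedures `abcscreen` implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real screen data.

## The screen and its quantities

The package analyses a two-strain yeast screen: a parental strain and an
"ABC-16" strain in which all 16 multidrug-resistance ABC-transporter genes
are deleted. A drug that is pumped out by ABC transporters loses that
protection in ABC-16, so differential growth inhibition between the strains
is a functional readout of substrate status. Two data modalities meet in the
analysis:

1. **Chemistry**: each compound is reduced to a 166-bit MACCS key profile
   (bit k = 1 iff substructure pattern k matches the molecule). MACCS keys
   are indexed 1..166; toolkit arrays with a dummy leading bit are sliced.
   Similarity between compounds is the Tanimoto coefficient on these bits;
   by convention two all-zero profiles score 0 (with a warning) to avoid
   0/0. Nearest-neighbor maps use all 166 keys — zero-variance filtering is
   a property of a particular training set, not of the chemistry — while
   modeling and enrichment matrices drop keys that are constant across the
   training drugs.
2. **Growth**: OD600 time series per (drug, strain, dose, replicate) well,
   reduced to a single relative-efficacy score per drug (below).

## Relative efficacy from growth curves

For each well the growth metric is the trapezoidal area under the OD600
curve. Within one (drug, strain, replicate), treated AUCs are normalized by
the no-drug control AUC, giving a growth fraction per dose (exactly 1 at
dose 0). The dose-response curve of fractions over the relative-dose grid
{0, 0.25, 0.5, 1.0} is again integrated by trapezoid — the control anchor
(0, 1) is included, which makes the no-inhibition curve integrate to exactly
1 and keeps the metric well defined when all treated doses are lethal.
The per-replicate score is

    relative efficacy = -log2( AUC_dr(ABC-16) / AUC_dr(parental) ),

zero when the strains respond identically, positive when the
transporter-null strain is more sensitive (substrate-like). Replicates are
averaged; the ternary category is sensitive / resistant when the mean score
exceeds ±ε and equal otherwise, with ε = 0.1 log2 units by default (the
"equal" band has no published width; 0.1 is well inside between-replicate
noise at the simulator's default noise level and is configurable).

Numerical guards: a treated growth AUC ≤ 0 is floored at 1e-6 × the control
AUC (with a warning) so the log-ratio stays finite for fully lethal doses;
a non-positive control AUC is an error, not a floor, because it means the
control well itself failed. The dose axis is relative to each drug's top
dose, which makes drugs with very different absolute potencies comparable;
truncated runs are integrated over the available span.

## Substructure enrichment

Each retained key is cross-tabulated against the binary sensitivity label
into a 2×2 table (a = present & sensitive, …). Association is tested with a
two-sided Fisher exact test computed directly from the hypergeometric
distribution: conditioning on the margins, the p-value sums the point
probabilities of all tables in the support whose probability does not
exceed the observed one, with a relative tie tolerance of 1e-7 (the
standard two-sided convention). Point probabilities use log-gamma
factorials; the unit tests check the implementation against exact
integer-arithmetic enumeration for every table with total ≤ 40 and against
an independent library implementation on random tables. A table with a
zero margin admits only one outcome, so p = 1 (warned).

Effect size is the natural-log odds ratio ln(ad/bc); when any cell is zero,
0.5 is added to every cell (Haldane–Anscombe) so the reported effect stays
finite. The correction never touches the p-value.

Multiplicity is handled by Benjamini–Hochberg step-up q-values computed
over the retained keys; because constant keys have degenerate tables, the
default denominator m is the number of retained keys, with an option to
inflate to m = 166 (the full dictionary) — both conventions appear in
practice and q-values simply scale by m. Significance is q < α with
α = 0.05 by default.

## Substrate-likeness modeling

The protocol is stratified k-fold cross-validation (k = 10) repeated R
times, with **meta-parameter marginalization**: within each fold, one model
per grid point is trained on the non-withheld drugs and scores the withheld
drugs, and a drug's final probability is the mean of its out-of-fold scores
over the entire grid and all repeats. Marginalizing rather than selecting a
per-fold best rewards learner families that perform well across their
configuration space and removes a selection step that is noisy at screen
sample sizes. Stratification deals each class round-robin into the
currently smallest folds, so per-fold class counts are within one drug of
proportional and no reweighting is needed. All randomness flows from one
master seed expanded per (repeat, fold, grid point) through hash-based seed
sequences, making runs exactly reproducible and order-independent.

Five learner families are supported, backed by scikit-learn:
k-nearest-neighbors (k ∈ {3,5,7,11}), logistic regression with L1 or L2
penalty (C ∈ {0.01,0.1,1,10}, liblinear), linear-kernel SVM with Platt
probabilities (same C grid), gradient boosting (trees ∈ {50,100,200} ×
depth ∈ {1,2,3}) and a single-hidden-layer neural net (2/4/8 units). The
published grids of the era's tooling are not recorded anywhere, so these
are moderate, conventional grids ordered small-to-large capacity;
`reduced_learners()` provides 1–2-point grids for fast runs. Demo and test
runs use k = 10 with R ∈ {1,2,5} and n = 150–400 drugs, sizes at which the
marginalized protocol's behavior (signal recovery, chance-level AUC under
label shuffling, optimism of in-sample fits) is already clearly expressed.

Metrics: AUC is the normalized Mann–Whitney rank statistic with ties
counted 1/2 (equivalently the probability a random positive outranks a
random negative). Confusion counts threshold the averaged probability at
0.5, one call per drug, so counts sum to n. For calling substrates on new
compounds the default threshold is 0.15: a conservative
high-precision/low-recall classifier concentrates true substrates in the
0.15–0.5 band, and lowering the threshold recovers them at little
false-positive cost.

The final model is trained on all drugs at the grid point with the highest
mean out-of-fold AUC (ties go to the smaller-capacity entry). Feature
importance is model-agnostic permutation importance: for each feature, the
column is shuffled n_permutations times, and the score is the mean drop in
accuracy divided by the standard error of the drops; features the model
ignores score ≈ 0. (A per-tree out-of-bag variant exists in some boosting
stacks; it is not implemented here because the backing estimator does not
expose per-tree bag membership, and the column-shuffling form is comparable
across all five learner families.)

Prospective validation compares predicted probabilities with measured
relative efficacy: Spearman rho with a two-sided label-shuffling
permutation p-value p = (1 + #{|rho*| ≥ |rho|}) / (1 + n_perm), plus
ROC/PR analysis treating drugs categorized sensitive as positives. When a
validation set has a single efficacy class the AUC is reported as
undefined rather than fabricated; rho is still computed.

## Synthetic data: what it emulates and what it does not

The fingerprint generator draws key prevalences uniformly from a
configurable range, samples bits independently per drug, and draws the
label from a logistic model over a sparse set of planted keys. The
intercept is calibrated by bisection against the closed-form expectation
of the positive fraction (exact enumeration over planted-bit
configurations), so the ~1/3 sensitive class balance of the screen is
reproduced without consuming randomness. The planted conditional log-odds
are ground truth for sign and approximate magnitude; note that with
several simultaneous effects the *marginal* log-odds seen by a 2×2 table
is attenuated below the planted conditional value (non-collapsibility), by
roughly 20% at the default settings. Power analysis at n = 400 with
BH-corrected Fisher tests shows planted effects need |log-odds| ≈ 1.5 at
prevalences 0.3–0.7 to be recoverable ≥ 90% of the time; the recovery
tests state and use those conditions. Weaker or rarer effects are genuinely
below the design's detection limit — a property of the statistics, not of
the implementation.

The growth simulator produces logistic growth curves OD(t) = OD0 +
φ·(K − OD0)/(1 + exp(−r(t − t0))) with the gap scaled by a Hill factor
φ = 1 − d^h/(d^h + IC50^h); substrates have lower IC50 in the
transporter-null strain. Acting on the gap rather than the rate keeps
zero-dose curves exactly logistic and makes the full-inhibition limit
(flat at OD0) analytic, which the tests exploit as closed-form oracles.
Defaults: 15 h at 15 min sampling, doses {0.25, 0.5, 1.0} of top dose plus
explicit control wells, duplicates, K = 1.0 OD, r = 0.8 h⁻¹, t0 = 7 h,
OD0 = 0.02, additive Gaussian noise SD 0.01 OD truncated at zero —
plate-reader-plausible values chosen once for testability.

What the synthetic fidelity does **not** show: real MACCS bits are strongly
correlated (shared substructures), real dose-responses need not follow Hill
kinetics, plate noise is heteroscedastic and edge-biased, and real
structure–efficacy relationships are not sparse-logistic. Green synthetic
tests therefore validate the statistical machinery and its contracts, not
biological performance claims.

## Numerical and design choices

- Fisher tie comparison at relative tolerance 1e-7; exact-integer oracle in
  tests.
- Log-odds correction only on the effect size; p-values never corrected.
- Nearest-neighbor ties broken by training-set order, logged.
- Probabilities, fold assignments and permutations all derive from
  `numpy.random.SeedSequence` children of a single master seed; file
  outputs carry the seed and a config hash in a manifest, and identical
  manifests imply byte-identical outputs.
- Degenerate inputs (missing control wells, single-class validation sets,
  constant vectors in correlation tests, zero-margin tables) raise or warn
  explicitly rather than returning silent NaNs.

## Known limitations

- The published reference Tanimoto pairs depend on the exact deposited
  registry records and the fingerprint dictionary revision of the original
  tooling; from standard literature structures the camptothecin–topotecan
  similarity computes to 0.879 (0.84 if the salt form is kept), versus the
  printed 0.87.
- Reproducing the screen's cross-validated metrics exactly requires the
  deposited training data and the era's unpublished grids/seeds; the
  package reproduces the protocol and validates it on planted-truth data.
- Growth scoring assumes complete, monotone-dose designs; it integrates
  truncated runs with a warning but does not model evaporation or edge
  effects.
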