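# Methods

## Model

The package factorizes a binary drug–disease association matrix
A ∈ {0,1}^{n×m} as A ≈ XᵀY with non-negative factors X (k×n), Y (k×m),
minimizing

L(X, Y) = ‖A − XᵀY‖²_F + μ(‖X‖²_F + ‖Y‖²_F) + λ(‖XᵀX − S_d‖²_F + ‖YᵀY − S_e‖²_F)

subject to X, Y ≥ 0. The similarity matrices S_d (drugs) and S_e
(diseases) are treated as targets for the factor Gram matrices: two
drugs with high similarity are pushed toward similar latent columns.
Modeling assumptions worth making explicit:

- every cell of A is treated as observed — 0 means "no known link",
  and the loss penalizes reconstructing it as anything but 0. There is
  no masking/missing-data semantics; unknown cells are exactly the
  candidate pool at prediction time.
- similarities are assumed non-negative, symmetric, with unit
  self-similarity; they are compared directly against Gram matrices, so
  their scale matters and should be commensurate with factor norms
  (self-similarity 1 matches unit-norm latent columns).
- the model is symmetric in drugs and diseases; nothing below depends
  on which axis is which.

## Optimizer

Alternating multiplicative updates (X then Y with the fresh X, one pair
per iteration):

X ← X ∘ (YAᵀ + 2λXS_d) ⊘ (YYᵀX + μX + 2λXXᵀX + ε)
Y ← Y ∘ (XA + 2λYS_e) ⊘ (XXᵀY + μY + 2λYYᵀY + ε)

These are the fixed-point updates obtained from the KKT conditions of
the non-negativity-constrained problem: at a constrained stationary
point each elementwise ratio is 1 (or the entry is 0). Properties
relied on and checked by the test suite:

- **non-negativity closure** — every iterate is elementwise ≥ 0, and an
  entry that is exactly 0 stays 0 (zero-locking);
- **empirical descent** — the objective sequence is non-increasing in
  practice. Unlike classical NMF, the quartic similarity term has no
  auxiliary-function monotonicity proof, so descent is treated as an
  empirical regression guard (relative slack 1e-8 per step), not a
  theorem;
- **KKT stationarity** — after deep convergence, min(X, ∂L/∂X) and
  min(Y, ∂L/∂Y) vanish to ≤ 1e-3 elementwise on small instances.

Numerical choices:

- **initialization**: entries i.i.d. uniform(0,1) × 2√(mean(A)/k),
  seeded. With this factor the expected entry of XᵀY equals mean(A)
  exactly, so the first multiplicative step starts near balance. An
  under-scaled start (e.g. dropping the factor 2) makes the first
  ratios ≫ 1, and the resulting overshoot can *raise* the objective on
  the first iteration before descent sets in — observed consistently at
  quarter-scale, never at this scale. For all-zero A the scale
  degenerates; the fit warns and uses 1/k so the similarity term can
  still shape the factors.
- **denominator guard**: ε = 1e-12 added to every denominator entry;
  preserves zero-locking while avoiding 0/0.
- **stopping**: after `max_iter` iterations (default 1000) or when the
  relative objective change per iteration falls below `tol` (default
  1e-6), whichever is first. On slow saddle-crossing trajectories a
  per-step relative-change rule can trigger on a plateau; the KKT
  diagnostics therefore use small instances where deep convergence is
  reliable.
- degenerate inputs: k ≥ min(n, m) is rejected up front; non-finite
  entries in any update input raise a numeric error rather than
  propagating NaN.

## Hyperparameters

| name | meaning | default | notes |
|---|---|---|---|
| k | latent dimension | 50 | must be < min(n, m); the planted-benchmark experiments use the true rank |
| μ | Tikhonov weight | 0.1 | stabilizes scale of X, Y; 0 disables |
| λ | similarity weight | 0.1 | 0 disables biological context; the useful range is instance-dependent, a grid helper (`grid_search`) scores candidates by CV AUC |
| max_iter | iteration cap | 1000 | |
| tol | relative-change stop | 1e-6 | 0 forces exactly max_iter iterations |
| ε | denominator guard | 1e-12 | |
| seed | init RNG seed | 0 | sole source of randomness in a fit |

Defaults are a reproducible, moderate-regularization starting point;
they are not tuned to any particular dataset, and real benchmarks will
generally want a grid search.

## Similarity canonicalization

Raw similarity inputs are repaired deterministically before use:
symmetrize via (S + Sᵀ)/2, clip negatives to 0 (the update numerators
require non-negative similarities), set the diagonal to 1. The
operation is idempotent and every repair is reported. Alignment
reorders (and, if needed, subsets) each similarity matrix to the
association matrix's identifier order; a drug or disease missing from
its similarity matrix is an error naming the missing identifiers.

## Evaluation protocol

Cross-validation partitions the positive (A = 1) cells into folds
(default 10) balanced to within one cell, seeded. For each fold the
model is refit on A with that fold zeroed; the test pool is the fold's
held-out positives (label 1) plus **all** cells unknown in the full
matrix (label 0). Training positives never enter the test pool, and
the fit never sees held-out positives (audited in the tests). This
"all unknown cells as negatives" pool matches how predictions are used
downstream — every unknown pair is a live candidate — and is the main
reason accuracy/specificity run high while precision runs low at 10 %
density: the negative class is ~9× larger than the positive class.

Metrics per fold: AUC (Mann–Whitney with half-credit ties, via
scikit-learn), AUPR (step-wise precision–recall summation over every
distinct score threshold, no interpolation), and the confusion-matrix
family (accuracy, sensitivity = recall, specificity, precision, F1) at
a per-fold threshold chosen to maximize F1 over the distinct test
scores (ties keep the highest threshold; the threshold is recorded in
the report so a fixed cutoff can be substituted). Aggregates are the
unweighted mean and population standard deviation over folds.

Candidate ranking excludes a drug's known associations, sorts by
descending score, and breaks score ties by lexicographic disease
identifier so rankings are reproducible across platforms.

## Synthetic benchmark generator

The generator emulates the *structure* of the drug-repositioning
gold-standard bundles — a sparse binary association matrix plus two
similarity matrices consistent with the latent factors — with full
ground truth:

1. draw X* (k_true×n), Y* (k_true×m) i.i.d. uniform(0,1) and scale each
   column to unit norm (so the Gram diagonals are exactly the canonical
   self-similarity 1);
2. set A = 1 on the `round(density·n·m)` top-scoring cells of X*ᵀY*
   (ties broken by cell index), making the positive count exact and
   fixture assertions tight;
3. set S_d = canonicalize(X*ᵀX* + noise), S_e likewise, with symmetric
   Gaussian noise of standard deviation `sim_noise` applied off the
   diagonal.

Default instance: 100 drugs × 80 diseases, rank 8, density 0.1 —
matched to the evaluation experiments and small enough that the full
pipeline (fit + 10-fold CV) runs in seconds on one CPU.

What the generator does **not** emulate: the value distributions of
real chemical-structure or phenotype-ontology similarities, per-drug
degree heterogeneity of curated association matrices, and — important
for interpreting recovery numbers — the thresholding step makes A the
indicator of a super-level set of X*ᵀY*. Because i.i.d. uniform
factors are mean-dominated, that indicator is a staircase-like pattern
whose linear rank is much higher than k_true, so *no* rank-k_true
scorer reconstructs it perfectly and held-out ranking quality
saturates below 1 even at zero similarity noise. Passing the recovery
experiments therefore shows the pipeline ranks hidden links far above
chance under planted structure, not that the generator's binarization
is exactly invertible — and says nothing quantitative about curated
benchmarks, whose association patterns arise very differently.

## Known limitations

- The similarity term is quartic in the factors; the multiplicative
  updates treat it heuristically and can stall on plateaus/saddles for
  some seeds, which is why stationarity diagnostics use small, deeply
  converged instances.
- Every 0 cell is penalized as a true negative during fitting; the
  model has no confidence weighting or masking for "unknown".
- Metrics with extreme class imbalance: accuracy and specificity are
  near-ceiling by construction when negatives dominate; AUPR and F1 are
  the informative numbers in that regime.
- Identifiers are opaque strings; no ontology or database resolution is
  attempted.
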