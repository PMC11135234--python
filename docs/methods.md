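# Methods

## Model and estimators

### NMF by multiplicative updates

A validated target matrix *V* (m features × n samples; nonnegative, finite,
no all-zero row or column, unique labels) is factorized as V ≈ WH with
W ≥ 0 (m×r) and H ≥ 0 (r×n).  Three update rules are implemented:

- **lee** — multiplicative updates for the Frobenius objective
  ‖V − WH‖²_F: H ← H ⊙ (WᵀV) ⊘ (Wᵀ(WH) + ε), then
  W ← W ⊙ (VHᵀ) ⊘ ((WH)Hᵀ + ε), with the H-update applied first.
- **brunet** — multiplicative updates for the generalized KL divergence
  D(V‖WH): H_{aj} ← H_{aj} · Σ_i W_{ia}V_{ij}/(WH)_{ij} / Σ_i W_{ia}, and
  analogously for W using the updated H.
- **nsnmf** — nonsmooth NMF: the doubly stochastic smoothing matrix
  S(θ) = (1−θ)I + (θ/r)·11ᵀ is interposed (V ≈ WSH) in the KL updates —
  WS acts as the basis in the H-step and SH as the coefficients in the
  W-step — which drives sparseness into both factors.  θ ∈ [0,1],
  default 0.5; θ = 0 reduces to plain KL NMF.  On return S is absorbed into
  W so that W@H is always the model reconstruction and the reported RSS has
  one definition across algorithms.

Both rules are monotone (the objective never increases); the test suite
checks this to 1e−9 relative over hundreds of iterations and verifies each
vectorized step against independent elementwise-loop implementations to
1e−10.

Denominators carry an additive guard ε = 2⁻⁵², one ulp of 1.0 — small
enough never to perturb a healthy update, large enough to prevent 0/0.
Rather than patching degenerate inputs, validation rejects zero rows and
columns outright.

### Initialization and reproducibility

W and H start i.i.d. uniform on (0, √(max V)], so the initial product WH has
the magnitude of the data.  The square root matters: multiplicative-update
trajectories are equivariant under V → cV only if the factors scale as √c,
and with this initialization the fitted RSS of cV equals c² times the fitted
RSS of V to rounding error — a property the tests assert at 1e−6 relative.

All derived randomness flows through one integer fold: restart k at rank r
uses seed `derive_seed(base, r, k)` (a SeedSequence hash kept below 2³¹), so
surveys are reproducible, restarts are independent, and results do not
depend on execution order.

### Stopping

Two convergence criteria serve two different uses:

- **Clustering fits** (`fit`, surveys): stop when the sample-to-cluster
  assignment (argmax coefficient per column of H) has been unchanged for 40
  consecutive checks, checking every 10 iterations, capped at 2000
  iterations.  This is the classical criterion for consensus work — once
  the clustering is stable, further polishing does not change connectivity.
- **Completion fits** (`masked_fit`, PRESS): stop when the relative
  objective improvement per check falls below `objective_tol` (default
  1e−10, cap 5000 iterations).  A stalled cluster assignment says nothing
  about how well held-out entries are imputed, and stopping on it leaves
  the true-rank prediction error convergence-limited; the objective
  criterion removes that artifact.

### The unit-invariant knee

Given the survey curve (ranks x, RSS y, ≥ 4 points), `check_curve`
classifies trend by the sign of y_last − y_first and convexity by which side
of the endpoint chord the curve predominantly lies on (below = convex).
`uik` computes each point's **vertical** distance to the chord and returns
the first and last abscissas attaining the maximum within a 1e−9 relative
tie band (`knee_start`, `knee_end`); the selected rank is `knee_start`,
snapped to the grid with ties toward the smaller rank.

Vertical — not perpendicular — distance is deliberate: rescaling y by b > 0
scales every vertical distance by b, and rescaling x by a > 0 leaves the
chord values at the sample points unchanged, so the argmax index is
invariant to the units of either axis.  Perpendicular distance has no such
invariance.  Collinear curves raise a no-knee error; constant curves a
degenerate-curve error.

An optional iterative mode re-draws the chord over the sub-curve up to the
current knee and re-locates the extremum until stable — a refinement for
long convex curves without a sharp corner.  The default single-chord
extremum is what the rank-selection pipeline and all validation use.

One geometric caveat, established during testing: appending flat tail
points to a curve shallows the chord and lifts every point's distance by an
amount growing linearly in x, so the knee can only stay or drift *right* —
never left — and a knee whose prominence exceeds the chord-rotation gain
stays put.  A guarantee that the knee index never changes under arbitrary
tail extension would be false for any chord-based estimator.

### Consensus and the cophenetic coefficient

Each restart's H induces a clustering (argmax row per column; ties and
all-zero columns go to row 0, the latter with a warning) and a binary
connectivity matrix; the consensus matrix is their elementwise mean with
unit diagonal.  The cophenetic correlation coefficient is the Pearson
correlation between the off-diagonal consensus distances D = 1 − C and the
cophenetic (ultrametric) distances of their average-linkage dendrogram
(scipy's `linkage`/`cophenet`).  Average linkage matches the reference
implementations in the NMF literature.  A perfectly uniform consensus has
zero distance variance; the coefficient is then undefined and surfaces as
NaN (null in reports) rather than an exception, so surveys over degenerate
ranks complete.

### PRESS cross-validation

`masked_fit` weights every update elementwise by a binary mask Ω so held-out
entries exert zero gradient; with an all-ones mask the arithmetic is bitwise
identical to `fit` for the lee algorithm (the unmasked updates evaluate
their denominators with the same association, Wᵀ(WH) and (WH)Hᵀ, to make
this exact).  `press` masks entries per fold, refits, and accumulates the
squared prediction error on held-out entries, reported **per held-out
entry** so schemes of different sizes are comparable.  Three schemes:
full leave-one-out (O(mn) fits — available but not the default), random
fraction (default: 5% of entries, 5 repeats), and bootstrap (entries drawn
with replacement).  Fold masks are re-drawn (up to 100 attempts) until every
row and column keeps at least r observed entries; an impossible scheme
raises an error naming the offending axis.

`select_rank_press` returns the argmin with ties toward the smaller rank,
with one numerical refinement: on noiseless exactly-low-rank data every
rank at or above the truth completes held-out entries to working precision
(measured 1e−13…2e−6 relative to mean(V²) across instances, versus ~1e−3
for even a one-rank misfit), and the ordering among such floor values is
convergence noise.  Ranks whose per-entry PRESS is below
`floor_rel · mean(V²)` (default 1e−5, ≥ 100× below any observed misfit) are
therefore tied at the exact-completion floor and the smallest wins.  On
noisy data all PRESS values sit orders of magnitude above the floor and the
rule is inert.

## The synthetic catalog generator

`simulate_catalog` emulates a benchmark of mutational processes: counts of
96 trinucleotide-context substitution types (6 pyrimidine-strand subtypes ×
4 flanking 5′ bases × 4 flanking 3′ bases, subtype-major ordering) across
G genomes, generated from P planted processes.

Defaults — the study conditions the package is validated under — are P = 10
processes, G = 100 genomes, Poisson counting noise, and an expected load of
1000 mutations per genome:

- **Signatures**: columns i.i.d. Dirichlet(0.1) over the 96 types (sharp,
  sparse motifs), resampled until all pairwise cosine similarities are
  below 0.3.  Random sparse Dirichlet draws occasionally share a dominant
  mutation type (cosines up to ~0.4), and that coherence alone is enough to
  smear the planted components' spectrum; the cap keeps the processes
  genuinely distinct, as the benchmark intends.
- **Exposures**: each genome is dominated by one process (ownership
  balanced across processes, then shuffled) with a log-uniform [0.3, 1]
  amplitude, while every process contributes a weak common background
  (10% of a log-uniform [0.05, 1] amplitude) to every genome.  Rows are
  then rescaled so all P processes carry equal signal power
  ‖s_p‖·‖e_p‖ — a benchmark in which every planted process is comparably
  recoverable — and the whole matrix is scaled to the target load.
- **Noise**: counts ~ Poisson(signatures @ exposures) entrywise; with noise
  off, the mean is rounded.

The power-equalization and distinctness choices are not cosmetic.  The
chord-distance knee of the RSS survey lands on the true rank only when the
smallest planted component's signal power exceeds the mean chord slope
(≈ the summed interior component powers divided by the rank span).  With
i.i.d. exposures the centered component spectrum has a Marchenko–Pastur-like
spread (roughly a factor 3–4 across the nine non-mean dimensions) and the
survey curve bends one to three ranks early; with equal-power, low-coherence
components even the exact SVD-truncation curve places the knee at the
planted rank, and so does the NMF survey.  This is verified in the tests
both through the NMF pipeline and against the SVD oracle.

Mutation types never observed in any genome (expected under sharp
signatures with Poisson noise: rare types have λ ≪ 1) are dropped by
`to_target_matrix` before validation, with the 100-genome axis untouched.

What the generator does *not* emulate: real COSMIC signature shapes, strand
bias, clustered mutations (kataegis), inter-genome load differences beyond
a factor ~20, or correlated process activities.  Passing rank recovery here
shows the selector works when distinct processes of comparable magnitude
exist; it does not certify behavior on cohorts dominated by one process or
with highly collinear signatures, where no rank selector is well posed.

## Preprocessing

For expression matrices, `preprocess` applies, in a fixed order: (1) drop
features with total count below a threshold, (2) log2(x + pseudo-count),
(3) per-sample normalization, (4) keep the top-k features by variance.
Filtering before the log matters (the threshold refers to raw read totals)
and the order is enforced and tested.  Per-sample normalization divides each
column by its mean by default, which keeps the matrix nonnegative as NMF
requires; subtract-mode exists behind a flag but clamps negatives at zero
with a warning.  Each step logs how many features survive.

## Problem sizes and runtime

Default validation sizes were chosen so the full suite runs in minutes on
one CPU: the headline recovery check runs ten independent 96 × 100 catalogs
through a 14-rank survey with 10 KL restarts each (~1400 fits, about a
minute); unit tests use 10×8 to 50×30 matrices.  The survey's default
`n_run = 10` restarts per rank follow the validation setting used
throughout; 20–30 give marginally smoother curves at proportional cost.

## Known limitations

- The knee needs ≥ 4 surveyed ranks and a genuinely bent curve; surveys
  over a range where RSS is still falling linearly raise a no-knee error
  rather than guessing.
- Rank-1 surveys are rejected: a one-cluster consensus is degenerate for
  the cophenetic metric.
- KL-based fits report RSS for the survey curve (one curve definition
  across algorithms), so their RSS is slightly above what a Frobenius fit
  of the same rank would reach; the knee position is unaffected in
  practice.
- Full leave-one-out PRESS is exact but O(mn) NMF fits; use the
  random-fraction scheme for anything larger than toy matrices.
- MATLAB `.mat` ingestion is out of scope; convert to TSV/CSV or
  MatrixMarket with `.rows`/`.cols` label sidecars.
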