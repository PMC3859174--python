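# Methods

This note documents the models, conventions and numerical choices behind
`qsbr`, and what the synthetic-data experiments do and do not demonstrate.

## The data and the response

The packaged dataset holds 227 entries — 222 peptides of 2–14 residues and 5
single amino acids — with bitterness measured by human sensory panels and
expressed as log(1/T), T the bitter-threshold concentration in mol/L. The
activities span 1.00–5.70 log-units. The table also carries the predictions
of three previously fitted models (MLR, SVM, ANN) and their individual
percentage deviations, which lets the whole validation suite be exercised
without recomputing descriptors. The stored split is 181 training / 36 test /
10 validation. A transcription checksum test (row counts and column sums)
guards the fixture.

Two quirks of the source data are preserved rather than repaired: repeated
sequences with distinct activities are legal (identity is row-based, with a
duplicate flag and a warning), and one printed per-point IPD (the training
dipeptide GR) disagrees with its own observed/predicted pair by 0.1
percentage points; recomputed values are used everywhere.

## Partitioning and screening

Training/test/validation splitting clusters the standardized feature rows
(k-means++, Euclidean, 10 clusters by default) and allocates each cluster's
members to the three subsets by largest-remainder apportionment of the
requested fractions (default 0.79/0.16/0.05), drawing members in a seeded
random order. This keeps every subset structurally representative; the
per-cluster deviation from the requested fractions is at most one record. If
a subset ends up empty (tiny inputs), one record is reassigned from the
largest subset.

Outlier screening is done in response space with standard scores
(|z| ≥ 3 against the series mean and population SD — the packaged activities
contain none) and in descriptor space with a PCA score map. PCA standardizes
columns internally and fixes each axis sign by making its largest-magnitude
loading positive, so scores are backend-independent.

## The six descriptors

Computed from a `Conformer` (elements, coordinates in Å, bond list).
Hydrogens are used if present and never added implicitly. All six are
invariant under rigid motion and atom relabeling (property-tested, along
with brute-force oracles on small conformers).

- **SPAN** (Å): maximum distance from the unweighted centroid to any atom.
- **MSD**: Balaban's mean-square-distance index,
  √(Σ_{i≠j} d²_ij / (A(A−1))) over topological distances; decreases with
  branching (verified by exhaustive enumeration over all trees on ≤ 6
  nodes: the path graph maximizes MSD).
- **Mor11v**: 3D-MoRSE sum Σ_{i<j} w_i w_j sin(s·r_ij)/(s·r_ij) at
  s = 10 Å⁻¹ with van-der-Waals-volume weights. Naming convention: Mor01
  corresponds to s = 0 (kernel defined as 1), so MorK uses s = K − 1 Å⁻¹.
  An off-by-one here silently changes results, hence the explicit
  `mor_descriptor(conformer, index, weight)` API.
- **E3s, G3p** (WHIM): eigendecomposition of the weighted covariance of
  centered coordinates. Accessibility E_m is the inverse kurtosis of the
  axis-m scores, λ²_m·n / Σ_i t⁴_im; symmetry G_m = 1/(1 + I) where I is the
  mean information content of the symmetric/asymmetric atom partition along
  the axis (an atom is "symmetric" if a mirror partner lies within a
  tolerance of 0.15·√λ_m of its reflected projection). Planar or linear
  geometries give a zero third axis: E3/G3 are reported as 0 with a
  degeneracy flag instead of raising, so batch runs survive flat molecules.
- **HATS8u** (GETAWAY): leverages h_i are the diagonal of the molecular
  influence matrix H = M(MᵀM)⁺Mᵀ of centered coordinates (pseudo-inverse for
  rank-deficient geometries; leverages sum to rank(M)); HATS8u sums h_i·h_j
  over unordered atom pairs at topological distance 8 and is 0 when the
  graph diameter is below 8.

Atomic weights are carbon-scaled: van-der-Waals volumes from Bondi radii
((r/r_C)³), static dipole polarizabilities relative to carbon's 1.76 ×
10⁻²⁴ cm³. The electrotopological scheme is computed per atom as the
Kier–Hall intrinsic state ((2/L)²·δᵛ + 1)/δ on the hydrogen-depleted graph,
scaled by the sp³-CH₂ carbon value 1.25, with explicit hydrogens weighted 0.
These are open-literature definitions; bit-compatibility with proprietary
descriptor software, whose exact weight tables and normalizations are not
published, is deliberately not promised — correctness here is established by
invariances and brute-force oracles, not by matching a black box.

## Descriptor selection

Three stages, each config-exposed:

1. **Correlation/frequency filter.** Drops constant columns; columns whose
   modal value occupies > 90 % of rows (the reading adopted for "fewer than
   10 % distinct cases"); and, from every pair with |r| > 0.99, the member
   less correlated with the activity (ties keep the earlier column). The
   filter is idempotent and logs the rule that fired per dropped column.
2. **Iterative GA-PLS.** Variables are processed in subgroups of ≤ 200. A
   steady-state genetic algorithm (population 30, tournament parent
   selection, single-point crossover at rate 0.5, per-bit mutation 0.01, 100
   chromosome evaluations per run) scores inclusion chromosomes by the
   cross-validated percentage of explained variance of a PLS model (5-fold,
   component count ≤ 10 picked by the same CV). The per-variable score is
   its fitness-weighted selection frequency in the final population,
   averaged over independent runs; scoring from the final rather than every
   evaluated population is what keeps the random initial chromosomes from
   swamping the signal. After each subgroup, the top 50 % merge with the
   next 100 variables and are rescored; 20 % of the final round survives.
   The run-to-run variability intrinsic to GA selection is exactly what the
   carry-half scheme stabilizes. PLS itself is an in-package SIMPLS that
   returns coefficients for every component count in one pass (the CV
   fitness would otherwise dominate runtime); it is cross-checked against
   scikit-learn's PLSRegression in the test suite.
3. **Stepwise regression.** Classical forward entry by partial-F test
   (p_enter = 0.05) with removal (p_remove = 0.10) — the common
   statistical-package defaults — followed by a bivariate check that drops
   the later entrant of any kept pair with |r| ≥ 0.9.

**Known limitation.** With p_enter = 0.05 and a few dozen surviving null
candidates, the familywise chance that at least one noise variable enters is
≈ 1 − 0.95^k (about 0.7 at k = 23), so the cascade typically returns the
planted variables *plus* one to four spurious ones. Recovery experiments
therefore measure containment of the planted set, not exact equality; users
wanting tighter supports should lower `p_enter`.

## Models

- **MLR**: ordinary least squares on the raw descriptor scale (keeping
  coefficients comparable with the published equation), with per-coefficient
  standard errors, R², adjusted R², F, and the standard error of the
  estimate. Rank-deficient designs raise an error naming collinear columns.
- **SVR**: ε-insensitive support-vector regression, RBF kernel, on
  z-scored inputs (the published γ = 0.06 is only plausible on a
  standardized scale). Defaults C = 91, ε = 0.07, γ = 0.06; `tune_svr` runs
  an exhaustive grid search minimizing 10-fold CV RMSE with ties broken
  toward smaller C, then larger ε.
- **ANN**: one hidden layer of 3 tanh units with a linear output ("three
  hidden" is read as three hidden *neurons*, consistent with the default
  single-hidden-layer architecture of the network tool named in the study
  protocol; the config allows any width). Inputs and response are z-scored
  on training statistics. Training is Levenberg–Marquardt on the
  sum-of-squares loss: damping starts at 10⁻³, ÷10 on an accepted step, ×10
  on a rejected one; stopping at gradient norm < 10⁻⁷, 1000 epochs, damping
  overflow, or 6 consecutive epochs without improvement on an internal
  validation split (70/15/15 random split of the training rows — the usual
  early-stopping guard for small-sample QSAR networks; fractions are
  config-exposed since the source protocol does not state them).

## Validation statistics

- IPD_i = 100·|(ŷ_i − y_i)/y_i|; MPD is its mean (reported with SD); ILRSD
  is the mean absolute relative deviation of replicate measurements × 100.
  Zero observed values are excluded with a warning.
- IPD bins use [0, 15), [15, 30], (30, ∞).
- R² is the squared Pearson correlation between observed and predicted —
  the convention under which the study's R and R² columns are mutually
  consistent; RMSE is the root mean squared deviation; adjusted R², F and
  the standard error follow the standard OLS formulas.
- q² = 1 − PRESS/SS_tot with held-out predictions; LMO uses 10 seeded folds
  by default, LOO is the n-fold special case.
- Y-randomization refits on shuffled activities and reports the fit R² per
  shuffle (10 by default).
- External criteria: through-origin slopes k (observed on predicted) and k′
  (predicted on observed); R0² and R0′² are the corresponding through-origin
  coefficients of determination; Rm² = R²(1 − √(R² − R0²)). Pass flags:
  R² > 0.6; ((R² − R0²)/R² < 0.1 and 0.85 ≤ k ≤ 1.15) *or* the primed
  counterpart — the either/or structure means the k/k′ labeling ambiguity in
  the source description cannot flip a verdict; |R0² − R0′²| < 0.3;
  Rm² > 0.5. The printed Rm² formula in the source is typographically
  garbled; the canonical Roy form above is used, and it reproduces the
  printed test-set values to within rounding.

Statistics recomputed from the packaged 2-decimal predictions inherit that
rounding; comparisons in the tests allow ±0.02 (±0.3 on percent-scale MPD).

## Synthetic-data conditions

The generators define the conditions under which the pipeline is validated:

- `gen_joint` draws multivariate-normal rows over (response, six
  descriptors) with the published intercorrelation matrix (symmetrized;
  slightly indefinite printed tables are repaired by clipping eigenvalues at
  10⁻⁸ and renormalizing the diagonal). Marginal moments: response 2.87 ±
  1.00 (the packaged activities), E3s 0.21 ± 0.10, HATS8u 0.33 ± 0.13,
  Mor11v 0.10 ± 0.40 (published training statistics). SPAN (25 ± 9), MSD
  (0.35 ± 0.10) and G3p (0.15 ± 0.05) were never published; their defaults
  are placeholders chosen once to keep equation outputs inside the observed
  1.0–5.7 range, and are config-exposed.
- `gen_equation_response` evaluates the published equation plus N(0, σ²)
  noise; σ defaults to 0.43, the training RMSE of the linear model (the
  equation block also prints "S.E.P. = 0.08", which is inconsistent with
  that RMSE; both are documented, the RMSE is used).
- `gen_wide_matrix` plants `n_informative` standard-normal columns driving
  the response with slope 0.35 each among iid noise columns, giving a
  six-variable model R² near 0.8 at n = 181 — the study's regime. Optional
  near-duplicate and near-constant columns exercise the filter rules.
- `gen_conformer` builds line / ring / random-chain toy conformers for the
  descriptor property tests.

What passing these experiments shows: the cascade finds truly informative
variables at the study's dimensionality and signal-to-noise ratio; OLS
coefficient recovery is calibrated (each slope within 2 SE in ≈ 95 % of
repeats); Y-randomization R² stays below 0.15; the generator reproduces the
configured correlations within ±0.02 at n = 20000. What they do not show:
behavior under the heavy-tailed, discrete and block-correlated structure of
real descriptor matrices, or any claim about the proprietary descriptor
values underlying the original study — the original LOO q², per-subset LMO
and shuffle tables cannot be recomputed without that matrix and are not
asserted anywhere.

## Problem sizes and determinism

Recovery experiments use the study's training size (n = 181, p = 244, 6
planted variables, noise SD 0.43) with a GA budget of 10 runs × 100
evaluations per subgroup — enough for the carry-half scheme to stabilize
scores, and the package's default experiment size; the GA-PLS config exposes
the full 100-run setting for production use. Every stochastic stage (k-means
seeding, GA, CV folds, ANN initialization and splits, shuffles, synthetic
draws) is driven by an explicit integer seed, and a pipeline rerun with the
same config and seed writes byte-identical artifacts for deterministic
stages.
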