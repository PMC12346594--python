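# Methods

## Data model and conventions

A *chromatographic system* is a chiral stationary phase (CSP) plus a
mobile phase at stated temperature and flow. Eluents are stored as
solvent → V/V% maps summing to 100, so neat alcohols and mixtures share
one representation; system identifiers are `CSP-eluent` strings.
Temperatures enter in °C at every I/O boundary and are converted to
kelvin (`T_K = T_C + 273.15`) internally, because the source tables are
reported in °C while all thermodynamic formulas need K.

Unresolved enantiomer pairs are encoded as *coelution*: resolution is
missing (not zero) and the elution order is the dedicated `coelution`
state. This preserves the distinction between "Rs = 0 was measured" and
"the pair was not resolved", which matters both for aggregation (sum-Rs
rankings count unresolved cells as 0, success counts exclude them) and
for the feature matrix (coelution gives directed Rs = 0 but leaves
thermodynamic features missing). Elution order is tracked by enantiomer
identity (R/S), not by elution position, so a "reversal" always means a
change in which configured enantiomer elutes first. Values from the
packaged screening table are stored exactly as printed, including
3-decimal retention factors.

## Screening metrics

Retention factor, selectivity, and resolution follow the standard
definitions `k = (tR − t0)/t0`, `α = k2/k1` (first/second eluter, so
α ≥ 1), `Rs = 2(t2 − t1)/(w1 + w2)`. Directed resolution signs Rs by
elution order (negative = S first); a resolved pair with unknown order
cannot be signed and is rejected rather than silently dropped. Baseline
separation uses the strict inequality Rs > 1.5.

EEO-reversal detection contrasts record pairs along one axis at a time:
*backbone* (same selector substituent, different polysaccharide
backbone), *substituent* (same backbone, different substituent),
*mobile phase* (same CSP, different eluent). Pairs where either side
co-elutes are reported separately as "not assessable" — coelution
carries no order information. Temperature-axis reversals are not
detectable from a single-temperature screen and are instead predicted by
the thermodynamic module (T_iso inside the operating window).

The screening aggregate reports its own baseline count (38 of 84 cells
above Rs = 1.5 in the packaged table, ≈45%); no external percentage is
asserted for this quantity.

## Van 't Hoff thermodynamics

Linear van 't Hoff behavior is assumed: `ln k = −ΔH°/(RT) + ΔS°*/R`,
with R = 8.314 J/(mol·K). The phase ratio Φ is unknown and absorbed
into the apparent entropy `ΔS°* = ΔS° + R ln Φ`; plain ΔS° is never
reported. Fits are ordinary least squares of ln k on 1/T with at least
3 distinct temperatures (configurable); a QC flag marks fits with
|r| < 0.98, the linearity level typical of well-behaved plots.

Enantioselective differences come from regressing
`ln α = −Δ(ΔH°)/(RT) + Δ(ΔS°)/R` on the shared temperature grid — not
from differencing per-enantiomer fits, although the two agree to
rounding on exact shared-grid data (a tested identity). Derived
quantities: `Δ(ΔG°)(T) = Δ(ΔH°) − T·Δ(ΔS°)` (equal to −RT ln α),
`T_iso = Δ(ΔH°)/Δ(ΔS°)` (undefined when Δ(ΔS°) = 0), and
`Q = Δ(ΔH°)/(T_ref·Δ(ΔS°))`. The reference temperature defaults to
298 K (configurable to 298.15 K). Control classification: |Q| > 1
enthalpy, |Q| < 1 entropy, |Q − 1| ≤ 0.05 mixed (band configurable);
a series with α ≡ 1 is reported as "no enantiorecognition" with T_iso
and Q undefined rather than fitted.

## Hysteresis and hystereticity inference

For loops swept forward (from 100% MeOH) and back, the hystereticity of
an enantiomer at composition x is `υ = k_forward(x)/k_reverse(x)`. The
ratio `υ_R/υ_S` is always computed in that fixed R-over-S orientation;
when the forward branch elutes S first, the *reciprocal* is the value
compared against 1, which makes the comparison value equal to
`α_reverse(signed)/α_forward` with A = the forward first-eluter. The
truncated deviation notation in the source material is interpreted as
|υ − 1|, the natural deviation-from-unity measure.

Inference rules (A = forward first-eluter; tolerance bands below):

- Case A (separated forward): ratio = 1 → selectivity unchanged;
  ratio > 1 → selectivity increased (order preserved); ratio < 1 →
  selectivity decreased with order preserved, **or** coelution, **or**
  EEO reversal. The three-way set is deliberate: a ratio below one only
  says the signed reverse selectivity dropped below the forward one
  (counterexample: k_Af=1, k_Bf=2, k_Ar=1, k_Br=1.5 gives ratio 0.75
  with the order intact), so a narrower claim would be unsound.
- Case B (forward coelution): the ratio reduces to k_Br/k_Ar, so ratio
  class and reverse elution order are in bijection: =1 coelution, >1 A
  first, <1 B first.

When reverse-branch data exist, the realized outcome is computed
independently and checked for membership in the inferred set.

Tolerances: two k values are "co-eluting" within relative 1e-3
(printed retention factors carry 2–3 decimals), and a ratio counts as 1
within relative 1e-3; both configurable. Because the coelution band (on
k) and the ratio band are defined on different scales, adversarial
inputs within O(tol²) of both boundaries can be classified differently
by the two paths; the soundness property is therefore exact (a theorem)
at zero tolerance and holds in practice away from band edges. Hysteresis
is *detected* when |υ − 1| exceeds a threshold (default 0.05) for either
enantiomer at any interior composition; the pure-solvent endpoints are
excluded because a closed loop re-measures the starting eluent where
υ = 1 by construction.

## Multivariate comparison

The feature matrix has one row per system and per-analyte columns of
directed Rs, Q, and Δ(ΔG°); missing cells are never imputed at assembly.
Pairwise correlation uses pairwise-complete observations with a minimum
of 3 shared features per pair; cells with fewer completions or zero
variance are missing, mirroring the grey cells of a screening heatmap.

Clustering and PCA impute first (column mean by default; an iterative
rank-1 SVD scheme is available) and standardize each feature to zero
mean/unit population variance. Clustering is agglomerative with
Euclidean distances; the linkage defaults to *complete* (the distance
metric is prescribed by the workflow being reproduced, the linkage was
not — complete is the common default of that tooling and is
configurable). PCA reports explained-variance fractions and per-variable
cos² computed from correlation-scale coordinates (eigenvector ×
√eigenvalue); an unstandardized variant preserves raw variance ratios
for covariance-recovery checks.

Representative-set selection cuts the dendrogram at k clusters (default
5) and picks each cluster's medoid (minimum mean within-cluster
distance), breaking ties lexicographically — a deterministic,
reproducible substitute for panel selection that was originally done
with human judgment; exact membership of any hand-picked panel is out of
scope.

## Cross-validated prediction

Preprocessing follows the fixed order: one-hot encoding of categorical
columns, range scaling of numerics to [0, 1], mean imputation, removal
of zero-variance features, and elimination of feature pairs with
|r| ≥ 0.999 (keeping the first by column order). The chain is
idempotent. Assessment is 3-fold CV repeated 5 times (15 resamples),
fold assignment fixed by the seed, scored by RMSE, with hyperparameters
tuned by grid search strictly inside each training split. Learners: a
random forest (200 trees; max_features gridded) and a single-hidden-layer
feedforward network (8 units, LBFGS) whose L2 penalty α ∈ {1e-4, 1e-2, 1}
is selected by the inner search — the weight-decay regularization
playing the overfitting-control role that Bayesian-regularized networks
fill in comparable workflows; full Bayesian evidence estimation is not
implemented. A permutation baseline (CV RMSE after shuffling the
response) provides the no-signal reference, which equals the response
standard deviation for a mean predictor. With only three analytes in
the real screen, grouped (analyte-aware) folds are statistically safer;
plain random folds remain the default for fidelity to the reproduced
workflow.

Molecular descriptors (molecular weight, Crippen logP, TPSA, H-bond
donor/acceptor counts, rotatable bonds, rings, heavy atoms) are computed
from SMILES with RDKit at call time; no network retrieval. Note RDKit's
default TPSA excludes sulfur contributions, so values differ from
databases that include them — immaterial for modeling, where features
are range-scaled.

## Synthetic data generator

The generator is the testing ground truth and emulates the study design:
7 CSPs × 4 eluents × 3 analytes at 20 °C for screening; temperature
series on the 10/20/25/30/40 °C grid; hysteresis loops over 100→0→100%
MeOH in 10% steps.

- Retention: `ln k = −ΔH°/(RT) + ΔS°*/R` with per-enantiomer parameters;
  ΔH° ~ U(−20, −5) kJ/mol and ΔS°* ~ U(−60, −10) J/(mol·K) for the first
  enantiomer (retention falls with temperature, k of order 0.1–10 —
  the observed regime).
- Enantioselectivity: the second enantiomer adds a compensated offset —
  |Δ(ΔH°)| ~ U(5, 15) kJ/mol with random sign, T_iso ~ U(250, 450) K,
  and Δ(ΔS°) = Δ(ΔH°)/T_iso. Compensated draws reflect the
  enthalpy–entropy compensation characteristic of chiral recognition and
  keep |Δ(ΔH°)| in the clear-recognition range where relative recovery
  error is a meaningful metric (independent uniform draws would place
  mass at Δ(ΔH°) ≈ 0, where any estimator's relative error diverges).
- Noise: Gaussian on ln k (σ default 0.01), i.e. multiplicative on k,
  consistent with the variance model a linear van 't Hoff fit assumes.
- Peaks: tR = t0(1 + k) with t0 = 1 min (arbitrary scale; k is
  scale-free) and widths w = 4·tR/√N from a plate-count model
  (N = 5000 default), so Rs follows the resolution formula exactly.
- Screening missingness: each cell co-elutes with probability 0.3
  (≈ the unresolved fraction of the real 84-cell screen).
- Hysteresis: forward ln k is log-linear in modifier fraction (an
  LSS-like assumption; quadratic available via custom base curves); the
  reverse branch subtracts `δ(x) = a·(x/100)(1 − x/100) + d·x/100`, so
  true hystereticity is exp δ(x) exactly — unity at the pure solvents
  unless the divergence term d is set, which reopens the loop toward
  high MeOH content. Per-enantiomer amplitudes plant EEO reversals at
  known compositions.

All randomness flows from the single config seed; equal configs give
byte-identical outputs.

What the generator does *not* emulate: peak tailing and detector noise,
column-conditioning kinetics, nonlinear (curved) van 't Hoff behavior,
and inter-analyte correlation structure. Recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data pathologies outside it.

## Problem sizes and numerical choices

Default validation sizes: 200 Monte-Carlo replicates for thermodynamic
recovery; 10,000 random retention quadruples for inference soundness;
n = 2000 draws for covariance-eigenvalue recovery in PCA; 30 systems in
5 planted clusters for selection; 200 rows for the noiseless regression
checks and 60 for permutation baselines — sizes at which the checked
statistics are stable to reseeding while the whole suite runs in about
two minutes. Degenerate inputs fail loudly: empty tables, k₂ < k₁ rows,
non-positive retention factors or widths, mismatched temperature grids,
single-composition loops, and all-features-eliminated preprocessing all
raise with specific messages rather than propagating NaNs.

## Known limitations

- Thermodynamic results are only as linear as the data; curved ln k
  plots are out of scope and will simply fit badly (flagged by the QC
  threshold, not modeled).
- The case-A/ratio<1 hysteresis inference is irreducibly ambiguous
  without reverse-branch data; the module returns the full admissible
  set rather than guessing.
- With three analytes the ML stage's random folds leak analyte identity
  across folds; the grouped-CV option exists precisely because the
  default is optimistic in that regime.
- Screening-table fidelity is to the printed values; printed rounding
  (2–3 decimals) propagates into derived selectivities.
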