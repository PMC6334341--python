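# Methods

This note records the models, numerical choices and limitations behind
`teaspec`, in the order the pipeline runs them.

## Synthetic data generator

**Model.** A sample spectrum in block b (MIR or NIR) is

    x_i = Σ_k c_ik · s_k^b  +  f^b(class_i)  +  β0_i + β1_i · r  +  ε_i

where `s_k^b` is component k's block-b signature (a sum of Gaussian bands
`A·exp(−(ν−ν0)²/(2w²))`), `f^b` a class-specific fingerprint, `(β0, β1)` a
per-sample linear baseline, `r` the normalized axis position and `ε` iid
Gaussian noise. Concentrations are `c_ik = m_{class(i),k}·(1 + CV·z_ik)`
clipped at zero, with class means `m = 1 + separation · pattern` drawn once
from a fixed design seed (so the "which teas exist" layout is not part of
the per-dataset randomness). All per-dataset randomness flows from a single
seed in a fixed draw order; two runs with equal configs are bit-identical.

**Components.** Six components: five catechin-like polyphenols and one
broad polysaccharide-like component, with activity-linked bands placed in
the 1540–1780 cm⁻¹ (MIR) and 4930–5300 cm⁻¹ (NIR) regions where carbonyl /
aromatic C–H / O–H combination absorptions of tea polyphenols fall. Two
deliberate confounds encode the physics that motivates data fusion:
`catechin_a`/`catechin_b` share identical MIR bands but are resolved in the
NIR, and `catechin_c`/`catechin_d` share a NIR band but are resolved in the
MIR. Because the members of each pair carry different activity weights, no
single block can identify the activity-weighted concentration sum; the
fused matrix can.

**Class fingerprints.** Discriminating 12 classes whose means live in a
6-dimensional mixture simplex is impossible for least-squares indicator
regression at any separation (the classic masking effect of linear
regression on >2 class indicators — we verified the ~85 % ceiling is
scale-invariant). Real teas differ in far more than the shared antioxidant
components (volatiles, amino acids, processing markers), so each class
additionally carries 3 small marker bands per block (amplitude
0.2·separation, positions from the design seed). This makes the class
structure full rank and single-block PLSDA reaches 100 % accuracy across
seeds, the behaviour the study design assumes. The markers carry no
antioxidant activity.

**Responses.** DPPH and ABTS are monotone logistic functions of their
activity-weighted concentration sums, affinely rescaled into the reported
assay ranges (DPPH 20.59–51.27 %, TEAC 1.81–5.72). The logistic keeps
responses bounded and mildly nonlinear — enough to justify a kernel model —
while preserving rank order (rank correlation 1 with the true activity sum
at zero noise). The conventional scavenging formula
`SA% = 100·(1 − A_sample/A_control)` is the default orientation of
`sa_percent`; the inverted ratio found in parts of the assay literature is
available behind `literal=True` but is unbounded below and not used.

**Defaults.** 12 classes × 10 samples; within-class concentration CV 5 %;
absorbance noise sd 0.003 a.u.; baseline offset ±0.02 and slope ±0.005
a.u.; separation 1.0. Grids: 1869 points over 4000–400 cm⁻¹ and 1557 over
10000–4000 cm⁻¹, stored descending (acquisition order). The point counts
follow the fused-matrix contract of 3426 variables; they imply data
spacings of ~1.93 and ~3.86 cm⁻¹, finer than the nominal 4 / 8 cm⁻¹
instrument resolutions — the counts, not the resolutions, are taken as
authoritative.

**What the generator does not emulate:** instrument physics (interferogram
artefacts, scatter, detector nonlinearity), multiplicative path-length
effects, wavenumber-correlated noise, or real band shapes (Voigt profiles,
shoulders). Passing tests therefore demonstrate the chemometric machinery
on data with the assumed statistical structure, not performance on real
tea spectra.

## Fusion and preprocessing

Low-level fusion is horizontal concatenation (matrix augmentation) with a
per-block scaling chosen by the caller: `none` (plain augmentation),
`blockwise-autoscale` (each column to mean 0/sd 1; the default when blocks
of different raw magnitude must be balanced) or `blockwise-unit-norm`
(block divided by its Frobenius norm). In the pipeline the fused matrix is
standardized column-wise using calibration-set statistics only, so the
held-out sets never leak into the scaling. Interval endpoints are always
reported as (high, low) cm⁻¹ pairs in the source block's coordinates,
regardless of storage order.

## Sample splitting

Classification uses a stratified random 88/32 split with fixed per-class
training counts (9, 6, 8, 8, 6, 8, 5, 8, 7, 8, 8, 7). Calibration uses
classical DUPLEX: the mutually farthest pair seeds the calibration set,
the farthest remaining pair seeds the other set, and the point with the
largest minimum distance to a set is assigned alternately until the 60/60
quotas are met; a second DUPLEX pass splits the 60 non-calibration samples
into monitoring and prediction sets of 30. Distances are Euclidean on the
autoscaled fused spectra (scale-free across blocks); ties break to the
lowest sample index, making the split fully deterministic and invariant to
row storage order. One plan is shared by all blocks and targets.

A note on coverage: DUPLEX guarantees good coverage of the *spectral*
space. Because nuisance directions (baselines, fingerprints) contribute to
the distances, the calibration set brackets the *response* range in most
but not all realizations; on average its 2-D projection hull is at least
as large as that of random 60-sample subsets, which is the property we
test.

## PLSDA

PLS is NIPALS on column-centered data, PLS1 (non-iterative per component)
for single responses and iterating scores to tolerance 1e-10 for matrix
responses; regression coefficients are `W(PᵀW)⁻¹Qᵀ`. The classifier
regresses the 12-column indicator matrix on the spectra and assigns by
argmax of the predicted indicators (no probabilistic threshold), ties to
the lowest class index with a warning. The latent-variable count minimizes
the cross-validated misclassification count — leave-one-out for n ≤ 100,
10-fold venetian blinds otherwise — with ties resolved toward fewer
components. Cross-validation first compresses the predictors to their row
space via SVD; PLS depends on samples only through inner products, so this
is exact and makes leave-one-out on 88 × 1869 matrices fast. Degenerate
folds whose residual rank is exhausted carry their last attainable
prediction forward.

## MWPLS variable selection

A width-60 window slides over the axis; at each position a PLS1 model of
the response on the window's columns is fitted for 1..5 latent variables
and the calibration SSR recorded ("residue lines"). Windows are batched
and solved with einsum-vectorized NIPALS, so a full fused scan (3300+
windows) takes about a second. Calibration SSR (not CV) matches the
residue-line convention; on a fused matrix windows never straddle the
MIR/NIR seam, since a window mixing two instruments' variables has no
physical meaning. Selection marks windows whose SSR minimum falls at or
below the 0.1 quantile of window minima and merges the columns they cover
into per-block intervals. The original interval choice was made visually
from residue-line plots; a quantile rule is the closest reproducible
analogue, and the printed interval lists serve only as a plausibility
pattern (our fused runs likewise select intervals inside 1540–1780 cm⁻¹
and 4930–5360 cm⁻¹).

## OSWLS-SVM

The weighted LS-SVM solves the (n+1)×(n+1) linear KKT system given in the
README; residuals satisfy `e_i = α_i/(γ v_i)`, so a small weight v_i
relaxes sample i's constraint (the w_min = 1e-3 lower bound keeps the
system nonsingular). Kernel: RBF `exp(−‖x−x′‖²/σ²)` by default (linear
available). The PSO searches the n calibration weights in [1e-3, 1] plus
log10 γ and log10 σ² in [−2, 6]²; hyperparameters are searched in log
space because their natural scales span decades. PSO settings: 70 cycles
(the study's stated budget), swarm 30, inertia 0.9→0.4 linearly, c1 = c2 =
2.0, velocities clamped to 20 % of each dimension's range, positions
clipped to bounds, NaN objectives treated as +inf; the first cycle is the
evaluation of the uniformly initialized swarm, and the global best is
non-increasing by construction. The objective is the RMSE on the
monitoring set, which guards the weight search against overfitting the
calibration set; the returned model is refit at the best position.
Squared distances are precomputed once, so each objective evaluation is an
exp, a 61×61 solve and a matrix–vector product. Model inputs are the
MWPLS-selected columns, standardized by calibration statistics.

## Validation statistics

Recovery is 100·predicted/actual per prediction sample, summarized as
mean ± sd (ddof = 1). The paired t-test uses d = actual − predicted,
t = mean(d)/(sd(d)/√n), df = n − 1; at n = 30 and α = 0.05 the two-sided
critical value is 2.045, which the scipy quantile reproduces to three
decimals. The EJCR regresses actual on predicted (the stated orientation;
the literature also uses the reverse) and tests whether

    (β̂ − β)ᵀ XᵀX (β̂ − β) ≤ 2 s² F_0.05(2, n−2)

holds at β = (0, 1). The ellipse area, used to rank models alongside
RMSEP, is the exact π·(2s²F)/√det(XᵀX). Monte-Carlo under a true (0, 1)
line reproduces the nominal 95 % coverage. `compare_models` orders blocks
by RMSEP with EJCR area as tie-break and flags the fused block when it
wins on both.

## Problem sizes and determinism

The default study (120 samples, full grids, 3 blocks × 2 targets, 70 PSO
cycles, swarm 30) runs in roughly ten seconds on one CPU; the test suite's
multi-seed properties (10-seed classification, 10-seed fusion advantage)
are sized to finish in a couple of minutes. Every stage seed derives
deterministically from one master seed (SeedSequence over the master seed
and a CRC32 stage label, reduced below 2³¹), so YAML config + seed fully
reproduce a run.

## Known limitations

* The generator's activity link is exactly recoverable from fused spectra
  by construction; real spectra–assay relationships include matrix effects
  and assay noise that would raise all RMSEPs.
* DUPLEX is the only splitter for calibration (no Kennard–Stone/SPXY);
  MWPLS is the only variable selector (no CARS/UVE/GA).
* The EJCR area ranking assumes comparable response scales across the
  compared models (always true here, where blocks share a target).
* SEN/SEL are point estimates; no confidence intervals or ROC analysis.
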