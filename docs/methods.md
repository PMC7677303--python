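# Methods

## Model and procedure

`cpgsig` selects a compact CpG-methylation signature for a K-class problem
in two stages.

**Discretization.** Mutual information is estimated on categorical data, so
each site's beta values are mapped to three states relative to their own
distribution: +1 above mean + t·σ, −1 below mean − t·σ, 0 otherwise, with σ
the sample standard deviation (ddof = 1 — stated explicitly because it
moves the thresholds at small n). Default t = 1.0, matching the common
behaviour of classical discretized-mRMR implementations; a zero-variance
site maps to all zeros and carries no information. t is configurable
(`--t`/`t=`): smaller t pushes more samples into the ±1 tails and raises
estimated MI across the board.

**Mutual information.** Plug-in (empirical-frequency) MI on the joint
contingency table, in bits by default (log base configurable to e). Class
labels are treated as just another categorical vector, so one routine
serves both the relevance term I(g, l) and the redundancy terms I(g, gᵢ).
The plug-in estimator is biased upward at finite n (≈ df / (2n ln2) under
independence); `cpgsig` deliberately does not bias-correct, because the
ranking only compares sites estimated on the same samples. Tests and the
generator's null calibration account for this bias rather than assuming
MI ≈ 0 under the null.

**mRMR (difference criterion).** Greedy maximization of
relevance − mean redundancy against the already-selected set, with the
convention that an empty selection has redundancy 0 (so step one reduces to
pure relevance, and the first score is exactly the top site's relevance).
Ties break to the lexicographically smallest probe ID — deterministic and
insensitive to input row order. Relevance values are computed once;
redundancy is accumulated incrementally (each newly selected site
contributes one vectorized MI pass over the remaining candidates), so
ranking N sites from a pool of n costs O(N·n) MI evaluations, which keeps a
full 450K-scale pool × N = 300 run feasible on a workstation. The quotient
(MIQ) variant is not implemented.

**IFS + LOOCV SVM.** For each nested prefix of the ranking, every sample is
predicted by an RBF-kernel SVM trained on the remaining samples. Classifier
defaults copy the classical `svm()` defaults: cost C = 1, kernel width
γ = 1/p (p = number of features), one-vs-one voting for K > 2, and feature
standardization. Standardization uses training-fold statistics only, so the
held-out sample never leaks into the scaler; a `pooled` compatibility mode
reproduces implementations that scale the full matrix up front (the two
differ only slightly at these sample sizes, but fold-safe is the defensible
default). A degenerate training fold — a singleton class whose only sample
is held out — is handled by training on the remaining classes; with one
sample per class this forces LOOCV accuracy 0, which is a property of LOOCV
itself, not a defect. The signature size is the smallest r attaining the
curve's maximum accuracy (tie-break toward conciseness). There is no
hyperparameter search and no class weighting.

## Synthetic data generator

The generator emulates a normalized, class-structured 450K beta matrix:

* **informative sites** — per-class logit-scale means
  logit(b₀) + effect·(c − (K−1)/2), within-class noise N(0, noise_sd) on the
  logit scale, squashed back through the inverse logit (values therefore
  stay strictly inside (0, 1));
* **redundant copies** — the parent's logit values plus N(0, noise_sd/4):
  strongly but imperfectly correlated, the regime the redundancy penalty is
  designed to punish;
* **null sites** — shared mean logit(b₀), same noise.

Defaults: class sizes (16, 19, 62) mirroring the hip/knee cartilage cohort
the package is aimed at; 2000 sites as a desk-scale stand-in for a full
array; 10 informative sites × 2 copies; effect 2.0 and noise_sd 0.5 (≈ 4σ
between adjacent class means, a clearly separable but noisy regime);
baseline mean 0.5. Identical specs (including the seed) give bit-identical
datasets. Probe IDs encode the ground truth (`inf_i`, `cop_i_j`, `null_k`);
`randomize_ids` blinds them without changing the values.

What the generator does *not* emulate: Type I/II probe chemistry and its
beta-distribution shapes, batch effects, cell-composition confounding,
genomic autocorrelation of methylation, or class-imbalanced effect
directions. Passing tests therefore demonstrate that the selection machinery
behaves correctly on class-structured, redundancy-laden data — not that any
specific biological signature would be recovered from a real cohort.

## Numerical choices and degenerate inputs

* TSV writers emit 12 significant digits; round trips are exact at that
  precision.
* Sites with any missing value are dropped on read (count logged), never
  imputed — no published imputation rule exists for this procedure and
  dropping fabricates nothing.
* Constant features pass through standardization centred (divisor 1), and
  constant sites discretize to all zeros (MI exactly 0).
* Sample clustering for heatmaps: Euclidean distance on row-scaled
  (z-scored, ddof = 1) values, average linkage. The linkage is a recorded
  default, not a claim about how any published figure was produced.
* "Hypermethylated in class X" means strictly greater mean raw beta in X
  than in the comparison class; exact ties are counted separately so the
  three counts always partition the site set.

## Open design points resolved

* The discretization width t and the MI log base are not fixed by the
  procedure's published descriptions; defaults (t = 1, bits) are exposed as
  parameters, and reported scores from other implementations should not be
  expected to reproduce bit-for-bit under different choices.
* Whether to standardize inside or outside LOOCV folds is likewise
  ambiguous in common practice; fold-safe is the default, pooled the flag.
* The whole candidate pool is ranked by default (no variance pre-filter).

## Problem sizes used in tests and the acceptance script

The shipped checks run the planted-signal study at (20, 20, 20) samples ×
1000 sites (10 informative blocks, mRMR N = 50, IFS max_r = 50), the greedy
optimality re-scan at 60 × 200, the permutation null at 20 replicates on a
(10, 10, 20) design, and pipeline determinism at 500 sites — sizes chosen so
the full suite completes in well under a minute of mRMR time and a few
minutes of LOOCV time while leaving the recovery and null properties
comfortably testable. Block-level recovery (a planted block counted as
found when its parent *or* a copy is ranked) is the stable recovery
statistic: a near-duplicate copy can legitimately be selected in place of
its parent, after which the parent is suppressed as redundant.

## Known limitations

* The plug-in MI estimator's upward bias makes individual null-site MI
  values of ~0.1–0.2 bits unremarkable at n ≈ 90; interpret scores
  comparatively, not absolutely.
* LOOCV on small cohorts overestimates generalization; a perfect curve
  value is not external validity.
* No normalization is performed — the pipeline consumes already-normalized
  beta values; IDAT processing and genome-build liftover are out of scope.
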