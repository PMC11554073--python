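# Methods

`kpsfusion` implements a multimodal prediction pipeline for the 6-month
postoperative Karnofsky Performance Status (KPS) in IDH wild-type
glioblastoma: the binary endpoint is KPS < 70 (loss of independent living) at
6 months after surgery. The pipeline fuses 28 routine clinical parameters
with deep imaging features extracted by variational autoencoders (VAEs) from
segmented pre- and postoperative MRI, and compares the fused classifier with
clinical-only and imaging-only models under repeated cross-validation.
Because the motivating single-center cohort is not publicly available, the
package ships a synthetic cohort generator that reproduces the published
marginal statistics of such a population and plants a known outcome model,
so every stage is testable end to end.

## Input representation

The imaging input is a 3D **label volume** per patient and timepoint
(pre-/postoperative), with classes 0 = background, 1 = brain parenchyma,
2 = peritumoral edema / non-enhancing tumor, 3 = lesion core (enhancing
tumor, necrosis, cysts), stored as NIfTI-1 with 3-mm slice spacing. Raw MRI
intensities are deliberately out of scope: the upstream segmentation model is
treated as given, and the VAEs consume its label maps.

For each volume the per-slice lesion-core area (class-3 voxel count × in-plane
voxel area) is measured, and a window of 24 axial slices is selected so that
the largest-core slice lies as close to the window centre as the volume
boundary allows ("central part" is formalised as minimising
|argmax − window centre|, clamping at the boundaries, ties to the earlier
start; volumes shorter than 24 slices are symmetrically zero-padded). One
window is selected **per patient**, on the preoperative volume, and applied
to both timepoints: re-selecting on the post-op volume would shift with the
resection and leak residual-tumor information into the brain-mask stack
through window position. The window is split into a 2-channel lesion stack
(core, edema) for VAE 1 and a 1-channel brain-mask stack (classes 1∪2∪3)
for VAE 2.

## Variational autoencoders

Each VAE maximises the per-image evidence lower bound with a Bernoulli
decoder: reconstruction log-likelihood (binary cross-entropy) summed over
voxels plus `kl_weight` × KL divergence of the diagonal-Gaussian posterior
from the standard-normal prior, summed over the 48 latent dimensions and
averaged over the batch. The standalone `elbo_loss` reports the
mean-per-voxel reconstruction convention for comparability; training uses
the summed (per-image) balance — with a mean-voxel reconstruction term the
KL gradient dominates and the posterior collapses to the prior, which we
observed directly (latents became outcome-independent).

No GPU or deep-learning framework is assumed: the encoder/decoder are dense
networks in numpy with hand-written backpropagation. A stack is first
average-pooled by fixed factors (default 2×4×4 → a 12×16×16 occupancy grid),
flattened, and passed through one hidden layer (default width 128) to the
48-dimensional mean/log-variance heads; the decoder mirrors this. This
replaces the 3D-convolutional encoder a GPU implementation would use; the
pooling factors, widths, KL weight and epochs are configurable.

Pretraining uses an **independent synthetic corpus** (default 250 patients →
500 pre/post stacks, drawn with a seed offset of 100000 from the study
seed), never the study cohort itself — mirroring the original design of
pretraining on an external public dataset, scaled down for a single CPU.
Feature extraction is deterministic: the posterior mean of each stack is the
feature vector, giving four 48-dim blocks per patient
(pre_lesion, post_lesion, pre_mask, post_mask) = 192 MRI features. An
optional flag appends four voxel-count summaries (pre/post core and edema
area within the window), giving 196 — provided because the original feature
count was reported as 196 without a decomposition; the default stays 192.

## Clinical encoding and design matrices

The 28 clinical parameters (demographics, presentation deficits,
intraoperative adjuncts, molecular markers, adjuvant therapy, radiological
findings) are encoded to 30 numeric columns: 21 binaries as 0/1, laterality
as a 3-column one-hot (one logical parameter), extent of resection as the
ordinal 0–3, and the five continuous parameters (age, preoperative KPS,
MIB-1 index, radiation dose, fractions) z-scored with **training-split
statistics only**. Missing values are imputed from the training split
(median/mode) with an imputation report. MRI latent columns are likewise
z-scored with training statistics: the latents are not unit-scale in
practice, and the unscaled block measurably degrades classifier training
(`scale_mri=False` restores raw latents). Three matrices share identical row
order (sorted by patient id): clinical (30), MRI (192), multimodal (222).

## Classifiers

The reference classifier is a dense softmax network (two hidden layers
64/32, ReLU, inverted dropout, Adam, two-neuron softmax output) trained on
weighted cross-entropy; `class_weighting="balanced"` reweights inversely to
class frequency. The study default uses dropout 0.5 and learning rate 3e-3
(300 epochs, batch 16), chosen in pilot runs because the fused 222-column
matrix overfits at lower dropout. For the multimodal model the MRI block can
optionally be routed through a small compression branch before concatenation
with the clinical columns (`mri_branch_widths`); the default is plain
concatenation, which matched or beat the branch in pilot runs. Everything is
deterministic given the seed.

Baselines are tree ensembles tuned by exhaustive grid search (inner
stratified CV on AUC, refit on the full input): random forest plus two
gradient-boosting variants standing in for XGBoost/LightGBM, which are not
available in this environment.

## Evaluation protocol

Patients are split 2:1 by operation date (earliest two thirds train; ties
break by patient id), reproducing a temporal hold-out. Model selection
statistics use stratified 5-fold CV repeated 10 times with fold assignments
re-drawn per repeat (50 records). Metrics: AUC (tie-aware rank statistic —
identical to the Mann–Whitney U scaled by n₁n₂), accuracy, sensitivity,
specificity and F1 at threshold 0.5, with KPS < 70 as the positive class.
ROC curves are averaged vertically on a 101-point FPR grid. Model
comparisons use the paired t-test over the 50 (repeat, fold) AUC pairs; CV
folds are not independent, so these p-values are descriptive.

## Interpretability

Grouped permutation importance: the drop in held-out test AUC when all
columns of a group are jointly permuted with one shared row permutation
(30 rounds by default), preserving within-group correlation. Groups are the
four MRI latent blocks plus each clinical parameter separately; negative
importances are reported unclipped.

## Synthetic cohort generator

The generator emulates the target population, not MRI physics:

- **Clinical marginals** follow the published 150-patient baseline table
  (e.g. 43.3% female, 18% biopsy-only, 52% 5-ALA, extent-of-resection
  distribution 20/14/28.7/37.3%). Age ~ N(64, 13²) clipped to [21, 92];
  MIB-1 log-normal with median 22.5; preoperative KPS on the 10-point grid
  with median 80 and P(≥70) ≈ 0.79; radiotherapy follows the stated
  regimens (60 Gy/30 fractions standard, 40.05 Gy/15 if age ≥ 70, ~7%
  untreated). Operation dates are uniform over Dec 2001–Dec 2022 so the
  temporal split is well defined. Only marginals are calibrated; the joint
  structure (beyond biopsy ⇒ lowest resection category) is not.
- **Tumors** are ellipsoidal cores with an edema shell inside a brain
  ellipsoid on a 64×64×32 grid (3-mm slices); resection relabels a uniform
  fraction of core voxels (within the recorded extent category's range) to
  parenchyma.
- **Outcome**: a logistic model on per-cohort z-scored covariates; the
  default plants half the signal variance in clinical covariates
  (age +1.0, preoperative KPS −1.0) and half in morphology (residual core
  volume +1.2, edema volume +0.7), latent noise 0.5, intercept −0.4
  (prevalence ≈ 0.4). The 10-point KPS endpoint is sampled consistently
  with the binary label.

A green test on this world establishes that the pipeline recovers planted
multimodal signal and ranking; it does not establish clinical performance —
real cohorts have correlated covariates, irregular tumor shapes, scanner
effects and label noise the generator does not model.

## Statistics

Fisher's exact test (two-sided by the point-probability rule) for 2×2
tables; the Freeman–Halton generalisation for r×c tables by exhaustive
enumeration up to 10⁷ tables, beyond that Monte-Carlo with fixed margins and
a reported standard error. Mann–Whitney U with midrank ties: exact
enumeration over assignments when n ≤ 12, otherwise the tie-corrected normal
approximation. The baseline table reports count (%) or median (range) per
outcome group with the appropriate test.

## Numerical choices and limitations

- Extraction uses the posterior mean (no sampling) for reproducible feature
  tables; checkpoints reload bit-compatibly.
- log-variances are clipped to ±8 for stability (gradient gated at the clip).
- Degenerate inputs: all-zero area vectors centre the slice window; single-
  class folds raise; zero-variance paired differences are flagged as ties.
- The dense VAE encoder is a deliberate CPU-budget substitute for a 3D
  convolutional one; latent fidelity to morphology is the main scaled-down
  bottleneck (residual-volume R² from post-op lesion latents is ≈0.3–0.7
  depending on seed and corpus size at the default budget).
- CV AUC differences of the order 0.01–0.02 are within fold-resampling noise
  at n=200 training patients; ordering checks use fixed seeds.
- In the synthetic world the extent-of-resection category causally determines
  the resected fraction, so it is a strong proxy of residual core volume
  (R² ≈ 0.6); when outcome signal is planted on residual volume, permutation
  importance legitimately splits credit between the post-lesion latents and
  this clinical ordinal, and their relative ranking is within permutation
  noise. Real cohorts, where extent is itself image-derived and noisier,
  need not show this coupling.
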