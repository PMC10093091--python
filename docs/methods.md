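# Methods

`lgan-dcis` implements a weakly supervised pipeline for stratifying ductal
carcinoma in situ (DCIS) patients by their risk of a subsequent breast
cancer event (BCE), from H&E-stained tissue-microarray (TMA) core images,
and fuses the resulting imaging risk with clinicopathological variables in
a discrete Bayesian network. This note records the models, the choices
made where the design was genuinely open, and what the synthetic fixtures
do and do not demonstrate.

## Imaging pipeline

**Tissue segmentation.** Each core's per-pixel Rec.601 luminance is
modelled as a 2-component univariate Gaussian mixture fitted by EM
(means initialised at the 25th/75th luminance percentiles, equal weights,
a common initial spread of a quarter of the inter-percentile distance;
log-likelihood tolerance 1e-4, at most 100 iterations). Tissue is the
lower-mean component — H&E tissue is darker than glass — and the mask is
the per-pixel MAP assignment, which makes the rule invariant to component
relabelling. The EM is implemented directly because the initialisation is
part of the contract and generic mixture implementations (k-means-seeded
covariances) were observed to fall into a degenerate optimum on
white-background cores in which one broad component swallows both modes.

**Colour normalisation.** Every core is normalised to one manually chosen
reference core by per-channel histogram matching at 128-bin resolution:
each input bin quantile is mapped to the smallest reference bin whose CDF
reaches it (ties toward the lower bin), output stays 8-bit. Matching is
monotone, idempotent up to one bin width (2 intensity levels), and
reproduces the reference CDF within the mass of one bin. A scale caveat:
full-histogram matching removes per-core intensity-distribution
differences. On real ~7000 px cores the histogram is dominated by stroma,
so class-relevant local structure survives; on very small synthetic cores
the nuclear signal is a large fraction of the histogram and matching can
attenuate it. The demonstration therefore uses 512 px cores, where the
effect is modest.

**Patch extraction.** Square patches on a raster grid from (0,0),
half-open windows, incomplete boundary windows dropped; a patch is kept
only if at least `min_tissue` (default 50%) of its area is tissue.
Training uses non-overlapping tiles; inference tiles with 50% overlap.
Defaults at desk scale are 512 px cores and 64 px patches; both are
configuration, the algorithms are size-agnostic.

**Features and backbones.** All trainable components are small dense
networks over a fixed patch representation: RGB downscaled to 16×16 plus
a 16×16 local-contrast map (the standard deviation of luminance in a 5 px
window, then downscaled). The texture channel matters: nuclear density,
pleomorphism and necrosis express themselves as nucleus-scale contrast
that plain downscaling averages away. Features are standardised with
training-set statistics stored on each model handle. The pipeline is
backbone-agnostic: a large pretrained CNN can stand behind the same
`EncoderHandle`/`ClassifierHandle` contracts.

**Adversarial patch generator.** The generator is trained on the real
patch pool in a PCA-compressed space (default 40 components of the
16×16×3 pixel features, coordinates whitened and soft-bounded by a scaled
tanh at ±4). The discriminator (one hidden layer, least-squares
adversarial objective) is trained to separate real from generated
coordinates; the generator minimises a feature-matching loss on the
discriminator's hidden activations — the standard stabiliser for
adversarial training at small sample sizes, where a classification-loss
generator was observed to run away from the data manifold on some seeds.
Sampled coordinates are decoded to pixels and completed with residual
noise matched per pixel to the training reconstruction residuals, so a
freshly trained held-out discriminator separates real from generated
patches only weakly (accuracy well below the 0.95 sanity bound).
Sampling is deterministic given the latent vector; the residual noise is
seeded from the latent batch itself.

**Latent-space selection.** Real and generated patches are embedded by an
encoder trained as a 2-class classifier on the weak labels (penultimate
layer = embedding). A generated patch is kept iff (a) its mean cosine
similarity to its k nearest real aggressive embeddings reaches τ
(defaults k=5, τ=0.5) and (b) it is closer in cosine to the aggressive
class centroid than to the non-aggressive one. The two-condition rule is
robust to outliers (the kNN part) and to class overlap (the centroid
margin); it is scale-invariant and monotone in τ.

**Weak labels.** No patch-level annotation exists: every patch from a
BCE patient is labelled aggressive, every patch from a non-BCE patient
non-aggressive. In the synthetic fixture this injects known label noise
(non-BCE patients' cores still contain occasional aggressive ducts),
which caps the patch-level AUC against weak labels near 0.8 even for a
perfect classifier; patient-level aggregation recovers most of the
separation.

**Classifier and patient score.** The classifier re-tunes its last k
parameterised layers (k=0 freezes everything bit-exactly; default all
layers for the small default backbone) on real patches plus selected
generated patches, the generated set sub- or oversampled until class
counts balance. Real data are split 90/10 patch-wise for a held-out AUC.
At inference the patient score is the fraction of 50%-overlap patches
whose predicted aggressiveness probability reaches the decision cutoff
(default 0.5). The operating threshold on that fraction is the Youden-J
maximiser (ties toward the smaller threshold) computed on a
calibration subset of training patients (default 30%, stratified) that
never enters classifier training — scores of patients whose own patches
trained the classifier are optimistically shifted and would push the
threshold above the test distribution.

## Fusion

**Pairwise screen.** All C(5,2)=10 unordered pairs of {age, size, grade,
TILs risk, imaging risk} are tested with Fisher's exact test (complete
cases per pair; the Freeman–Halton extension, by direct enumeration of
all tables with the observed margins, covers the 3-level grade), and
adjusted by Benjamini–Hochberg at FDR 0.1.

**TILs risk.** A Cox proportional-hazards model (partial likelihood,
Breslow ties, via statsmodels PHReg) on the four binary TILs variables;
patients are dichotomised at the training-median linear predictor
(≤ median → low). Degenerate designs (constant covariates, separation)
fall back to the null model, i.e. everyone low.

**Structure learning.** Greedy hill climbing over add/delete/reverse
moves on the 6-node graph {Age, Grade, Size, GAN, TILs, BCE}, scored by
AIC (sum of per-node multinomial log-likelihoods minus the number of free
CPT parameters), under the role constraints that Age admits no incoming
and BCE no outgoing edges; ties break by move-enumeration order; default
10 seeded restarts from random constraint-respecting DAGs. Category
spaces are fixed a priori (all canonical levels stay in the model even if
unobserved in a training fold). Note the statistics of the score: a
spurious edge improves AIC whenever the corresponding likelihood-ratio
statistic exceeds twice its degrees of freedom (probability ≈0.16 for a
1-df edge), so learned graphs typically carry one or two extra edges at
any sample size; the planted edges themselves are recovered essentially
always at n=5000. This is a property of AIC, not of the search.

**Parameters and inference.** CPTs use additive smoothing (default α=1;
α=0 is the raw MLE with uniform fallback for empty rows). Inference is
exact enumeration over the ≤6 discrete nodes; with all BCE parents
observed it reduces to a CPT-row lookup.

**Leave-one-out validation.** Each patient is predicted by a network
whose structure and parameters are refit on the other n−1 patients
(a fixed-structure mode exists for comparison); the AUC is Mann–Whitney
over held-out probabilities. Two estimator properties are worth knowing.
First, patients sharing an evidence configuration receive probabilities
perturbed by their own removal, anti-correlated with their own label, so
same-evidence pairs score 0 rather than ½: the attainable optimum is the
Bayes AUC without tie credit. Second, for the same reason the permutation
null sits below 0.5 rather than at it. Both effects shrink as evidence
gets richer.

**Survival.** Kaplan–Meier curves (lifelines) for the two predicted risk
groups, time administratively censored at 5 years, events after the
horizon censored; two-sample log-rank test with a χ²₁ p-value.

## The synthetic data

Cores are rendered as near-white canvases with duct lobules: a stromal
halo disc, an epithelial duct disc, nuclei as small dark discs. Tissue is
the union of halos, so the ground-truth mask is exact and a core with no
ducts has no tissue. Aggressive morphology means threefold nuclear
density, threefold nucleus-radius dispersion (pleomorphism), and a
central necrosis disc with peripherally displaced nuclei (comedo
pattern) drawn with probability `necrosis_prob`. Each duct is aggressive
independently with probability `aggressive_fraction`; cores of BCE
patients use the high level (default 0.7), others the low level (0.1).
Everything is bit-reproducible under the `SyntheticCoreSpec.seed` field.

Cohort tables are sampled from a planted generative structure — Age,
Grade, imaging risk and TILs variables from marginals matching the
published cohort table; Size from a grade-conditional table whose
high-grade row is the published 72% (the unpublished low/intermediate
rows, 0.20/0.21, were chosen once to match the overall size marginal);
BCE from a 4-row table over Age × imaging risk (0.70/0.30/0.50/0.10,
chosen once for ~29% prevalence with both parents informative); imaging
risk independent of Age by construction. Follow-up is a truncated normal
whose parent parameters are solved so the *truncated* distribution has
the published mean and SD — the published numbers describe the observed,
range-limited data, and using them as parent parameters directly would
bias the mean by ≈+0.35 years for the training cohort. A marginal-exact
mode reproduces a printed count table exactly, with each column an
independently shuffled permutation (joint structure random given the
marginals).

What the fixtures do not emulate: real stain variation and scanner
effects, tears and artefacts, the full 7000×6000 px core scale,
non-duct tissue classes, and any true biological coupling between
morphology and the clinical covariates beyond the planted edges. Passing
tests demonstrate that the pipeline recovers signal it is supposed to
recover and respects its contracts — not clinical performance.

## Problem sizes used

The bundled demonstration runs 40 training patients (1:9 BCE imbalance —
deliberately hostile to plain fine-tuning, the regime augmentation is
for), 40 balanced test patients, 1–3 cores of 512×512 px per patient,
64 px patches, 2,000 generated patches, and small dense networks; the
full chain completes in roughly a minute on one CPU and the five-seed
paired ablation in about five minutes. Sweeping the planted conditions
(larger cores, more patches, deeper backbones) is configuration, not
code.

## Known limitations

- The default backbones are small dense networks on 16×16 features;
  they demonstrate the pipeline's mechanics, not state-of-the-art
  histology modelling.
- The generator models a PCA-compressed patch space; high-frequency
  content beyond the matched residual noise is not generated.
- The ratio-threshold calibration is as good as the calibration subset;
  with very few outcome-positive patients it degenerates to a single
  patient's score (the pipeline falls back to whole-cohort calibration
  when a class is missing entirely).
- Continuous or hybrid networks, competing risks, and multivariable Cox
  beyond the TILs score are out of scope.
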