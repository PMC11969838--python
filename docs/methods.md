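# Methods

This note documents the models, statistics and design choices behind
`causalcyto`, in the order data flows through the package.

## Kernel independence testing

Dependence between two variables is measured with the Hilbert–Schmidt
Independence Criterion.  With Gaussian RBF kernel matrices `K_X`, `K_Y`
(bandwidth: median pairwise Euclidean distance, falling back to 1.0 when the
median is zero; overridable) and the centering matrix `H = I − (1/n)·11'`,

```
HSIC(X, Y) = tr(K_X H K_Y H) / (n − 1)
```

Because `tr(K_X H K_Y H) = tr(H K_X H · K_Y)` by cyclicity, the
implementation computes the centered kernel once and takes an elementwise
product — the two readings of the trace are identical.  The statistic is
non-negative (trace of a product of PSD matrices) and symmetric in X and Y.
The `1/(n − 1)` scaling is exposed alongside a `squared` variant
(`1/(n − 1)²`); permutation calibration makes the constant irrelevant to
decisions.  Discrete labels use a delta kernel (1 iff equal).

Significance comes from a seeded permutation null: rows of Y are permuted
`B` times (default 199) and the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + B)` is reported, so p is never exactly
zero and is uniform (slightly conservative) under the null.  For a discrete
Y the permuted statistic is a sum of within-class quadratic forms, which is
evaluated for all permutations in a single matrix product — the same null,
just cheaper.

### Conditional independence

Conditional dependence of X and Y given a *discrete* Z uses the triple-trace
statistic over centered kernel matrices:

```
KCI(X, Y | Z) = tr(Kc_X Kc_Y Kc_Z) / n²
```

Its null distribution is generated by permuting Y within each stratum of Z,
which preserves the Y|Z margins exactly and is therefore a valid conditional
null for discrete Z.  Continuous Z is rejected with an explicit error: a
within-stratum permutation scheme does not exist for it, and supporting it
(e.g. via kernel-ridge residualization) is out of scope.

One numerical property matters: the triple trace is *not* centered at zero
under conditional independence — the marginal Z-dependence of X and of Y
alone inflates it — and conditional dependence can shift it in either
direction (in a collider `X → y ← Z`, conditioning induces *negative*
within-stratum correlation, which pushes the statistic below its null
center).  The test therefore measures extremeness two-sidedly around the
permutation-null mean, keeping the add-one convention.  This preserves the
intended monotonicity — stronger conditional dependence, smaller p — for
dependence of either sign.  Verified behaviour at the defaults: type-I error
0.03 at α = 0.05 under a true conditional null; the collider pair is flagged
in ≈ 100% of simulations at n = 300.

Single-member strata cannot be permuted; they are left fixed with a warning.

## Causality map

After the final pooling layer each channel i of a sample is a k×k
non-negative activation grid `F^i`.  The stack is normalized by the sample's
single largest activation (per-sample, across channels — per-map
normalization would force every channel's peak to 1 and erase cross-channel
magnitude; it is available behind a flag for comparison).  The pairwise
conditional-probability estimate is

```
P(F^i | F^j) = max(F^i) · max(F^j) / sum(F^j)
```

which lies in [0, 1] because every entry is ≤ 1 and `sum(F^j) ≥ max(F^j)`.
An all-zero channel carries no conditional evidence; its column is zero by
convention.  The n×n map is computed per sample from the per-channel maxima
and sums in O(n²).

## Causal factor selection

Flattened feature maps become candidate factors; the default flattening is
one factor per channel (its peak activation, i.e. "feature presence"), with
a `full` mode exposing every pixel.  Selection is two-staged:

1. **Marginal screen** — HSIC permutation test of every factor against the
   label (delta kernel on y); factors with p ≥ α (default 0.05, raw per
   test; Benjamini–Hochberg optional) are removed.  Per-factor seeds derive
   from the factor's rank in sorted-id order, so results are invariant to
   column order.  Constant columns are removed outright with p = 1.
2. **Cause-pair detection** — for each unordered pair of kept factors,
   a marginal HSIC p-value and a conditional KCI p-value given y.  Two
   causes of y form a collider, so conditioning on y strengthens their
   dependence: a pair is flagged iff `p_cond < p_marg` and `p_cond < α`.
   P-values are compared rather than raw statistics because the two
   statistics have different scales.  A stricter classic-collider gate
   (`p_marg ≥ α`) is available by configuration.  Pair seeds also derive
   from sorted-id ranks, so the flag set is independent of execution order.

Downstream fusion consumes **all kept factors**; the cause-pair flags
identify which kept factors act as causes rather than effects and are
reported for interpretation.  For that reason the image pipeline defaults to
the screen only (`detect_pairs=False` in `PipelineConfig`) — running the
O(pairs · B · n²) pair sweep changes nothing about the fused features — while
`select_causal_factors` runs both stages by default for tabular analyses.

## Deep pipeline

Images are resized to a square side (224 default; the desk-scale
configuration uses 64) and scaled to [0, 1].  Splits are stratified
60/20/20 per class (remainder to training).  Training-set augmentation
enlarges the split to `factor ×` its size using five technique families —
geometric transforms, color jitter, blur/sharpen kernels, random erasing,
and same-class image mixing — leaving validation and test untouched.

The built-in backbone is a three-block 3×3 conv + ReLU + 2×2 max-pool
network in numpy (64×64 → 8×8 maps over 32 channels).  Freshly constructed
it holds seeded He-initialized random weights; `fit` fine-tunes it
end-to-end through a temporary linear softmax head on the flattened maps
(Adam, lr 6e-3 with a three-epoch linear warmup, weight decay 1e-4, label
smoothing 0.05, early stopping on validation accuracy with best-weight
restore).  The warmup matters: without it, large early Adam steps can kill
every ReLU path for some initializations, pinning the loss at ln C; a
dead-start guard additionally reinitializes once at half the rate if the
loss ends within 0.10 of ln C.  The default regime freezes
the first block at its random initialization — partial fine-tuning — which
lets the frozen prefix be precomputed once and cuts training time roughly in
half at a small accuracy cost.  Any other extractor satisfying the
`BackboneContract` (n non-negative k×k maps per sample) can be plugged in.

Per sample, three segments are concatenated into the fused vector:
the flattened causality map (n²), the kept causal-factor values, and the
flattened normalized feature maps (n·k²).  A dense softmax head (two hidden
layers, 128/64, Adam, early stopping) classifies the fused vectors; the
paired **base model** trains the identical head on the flattened maps alone,
sharing the same backbone and seed, giving a clean ablation of the causal
segments.  Factor selection and feature standardization are fit on the
training split only and frozen; deleting or corrupting the test split does
not change the trained model (tested).

Default problem sizes for the end-to-end benchmark: 1000 synthetic images
(200 per class) at 64×64, ×4 augmentation of the training split, a 24-epoch
fine-tuning cap, and 5 seeds for the ablation comparison.

## Morphometrics

Segmentation uses three-band multi-Otsu intensity thresholding on grayscale
(darkest band → nucleus, middle → cytoplasm, lightest → background in a
bright-field stain), morphological opening/closing, largest-component
selection and hole filling.  The synthetic generator's ground-truth masks
can bypass segmentation so feature code is testable independently of
segmentation quality (mean nucleus Dice on the synthetic cells ≈ 0.99).

Shape descriptors per compartment (the "cytoplasm" outer compartment is the
full cell region, nucleus + cytoplasm, whose closed contour is what the
perimeter and diameters describe):

* area — pixel count; N/C ratio — N/(N+C);
* perimeter — boundary length of the mask contour;
* longest diameter — diameter of the minimum circumscribing circle of the
  mask pixels (via Welzl's algorithm through `shapely`);
* shortest diameter — diameter of the largest inscribed circle, i.e. twice
  the maximum of the Euclidean distance transform;
* roundness — area / (π · (longest/2)²), ≤ ~1, equal to 1 for a disk;
* elongation — shortest / longest diameter, in (0, 1];
* nucleus position — `1 − d / (cell longest diameter / 2)` with d the
  nucleus–cell centroid distance, clamped to [0, 1]; 1 means perfectly
  central.  This definition is monotone in centrality, which is all the
  classifier consumes.

Texture uses a gray-level co-occurrence matrix restricted to pixel pairs
inside the cell mask: 8 uniform intensity bins over [0, 1], distance 1,
four angles (0°, 45°, 90°, 135°) averaged, symmetric, normalized.
Properties: contrast `Σ P (i−j)²`; energy `sqrt(Σ P²)` (root of the angular
second moment); homogeneity `Σ P / (1 + |i−j|)` (inverse-difference form —
note some libraries use `1/(1+(i−j)²)` under the same name); correlation via
GLCM means/variances, defined as 1 when either marginal variance is zero
(a constant region is perfectly self-correlated).

Classical classification standardizes features on training statistics and
uses KNN (k = 5), RBF-kernel SVM, or a 200-tree random forest, all seeded.
With causal selection enabled, the kernel-test selection runs on the
training split only and the classifier consumes the kept features.

## Evaluation

One-vs-rest TP/FP/FN/TN from the confusion matrix give per-class precision,
recall and F1 (0/0 → 0 convention, with a warning when a class is never
predicted); accuracy is trace/total; macro averages are unweighted (micro
available).  Two AUCs are reported and labeled: the trapezoidal area under
the full ROC threshold sweep, and the single-operating-point quantity
`(TPR − FPR + 1)/2` evaluated at the argmax decision, which equals the
balanced accuracy of that operating point.  They answer different
questions and can differ materially; the operating-point value is reported
because it is cheap and threshold-free, the trapezoidal value because it is
the standard curve summary.

## Synthetic data

**Tabular SCM.**  Causes are standard Gaussians; the label discretizes
`effect_size · Σ causes + N(0, noise_sd)` into `n_classes` quantile bins;
effects are a centered class coding of the label plus Gaussian noise;
independents are pure noise.  Defaults (5 causes, 5 effects, 10
independents, effect 1.0, noise 1.0, n = 300, 5 classes) give each cause a
marginal correlation of ≈ 0.41 with the latent score — strong enough that
the screen keeps all dependent factors, weak enough that recovery is not
trivial.

**Cell images.**  One elliptical cytoplasm containing one elliptical
nucleus on a light noisy background, rendered with a ~1-pixel soft edge;
binary truth masks and all generative latents are returned.  Five classes
lie along a monotone severity axis with overlapping uniform bands:

| class | N/C ratio | nucleus axis ratio | centroid offset fraction |
|---|---|---|---|
| 1 | 0.06–0.14 | 0.85–1.00 | 0.00–0.12 |
| 2 | 0.13–0.24 | 0.78–0.95 | 0.05–0.18 |
| 3 | 0.22–0.36 | 0.70–0.88 | 0.10–0.25 |
| 4 | 0.33–0.48 | 0.62–0.82 | 0.15–0.35 |
| 5 | 0.45–0.60 | 0.55–0.75 | 0.20–0.45 |

The overlaps are deliberate: adjacent classes are genuinely ambiguous for a
fraction of cells, as in real cytology, so no classifier is expected to be
perfect.  A nearest-band-center rule on the true N/C ratio scores ≈ 0.86–0.93
depending on sample; a classifier using all three latents tops out around
0.93–0.94 — these are the practical ceilings against which pipeline accuracy
should be read.  A seven-class layout interpolates the same severity axis.

A nuisance grating texture (4 frequency/orientation ids) plus a small hue
shift is applied to the cytoplasm.  In `clean` mode the texture id is
independent of the class; in `confounded` mode it matches the class with
probability 0.8.  The nuisance carries no morphological information, so a
model leaning on it degrades under the clean/confounded shift.

What the generator does **not** emulate: overlapping cells, staining
variability, debris, chromatin texture inside the nucleus, and real optics.
Passing tests on this data show the machinery is correct and the causal
selection behaves as designed; they say nothing about clinical performance.

## Known limitations

* The conditional test supports only discrete conditioning variables.
* The printed triple-trace statistic is a heuristic; its two-sided
  permutation calibration is valid, but its power profile differs from
  residualization-based conditional tests.
* The built-in backbone is deliberately small; accuracy on the synthetic
  benchmark (~0.85) sits below the latent ceiling (~0.93), the gap being the
  price of a tiny fine-tuned network at this sample size.
* The operating-point AUC depends on the chosen operating point; only the
  trapezoidal AUC is comparable across models with different thresholds.
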