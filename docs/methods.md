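# Methods

`leafkdx` diagnoses potassium (K) deficiency in apple leaves from RGB
photographs of detached leaves on a light calibration board.  K-starved
leaves develop a yellowing band along the margin, brown necrotic spots,
and eventually scorch, while the veins and leaf body stay green longer;
the pipeline quantifies these symptoms as color and shape features and
classifies each leaf as deficient (class 1) or normal (class 2), with a
separate model per growth period (flowering, young fruit, fruit
enlarging, mature), since leaf color and geometry drift over the season.

## Image chain

1. **Gaussian denoising** — separable normalized kernel, defaults
   ksize = 5, σ = 1 px.  Kernel weights sum to 1, so constant regions are
   preserved exactly (up to integer rounding).
2. **Background removal** — excess-green index 2G−R−B thresholded by
   Otsu, largest 8-connected component, holes filled.  Brown necrotic
   spots fall below the vegetation threshold and would otherwise punch
   holes; hole filling recovers them into the leaf support.  A frame
   with no contrast is resolved by the sign of the mean index: uniformly
   vegetation-colored frames give a full-frame mask, board-only frames
   raise an empty-segmentation error.
3. **Contour extraction** — Moore-neighbor boundary tracing with Jacob's
   stopping criterion on the single-leaf mask.  Perimeter is the
   weighted chain length (1 per axial step, √2 per diagonal); on a
   rasterized disk this estimator runs ≈ 4 % above the true
   circumference, which is why the circularity F of real rasters sits
   slightly below 1 even for round leaves.  Masks smaller than 4 px are
   rejected as degenerate.
4. **Single-leaf splitting** — one crop per 8-connected component with
   area ≥ 25 px², fixed 5 px margin, ordered top-to-bottom then
   left-to-right.  Touching leaves merge into one component; the package
   does not attempt to separate them.
5. **MSRCR illumination correction** — multi-scale retinex with color
   restoration:
   R_i = gain · [C_i · Σ_k w_k (log(I_i+1) − log(G_{σ_k}∗I_i+1))] + offset,
   C_i = β (log(α I_i + 1) − log(Σ_j I_j + 1)), followed by a 1 %/99 %
   per-channel percentile clip rescaled to [0, 255].  Constants are the
   standard α = 125, β = 46, gain = 192, offset = −30 with equal weights.
   The canonical surround scales (15, 80, 250) px presume roughly
   1000-px photographs; the pipeline scales them by min(H, W)/1000
   (floor 2 px), because a surround much larger than the leaf itself
   produces boundary halos instead of flattening illumination.  Halos
   remain the method's main artifact: within a few pixels of the leaf
   boundary the corrected luminance reflects distance to the bright
   board, not leaf color.
6. **Region segmentation** — HSV boxes on the H ∈ [0, 180), S, V ∈
   [0, 255] convention: green body H ∈ [35, 77] with S, V ≥ 30; brown
   spots H ∈ [0, 25] with V < 120, morphologically opened (disk radius
   1); yellowing margin = leaf − green − spots, i.e. the margin is
   defined by subtraction rather than by its own hue box.  By
   construction the three regions partition the leaf.

Region masks are computed on the **denoised** image and color means on
the **MSRCR-corrected** image: the hue boxes are calibrated on natural
leaf colors, which the retinex log-surround transform does not preserve,
while channel means are only comparable across lighting conditions after
correction.

## Features (22 per leaf)

Color (12): masked means of R, G, B; H, S, V; L, A, B (LAB on the 8-bit
offset scale: L·255/100, A+128, B+128); and the chromaticity coordinates
NRI = R̄/(R̄+Ḡ+B̄), NGI, NBI.  The chromaticities sum to 1 exactly, which
makes the 22-column design structurally rank-deficient (see Screening).

Shape (10): long/short axis l₁ ≥ l₂ of the mask's second-moment
equivalent ellipse (rotation-stable, unlike caliper diameters),
perimeter C, areas S (leaf), S₁ (margin), S₂ (spots), and the derived

* eccentricity E = √(1 − (l₂/l₁)²),
* circularity F = 4πS/C² (1 for a perfect disk; ≤ 1.1 allowing
  discretization),
* color change ratio CR = S₁/S,
* spot change ratio SR = S₂/S.

Canonical column order: R, G, B, H, S, V, L, A, Bb, NRI, NGI, NBI, l1,
l2, C, S_area, S1, S2, E, F, CR, SR (the leaf area is named `S_area` to
avoid colliding with HSV saturation `S`).

## Screening (influence factors)

Both the 22 features and the response — measured leaf K content by
default, the class label as a configurable alternative — are z-scored
(population sd), an ordinary least-squares regression is fitted, and
each feature's **influence factor** is the magnitude of its standardized
coefficient.  Features below the arithmetic mean of the factors are
dropped; the retained set is never empty because the maximum is always
at least the mean (a 10⁻⁹ relative tolerance guards the all-equal case
against float summation error).  A fixed cutoff (for example 0.35, the
mean reported for the original field data) may be supplied instead of
the recomputed mean.

Because NRI + NGI + NBI ≡ 1, the centered design always has a null
direction; the screening solver therefore falls back to the minimum-norm
(pseudoinverse) least-squares solution, which distributes a collinear
group's weight symmetrically and is deterministic.  The strict solver
`fit_mlr` keeps its rank-deficiency error for general use.

With many features strongly correlated through severity, individual OLS
coefficients split the shared signal, so the retained set varies with
the sample — an inherent property of coefficient-magnitude screening,
not a defect of the implementation.

## Fisher LDA

Unnormalized scatter matrices S_W = Σ_c Σ_{i∈c}(x_i−μ_c)(x_i−μ_c)ᵀ and
S_B = Σ_c n_c(μ_c−μ)(μ_c−μ)ᵀ (their sum equals total scatter); the
projection takes the top generalized eigenvectors of (S_B, S_W), unit
normalized with the first nonzero component forced positive so runs are
bit-reproducible.  A singular S_W receives an εI ridge with
ε = 10⁻⁶·trace(S_W)/p, logged.  For two classes rank(S_B) = 1, so the
default 2-D output pads with the second generalized eigenvector (near-
zero eigenvalue) and warns; `n_components=1` gives the canonical
behavior.  The 2-D mode exists for visualization parity, not because a
second discriminant carries class information.

The discriminant scores are z-scored on the training set (frozen in the
model) before the classifier.  The raw projected scale depends on the
within-class covariance and can sit orders of magnitude below 1, at
which point fixed kernel widths are meaningless — an RBF with γ = 0.1
sees an all-ones Gram matrix and collapses to the majority class.  Unit
scale is what fixed hyperparameters presuppose.

## Classifiers and evaluation

* SVM: RBF kernel k(u,v) = exp(−γ‖u−v‖²), C = 10, γ = 0.1.
* KNN: k = 6, Manhattan distance; 3–3 vote ties resolve to class 1
  (deficient), the fail-safe direction; distance ties resolve by sample
  index.
* Decision tree: Gini, best-split, depth ≤ 5, no further pruning.

Data are split stratified 70/30 (1700 samples → 1190/510) per period,
independently per period.  Metrics condition on class 1 (deficient) as
positive: Acc = (TP+TN)/n, Rec = TP/(TP+FN), Pre = TP/(TP+FP),
F1 = 2·Pre·Rec/(Pre+Rec), with F1 ≡ 0 when Pre·Rec = 0.  A stratified
k-fold tuning utility exists but the defaults are the fixed values
above.

## Synthetic data generator

No public image set accompanies the diagnosis task, so the generator
defines the study conditions.  Each leaf is an ellipse (default
half-axes 45×28 px in a 128×128 frame, jittered ±15 % per sample) with
low-order sinusoidal radial wobble (orders 3–7, amplitude ≤ ~0.1); the
yellowing margin is an inward distance-transform band whose area is set
to the requested fraction exactly (pixel-count quantile with
deterministic tie-breaking); spots are non-overlapping disks placed in
the green interior; colors get per-channel Gaussian noise (sd 6) and a
multiplicative linear luminance ramp (default amplitude 0.15, random
direction); the board is light gray with faint calibration grid lines.

Severity s ∈ [0, 1] drives the symptoms (margin fraction 0.7·s, spot
count ⌊8·s⌉) and K content via k = 1.2 − 0.8·s + N(0, 0.05) % dry mass,
labeled deficient below 0.8 %.  The cutoff separating deficient from
normal K is a parameter, not a biological constant — grading standards
vary — and the defaults were chosen once as a plausible orchard
contrast: healthy leaves s ~ TruncNormal(0.08, 0.03), deficient
s ~ TruncNormal(0.70, 0.08) in equal proportion, i.e. clearly expressed
deficiency versus healthy foliage, matching a design with deliberately
K-starved versus well-fertilized trees.

What the generator does **not** emulate: venation, specular highlights,
camera noise models, occlusion, petioles, out-of-plane pose, or leaves
touching one another.  Passing tests therefore demonstrate that the
chain is correct and self-consistent under controlled conditions — mask
recovery, ratio recovery, screening behavior, separability — not that
field accuracy on real orchard photographs would match.

## Problem sizes and numerics

The shipped evaluation runs 500 leaves per period across 4 periods at
128×128 px, chosen to exercise the full chain at a realistic per-period
sample count.  All randomness flows from a single master seed through
`numpy.random.SeedSequence`, so every stage — generation, splitting,
classifier internals — is bit-reproducible.  Quantities frozen in a
fitted model: feature means/sds, retained feature list, LDA projection,
score scaler, classifier state.  Degenerate inputs are handled
explicitly: empty masks error, all-one-class datasets warn at generation
and error at fit, masks under 4 px are rejected by the tracer, and
sub-25 px² components are discarded at splitting.

## Known limitations

* Margin-by-subtraction means any pixel that is neither green nor brown
  counts as "yellowing", including hue outliers from sensor noise.
* The retinex halo band (few px at the leaf rim) biases corrected color
  means slightly toward the background.
* Severely clipped highlights (illumination amplitude near 0.5 with
  bright yellows) shift hue and can leak margin pixels into the green
  box.
* The influence-factor screen is unstable under strong collinearity;
  the LDA step downstream compensates, but the retained list itself
  should not be over-interpreted.
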