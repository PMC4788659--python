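# Methods

This note records the exact definitions, parameter choices and numerical
conventions used by `hepatex`, and the rationale behind each.

## 1. Model and assumptions

The working hypothesis is that cirrhotic liver parenchyma differs from
normal parenchyma in the *coarseness and irregularity* of its ultrasound
speckle texture, and that this difference survives a drastic reduction:
local pattern coding → global binarization → counting of horizontally
connected dark runs. The model deliberately ignores absolute echogenicity
(gray shifts cancel in both pattern operators) and uses only small
templates, assuming the operator has already selected a vessel-free
region of interest.

All computation is deterministic. Images are 2-D integer arrays;
templates are validated to be integer-typed and within a declared gray
range before processing.

## 2. Pattern operators

### Neighborhood geometry

For radius *R* the neighborhood is the perimeter of the (2R+1)×(2R+1)
square window, giving P = 8R neighbors (8, 16, 24 for R = 1, 2, 3).
Neighbors are enumerated counterclockwise starting at the east offset
(0, +R). A square ring (rather than an interpolated circle) keeps every
neighbor an exact pixel, so codes are exact integers with no
interpolation parameters.

### LBP

With center gray value g_c and neighbors g_1 … g_P in enumeration order,

    code = Σ_{p=1..P} s(g_p − g_c) · 2^(p−1),   s(z) = 1 if z ≥ 0 else 0.

Bit *p* carries weight 2^(p−1): the first neighbor is the least
significant bit, so codes span [0, 2^P − 1]. Equality (g_p = g_c) sets
the bit, making constant windows map to the all-ones code.

### DLBP (differential LBP)

Bit *p* is set when |g_p − g_c| > σ, where σ is the standard deviation
of *all* pixels in the window (center included, population normalization,
`ddof = 0` by default). A constant window maps to code 0. The absolute
difference makes the operator respond symmetrically to dark and bright
salient structure; the σ threshold suppresses bits caused by ordinary
speckle-level fluctuation, which is why DLBP-derived counts separate the
classes better than plain LBP counts.

**Exact integer comparison.** The bit test |d| > σ is evaluated without
floating point. With n pixels of window sum S and sum of squares S2,
population variance is (n·S2 − S²)/n², so

    bit = 1  ⇔  n·(n − ddof)·d² > n·S2 − S²

using exact (int64) arithmetic. This removes any dependence on float
rounding at the decision boundary; a property test confirms agreement
with an exact `fractions.Fraction` oracle. The full-image transform
computes window sums with integral images, so it is O(pixels) per radius.

### Valid region

Both operators are evaluated only where the full window fits: the output
shrinks by 2R per axis (50×50 → 48×48, 46×46, 44×44 for R = 1, 2, 3).
No padding is used, because padded borders would inject artificial
pattern codes into the histogram that Otsu thresholds.

## 3. Otsu binarization

### 8-bit rescale of code images

Raw code ranges grow as 2^(8R) (up to 2²⁴ for R = 3), so code images are
first min-max rescaled to integer levels [0, 255]:

    level = floor(255 · (code − min) / (max − min))

computed with integer floor division (order-preserving, exact). A
constant code image cannot be rescaled and raises
`DegenerateHistogramError`; the feature extractor maps that radius to
all-zero counts, which is the correct reading — a constant code image
means no salient structure at that scale.

### Threshold selection

The threshold t* maximizes the between-class variance

    σ_B²(t) = ω₀(μ₀ − μ_T)² + ω₁(μ₁ − μ_T)²

over all t whose low class (levels ≤ t) and high class are both
nonempty. This is equivalent to maximizing ω₀ω₁(μ₀ − μ₁)², which the
test suite verifies independently. Histograms with a single occupied
level raise `DegenerateHistogramError`.

**Tie handling.** Ties resolve to the smallest t. Unoccupied gray-level
stretches make σ_B² mathematically constant across many consecutive
thresholds, and float rounding noise (≈1e-16 relative) can make an
arbitrary plateau member the literal `argmax`; the implementation
therefore selects the first t within 1e-10 relative of the maximum.
Test oracles use the same plateau-tolerant comparison, and the achieved
variance is additionally cross-checked against scikit-image's Otsu.

### Binarize and complement

Pixels with level > t* become 1 (white), the rest 0 (black); the image
is then complemented so that low-code (structure-poor → after
complement, structure-rich) regions are black for run counting.

## 4. Run-connectivity features

For each row of the complemented binary image, maximal runs of black
pixels are found; a run contributes 1 to count(k) if its length is ≥ k.
Counts are therefore monotone nonincreasing in k, a validated invariant.
The nine features are count(k) for k ∈ {3, 4, 5} at radii 1–3, with
column names `lbp_r{R}_k{K}`. k starts at 3 because 1–2-pixel runs are
dominated by speckle noise rather than tissue structure.

## 5. Classification

### Interval rules

Per (radius, k) pair: `normal` if count ≤ normal_max, `cirrhotic` if
count ≥ cirrhotic_min, otherwise `indeterminate` (the gap flags possible
fibrosis, intermediate coarseness). The packaged boundaries were derived
from the reference DLBP counts: each normal_max equals the per-column
maximum of the typical normal templates (one atypical normal template is
excluded by the boundaries, which is why rule voting labels 48 of 50
reference templates correctly, not 50). Multi-rule classification takes
a majority vote; a tie is `indeterminate`.

The rules encode *clinical* count magnitudes. Synthetic irregular
textures produce counts in the indeterminate gaps of several rules and
typically vote `indeterminate`; that is expected, not a defect.

### Linear soft-margin SVM

`fit_margin_classifier` standardizes features (zero mean, unit variance)
and fits `SVC(kernel="linear", C=1, class_weight="balanced")`. Rationale:
feature standardization plus per-class box-constraint rescaling is the
classic default protocol of early MATLAB-era SVM tooling that this kind
of two-feature analysis historically used, and with 44-vs-6 class
imbalance the balanced weighting is what keeps the small normal class
from being absorbed by the margin. Accuracies are reported per class on
the training set itself (the protocol of interest is descriptive
separability of the 50 templates, not generalization).

### k-nearest neighbors

A small exact numpy implementation (k = 3 default, Euclidean distance,
stable sort). A tied vote with even k falls back to the label of the
single nearest neighbor.

### Reference accuracies

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, on the bundled 50-template reference counts, radius-3
(k = 4, k = 5) feature pair:

- DLBP: 86.36 % cirrhotic-class, 100 % normal-class accuracy,
- plain LBP: 79.55 % cirrhotic-class accuracy.

DLBP strictly dominates plain LBP in both classes under the identical
protocol, which is the substantive comparison. No classifier parameter
was tuned against these numbers; the protocol was fixed first and the
numbers are whatever it produces.

## 6. Synthetic texture generator

Purpose: exercising and property-testing the full pipeline without
clinical images. It is a caricature, not a simulator of B-mode physics.

- **Regular** (`kind="regular"`): a two-tone checkerboard (tones 100 and
  180), period 2 by default (period must be even so the pattern tiles);
  a stripe pattern is also available. Deterministic. A period-2 checker
  is provably invisible to the pipeline — every window of every radius
  sees the same two-tone arrangement up to translation, the code image
  is two-valued and periodic, and after Otsu + complement no black run
  of length ≥ 3 exists — so all nine counts are exactly zero.
- **Irregular** (`kind="irregular"`): uniform background 128, additive
  Gaussian speckle (σ = 10), and 12 overlapping dark discs with radius
  drawn uniformly from [2, 4] and contrast 80, clipped to uint8. The
  discs mimic coarse granular hypoechoic structure at the scale the
  radius-1–3 operators probe. Seeded with `numpy.random.default_rng`;
  `generate_dataset` derives independent per-template seeds from one
  master seed.

Limits: no multiplicative (Rayleigh-like) speckle by default, no depth
attenuation, no anisotropy, and count magnitudes do not match clinical
ones — do not use the interval rules on synthetic data (use the SVM or
k-NN modes).

## 7. Known limitations

- The reference dataset is counts, not images; the image pipeline is
  validated against oracles and synthetic data, not against the original
  clinical templates.
- Training-set accuracy on 50 templates with 2 features is a
  separability statement, not a clinical performance estimate; no
  cross-validation is performed.
- The normal class has only 6 templates; the 100 % normal-class figure
  rests on 6 points.
- Otsu assumes a bimodal histogram; near-degenerate code images are
  handled by the all-zero convention rather than by a more nuanced
  fallback.
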