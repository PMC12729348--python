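# Methods

## Problem and scope

Transverse ("short-axis") ultrasound of the median nerve shows a dark
(hypoechoic) fascicular cross-section with a bright epineurial rim inside
layered, speckle-textured soft tissue. Clinical use hinges on the nerve's
cross-sectional area (CSA, mm²): enlargement at the wrist relative to the
distal forearm indicates carpal tunnel syndrome. This package implements
the full measurement pipeline — synthesis of ground-truthed phantom images,
mask preprocessing, intensity augmentation, encoder–decoder segmentation,
overlap metrics, and manual-vs-automated CSA agreement — at desk scale, on
one CPU, with every random quantity seeded.

## Phantom generator

Each phantom is an image–mask–tracing triplet with known geometry.

**Geometry.** The nerve is an ellipse whose area is drawn from
Normal(μ, σ²) truncated at 0.5 mm² (wrist: μ = 9.8, σ = 2.4 mm², matching
normative wrist CSA; forearm: μ = 5.9, σ = 1.5 mm², matching typical
forearm manual measurements), aspect ratio a/b uniform on [1.2, 2.0],
orientation uniform on ±0.35 rad. The boundary radius is modulated by a
low-order (2–4 cycle) random Fourier series with relative amplitude 0.06,
giving the slightly lobulated outline of a real nerve while keeping the
polygon simple. The polygon has 64 vertices; its shoelace area times the
squared pixel spacing is the *true CSA* carried with the sample. The depth
of the centroid distinguishes sites: wrist 0.22–0.42 of image height
(superficial), forearm 0.52–0.75 (deep). Geometries that would leave the
canvas are rejected and resampled, at most 100 times.

**Appearance.** The background is a stack of horizontal tissue bands
(wrist 3, forearm 5) with alternating base echogenicity around 0.37–0.61,
the nerve interior is set to 0.18, and a 2-px dilated rim to 0.75. The
whole field is multiplied by (1 + c·g) where g is a unit-variance Gaussian
random field smoothed to a correlation length of 1.5 px and c = 0.35 —
multiplicative correlated speckle. Intensities live in [0, 1] as float32
and are quantized to 8 bits only when written to PNG. The generator
emulates the *statistical* structure the pipeline exercises (contrast,
texture, site differences, known truth); it does not model beamforming,
attenuation, shadowing or probe artifacts, so passing tests demonstrate
pipeline correctness, not clinical-grade performance.

**Simulated rater.** A tracing displaces each polygon vertex radially by
Normal(bias, jitter²) millimetres (defaults: jitter 0.05 mm, bias 0).
Radial jitter is exactly area-unbiased (polygon area is bilinear in
adjacent radii, which are independent); a positive bias inflates the traced
area like an annulus. If jitter produces a self-intersecting polygon the
vertices are re-ordered by angle about the centroid.

**Pixel spacing** is explicit metadata (default 0.1 mm/px; the 64-px test
profile uses 0.2 mm/px so the anatomy keeps the same physical size). All
CSA outputs are mm² through this calibration.

## Preprocessing

Tracings are filled by a nonzero-winding test at pixel centers, with
centers lying exactly on the boundary counted as foreground — so an
axis-aligned square with integer corners (10,10)–(19,19) fills exactly
10×10 pixels. The rasterizer is implemented here (vectorized winding
number) because off-the-shelf polygon fills differ from a pixel-center
point-in-polygon rule at boundary-adjacent pixels, and the package's CSA
accounting requires the rule to be exact and testable against a per-pixel
brute-force oracle.

Canvas geometry reproduces the standard ingestion transform: center-crop to
a fixed acquisition size, then pad symmetrically (extra pixel to the
bottom/right on odd remainders) to a square network input — 1024×690 →
1024×1024 at full scale, with the pad offsets recorded so coordinates are
invertible. A uniform scale factor yields desk-scale canvases. Mask rasters
are binarized at >127.

## Augmentation

Intensity-only, applied independently (never composed), masks untouched:

| kind | parameters | convention |
|---|---|---|
| CLAHE | clip 0.01 (8×8), 0.02 (8×8), 0.03 (16×16 tiles) | clip limit = fraction of tile pixel count, 256 bins (scikit-image backend) |
| gamma | γ = 0.70, 0.80, 1.20, 1.30 | out = in^γ on [0,1] |
| speckle | v = 0.10, 0.20, 0.30 | out = clip(in + in·n, 0, 1), n ~ N(0, v) |

With the retained original this is an 11× expansion. On canvases smaller
than the full scale the CLAHE tile grids are clamped so each tile keeps at
least 16 px per side; below that the integer clip counts of the three
settings coincide and the variants degenerate. The speckle "level" is
interpreted as the variance of zero-mean multiplicative Gaussian noise and
the result clipped to [0, 1]; both are declared conventions.

## Segmentation network

A 4-level U-Net: per level two 3×3 same-padding convolutions + ReLU, 2×2
max-pool between levels, filter widths doubling from `base_filters`
(default 16; desk-scale profile 8); a mirrored decoder using learned 2×2
stride-2 transposed convolutions and skip concatenations; a 1×1 projection
to two classes with per-pixel softmax. Input sizes must be divisible by
2^depth. The implementation is pure NumPy: im2col + BLAS matmul
convolutions with hand-derived backward passes (verified against central
differences in float64 to ~1e-5 relative error), He initialization, Adam.
Everything is float32 and driven by a single `numpy.random.Generator`, so a
(seed, data) pair reproduces training bit-for-bit on CPU.

Training follows the reference recipe — categorical cross-entropy on
one-hot masks, Adam at lr 1e-4, batch 4, 100 epochs, no early stopping —
with a 10% carve-out of the training split monitored per epoch for learning
curves only. The desk-scale profile (`SCALED_TRAIN`) uses 128×128 inputs,
8 base filters, 30 epochs and lr 1e-3: with ~40 minibatches per epoch a
desk-scale run sees ~1 000 Adam steps, and the higher rate reaches
convergence in that budget on the easy phantom task. Prediction is argmax
over the softmax with exact ties going to background.

## Metrics

Dice, IoU, accuracy, precision, specificity and sensitivity from exact
TP/TN/FP/FN pixel tallies. Conventions: empty-vs-empty masks score
Dice = IoU = 1 (edge guard; phantoms always contain a nerve); any other
zero denominator returns NaN as an undefined marker rather than raising.
Aggregates are per-image means with sample (n−1) SDs. The identity
Dice = 2·IoU/(1+IoU) is enforced to 1e-12 in tests.

## CSA agreement

CSA = foreground pixel count × spacing², by default restricted to the
largest 4-connected component (a nerve is a single structure; stray
false-positive islands would corrupt the area). Differences are
manual − predicted throughout.

* Paired difference: one-sample t on d with 95% CI mean ± t₀.₉₇₅,ₙ₋₁·SD/√n;
  also computable from published summary triples (mean, SD, n).
* Pearson r with Fisher-z CI: tanh(atanh(r) ± 1.96/√(n−3)); |r| clamped to
  1−1e-12 so perfect correlation yields a degenerate interval, not an
  overflow.
* ICC(2,1): two-way ANOVA mean squares, absolute agreement, single
  measurement, (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n); 95% CI by the
  Shrout–Fleiss F procedure with Satterthwaite degrees of freedom
  (cross-checked against pingouin's ICC(A,1) in tests).
* Bland–Altman: bias ± 1.96·sample SD of the differences, with per-pair
  means/differences exported for plotting. All points enter the
  computation; outlier display is a plotting concern only.

No multiple-testing correction is applied (raw p-values are reported), and
frames are treated as independent measurements — both deliberate mirrors of
common practice in method-comparison reports; grouping frames by subject
would be the stricter design and an optional group-aware split exists.

## Experiments and problem sizes

All designs draw their randomness from one run seed (trial i uses
base_seed + i) and enforce id-disjoint train/test sets; test counts are
floor(n × fraction), the only rounding consistent with 786 → 157.

Desk-scale study sizes, chosen to exercise each property within a single
CPU budget:

* **Baseline**: 200 wrist phantoms at 128×128 (0.1 mm/px), 80–20 split,
  30 epochs — held-out Dice and CSA agreement.
* **Generalization gap**: 24 training phantoms at 64×64 (0.2 mm/px),
  12 id-disjoint test phantoms rendered in-domain and gamma-0.55-shifted
  (a shift outside the augmentation lineup); the plain model trains
  60 epochs, the 11×-augmented model 8 epochs so optimization budgets are
  comparable; repeated over 3 seeds.
* **Stability**: five independent 80–20 splits of 60 phantoms at 64×64,
  30 epochs each; the spread (max−min) of per-trial mean Dice is the
  statistic.
* **ICC recovery**: 500 replicates of 100 simulated subjects × 2 methods
  with σ_s² = 4, σ_e² = 1; n = 100 keeps the ANOVA estimator's small-sample
  bias well below the Monte-Carlo standard error of the mean.
* **Rater bias power**: 100 repetitions × 20 phantoms; "non-significant"
  is operationalized as |mean d| < 3·SD/√n.

## Known limitations

* Phantoms contain exactly one bright-rimmed dark ellipse; there are no
  confusable structures (tendons, vessels, bone shadows), so absolute Dice
  values here are far above what clinical images yield and only the
  *relative* comparisons (domain gap, augmentation effect, stability) carry
  over qualitatively.
* The NumPy network is CPU-bound; full-scale 1024×1024, 100-epoch training
  is out of scope by design.
* Max-pool gradient routing sends ties to all argmax positions (ties are
  measure-zero with continuous inputs).
* The simulated rater jitters vertices independently; real tracing errors
  are spatially correlated and systematically biased at ambiguous
  boundaries.
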