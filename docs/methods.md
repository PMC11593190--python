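# Methods

This note documents the models, numerical choices and limitations of
`histofuse` — the account a maintainer needs to trust or change the
defaults.

## Pipeline model

Each RGB tile (natively 768×768, the LC25000 convention) is resized to
224×224 with anti-aliased bilinear interpolation and fed to three feature
extractors. The resize kernel and the grayscale weighting are not dictated
by the classification protocol itself; we fix bilinear+anti-aliasing and
ITU-R BT.601 luma (0.299R + 0.587G + 0.114B) as the common imaging
defaults, keep the luma unrounded (no second quantisation before LBP
thresholding), and expose both choices in the preprocessing module. The
class vocabulary is fixed: LACA=0, LSCC=1, benign=2; reports display
classes in the order (LACA, benign, LSCC).

### Deep block

The deep branch is a contract, not a fixed network: any callable
`224×224×3 → h'×w'×C` feature map, followed by global average pooling to a
C-vector (C=1280 and 7×7 spatial extent by default, the penultimate shape
of EfficientNet-B0). Reimplementing and fine-tuning a pretrained CNN is
out of scope — it requires weights the package cannot ship — so the
contract accepts a user-supplied pretrained adapter (which applies its own
input normalisation), while a *seeded test backbone* carries all automated
testing: a fixed stack of non-overlapping strided patch projections
(strides 4·4·2 for 224→7) with tanh nonlinearities and N(0, 1/fan_in)
weights drawn once from the seed, pixels scaled to [0,1]. It is a real,
deterministic convolutional feature extractor — just an untrained one —
so tests exercise exactly the code paths a pretrained backbone would.

### Textural block (LBP)

LBP codes use the circle convention: neighbour p of a pixel sits at
(−R sin θ_p, +R cos θ_p), θ_p = 2πp/P, counter-clockwise from east in
(row, col) coordinates. Non-integer positions are bilinearly interpolated;
coordinates within 1e-8 of an integer are snapped so axial samples read
pixels exactly. Interpolation stencils are precomputed once per (P, R).

Numerical choice: the sign threshold s(g_p − g_c) is evaluated on the
*interpolated difference* Σ w·(G_corner − g_c) rather than on the
interpolated value minus the centre. The two are algebraically identical,
but the difference form is exact on constant patches even though the four
bilinear weights need not sum to 1 bit-exactly — otherwise a constant
image would not produce the all-ones pattern. This also makes
monotone-shift invariance (adding a constant to every pixel) hold exactly.

Histogram modes: `raw` (2^P bins) is only enumerable for P ≤ 16 and exists
for oracle testing; `uniform` bins patterns with ≤ 2 circular transitions
by their count of ones (bins 0..P) and pools all others into bin P+1,
giving P+2 bins. The pipeline default P=1278, R=1 therefore yields a
1280-d textural block, the same width as the deep block. P=1278 on a
radius-1 circle oversamples the 8 physical neighbours; the sampling is
implemented literally (interpolated duplicates), streaming over neighbours
with running accumulators so memory stays at a few image planes
(~0.4 s per 224×224 tile). Pixels within ceil(R) of the border are
excluded (valid-region policy) rather than padded — padding invents data.
The histogram is normalised to sum 1 by default (configurable); raw counts
differ only by a constant factor at fixed image size.

### Contextual block (ViT encoder)

Geometry follows ViT-Base/16: patch size 16 (196 tokens at 224×224),
embed dim 768, 12 heads, 12 pre-norm residual layers, MLP width 3072,
exact GELU, layer-norm ε=1e-6. No class token is prepended: the output is
exactly the 196 patch tokens (196×768, flattened row-major to 150,528).
Per-head projections are the d_k-column blocks of full d×d Q/K/V
matrices; softmax uses max-subtraction stabilisation. Weight source is
either a seeded scaled-normal initialisation (projection weights
N(0, 0.02²), zero biases, unit layer-norm gains) with a *fixed sinusoidal*
positional table — fully deterministic, no training required — or a
user-supplied pretrained bundle with a learned positional table. A `zero`
positional mode exists to exercise the token-permutation equivariance of
pure self-attention. Pixels are scaled to [0,1] for seeded runs.

### Fusion, split, classification

Blocks concatenate in the fixed order (deep, textural, contextual); block
offsets are recorded so any block can be sliced back bit-exactly. The
train/test split is 80/20, stratified by default (per-class allocation is
exact whenever 0.8·n_class is integral — 12,000/3,000 for 15,000 tiles
with 1,000 test tiles per class); the seed fully determines the
permutation.

Classifier defaults (the evaluation protocol does not pin
hyperparameters, so we use the common library defaults, all overridable
and recorded in the run manifest): RBF-SVM with C=1 and L2 logistic
regression, both one-vs-rest and standardised (per-feature z-score with
train statistics; zero-variance features map to 0); LightGBM (leaf-wise,
100 trees, max depth 8, deterministic single-thread mode) and XGBoost
(level-wise, 100 trees, max depth 6, hist method), unstandardised since
trees are scale-invariant.

### Evaluation

One-vs-rest counts come from the K×K confusion matrix (rows true,
columns predicted): TP = C_kk, FN = row − TP, FP = column − TP,
TN = total − TP − FN − FP. Precision, recall, F1 = 2PR/(P+R) and the
per-class one-vs-rest accuracy (TP+TN)/total follow; ratios with a zero
denominator are defined as 0 (logged convention). The multiclass headline
accuracy is trace/total. Display rounding is 4 decimals, round-half-even;
raw values are kept in machine-readable output.

A reference benchmark table for the 13 published evaluation scenarios on
the LC25000 lung subset ships in `histofuse.benchmark` as *input data* for
metric-identity checks. Note one subtlety: the table prints precision and
recall already rounded to 4 decimals, so the harmonic mean of a printed
pair can differ from the printed F1 (computed from unrounded values) by
one unit in the last digit; 36 of 39 class rows reproduce exactly and the
identity checks allow exactly that 1e-4 slack. The accuracy column is
reproduced exactly for all 13 scenarios from the per-class recalls at
1,000 test tiles per class.

## Synthetic data generator

The generator emulates the *geometry and contrast structure* of H&E lung
tiles, not their biology: a Gaussian-smoothed random background field at a
class-specific correlation length, tinted with a stain-like hue, overlaid
with a Poisson count of elliptical "nuclei" (class-specific density and
eccentricity, hematoxylin-like colour with per-nucleus jitter, alpha
blending), plus i.i.d. pixel noise, rendered at the native 768×768 size so
tiles pass through the same resize/grayscale path as real data. Defaults:
benign = sparse round nuclei on a coarse background (density 80,
eccentricity 0.05–0.30, correlation length 20 px); LACA = dense, fine
background (260, 0.25–0.55, 6 px); LSCC = densest, elongated nuclei
(420, 0.55–0.85, 12 px). Parameters are chosen for class separability,
not realism — passing tests demonstrate that the pipeline's machinery
(extraction, fusion, training, evaluation, determinism) is correct, **not**
that the method reaches any particular accuracy on real histopathology.
Real tiles differ in stain variability, tissue architecture, artefacts and
class overlap, none of which are modelled.

Per-tile seeds derive from the master seed through a splitmix64 counter
(`child_seed(master, i) < 2^31`), so generation is order-independent and
parallel-safe.

## Problem sizes used in the automated runs

The full-scale protocol (15,000 tiles, 1280+1280+150,528 features) is
exercised at the *dimension-contract* level (single-tile full-width
extraction, split arithmetic on 15,000 labels). The end-to-end benchmark
runs a reduced-width configuration chosen as a desk-scale working point:
50 tiles/class, LBP P=78 (80-d block), 2-layer ViT with d=64 (12,544-d
block), full 1280-d deep block, RBF-SVM, averaged over 3 seeds. Scenario
grids in tests use still smaller extractor widths (LBP P=8, 1-layer d=16
ViT, 32-channel backbone) on 5 tiles/class.

## Determinism

Every stochastic component is seed-driven: generator (splitmix64 child
seeds), backbone and ViT initialisation (numpy `default_rng`), split
permutation, classifier seeds (single-threaded deterministic modes for the
tree libraries). Re-running a scenario with identical seeds reproduces the
run manifest bit-identically; wall-clock timings are kept outside the
manifest's canonical JSON for that reason.

## Known limitations

* No pretrained weights are shipped; reproducing published full-scale
  accuracies requires the user to supply a fine-tuned CNN backbone and
  (plausibly) pretrained ViT weights, plus the LC25000 download.
* The LBP P=1278 configuration is honoured literally although it
  oversamples 8 physical pixels ~160-fold; whether the histogram should be
  normalised is a convention choice (we normalise).
* Whole-slide pyramids, stain normalisation and colour deconvolution are
  out of scope; inputs are single-resolution RGB tiles.
* The synthetic benchmark's perfect separability means its accuracies say
  nothing about real-data performance (see above).
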