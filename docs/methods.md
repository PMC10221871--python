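# Methods

## Problem and model

Bone age assessment estimates skeletal maturity (in months, over the range
0 < age ≤ 240) from a left-hand radiograph. Clinically it is read either by
whole-hand atlas matching or by staging specific regions of interest (carpal
bones, phalanges). This package follows the weakly-supervised formulation:
the only supervision is an image-level, often *ambiguous*, age statement from
a radiology report, and the regions that matter are discovered by the model
itself.

### Label distributions

Ages are discretised to 240 one-month bins `l_i = i` (month 0 is excluded
because the age range is open at 0). A report statement is reduced to a mean
`μ`:

* point statements ("approximately 9 years old") map to the stated age in
  months;
* interval statements ("12–13 years old", "aged between 13 and 14") map to
  the interval midpoint, which reproduces the conventional reading of
  "12–13 years" as ≈150 months.

`μ` is then encoded as a discrete Gaussian, renormalised over the 240 bins
(an implicit truncation to the label range):

    y_i = φ(l_i; μ, σ) / Σ_c φ(l_c; μ, σ).

The width σ is a single global hyperparameter (default 3 months, the value
that performs best in the σ ∈ {1,…,4} range; 2.58σ ≈ 7.7 months then matches
the typical disagreement of human raters). Interval width does **not**
modulate σ: a per-label σ was considered and rejected because the two label
kinds differ systematically in width (points ≈ ±6 months, intervals ≈ ±6
months after midpointing), so a single σ treats them uniformly and keeps the
codec a bijection given σ.

Decoding a predicted distribution to months uses the expectation
`Σ_i p_i l_i` by default — standard in label-distribution age estimation and
differentiable-friendly — with an argmax readout behind a config switch. The
truncation makes the round trip exact to <0.01 months whenever μ is at least
3σ+2 bins from either boundary.

### Weak localization (CAM)

Backbone features `F ∈ R^{H×W×K}` pass through a bias-free 1×1 convolution
to per-class activations `A ∈ R^{H×W×C}` (bias is omitted so pooling commutes
exactly with the projection); global average pooling gives class scores and a
softmax the predicted distribution. The activation channel of the predicted
(argmax) class is min–max normalised and thresholded at τ = 0.6; the tight
bounding box of the largest 8-connected component, rescaled to image pixels,
is the hand crop. Design points:

* masking uses the **predicted** argmax channel, at train and test time alike
  (the ground-truth μ's channel is an option); a `cam="soft"` mode uses the
  probability-weighted sum of channels instead;
* a constant activation channel cannot be normalised; it and an empty mask
  fall back to the full image with a warning, so training never stalls;
* boxes are 0-based half-open `[x0,x1)×[y0,y1)` with (x, y) = (column, row).

### Part proposal

The same channel, resized to a square working frame (576 px at full scale)
and contrast-stretched by `S = z(exp(η·z(A_c)))` (z = min–max), is scored
under a lattice of anchors: aspect ratios {2:3, 1:1, 3:2} × scales
{128, 160, 224, 288, 384} at a 32-px stride, all stated in the 576 frame and
rescaled proportionally at other frame sizes. Each anchor's confidence is the
mean of S inside it, computed by a summed-area table (exact). Greedy NMS
(IoU 0.25) and a top-N cut (N = 4) give the part crops, resampled to 288 px
(48 px at desk scale). Choices the formulation leaves open, fixed here:

* η = 4.0 — large enough that distant flat regions cannot outscore a peak,
  small enough to keep several distinct parts alive;
* the low IoU threshold 0.25 forces spatially distinct parts;
* a literal "anchor at every pixel" lattice (~5M anchors) is replaced by the
  32-px stride (~5k anchors); stride, η, N and the threshold are configurable;
* boundary-crossing anchors are discarded, not clipped, so a score is never a
  mean over a truncated box.

### Losses and temporal ensembling

Each branch minimises `KL(Y‖Ŷ) + ‖Y−Ŷ‖₁` (the L1 distance is summed over
bins, averaged over the batch). The raw- and hand-image branches add a
consistency term: the same KL kernel against the bias-corrected exponential
moving average of the model's own per-sample predictions across epochs,

    S_t = γ S_{t−1} + (1−γ) Ŷ_t,     Ȳ_{t+1} = S_t / (1−γᵗ),

weighted by the ramp `T(t) = T_max·exp(−5(1−t)²)` with t = epoch/ramp_length
capped at 1. The EMA targets are stored constants (no gradient flows into
them); samples whose assembled target is still the zero initialisation are
excluded from the term rather than renormalised. The part branch omits the
term — individual part crops change identity across epochs, so a per-sample
EMA is not a stable target — and its N part losses are averaged to keep the
branch on the same scale as the others. Defaults: γ = 0.6 (the canonical
temporal-ensembling momentum), T_max = 1.0, ramp_length = 80% of the epoch
budget. The KL is implemented as the standard non-negative forward divergence
`+Σ y log(y/ŷ)` with predictions clipped at 1e−12.

### Architecture and training

One backbone and one projection head are shared by all three branches
(default; a switch gives each branch its own). Crops are taken from the input
image, not differentiably from feature maps: localization is hard attention
and no gradient crosses a crop boundary. Every part crop is supervised with
the same image-level label distribution, since no part-level labels exist.
Per-sample EMA state is keyed by manifest row index.

The bundled backbone is a compact NumPy CNN — four 3×3 stride-2 convolutions
(8, 16, 24, 32 channels) each followed by instance normalisation and ReLU,
×16 downsampling — with manual backpropagation (im2col). Instance
normalisation plays the role batch normalisation plays in large backbones:
without it, the shared component of the features (two orders of magnitude
larger than the inter-image differences) dominates optimisation and the
softmax head collapses to a constant prediction. The backbone is pluggable;
a pretrained large network can be substituted through the same
forward/backward interface.

Optimisation is minibatch momentum SGD (momentum 0.9) with gradient
accumulation per batch. Full-scale defaults follow the reference setting:
576-px inputs, batch 32, lr 1e−3 decayed ×0.1 every 30 epochs. The
**desk-scale** configuration (`desk_config()`) — 96-px inputs, 48-px parts,
batch 8, 30 epochs — raises the lr to 0.3 with a 10× multiplier on the 1×1
head: a from-scratch tiny network must grow head weights large enough to
sharpen a 240-bin softmax within the budget, which the full-scale lr cannot
do without pretrained features. Model selection keeps the weights with the
best validation MAE. Batch order depends only on (seed, epoch), so a resumed
checkpoint reproduces an uninterrupted run bit for bit.

At test time the hand branch (Branch 2) alone is the output — it sees a
normalised, centred hand at full working resolution and is consistently the
most accurate branch — and the raw branch runs only to localise the hand.

## Evaluation

MAE in months, `MAE = (1/N) Σ |y − ŷ|`, plus accuracy within ±6, ±12 and
±24 months (boundaries counted as within). The accuracies are nested by
construction.

## The phantom testbed

Phantoms are schematic stand-ins for radiographs: a bright hand rectangle on
dark noise containing (i) five "phalange" bars whose length grows linearly
from 15% to 65% of the hand height over the age range — a fine-grained
signal, strong enough that a 1-D regression of age on bar length explains
>90% of age variance — and (ii) a "carpal" blob cluster gaining one blob per
24 months — a coarse stepwise signal. Report strings alternate point and
interval phrasing and always bracket the true age within 6 months. Ages are
drawn uniformly on [24, 228] months. Everything derives from a single seed
and is bit-reproducible.

What the phantoms deliberately lack: X-ray physics, anatomy, pose and
rotation variation, equipment domain shift, and the class imbalance of
clinical archives. Passing the end-to-end tests therefore shows that the
pipeline's machinery — codec, localization, proposal, losses, training loop —
is correct and can recover an age signal through the full
localise–crop–predict chain; it says nothing about accuracy on real
radiographs, which additionally requires a large pretrained backbone and
clinical data.

Experiment sizes in the test suite (200 phantoms, 96-px inputs, 30 epochs,
tiny backbone) were chosen so the whole suite runs on a single CPU in a few
minutes while leaving the recovery margin large (held-out MAE ≈ 29 months vs
≈ 59 for predicting the training mean).

## Numerical conventions and degenerate inputs

* min–max normalisation maps a constant array to all zeros (declared
  convention); a constant activation channel yields a degenerate, empty mask.
* softmax is computed with max-subtraction; KL clips predictions at 1e−12.
* bilinear resampling uses half-pixel centres with edge clamping; boxes are
  rescaled between frames by rounding outward, then clipped.
* NMS and top-N tie-breaks are stable (earlier index wins), making the whole
  proposal chain deterministic.
* the EMA's first update uses t = 1, so the bias correction never divides by
  zero; a parse failure on a manifest row skips the row (counted), and a
  manifest with no parseable labels aborts.

## Known limitations

* The NumPy backbone is CPU-sized; no GPU path, no multi-worker loading.
* The report parser is a rule-based English-pattern extractor (plus bare
  numeric labels); it is a stand-in for clinical NLP and does not handle
  free-text findings or non-English reports.
* Gender, a known covariate of skeletal maturity, is not an input.
* Anchor geometry assumes a roughly centred, upright hand; there is no
  rotation correction and no handling of multiple hands in frame.
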