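# Methods

## Problem and approach

Crop-disease classification from leaf photographs is usually run on raw
RGB. The hypothesis this package operationalizes is that the class
signal decomposes differently across color representations: chroma-heavy
cues (lesion hue, tissue saturation) concentrate in the H/S, a\*/b\*,
u\*/v\*, Cr/Cb or U/V channels of the alternative spaces, while
brightness and texture cues live in V/L\*/Y/L. The package therefore
treats the input color space as the experimental variable: identical
networks, identical splits, identical seeds, one representation per run.

## Color-space conventions

All conversions start from float RGB in [0, 1] (8-bit files are divided
by 255 at load time). The fixed definitions:

| space | definition | native ranges |
|---|---|---|
| HSV / HLS | hexcone model; hue stored as a fraction of a turn in [0, 1); hue of achromatic pixels defined as 0 | all channels [0, 1] |
| XYZ | linear sRGB (gamma decoded) through the published sRGB→XYZ matrix, D65 white | X [0, 0.9505], Y [0, 1], Z [0, 1.0888] |
| LAB / LUV | CIE 1976 from that XYZ | L\* [0, 100]; chroma bounded by the sRGB gamut extrema |
| YCrCb | ITU-R BT.601, full-range float, chroma offset +0.5 | all channels [0, 1] |
| YUV | BT.601 analog matrix, no offset | Y [0, 1], U ±0.436, V ±0.615 |

"HSL" and "HLS" name the same hexcone space; one `HLS` identifier is
exposed. The XYZ/LAB/LUV path computes its reference white as the XYZ
of RGB (1,1,1) under the same matrix, so grays are exactly achromatic
(a\* = b\* = u\* = v\* = 0) — a property the test suite asserts at 1e-5
and which mixed-convention library pipelines violate at the 1e-3 level.

Because a network should see commensurate inputs regardless of
representation, every channel is affinely mapped from its theoretical
native range (the table shipped as `channel_ranges.json`) onto [0, 1]
before entering the model, with sub-1e-6 float excursions clipped.
Normalization is deliberately non-idempotent — renormalizing an already
normalized batch is an error, not a no-op — so unit mix-ups fail loudly.

## Architecture

Defaults: 32×32×3 input, groups g = 3, 54-filter 3×3 grouped stem with
ReLU → BatchNorm → PReLU (the double activation is part of the design
being reproduced; `lead_relu=False` removes the leading ReLU for
ablation), AvgPool 2×2; N = 2 residual blocks of GroupedConv(108, 3×3)
→ BatchNorm → PReLU with skip connections (N is constrained to
multiples of 2, matching the architecture family's depth rule); head of
MaxPool 2×2, 1×1 grouped conv (108), Dense 128 → Dropout 0.5 → Dense 64
→ Dense K → softmax.

Open points resolved as package design choices:

* **Skip at a channel mismatch (54→108):** a 1×1 grouped projection
  convolution, the standard choice; `skip_mode="off"` gives the
  no-shortcut ablation.
* **Fusion of branches:** "fusion of the final layer" admits two
  readings, both provided — `concat_features` (concatenate each
  branch's 64-unit feature layer, fresh softmax head; the default) and
  `average_probs` (mean of branch softmax outputs).
* **Class count:** the head is configurable K-way (default 10). The
  source material describes the task both as binary
  (healthy/unhealthy) and as 10-class; the package does not resolve
  that contradiction, it parameterizes it.
* **Initialization:** variance-scaling fan-in normal weights, PReLU
  slopes 0.25, all drawn from a single seeded generator, so two builds
  from one config are bit-identical.

## Training backend

No deep-learning framework is used: layers, backprop and optimizers are
implemented directly in NumPy (float32, channels-last). The grouped
convolution used in training is an im2col/GEMM implementation; its
semantics are pinned by a second, naive slicing implementation
(`cropgcnn.gconv`) and the two are cross-checked to 1e-5 on random
cases, alongside central-difference gradient checks through the full
network. Training defaults — Adam, learning rate 1e-3, batch 32, 10
epochs, no augmentation, early stopping off — are conventional choices;
the underlying experiment description does not specify them. Runs are
deterministic for a fixed seed on a fixed BLAS configuration. Cross-
entropy is reported as mean nats per sample with probabilities clipped
at 1e-12; "F1" in reports is macro-F1 (unweighted mean of per-class F1,
0 for a class with neither support nor predictions), with per-class F1
and the confusion matrix alongside. The execution-time column of the
comparison table is recorded for layout parity only; it is
hardware-dependent and never asserted.

## Synthetic data: what it emulates, and what it does not

The generator emulates the imaging setup behind the public leaf
archives: a single leaf on a dark sheet, photographed in daylight, then
downsampled to 32×32. Each image is an ellipse (randomized center,
axes, rotation; ~55–60% frame coverage) filled with a class-specific
hue/saturation at base value 0.62, with per-image value jitter
(σ = 0.03) and light per-pixel noise, dotted with brown (hue 0.08)
circular lesions whose expected area fraction is the class's lesion
rate. Class identity is thus encoded partly in chroma (hue/saturation)
and partly in luminance/texture (lesion coverage) — so different color
spaces genuinely carry different class information.

Classes 0 and 1 form the default *chroma-only pair*: same saturation,
same lesion rate, hues 0.1138 and 0.4985. Those two hues are chosen
analytically so their hexcone chroma patterns have identical BT.601
luma (both 0.701 at unit saturation/value), hence the pair is invisible
to any luminance-only representation — the probe used to demonstrate
color-space sensitivity. Measured on the default set, the pair's mean
luma differs by ~0.001 while mean hue differs by ~0.18.

What the generator does *not* reproduce: real lesion morphology and
venation, specular highlights, shadows, background clutter, inter-image
illumination color shifts, and class-imbalance. Passing the synthetic
benchmarks therefore shows that the pipeline is implemented correctly
and can learn chroma- and luminance-coded classes; it does not predict
absolute accuracy on field imagery.

## Problem sizes and numerical choices

* Full-scale learning checks train the default model on 2,000 synthetic
  images (10 classes × 200) for 10 epochs; the chroma-sensitivity check
  uses 800 images for 8 epochs and compares HSV input against a
  luminance-only control (BT.601 luma replicated across the three
  channels). Success criteria are majority-of-3-seeds because
  small-sample CNN training is seed-sensitive (one seed in three may
  converge slowly at these sizes; see the variance note below).
* Unit-level training tests use a reduced configuration (16×16 input,
  6/12 filters) so each run takes seconds.
* Splits: sizes are round(n·fraction) per set with the remainder
  assigned to train (so 1,000 images give exactly 700/100/200);
  stratified per class by default; classes with fewer than 3 members
  fall back, with a warning, to pooled assignment.
* Ties and degenerate inputs: hue at zero saturation is 0; max-pool
  gradient is shared equally among tied maxima; double normalization,
  non-RGB conversion sources, out-of-range inputs, empty datasets and
  group-divisibility violations raise typed errors.

## Known limitations

* Training throughput is NumPy-bound (roughly a quarter second per
  32-image forward/backward step for the default model on one CPU
  core); the package targets 32×32-scale studies, not large-image
  production training.
* At the 500–1,000-image scale, one seed in three can remain far from
  convergence after 10 epochs at the default learning rate; the
  experiment runners keep seeds explicit so such runs are reproducible
  rather than hidden.
* LAB and LUV have no implemented inverse (nothing in the pipeline
  needs one); round-trip guarantees cover HSV, HLS, YCrCb, YUV, XYZ.
* Grouped convolutions use contiguous channel grouping with no channel
  shuffle; cross-group mixing happens only in the dense head.
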