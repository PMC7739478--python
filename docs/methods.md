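# Methods

## Problem and model

Pneumothorax (PTX) appears on a frontal chest radiograph as a subtle
peripheral lucency: pleural air with no lung markings, often overlapping
ribs and varying from a thin crescent along the chest wall to a large
region. `ptxseg` treats detection as two-class semantic segmentation
(background vs. lesion pixels) followed by a pixel-count rule for the
image-level call.

The segmentation network is an encoder–decoder fully convolutional
DenseNet. Every dense-block layer applies batch normalisation → ELU → 3×3
convolution → dropout (ρ = 0.2) and emits `k` feature maps (the growth
rate) that are concatenated onto all earlier maps, so a block with `L`
layers adds exactly `L·k` channels. Transition-down blocks (BN → ELU →
depth-preserving 1×1 convolution → dropout → 2×2 max pool) halve the
spatial size; transition-up blocks (stride-2 3×3 transposed convolution)
double it, and skip connections concatenate each encoder block's output
into the matching decoder block. A 1×1 convolution plus per-pixel softmax
closes the network.

Two optional modules extend the backbone:

* **Multi-scale stem** — three parallel same-padding convolutions with
  3×3, 5×5 and 7×7 kernels (16 filters each by default), channel-
  concatenated. Small kernels help tiny lesions, the 7×7 branch widens
  the receptive field for large ones.
* **scSE recalibration** — concurrent spatial and channel
  squeeze-and-excitation. The spatial branch projects the C channels at
  each pixel through a 1×1 convolution and a sigmoid into a per-pixel
  gate; the channel branch global-average-pools to a length-C vector,
  passes it through a C → C/2 → C bottleneck MLP (ReLU, then sigmoid) and
  gates each channel. The module output is the sum of the two gated maps,
  so all gates lie in [0, 1], the output is bounded by 2·|input|
  elementwise, and zero logits give an exact identity.

### Pinned layout and parameter accounting

The published backbone layout is pinned as the 103-layer configuration:
down-path dense blocks of [4, 5, 7, 10, 12] layers, a 15-layer
bottleneck, a mirrored up path, a 48-channel stem and growth rate k = 12.
Parameter counting treats batch-norm scale and shift as trainable (2C per
layer; running moments are not parameters) and gives every convolution a
bias. Under this accounting the backbone with a **3-channel input stem**
has exactly **5,415,278** trainable parameters; this value is unique to
that configuration in a search over input channels, batch-norm
accounting, bias placement and stem widths, which is why the package
replicates grayscale input to three channels at the stem.

With the multi-scale stem and one scSE module per dense block (encoder
blocks recalibrate their full concatenation; the bottleneck and decoder
blocks recalibrate the newly created maps, the only ones that propagate
forward there) the network has 5,978,221 parameters, a 10.4% increase
over the backbone. Per-layer scSE placement (one module on each layer's
k new maps) is selectable via `scse_placement="per_layer"`.

## Spatially weighted cross-entropy (SW-CEL)

Lesion pixels are rare and the clinically hard part is the contour, so
the loss weighs pixels per image:

* every pixel of class c weighs |N| / |T_c| (inverse class frequency;
  |N| is the image's pixel count, T_c the class-c pixel set);
* in `swcel` mode, pixels of a boundary band additionally receive
  |N| / |B_c|, where the band is the lesion contour dilated with a 3×3
  cross-shaped element (2 iterations by default) and B_c is the part of
  the band in class c — so both the lesion rim and the adjacent
  background ring get the bonus while B_c ⊂ T_c is preserved.

A lesion pixel is a contour pixel when at least one in-bounds
8-neighbour is background; out-of-bounds neighbours are ignored, so a
full-frame lesion has no contour (this also keeps image borders from
being declared boundary wholesale). Classes or bands that are empty are
skipped, never divided by. `cel` mode is plain cross-entropy, `wcel`
drops the band term. Probabilities are clamped at 1e-7 inside the log;
the training reduction is the mean over pixels (a sum is also exposed),
and weight maps are computed per image, never per batch.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999) with learning rate 1e-4 and L2 weight decay
1e-4, batch size 4, He-uniform initial weights and zero biases, up to 200
epochs with random horizontal flips (p = 0.5, applied jointly to image,
mask and weight map). The validation-set lesion Dice (DSC₁) is monitored
each epoch; training stops once it has not improved for `patience` (20)
consecutive epochs, and the best epoch's weights are restored (earliest
epoch on ties). Early stopping is load-bearing here: prolonged training
drives the boundary-weighted loss toward flagging extreme noise pixels as
lesion, which costs whole-image Dice on lesion-free images long before it
shows in the training loss.

Diagnosis: an image is called PTX when its predicted binary mask
(per-pixel argmax, exact ties to background) contains strictly more than
50 positive pixels, counted at the network's output resolution. The
binarised map, not the probability map, is counted.

## Evaluation conventions

Pixel accuracy and Dice are computed per image and class and averaged
over both (MPA, DSC); PA₁/DSC₁ restrict to the lesion class. A class
empty in the ground truth scores 1 when the prediction is also empty for
it and 0 otherwise — correctly clean lesion-free images are rewarded,
any false speck costs the whole image. The Hausdorff distance is the
symmetric max-min Euclidean distance between predicted and true contour
point sets (contours from the same 8-neighbour rule as the loss,
0-based (row, col) coordinates, pixel units); it is undefined when either
contour is empty and such images are excluded from aggregates, which are
reported as max (mean). Diagnostic metrics are the standard
confusion-matrix ratios with PTX positive, in percent; Student's
two-sample t-test on per-image Dice vectors is provided for model
comparisons.

## Synthetic phantoms

The generator emulates the structure of a two-class chest-radiograph
dataset without any download: a bright thorax ellipse (0.55) on dark
background (0.12), two dark lung fields (0.25), sinusoidal rib-like
stripes (period 9 px, amplitude 0.06), Gaussian noise (σ = 0.03), and —
on lesion-positive images (probability 0.504, matching the modelled
dataset's class share) — a crescent or ellipse of further reduced
intensity (0.07) anchored on the lung periphery, its support being the
ground-truth mask. Lesion areas are log-uniform in [60, 600] px at
64×64 (the minimum deliberately above the 50-pixel diagnosis threshold);
a bisection on the lesion radius guarantees the area lands in range.
Images are quantised to 8 bits so PNG round-trips are lossless, and all
randomness derives from one integer seed. Datasets are written with a
stratified 64/16/20 train/val/test split that preserves the class ratio
within one image per split.

The phantoms are stylised, not anatomically realistic: no projection
physics, no clavicles or devices, lesions always darker than lung with a
sharp edge. Passing the desk-scale study therefore shows that the
architecture, loss, protocol and metrics interlock correctly on a
learnable signal with confounders — not that the network reaches
clinical performance on real radiographs; the dark extra-thoracic
background is intensity-similar to pleural air, so spatial context (not
just intensity) is genuinely required, which is the failure mode the
early-stopping protocol guards.

## Desk-scale study sizes

The end-to-end check trains a reduced network (k = 4, blocks [2, 2, 2],
12-channel multi-scale stem, ~15k parameters) on 200 phantoms of 64×64
(128 train / 32 val / 40 test), batch size 8, learning rate 2e-3, at most
30 epochs with patience 8 — sizes chosen so the whole study runs in a few
minutes on one CPU while still exercising every component (multi-scale
stem, scSE, SW-CEL, early stopping, evaluation, diagnosis). The same
seeds drive an SW-CEL and a plain-CEL run for a loss-ablation contour
comparison.

A caveat the phantom study itself exposes: on these phantoms the lesion
is separable almost pixel-locally, and plain cross-entropy — whose
per-pixel weights are flat — converges to near-perfect masks, while the
boundary-weighted loss concentrates most of its mass on a few contour
pixels, increases gradient variance and promotes occasional off-lesion
speck predictions; at this scale SW-CEL therefore does not beat plain CE
on contour (Hausdorff) agreement. The advantage claimed for
boundary weighting presumes lesions whose interiors are ambiguous and
whose contours carry the discriminative signal, which stylised phantoms
do not emulate — a property of the data regime, not of the loss
implementation, and worth keeping in mind when transferring conclusions
from the desk-scale study to radiographs.

## Numerical choices

The network engine is a NumPy layer framework written for this package
(float32 forward/backward, im2col convolutions with numba-accelerated
gather/scatter and a pure-NumPy fallback, analytic batch-norm backward,
Adam with L2 decay). All layer gradients are verified against central
differences in the test suite. Batch-norm ε is 1e-5, running-stat
momentum 0.9. Inputs must be divisible by the encoder's pooling factor
(2^number of down blocks); the CLI-facing default is to reject
incompatible sizes rather than silently resize. Max-pool uses floor
semantics on odd sizes. Checkpoints store weights in `.npz` with a JSON
sidecar of the full network configuration so parameter counts are
bit-reproducible.

## Known limitations

* No GPU path; the pinned full-size network trains impractically slowly
  at realistic resolutions — the package is built for method study and
  desk-scale validation, with the full architecture instantiable for
  structural work (counts, shapes, serialization).
* Single-image weight maps assume binary masks; multi-class extension
  would need per-class contour handling.
* The Hausdorff aggregate ignores images where either contour is empty,
  so it is silent about false-positive specks on lesion-free images
  (Dice and the diagnostic metrics cover those).
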