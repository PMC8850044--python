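# Methods

## The model family

`wnetseg` implements a family of stacked two-U-Net ("W-Net") segmentation
networks for grayscale CT slices. Four paths make up the full model: B1/B2
are the contracting and expansion halves of the first U-Net, B3/B4 those of
the second. Each path has five levels; level *l* operates on feature maps of
spatial size `input / 2^(l-1)` with `base_filters * 2^(l-1)` channels, so a
256×256 input with base 64 bottoms out at 16×16×1024 (base 32 at 16×16×512).

A contracting block is `conv3×3 → act → conv3×3 → act`, followed at levels
1–4 by 2×2/stride-2 max-pooling and dropout; level 5 is the unpooled
bottleneck. An expansion block is nearest-neighbour upsampling, a 2×2
"up-convolution" that halves the channel count, a channel-wise concatenation
with its lateral inputs, then `conv3×3 → act → conv3×3 → act → dropout`.
All joins are concatenations, never additions: concatenation widens the
feature space so the following convolution can learn functions of both the
high- and low-level inputs, at the price of proportionally more parameters
(`count_parameters` makes this inspectable and strictly monotone in the
number of active bridges).

Besides the ordinary intra-U-Net skips (B1→B2, B3→B4 at equal level), three
*bridge* families connect the U-Nets:

| bridge | from → to | active in |
|---|---|---|
| B1→B4 | first encoder → second decoder | original, compound |
| B2→B3 | first decoder → second encoder | original, modified, compound |
| B2→B4 | first decoder → second decoder | modified, compound |

The **compound** variant activates all three, so every B4 block concatenates
four maps: its own up-convolved input plus the same-level B1, B2, and B3
features. The head is a 1×1 convolution (64 input channels in the base-64
model) with a sigmoid, yielding a per-pixel liver probability.

## Resolved ambiguities (design choices)

Several architectural details admit more than one reading; the package fixes
them as follows, with each choice one configuration switch away:

- **Padding.** Same-size (zero-padded) 3×3 convolutions. The stated shape
  schedule (256 → 128 → 64 → 32 → 16 with equal sizes per level) is
  arithmetically impossible with valid (unpadded) convolutions, so the shape
  schedule wins.
- **Activations.** ELU at levels 1–3, ReLU at levels 4–5, on every path
  (`relu_levels` is configurable).
- **Pooling extent.** Pooling at levels 1–4 and an unpooled level-5
  bottleneck — the only arrangement that produces the twice-stated 16×16
  bottleneck from a 256×256 input.
- **Expansion dropout.** 0.4 by default (0.45 reachable via config).
- **B3's first input.** The second encoder starts from B2's final feature
  map (64 channels at base 64), not from the raw image.
- **Up-convolution.** Nearest-neighbour ×2 upsample followed by a
  same-padded 2×2 convolution that halves the channels.
- **Output activation.** Sigmoid, required by a Dice loss on probabilities.
- **Modified bridge.** Defined as {B2→B3, B2→B4}, i.e. without B1→B4; the
  compound model adds B1→B4 back. `VariantSpec` takes an explicit bridge
  set, so any other composition is expressible.

## Loss and metrics

For truth set X and prediction set Y, `Dice = 2|X∩Y| / (|X|+|Y|)` and the
training loss is `1 − Dice`. Liver pixels are outnumbered roughly 1:15 by
background, which biases pixel-wise cross-entropy toward the background
class; the overlap-based loss sidesteps this. Training uses the smoothed
soft Dice on probabilities, `(2Σpt + s)/(Σp + Σt + s)`, with `s = 1.0` by
default (stable gradients, defined for empty masks); `s = 1e-6` reduces it
to the set formula on binary inputs within 1e-4, which the tests verify by
brute-force enumeration of 4×4 binarisations. Evaluation thresholds
probabilities at 0.5 (the threshold is a parameter) and reports per-image
Dice, averaged arithmetically over images — not over pooled voxels, which
would weight large livers more heavily; with per-slice evaluation both
conventions can disagree noticeably when slice-wise liver area varies.
When both masks are empty, Dice is defined as 1.0 and a warning is issued
rather than poisoning cohort means with NaN. IoU, precision, and recall are
reported alongside (`d = 2j/(1+j)` ties Dice to IoU and is property-tested).

## Data pipeline

DICOM series (one directory per patient, images plus expert liver masks in
the 3Dircadb1 layout) are read with pydicom, modality-rescaled, ordered by
instance number, and binarised (any positive mask label → 1). Slices
without liver are retained — no filtering. Intensities are min-max mapped
per slice onto 0–255 with *no* Hounsfield-unit windowing or histogram
equalisation, deliberately: the varying HU ranges across patients act as a
mild intensity augmentation. (Per-volume normalisation would preserve
inter-slice contrast relationships; per-slice is the default.) Images are
resized 512→256 bilinearly, masks nearest-neighbour and re-binarised.

Augmentation expands each slice by the grid of 4 flip variants (identity,
horizontal, vertical, both) × 10 rotation angles (0°–135° in 15° steps) =
40 outputs per input, carrying 2,823 slices to exactly 112,920. Only the
transform identities and the 40× total are externally fixed; the 4×10
factorisation is this package's default and any other decomposition is one
`AugmentationConfig` away. Rotation borders are zero-filled and masks
re-binarised at 0.5. Image and mask always receive the same geometric
transform, and provenance strings record the chain.

Splitting is by patient — 14 train / 4 validation / 2 test with patients 5
and 20 held out in the canonical 20-patient design — with a seeded shuffle
of the non-test patients. Slice-level split percentages are deliberately
not targeted: reference slice-level split counts for the real cohort are mutually inconsistent, whereas
the patient-level counts are unambiguous, and patient-level splitting is
the only leakage-safe choice anyway. `audit_no_leakage` re-checks before
every training run that no test patient's slice (original or augmented)
reaches the optimiser.

## Numeric backend

The forward/backward executor (`wnetseg.nn`) is written directly on numpy:
im2col/matmul convolutions with same padding (asymmetric for the even 2×2
kernel), tie-splitting max-pool gradients, inverted dropout, nearest
upsampling, and standard Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Weights are
He-initialised (fan-in scaled) from a seeded generator; dropout masks and
batch shuffles come from the same stream, so a fixed seed reproduces a
training history bit-for-bit in single-threaded numpy. Activations are
float32 and kept NHWC internally so the im2col gather runs over contiguous
channel vectors; the public interface is NCHW to match the graph's shape
annotations. Every layer's gradient is pinned by central-difference checks
in float64 (worst relative error below 1e-4 across all parameters of a
two-level model, including through active dropout with a replayed mask).

## Synthetic phantoms

Phantom slices emulate the specific difficulty of liver CT — neighbouring
organs with near-liver intensities — with one bright elliptical "liver"
(the exact mask) over 3 confounder ellipses whose intensities sit within
±10 grey levels of the liver's, on a darker background (60 vs ~140) with
Gaussian noise (σ = 8). Confounders are rendered beneath the liver, so the
mask region is unambiguous. Per patient, liver semi-axes are drawn from
0.16–0.22 / 0.09–0.13 of the frame (mean coverage ≈ 6.6%, i.e. ≈ 1:14
imbalance, mirroring the ~1:15 of real liver CT) and perturbed per slice to
mimic through-volume variation.

What phantoms do *not* model: anatomy (no organ shapes, no texture), HU
calibration, partial-volume effects, annotation noise, tumours, or
inter-slice 3-D coherence beyond smooth parameter drift. Passing the
training acceptance on phantoms therefore demonstrates that the
architecture, loss, optimiser, and protocol plumbing are correct and that
the model family can learn shape/size-based discrimination that defeats
thresholding — it says nothing about Dice levels attainable on real CT.

## Training protocols and problem sizes

The full-scale reference recipe is kept as the `TrainConfig`/`WNetSegmenter` defaults:
Adam at learning rate 1e-5, 10 epochs, batch 8, dropout 0.5/0.4, 256×256
inputs, base 64. At phantom scale those settings are not a sensible
optimisation protocol (1e-5 barely moves a small model in 10 epochs on 42
slices), so the package defines a desk-scale protocol used throughout the
tests: base 4 filters, 64×64 phantoms, learning rate 1e-3, batch 8,
dropout 0.1/0.1, smoothing 1.0. The memorisation probe (4 slices, 200
epochs, dropout 0) checks raw capacity; the generalisation check trains 40
epochs on the 14 training patients of a 20-patient × 3-slice cohort and
evaluates the 2 held-out patients, replicated over seeds {0, 1, 2} with the
median reported. Final-epoch weights are evaluated — no early stopping, no
checkpoint selection, no learning-rate schedule.

`compare_variants` reproduces the comparison-table layout (variants ×
filter schedules × {normal, augmented} test groups) on one shared split.
The "augmented" group applies the full 40× expansion to the held-out
patients' slices only, after the split — re-augmenting the full pool and
filtering afterwards would be equivalent here but is leakage-prone as an
implementation pattern, so the safe order is hard-coded.

## Known limitations

- CPU-bound numpy training: full-scale (base 64, 256×256) models are
  constructible and inspectable, and the executor runs them, but training
  at that scale is impractical without an accelerator backend.
- 2-D only: slices are independent; no 3-D context, in line with the model
  family's design.
- The DICOM reader targets the 3Dircadb1 layout (plus a PNG fixture
  layout); other series organisations need a thin adapter.
- Nearest-neighbour upsampling + 2×2 convolution is one concrete reading of
  "up-convolution"; transposed convolution is not implemented.
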