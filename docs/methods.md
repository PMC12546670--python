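# Methods

## Problem and model

Sorghum varieties destined for Baijiu brewing differ in chemistry (moisture,
starch, fat, protein — visible as NIR absorption features) and in seed
morphology (hue, shape, surface speckle — visible in microscope images).
Neither measurement alone separates all varieties reliably, so the package
fuses both: a 1-D CNN embeds each grain's mean NIR reflectance spectrum, a
2-D CNN embeds its RGB image, and a cross-modal attention block merges the
two 64-dimensional embeddings before a softmax classifier.

### Spectral branch

Input is a length-L reflectance vector (default L = 480; the 471-band
screened grid is equally supported — the convolution arithmetic adapts and
only the first fully connected layer changes size). Six conv/batch-norm/ReLU
layers with channels 1→16→32→64→128→256→512, kernels 7/7/5/5/3/3, stride 2,
padding 1 give per-layer lengths 238/117/58/28/14/7 at L = 480 and a
3584-long flattened vector, reduced 3584→256→128 by fully connected layers
and to 64 by a shared layer. Channel attention (CBAM form) is applied to
the final conv feature map: average- and max-pooled channel descriptors
pass through one shared two-layer perceptron (reduction ratio 8) and a
sigmoid; the resulting per-channel gate multiplies the map. The placement
(after the last conv layer, before flattening) and the reduction ratio are
design choices — the attention stage has no canonical position in a 1-D
stack, and r = 8 is the common CBAM default.

### Image branch

A registered 2-D backbone maps the normalized RGB input to a feature map:
`shufflenet_v2` (native implementation, 1.0× width: stem conv + max-pool,
stages of 116/232/464 channels with channel split, depthwise convolution
and channel shuffle, final 1×1 conv to 1024), `vgg16` (the 13-conv trunk;
the classifier head is omitted because the fused model's reported parameter
budget is far below a full VGG16), or `tiny` (three strided conv blocks,
64 channels out) for scaled-down experiments. A squeeze-and-excitation
block (reduction 16) rescales the final feature map channel-wise, followed
by global average pooling, a fully connected layer to 128, and the shared
layer to 64. Backbones are randomly initialized: nothing in the protocol
presumes transfer learning, and pretrained weights are deliberately not
bundled.

The "shared" 128→64 layer is one weight-tied linear map used by both
branches (an untied variant is available). Tying is the natural reading of
a layer that appears once in each branch with identical dimensions; it also
forces both embeddings into a common space before fusion.

### Cross-modal attention fusion

Both 64-d features are treated as length-64 single-channel sequences. Four
1×1 projections — realized as linear maps, which is mathematically
identical on 1×1 spatial maps — produce Q from the image feature and K, V
from the spectral feature. The attention matrix is the row-softmax of the
scaled outer product Q Kᵀ (64×64; each row sums to 1), the attended value
Z = A V re-enters through a residual connection, and batch normalization
plus leaky ReLU (slope 0.01) finish the fused feature. Two conventions
required a decision:

* **Scale.** The description of the softmax argument names the hidden
  channel count C′ = 64 both as divisor and as "the scaling factor". The
  default here is √C′ — the standard scaled-dot-product form — with the
  plain C′ divisor available as `cma_scale="dim"`.
* **Shapes.** A literal attention product between two 64×1 vectors is
  shape-inconsistent; the sequence-of-scalars contract above (A is 64×64,
  Z is length 64) is the adopted interpretation.

Without attention (the ablation axis), fusion degrades to concatenation of
the two 64-d features, a linear map back to 64, batch norm and leaky ReLU;
the branch attention blocks (CBAM, SE) are removed at the same time. The
no-attention fusion operator is unspecified in the protocol being modeled;
concatenation + linear is the plainest feature-level merge.

## Training protocol

Stratified 80/20 train/test split; stratified 5-fold cross-validation on
the training set; each fold trains with Adam (full-scale defaults: learning
rate 1e-4, 200 epochs, batch 32, cross-entropy loss — the loss is a design
choice, universal for softmax classifiers). The best fold's weights (by
validation accuracy, ties to the lowest fold index) initialize a final
model retrained on the whole training set. Monitoring the test set during
final training risks selection leakage, so two modes exist: the default
records per-epoch test accuracy but always keeps the final-epoch model;
`honest=True` touches the test set exactly once at the end. Metrics:
accuracy, macro-averaged precision and recall (the averaging convention is
a choice; macro weights all 12 classes equally), per-class F1, and a
confusion matrix in counts and row percentages. Batch size 32 is a default,
not a protocol constant.

## Synthetic data

The generators stand in for unavailable instrument data; their defaults are
the study design they emulate.

* **Spectra** — 12 classes × 300 samples, 512 bands on 886–1735.34 nm.
  Each class prototype is a smooth baseline (level 0.55 plus a gentle
  half-sine) minus Gaussian dips (σ = 15 nm) at 920/980/1030/1130/1230/
  1480 nm; per-class dip depths rescale a fixed template with Dirichlet
  weights so classes share the overall trend but differ regionally. I.i.d.
  noise (sd 0.01 reflectance) is added everywhere, inflated tenfold on the
  first 9 and last 32 bands — the regions the band screen removes.
* **Images** — one elliptical grain per frame on a textured, non-black
  background; hue, aspect ratio and speckle density are class parameters;
  dark-spot defects appear with a configurable probability (grains with
  spots and cracks are deliberately kept, as a real protocol would keep
  them).
* **Hypercubes** — 5×5 grain disks with ±2 px placement jitter (configs
  whose jitter could make grains touch are rejected), plus optional specks
  below the 80 px area threshold. Reflectance is scaled into raw intensity
  as `raw = dark + R·(white − dark)` against per-column line-scan reference
  frames, so black/white correction inverts the construction exactly on
  noiseless data. Grain and background levels are chosen so the fixed
  thresholds (70 and 25 on the 0–250 scale) segment correctly by
  construction.
* **Complementary multimodal design** — for fusion experiments, class
  identity is split across modalities: spectra follow `label // 2` (six
  spectral prototypes), images follow `label % 2` (two visual prototypes).
  The information-theoretic ceilings are then 1/2 for a spectral-only
  model, 1/6 for an image-only model, and 1 for any model that fuses both —
  which is what makes the fusion-advantage ordering a property of a correct
  build rather than of lucky tuning.

What the generators do **not** model: scatter and continuum effects,
instrument line-scan geometry, correlated (non-i.i.d.) spectral noise,
photorealistic seed appearance, touching grains. Passing tests therefore
demonstrate that the pipeline's mechanics are correct and that fusion
recovers split information; they do not predict accuracy on real seeds.

## Scaled-down study conditions

The ablation study used by the tests and described in the README runs at
12 classes × 30 samples, tiny backbone at 32×32 input, 15 epochs, batch 32,
Adam at 1e-3, five seeds, medians reported. The raised learning rate is the
appropriate choice for a 135-step budget (the 1e-4 default pairs with 200
epochs at full scale). Problem sizes were fixed before running the study
and are the package's chosen desk-scale conditions.

## Numerical and implementation notes

* The network stack is a numpy reverse-mode autodiff core (convolutions
  lowered to im2col + GEMM; depthwise convolution vectorized per channel).
  Every layer family is checked against central finite differences at
  float64 in the test suite.
* Conv/BN ordering within a block is conv → batch norm → ReLU (the
  textbook order; the source protocol states only that both follow each
  convolution).
* Batch norm: momentum 0.1, eps 1e-5; running statistics used in eval mode.
* Correction guards: epsilon 1e-8 in the denominator; negative reflectance
  clipped to 0 and counted; values above 1 kept (specular pixels carry
  masking information); a band whose white and dark frames coincide
  everywhere is a hard error; white < dark pixels are counted, not fatal.
* Nearest-band lookup breaks ties toward the lower index.
* ROI row grouping sorts centroid Y and splits at the n_rows−1 largest
  gaps — deterministic and robust to a few pixels of jitter. Labeling is
  8-connected; the morphology kernel is a 3×3 ellipse. The fine
  segmentation step applies the fixed 25/250 threshold by default
  (reproducible); an Otsu mode computes the threshold from the candidate
  region instead. The score plane fed to thresholding is the 954.15 nm
  band by default (configurable window) — which plane the original
  workflow binarized is unstated.
* GrabCut: five iterations of full-covariance 5-component Gaussian
  mixtures (fixed random state, so the segmentation is deterministic) and
  an 8-connected min-cut with contrast-sensitive edge weights
  (γ = 50, β = 1/(2·mean‖Δz‖²)); pixels outside the initialization
  rectangle (default: bounds shrunk 5 % per side) are held as background.
* Image normalization defaults to the ImageNet channel statistics
  (configurable) — the backbones are ImageNet-era designs.
* Parameter accounting: count = all unique trainable tensors (weight-tied
  layers counted once); size = count × 4 bytes in MiB to two decimals.
  Exact parameter totals of the original fused models are not reproducible
  from their description (attention insertion points and backbone width are
  underdetermined); the count↔size relation is the verifiable surface, and
  the package's own counts satisfy it by construction.

## Known limitations

* Pure-numpy training is practical at desk scale only; the full-scale
  protocol (3600 samples, 224×224 ShuffleNetV2, 200-epoch folds) is
  supported by the same code but is not exercised in the test suite.
* `mobilenet_v3` and `ghostnet` are admitted by the backbone registry
  interface but not implemented; unknown names raise with the registry
  listing.
* The ENVI reader parses only the dialect the package writes (BSQ,
  float32, wavelength block).
* GrabCut assumes one grain per frame, matching the acquisition protocol
  it models.
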