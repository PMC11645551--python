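# Methods

## The problem and the model

Sequencing-based spatial transcriptomics (Visium-style) measures gene
expression in circular capture spots of 55 µm diameter at 100 µm pitch; each
spot mixes roughly 5–30 cells and the gaps between spots are unobserved.
`supergrid` infers expression on a dense grid of 8 × 8 µm *superpixels* —
approximately single-cell scale — across the entire tissue, including regions
never covered by a spot.

The model couples three per-superpixel information sources into one
multimodal feature vector `h ∈ R^C`:

* **histology features** (F channels): the H&E image, rescaled to 0.5 µm/px,
  is cut into 224 × 224 tiles and a backbone maps each tile to a 14 × 14 grid
  of patch features — one 16 × 16 px patch per superpixel;
* **position** (2 channels): normalized row/column coordinates
  `α·i/n_rows`, `α·j/n_cols` (α = 1), letting the network separate regions
  with similar morphology but different expression;
* **RGB** (3 channels): 16 × 16 average-pooled image intensities in [0, 1].

So C = F + 5 (1029 with a production pathology backbone of F = 1024; 37 with
the shipped fallback at F = 32).

For each spot, the D × D block of superpixels spanned by the spot diameter
(D = round(55/8) = 7 at the defaults) forms a graph: superpixels are nodes,
each connected to its four nearest neighbours by physical distance (the
von Neumann grid neighbourhood). All spots share this topology, so one
normalized operator `Â = D̃^{-1/2}(A + I)D̃^{-1/2}` is cached and reused. Two
graph convolutions with ReLU produce a 512-dimensional representation per
superpixel, and a linear head with `ELU(x) + 1` output yields strictly
positive predicted expression `Z ∈ R^{D²×K}` for K genes:

    H1 = ReLU(Â X W0),  H2 = ReLU(Â H1 W1),  Z = ELU(H2 W2 + b) + 1.

**Weak supervision.** No superpixel-level labels exist. Training instead
constrains sums: the predicted expression summed over the superpixels whose
centers fall inside a spot's 27.5 µm disc (the *circular filter*) must match
the observed spot vector `g_j`:

    Loss = Σ_j || g_j − Σ_{n ∈ disc(j)} Z_jn ||².

The loss is a plain squared sum over spots and genes; spot expression stays
on the linear count scale throughout, because the sum constraint is only
meaningful there. Log transforms are applied downstream for metrics and
clustering only. Superpixels outside every spot disc contribute to the GCN
input (full D × D block) but not to the loss; regions covered by no spot are
simply unsupervised.

**Inference.** The whole feature map is zero-padded to multiples of D, cut
into non-overlapping D × D tiles, each tile predicted with the same graph and
weights, reassembled in place, cropped, and zeroed outside the detected
tissue mask. Overlapping-tile averaging is deliberately not implemented: the
tiled scheme is the model's own definition of whole-slide inference.
Transfer inference — predicting a second section from its histology alone —
is the same call with a different feature map.

## Backbones

Any extractor satisfying the contract (224 px tile → 14 × 14 × F features,
deterministic) plugs in; production use is a pretrained pathology vision
transformer. The shipped `FallbackBackbone` is a training-free extractor:
per-patch channel means and standard deviations plus an 8-bin gradient-
magnitude histogram, expanded to F channels by a fixed seeded random
projection. It is strictly patch-local and deterministic, which the test
suite exploits (locality and alignment assertions). It is *not* a learned
representation: it resolves color and simple texture, not nuclear morphology,
so absolute prediction quality with it reflects the fallback, not the
architecture's ceiling.

Histology channels are standardized (zero mean, unit variance over masked
superpixels) before stacking so the F ≫ 5 histology block does not drown the
positional/RGB channels; a switch disables this.

## Numerical and implementation choices

* The network, backpropagation and Adam are implemented directly in numpy —
  at D² = 49 nodes and 512 hidden units, dense matmuls are fast, exactly
  reproducible, and dependency-light. Gradients are verified against finite
  differences, the forward pass against an independently coded dense oracle.
* Adjacency normalization: symmetric with self-loops (default); row-
  normalized and raw modes are available (`normalization="row"/"none"`).
  The raw mode reproduces the plain `A·H·W` formulation.
* Non-negativity: ELU alone maps to (−1, ∞); the output is `ELU(x) + 1`,
  smooth and strictly positive.
* D rounding: round-half-up of diameter/superpixel (55/8 → 7, 100/8 → 13).
* Patch centering: block top-left = center superpixel − ⌊D/2⌋; border blocks
  are zero-padded, padded nodes stay in the graph but never enter the filter.
* Optimizer defaults: Adam, lr 2e-3, batch 32 spots, 500 epochs, early stop
  after 50 epochs without a new best epoch loss, seed 0. The rate was chosen
  by sweeping on the synthetic benchmark: the squared-sum loss converges
  slowly, in relative terms, on low-count boundary spots, and 1e-4-scale
  rates leave their sum constraints ~10% off after 500 epochs; 2e-3 reaches
  a ~4% median relative sum error, while 3e-3 destabilizes late training.
  Floats are 32-bit in training; two runs with one seed are bitwise equal.
* Training requires ≥ 2 spots and aborts with a diagnostic on non-finite
  loss.

## Geometry conventions

Physical units are µm; origin at the top-left of the rescaled image, x
rightward, y downward. Superpixel (m, n) = (row, col), 0-based, covers the
half-open square [8m, 8m+8) × [8n, 8n+8). Spot membership rules: a *cell*
belongs to a spot when its centroid lies in the disc (all-or-nothing; the
area-weighted split is the cell→superpixel partition's job); a *superpixel*
belongs when its center lies in the disc. Cell footprints default to
axis-aligned squares of the recorded area centered on the centroid, making
footprint ∩ superpixel overlap areas exact in closed form.

Hex spot layouts place rows at pitch·√3/2 spacing with alternate rows offset
by pitch/2, keeping all nearest-neighbour distances exactly at the pitch;
the lattice is centered in the bounding box and no disc crosses the box
edge. Highly-variable-gene selection ranks genes by the variance of
library-size-normalized log1p counts with lexicographic tie-breaks.

## Evaluation protocol

Per gene, both predicted and true 2-D maps are min–max normalized over the
tissue mask before scoring (RMSE, MAE, Pearson r, and SSIM with an 11 × 11
Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03, data range 1). Constant maps
are flagged and excluded from the median/mean summaries. Spot-only datasets
are scored by summing predicted superpixels under each observed spot disc
and comparing spot vectors (no SSIM in 1-D). Marker-panel scoring (e.g.
tertiary lymphoid structures) averages min–max-normalized marker maps.
Tissue segmentation runs k-means (k-means++, 10 restarts, fixed seed) on the
512-dimensional second-layer GCN activations, with labels ordered by
descending cluster size for determinism.

The tissue mask is Otsu's threshold on the pooled grayscale image (keeping
the dark class — stained tissue on a white background), a 3 × 3 morphological
closing, and removal of components below 0.1% of the grid area; padded
border superpixels are forced to background.

## The synthetic benchmark

Real pipelines for this problem consume multi-GB Xenium / Visium HD / Visium
downloads and a pretrained backbone. The shipped generator instead builds a
fully seeded, desk-scale world in which the method's core assumption — that
histology is informative of expression — holds by construction:

* a few latent spatial programs (Gaussian blob, stripe, gradient, ring),
  smooth and normalized;
* gene means = Dirichlet loadings × log-normal gene depths × programs,
  observed through Poisson sampling (or truncated Gaussian noise), masked to
  the ellipse inscribed in the grid;
* pseudo-histology: each program absorbs light in a distinct base color over
  a baseline stain haze, per-superpixel colors upsampled 16× with seeded
  texture noise — so patch-mean color linearly encodes the programs (a
  linear probe from pooled features reaches R² ≥ 0.5 on defaults, asserted
  in tests);
* an optional cell table (seeded point process inside the mask, expression
  proportional to the local truth) emulating imaging-based single-cell ST
  exports;
* pseudo-Visium spots: in-disc sums of the truth under a hex layout
  (55 µm / 100 µm), so the weak-supervision constraint has an exact known
  solution.

Default conditions: 96 × 96 superpixels (768 × 768 µm), 25 genes, 3 programs,
~68 spots, F = 32 fallback features. A full train → infer → evaluate run
takes a few minutes on one CPU.

**What passing these tests does and does not show.** The benchmark
establishes that the implementation is correct (oracle equivalence), that the
weak-supervision optimization satisfies its sum constraints, and that the
architecture recovers sub-spot structure far better than uniform in-disc
disaggregation when features are informative. It does not certify real-data
accuracy: pseudo-histology lacks nuclear morphology, stain variation and
segmentation artifacts; the fallback backbone is far weaker than a
pretrained pathology transformer; and per-superpixel Poisson noise at
single-cell depth caps attainable per-gene correlation and SSIM against the
noisy ground truth well below 1 — absolute metric values on the benchmark
are not comparable to values reported on real Visium HD or Xenium data.

## Known limitations

* No stain normalization or multi-resolution (hierarchical) feature
  extraction; the backbone contract is single-scale.
* One section at a time; transfer inference is supported, but there is no
  multi-section joint training or domain adaptation.
* The depth-normalization of spot counts before training is exposed as a
  choice but defaults to off; heavily depth-skewed real data may need it.
* k-means segmentation quality depends entirely on the learned features; it
  is a readout, not a spatial-clustering method.
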