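# supergrid

Super-resolution spatial gene expression from spot-based spatial
transcriptomics, histology and location, via a weakly supervised graph
convolutional network — plus the pseudo-Visium benchmark machinery needed to
validate such predictions.

## The problem

Sequencing-based spatial transcriptomics (10x Visium and kin) measures gene
expression in circular capture spots 55 µm across at 100 µm pitch. Each spot
mixes 5–30 cells, and the space between spots is unmeasured. Imaging-based
platforms (Xenium) and Visium HD resolve single cells or 8 µm bins but trade
off gene throughput or availability. `supergrid` is for researchers who have
spot-level data plus the H&E image and want expression on a dense 8 × 8 µm
*superpixel* grid — approximately single-cell scale — across the whole
tissue, including regions no spot ever covered.

## The model

Each superpixel gets a multimodal descriptor `h ∈ R^C`: F histology-backbone
features from its 16 × 16 px image patch, 2 normalized position channels
(`α·i/n_rows`, `α·j/n_cols`), and 3 pooled RGB channels (C = F + 5). The
D × D block of superpixels under each spot (D = round(55/8) = 7) is a graph
with 4-nearest-neighbour grid edges and a shared normalized adjacency
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}`. The network

    H1 = ReLU(Â X W0)        # C -> 512
    H2 = ReLU(Â H1 W1)       # 512 -> 512
    Z  = ELU(H2 W2 + b) + 1  # 512 -> K genes, strictly positive

is trained with *weak supervision*: no superpixel labels exist, so the
predicted expression summed over the superpixels inside each spot's disc must
match the observed spot vector,

    Loss(Θ) = Σ_j ‖ g_j − Σ_{n ∈ disc(j)} Z_jn ‖².

After training, the whole feature map is tiled into D × D blocks and
predicted with the same graph, giving the full superpixel expression field,
masked to the detected tissue contour. See `docs/methods.md` for assumptions,
parameter choices and limitations.

The package also implements the benchmark protocol for validating any such
method: partition single-cell-resolution data (cell tables or gapless bins)
onto the superpixel grid, aggregate it into pseudo-Visium spots under a hex
layout, train on the pseudo-spots only, and score predictions gene by gene
(RMSE / SSIM / PCC / MAE on min–max-normalized maps) against the withheld
single-cell-resolution truth — plus spot-level re-aggregation scoring for
spot-only datasets, marker-panel (TLS) scoring, and k-means tissue
segmentation on the learned 512-dimensional GCN features.

## Worked example

```python
import numpy as np
import supergrid as sg

# 1. a fully seeded benchmark: truth field, pseudo-histology, pseudo-Visium spots
bench = sg.make_benchmark(sg.SyntheticConfig(seed=0))
print(f"{bench.spots.counts.shape[0]} spots, {bench.truth.n_genes} genes, "
      f"grid {bench.truth.grid.shape}")

# 2. multimodal feature map (fallback backbone, F=32 -> C=37 channels)
fmap = sg.build_feature_map(bench.image, 0.5, sg.FallbackBackbone(32, seed=0))
print("feature map:", fmap.channels.shape)

# 3. fit the weakly supervised GCN
model = sg.SuperResolutionGCN(fmap, bench.spots)
res = model.fit()
print(res.summary())

# 4. infer the superpixel field and score it against the known truth,
#    next to the naive baseline that spreads each spot evenly over its disc
pred = res.predict()
metrics = sg.evaluate_highres(pred, bench.truth)
print("median gene-wise RMSE:", round(metrics.summary["median_rmse"], 3))

baseline = sg.uniform_disaggregation(bench.spots, bench.truth.grid)
mask = pred.mask & bench.truth.mask
def median_r(hr):
    rs = [np.corrcoef(hr.values[:, :, k][mask],
                      bench.truth.values[:, :, k][mask])[0, 1]
          for k in range(bench.truth.n_genes)]
    return float(np.median(rs))
print("median gene-wise PCC, model:   ", round(median_r(pred), 3))
print("median gene-wise PCC, baseline:", round(median_r(baseline), 3))
```

Output (seed 0, ~3 minutes on one CPU):

```
68 spots, 25 genes, grid (96, 96)
feature map: (37, 96, 96)
Super-resolution GCN results
==============================================
spots (training patches)      68
genes                         25
input channels                37
patch span D                  7 (49 nodes)
hidden dimension              512
adjacency normalization       sym
epochs run                    500
initial epoch loss            901917
final epoch loss              3486.03
median spot-sum rel. error    0.0438
median gene-wise RMSE: 0.287
median gene-wise PCC, model:    0.393
median gene-wise PCC, baseline: 0.123
```

Reading the numbers: the training loss drops by ~250× and the fitted model
reproduces each spot's observed expression from its in-disc superpixel sums
to a 4.4% median relative error — the weak-supervision constraint is
essentially satisfied. Against the withheld single-cell-scale truth, the
inferred field reaches a median gene-wise Pearson r of 0.39 versus 0.12 for
the naive baseline that spreads each spot evenly over its disc. Absolute
values are capped by the benchmark's per-superpixel Poisson noise and the
deliberately simple fallback backbone (see `docs/methods.md`); the margin
over the baseline is the meaningful readout.

## Command line

```bash
supergrid synth     --out bench --seed 0                  # synthetic benchmark
supergrid simulate  --bins bench/truth.h5 --layout hex --out sim
supergrid featurize --image bench/image.png --pixel-size 0.5 \
                    --backbone fallback:32 --out fm.h5
supergrid train     --features fm.h5 --spots bench --out model.npz
supergrid infer     --features fm.h5 --model model.npz --out pred.h5
supergrid evaluate  --pred pred.h5 --truth bench/truth.h5 --out metrics.csv
```

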