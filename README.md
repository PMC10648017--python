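# forestseg

Automatic pixel-label generation and downscaled U-Net models for forest
semantic segmentation of 4-band (RGBN) aerial imagery.

Training a segmentation network normally requires per-pixel labels that a
human operator has to draw. `forestseg` implements a fully unsupervised
alternative for forest mapping: it clusters the 4-band pixel distribution
of aerial images with a Gaussian mixture model, turns the clusters into
forest/no-forest masks, keeps only the most reliably clustered images, and
uses those masks as training labels for a family of U-Net models whose
width can be scaled down ~1000× in parameter count with modest accuracy
loss. Because the source imagery such a workflow runs on is typically
proprietary, the package also ships a synthetic scene generator with known
ground truth so the whole pipeline is runnable and testable end to end.

## The method

**Labeling.** For an image with pixels x ∈ ℝ⁴ (R, G, B, NIR digital
levels), fit Gaussian mixtures with K = 2…10 components by EM and score
each fit with the information criteria

    AIC = 2k − 2 ln L        BIC = k ln N − 2 ln L

where ln L is the mixture log-likelihood, N the number of pixels, and
k the number of free parameters (for K full-covariance components in 4
dimensions, k = (K−1) + 4K + 10K). The component count is chosen at the
elbow of the criterion curve — the K where its decrease slows most
sharply. Clusters are then merged into a single forest class: the seed is
the component with the highest NIR mean (lit canopy — healthy dense
vegetation is NIR-bright), and any component that is both spatially
interleaved with the seed and darker in visible luminance is merged into
it, capturing the cast-shadow cluster produced by tree-height relief. The
binary mask is cleaned with a median filter and a morphological closing
(square kernels), which removes speckle and fills small withered-tree
voids. Images are ranked by the Davies–Bouldin index

    DB = (1/N) Σᵢ maxⱼ≠ᵢ (σᵢ + σⱼ) / d(cᵢ, cⱼ)

(lower = tighter, better-separated clusters) and only the best-ranked
images become training labels.

**Segmentation.** The U-Net family is parameterized by its first-encoder
width b: encoder widths (b, 2b, 4b, 8b), a 16b bridge, decoder widths
(8b, 4b, 2b, b); two 3×3 same-padded convolutions per block, 2×2
max-pooling, 2×2 transposed-convolution upsampling that halves channels,
concatenation skip connections, dropout after the encoding path, and a
1×1 sigmoid output trained with binary cross-entropy and Adam
(β₁ = 0.9, β₂ = 0.999). Six standard scenarios halve b from 64 down
to 2. `count_parameters` derives an exact per-layer ledger; building a
model asserts its actual parameter count equals the ledger. The network
engine is a compact NumPy implementation (im2col convolutions with
explicit backprop) — deterministic under a seed and sized for the tile
datasets this package produces.

## Worked example

Ledger accounting for three scenarios (no training involved):

```
$ forestseg report --no-train --scenarios 1,4,6 --out rep
scenario,total_kernels,trainable_parameters
1,6848,31032321
4,856,485889
6,214,30585
```

Scenario 1 is the full-width network (b = 64, ~31.0 M parameters);
scenario 4 (b = 8) has 64× fewer parameters and scenario 6 (b = 2) about
1000× fewer — the point of the family is that these remain usable.

Label four synthetic 160×160 scenes:

```
$ forestseg label --config demo.yaml --seed 1 --out lab
selected K=4, merged components [2, 3], mean ground-truth agreement 0.9975
```

The criterion scan behind that selection (`lab/criterion_scan.csv`):

```
K,logL,k,AIC,BIC
2,-213911.863624,29,427881.727247,428096.114443
3,-200609.660176,44,401307.320353,401632.597478
4,-193308.338145,59,386734.676290,387170.843343
...
```

The elbow lands at K = 4: the scene's pixel distribution has four
effective modes (lit canopy, shadow, vegetation, built/bare ground), the
curve drops steeply up to K = 4 and flattens after. Components 2 and 3
were merged — the NIR-brightest component plus the dark interleaved
shadow component — and the resulting masks agree with the generator's
ground truth on 99.75% of pixels.

Other subcommands: `synth` (one scene with ground truth), `tile`
(rank, select, and tile labeled images), `train` (full pipeline through
training, JSON report), `sweep` (learning-rate comparison), `evaluate`
(saved model on a patch array).

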