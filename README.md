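# taxofeat

Automatic species identification from single-specimen photographs —
fish, leaves, butterflies, or anything else photographed against a roughly
uniform background.

Expert taxonomists are scarce; large museum collections and field surveys
need a way to assign specimens to species without one. `taxofeat`
implements a classical morphometric pipeline: each photograph is reduced to
a fixed vector of 15 shape, texture and moment descriptors, and a small
neural network learns to map those descriptors to species labels from a
set of expert-identified training images.

## The pipeline

**Preprocessing** (`taxofeat.imaging`) turns a raw photograph into the
rasters the descriptors need: background removal (rectangle-initialised
background-statistics segmentation, or a supplied mask), luminance
grayscale, 3×3 mean + 3×3 median filtering, Otsu binarization, boundary
extraction and Zhang–Suen skeletonization.

**Features** (`geometry`, `texture`, `moments`, assembled by `features`)
— the fixed-order 15-vector:

| group | features |
|---|---|
| geometric | area *A*, perimeter *P* (boundary-pixel count), equivalent diameter *D* = √(4A/π), compatibility *C* = 4πA/P², compactness *Co* = P²/4πA, solidity *S* = A / hull area |
| texture | histogram mean μ = Σx·h(x) and variance δ² = Σ(x−μ)²h(x); from the gray-level co-occurrence matrix P(x,y) at offset (r=1, θ=−45°): uniformity ΣP², entropy −ΣP ln P, homogeneity ΣP/(1+\|x−y\|), inertia ΣP(x−y)² |
| moments | first Hu invariant φ₁ = η₂₀+η₀₂; affine invariants I₁ = (μ₂₀μ₀₂−μ₁₁²)/μ₀₀⁴ and I₂ = (μ₃₀²μ₀₃² − 6μ₃₀μ₂₁μ₁₂μ₀₃ + 4μ₃₀μ₁₂³ + 4μ₂₁³μ₀₃ − 3μ₂₁²μ₁₂²)/μ₀₀¹⁰ |

All 15 are translation invariant; the moment invariants are additionally
rotation-, scale- (φ₁) and affine-invariant (I₁, I₂).

**Classifier** (`ann`) — a from-scratch one-hidden-layer sigmoid
perceptron, 15 → *h* → *m* (one output per species),

y = φ(Σᵢ wᵢxᵢ + b),  φ(x) = 1/(1+e⁻ˣ),

trained by online backpropagation: stochastic gradient descent on squared
error, one weight update per pattern presentation ("generation"), inputs
z-scored with the training-set statistics. The winning species is the
argmax output; the 0.5-thresholded binary output vector is also reported.

**Evaluation** (`evaluation`) — stratified 60/40–90/10 train/test splits,
success rate = % of test specimens identified correctly, confusion
matrices, and a success-rate-vs-hidden-neurons sweep.

**Synthetic benchmark** (`synthetic`) — a generator of labeled "species"
image sets (Fourier-perturbed ellipse silhouettes with striped noisy
texture, jittered per individual), with controllable inter-species
separation down to near-identical congener pairs.

## Worked example

```python
import taxofeat as tf

specs = tf.default_specs(4)                      # 4 synthetic species
ds = tf.generate_dataset(specs, 20, seed=42)     # 20 individuals each
table = tf.feature_table([tf.extract_features(im) for im in ds.images],
                         ds.labels)
print(table.head(3).round(4).to_string())

train, test = tf.stratified_split(table, 0.8, seed=0)
model = tf.train(train, tf.TrainConfig(learning_rate=0.1,
                                       generations=20000, hidden=20, seed=0))
rate, confusion = tf.success_rate(model, test)
print(f"test success rate: {rate:.1f}%")
print(confusion)
```

prints

```
       A      P        D       C      Co       S        u       d2       E       H      HG        I    phi1      I1   I2 species
0  595.0  114.0  27.5241  0.5753  1.7381  1.0000  66.5748  79.1889  0.1377  2.6582  0.7125  11.0507  0.1930  0.0064 -0.0    sp00
1  618.0  122.0  28.0511  0.5218  1.9166  0.9968  57.6864  59.7857  0.1375  2.8391  0.7114   6.9421  0.1953  0.0064 -0.0    sp00
2  587.0  109.0  27.3385  0.6209  1.6107  0.9983  61.4514  67.6546  0.1393  2.7602  0.6878   9.9009  0.1862  0.0064 -0.0    sp00
test success rate: 100.0%
      sp00  sp01  sp02  sp03
sp00     4     0     0     0
sp01     0     4     0     0
sp02     0     0     4     0
sp03     0     0     0     4
```

Each row is one specimen: ~600 px of area, solidity ≈ 1 (smooth convex-ish
silhouettes), mean interior gray ≈ 60–67, and moment invariants that vary
with silhouette shape. The four species are cleanly separated, so the
16 held-out specimens are all identified correctly.

The same workflow is available from the shell:

```sh
taxofeat simulate --species 10 --n 30 --seed 1 --out data/
taxofeat extract data/ --out features.csv
taxofeat train features.csv --hidden 60 --lr 0.1 --generations 50000 --seed 1 --out model.tfm
taxofeat predict model.tfm data/sp00/img_000.png
taxofeat evaluate features.csv --splits 0.6,0.7,0.8,0.9 --repeats 3 --out report/
taxofeat sweep features.csv --hidden 5:65:10 --out sweep/
```

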