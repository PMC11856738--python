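# mcmunet

Segmentation of the prostate on T2-weighted MRI is hard exactly where it
matters: the organ's boundary against surrounding soft tissue is faint, and
the apex and base (the first and last slices the gland occupies) are
inherently blurry. `mcmunet` implements a U-Net-style segmenter, **MCM-UNet**,
that attacks both problems with two additions to an nnU-Net-style 2D
encoder–decoder backbone:

* a **context-modeling (CM) block** at each decoder skip connection. With
  per-scale class probabilities `D` (from the deep-supervision head) and
  stage features `f_sf ∈ R^{HW×C}`, it forms per-class region
  representations `R_l = Σ_i Nor(D_l)_i · f_sf,i`, redistributes them per
  position into `f_seg = Σ_l Nor(D)_l · R_l`, computes attention
  `W = softmax(f_sf f_segᵀ / C)` (rows sum to 1), aggregates
  `R_sf = W f_sf`, and merges `R_sf` back into the decoder by channel
  concatenation + 1×1 compression;
* a **first-in-first-out feature memory bank** at the deepest features. A
  fixed-capacity queue stores dataset-level feature maps `f_dl`; the three
  entries most cosine-similar to the current features are fused,
  `f_dl' = δ(f_dl,m ⊕ f_dl,n ⊕ f_dl,h ⊕ f_sf)`, with `δ` a learned 1×1
  channel compression. Each training batch pushes the fused result
  (detached) and evicts the oldest entry once the bank is full.

Around the network, the package ships everything needed to exercise it end
to end without patient data: gzipped-NIfTI volume I/O and the preprocessing
chain (resampling to [0.66 × 0.66 × 5] mm, Z-score normalization, 2D
slicing / 3D patching), the batch-averaged Dice + cross-entropy objective
with deep supervision, the SGD/Nesterov schedule with poly learning-rate
decay `(1 − epoch/epoch_max)^0.9`, the evaluation metrics
(ASSD, HD95, Jaccard, DSC, inter-annotator correlation), and a **synthetic
phantom generator** producing bright ellipsoidal organs whose boundary blur
is strongest at the apex/base analogue slices.

The network runs on a small NumPy reverse-mode autodiff engine built into
the package (`mcmunet.nn`), so training and inference need only the
scientific Python stack — no GPU framework.

## Worked example

```bash
python examples/05_train_and_evaluate.py
```

trains a small model on ten 32×32 synthetic phantoms (about a minute on one
CPU) and prints:

```
epoch    7  lr 0.00154  loss -0.7305  val DSC 96.37%

per-case metrics on held-out phantoms:
 case_id  assd_voxel  hd95_voxel  jaccard_pct   dsc_pct
case_008    0.083617         1.0    93.310463 96.539485
case_009    0.092342         1.0    92.727273 96.226415

mean DSC  96.38%  mean ASSD 0.088 voxels
```

A DSC near 100% and an ASSD below 0.1 voxels mean the predicted organ
almost coincides with the clean ellipsoid ground truth; HD95 of 1 voxel
says even the worst boundary disagreements are a single voxel. The other
`examples/` scripts walk through the phantom generator, the metrics, the CM
attention chain, and the memory bank individually.

A thin CLI mirrors the library:

```bash
mcmunet synth --n-cases 40 --seed 1 --out data/
mcmunet train --config cfg.yaml --data data/ --out run/
mcmunet predict --checkpoint run/checkpoint.npz --in data/case_000_img.nii.gz --out pred.nii.gz
mcmunet evaluate --pred preds/ --gt gts/ --out report.csv
mcmunet ablate --config cfg.yaml --data data/ --out ablation.csv
```

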