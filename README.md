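# lesionbow

Content-based retrieval of focal liver lesions in triple-phase
contrast-enhanced CT.

Radiologists tell hepatocellular carcinoma (HCC), hemangiomas and cysts
apart largely by how a lesion's density evolves relative to the
surrounding liver parenchyma across the arterial (AP), portal venous
(PVP) and delayed (DP) phases: HCC is "fast in and fast out"
(hyper-dense in AP, hypo-dense afterwards), hemangiomas enhance at the
rim and fill in centripetally, cysts stay uniformly dark. `lesionbow`
implements a retrieval system whose features are built to capture
exactly that spatio-temporal structure, so that querying with a new
patient returns database patients with similar lesions.

## Method

1. **Lesion partitioning.** The binary lesion mask undergoes a
   city-block distance transform (integer layers 1..L from the boundary
   inward). With `p = L // s` and `q = L mod s`, the layers are grouped
   into `s` concentric regions — `s-1` outer regions of `p` layers and
   an innermost region of `p + q` (default `s = 3`) — and the normal
   parenchyma inside a 2-pixel-margin bounding box becomes region
   `s + 1`.
2. **Regional bag of visual words.** Dense 7×7 raw-intensity patches are
   taken at every labeled pixel, patches with ≤ 15 nonzero gray values
   are discarded as background, and the rest are quantized against a
   K-means codebook `V = {v_1..v_N}` (default `N = 1024`; the phantom
   experiments use 64). Per region, hard assignment
   `argmin_{u∈V} ||u − p_k||` yields a word histogram, normalized to a
   probability vector; the lesion descriptor is the concatenation over
   regions, dimension `(s+1)·N`. Patient features are the element-wise
   mean of the patient's image features over a chosen phase subset.
3. **Low-level bank.** For comparison, 93 classical features per ROI:
   5 gray-histogram statistics, 16 GLCM (contrast, homogeneity, energy,
   correlation × 4 angles), 48 Gabor (4 frequencies × 6 orientations,
   magnitude mean/sd), 12 wavelet-texture and 12 radial-distance shape
   statistics.
4. **Distances.** L1/L2 in raw space, or L2 after a learned projection:
   RLDA (PCA to `M−1`, then leading eigenvectors of
   `(S_w + αI)^{-1} S_b`, `α = 0.001`) or LDP (generalized eigenvectors
   of the between- vs within-class sample-difference covariances).
5. **Evaluation.** Patient-level stratified K-fold cross-validation:
   each test patient queries the training-patient database; rankings are
   scored by `P(n)` (mean precision after the top *n* patients) and MAP,
   defined as the mean of `P(n)` over `n = 1..T`. Note this MAP
   saturates below 1: with `R` relevant among `T`, a perfect ranking
   scores `(R + R·(H(T) − H(R))) / T`.

No clinical images ship with the package; a phantom generator renders
seeded triple-phase datasets whose class-conditional enhancement follows
the patterns above, so the whole pipeline runs self-contained.

## Worked example

```python
import lesionbow as lb

manifest = lb.generate_dataset(lb.PhantomParams(seed=1), "phantoms")
config = lb.ExperimentConfig(feature="regional_bow", phases=("AP", "PVP", "DP"),
                             metric="L2", s=3, codebook_size=64, n_folds=5, seed=1)
report = lb.run_experiment(manifest, config)
print(report.precision(1), report.precision(4), report.precision(5), report.map)
```

prints

```
1.0 1.0 0.8 0.6732924482924484
```

Fifteen phantom patients (5 per class) under 5-fold cross-validation
give 12-patient databases with 4 patients per class. `P(4) = 1.0` means
every query retrieves all of its same-class patients before any other
patient; `P(5) = 0.8` is the maximum possible (only 4 relevant patients
exist), and MAP equals the perfect-ranking ceiling
`(4 + 4·(H(12) − H(4))) / 12 ≈ 0.6733` — the ranking is exactly perfect.
The `examples/` directory walks through each stage (phantoms,
partitioning, codebooks, the 93-feature bank, metric learning,
evaluation) as runnable scripts; a thin `lesionbow` CLI wraps the same
calls (`lesionbow phantom`, `build-codebook`, `extract-features`,
`train-metric`, `evaluate`).

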