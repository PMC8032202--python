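# graphsig

Graph-of-graphs analysis for multiplexed data: per-data-point random-walk
signatures and a diffusion-maps embedding over them.

## The problem

Many spatial assays measure *m* features at each of *n* positions: in
imaging mass cytometry (IMC), every region of interest (ROI) of a tissue
slide carries a stack of *m* marker patches of *d* pixels each; in a
sensor-network localization problem, every hidden object is seen by *m*
sensors through *d*-dimensional noisy readouts.  Comparing the raw feature
values across positions is fragile — each ROI contains different cells,
each sensor has its own dynamics.  What is robust is the *mutual
relationship* among the features at one position.

`graphsig` encodes those relationships in two graph-building stages:

1. **Local stage.**  For data point x_i with features f_1, …, f_m, build
   the complete graph with Gaussian weights
   `W_i(k,l) = exp(−‖f_k − f_l‖² / 2ε)` and the random walk
   `P_i = D_i⁻¹ W_i`.  Because W_i is symmetric with unit diagonal, the
   walk's unique stationary law — the **steady-state distribution (SSD)**
   `π_i ∝ D_i 1` — is just the normalized degree vector, an m-dimensional
   signature computable without any eigendecomposition.  Spectral
   comparators (DKS `Σ_j λ_j^t ψ_j²`, HKS `Σ_j e^{−(1−λ_j)t} ψ_j²`, WKS
   log-Gaussian band filters) are provided for benchmarking; the SSD is
   the t = 1 diffusion-kernel signature up to normalization.
2. **Global stage.**  Stack the n signatures, build a second Gaussian
   kernel on their pairwise **l1** distances (the natural metric, since
   the total variation between two SSDs is an l1 distance), and embed with
   diffusion maps `x_i ↦ (λ_2^t φ_2(i), …, λ_{l+1}^t φ_{l+1}(i))`.  The
   number of informative coordinates l is chosen by a Jackstraw-style
   permutation test: signature columns are permuted across points, the
   kernel rebuilt, and observed eigenvalues kept while they exceed the
   permutation-null maxima.

A statistical companion (`graphsig.theory`) models the features of one
point as an md-dimensional Gaussian with per-feature means μ_j, variances
σ_j and cross-covariances σ_{k,l}, defines the per-feature
**heterogeneity** h(j) = (μ_j − ⟨μ⟩)/μ_j and its weighted form
g(j) = μ_j − ⟨μ⟩, and derives a closed-form approximation of the expected
SSD in terms of g², σ and the covariance summary — which shows the SSD
encodes exactly this heterogeneity, and yields total-variation bounds under
which SSD-based two-class discrimination beats the per-feature MAP rule.

## Worked example

Localize 800 objects in four spherical regions from five variance-encoding
sensors (no sensor alone can separate the regions):

```python
import numpy as np
import graphsig as gs
from graphsig import evaluate as ev

cfg = gs.SimulationConfig(scenario="sim1", seed=1)
scene = gs.make_scene(cfg)                      # 800 points, 4 regions, 5 sensors
bundles = gs.observe_sim1(scene, cfg)           # 5 x 100 observations per point

result = gs.graph_of_graphs(bundles, dimension=3)   # SSDs -> 3-D embedding
report = ev.kfold_cv(
    ev.LabeledEmbedding(result.coordinates, scene.region_labels),
    k=10, seed=1)
print(f"4-region accuracy: {report.accuracy:.3f}")
print("per-region:", {k: round(v, 3) for k, v in report.per_class_accuracy.items()})
```

Output:

```
4-region accuracy: 0.849
per-region: {0: 0.775, 1: 0.96, 2: 0.76, 3: 0.9}
```

A 10-fold-validated RBF-SVM on the 3-D SSD embedding identifies ~85–90% of
object positions correctly; the same classifier on any *single* sensor's
diffusion-maps embedding stays below 50% (run `_sim1_accuracies` in
`tests/test_acceptance.py` to see the contrast).  For IMC-style images,
`graphsig.imc_io.preprocess_and_extract` applies nonzero-pixel z-scoring
(optionally a 3×3 median filter), anchors b×b ROIs on the brightest
Cytokeratin windows, and returns the bundles the same pipeline consumes.

A CLI mirrors the stages:

```bash
graphsig simulate --scenario imc --seed 0 --out bundles/
graphsig signatures --input bundles/ --kind ssd --out sigs.tsv
graphsig embed --signatures sigs.tsv --seed 0 --out emb.tsv
graphsig classify --embedding emb.tsv --protocol kfold --out report.json
```

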