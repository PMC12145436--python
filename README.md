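# brainkrig

Spatial prediction of cortical activity maps by multiresolution lattice
kriging.

## The problem

Task-evoked brain activity has two tails: regions that activate
(task-positive) and regions that deactivate (task-negative).  If both tails
are expressions of a single smooth spatial process on the cortical sheet,
then the *geometry* of one extreme should predict the other.  `brainkrig`
tests exactly this: it thresholds a per-vertex z-map to its extreme tail
(bottom 25% of vertices by default), fits a spatial Gaussian-process
approximation on the masked vertices only, predicts the whole surface, and
scores the agreement at the unseen out-of-mask vertices with Spearman's ρ.
The same machinery runs on planar widefield-imaging frames (top 25% of
pixels predicting the rest), and two null procedures — spin permutation of
label maps and eigenmode surrogates with preserved spatial autocorrelation —
probe *why* the prediction works.

It is written for researchers analysing surface-projected neuroimaging maps
(GIFTI metric/label files on spherical meshes) or 2-D imaging time series
(HDF5 stacks), and ships a synthetic-data module so every analysis can be
exercised, and every claim tested, without any real data.

## The model

Observed values y at locations x on the sphere (or plane) follow

    y = X β + Φ(x) c + ε,     c ~ N(0, ρ Q_α⁻¹),   ε ~ N(0, σ² I)

where Φ is a sparse design of compactly supported Wendland radial basis
functions, w(r) = (1−r)⁶(35r² + 18r + 3)/3 for r < 1, centred on a
multiresolution icosphere (or planar) lattice — three levels with relative
variance weights α = (1, 0.25, 0.01) by default — and Q_α is a sparse
spatial-autoregressive (SAR) precision built from each level's lattice
adjacency, Q = BᵀB with B = diag(degree + κ²) − A.  With λ = σ²/ρ the
coefficients solve the penalized least squares system

    (ΦᵀΦ + λ Q_α) c = Φᵀ (y − X β),

which keeps everything sparse and positive definite while approximating
full kriging.  Distances are great-circle on the unit sphere, Euclidean on
the plane.  λ is fixed or selected by GCV/profile likelihood on a grid.

The core is a scikit-learn style estimator:

```python
import numpy as np
from brainkrig import (build_icosphere, build_sphere_lattice, LatticeKriging,
                       SynthesisSpec, synth_map, threshold_mask,
                       krige_from_mask)

mesh = build_icosphere(4)                      # 2562-vertex sphere
smap = synth_map(mesh, SynthesisSpec(spectrum_decay=3.5, n_modes=200,
                                     noise_sd=0.05, seed=0))
mask = threshold_mask(smap, quantile=0.25, tail="low")   # task-negative tail
result = krige_from_mask(smap, mask, {"n_levels": 3,
                                      "alpha": (1, 0.25, 0.01)})
print(result.metrics)
```

which prints (numbers from this exact run):

```
         restriction     n  spearman_rho       mae  defined
0               none  1922      0.892426  0.523784     True
1  observed_positive  1308      0.781093  0.697202     True
2       min_distance  1824      0.874306  0.547808     True
```

Read: from the bottom quarter of the map alone, the model ranks the unseen
three quarters of the surface with ρ ≈ 0.89 (n = 1922 out-of-mask
vertices); restricting to truly task-positive vertices (z > 0) or to
vertices more than 0.1 rad from the mask barely dents it.  Running the same map with `spectrum_decay=0` (white
noise) collapses ρ to ≈ 0 — the prediction lives entirely on spatial
autocorrelation.

Higher-level analyses: `pairwise_specificity` (conjunction-mask
true-vs-alternative task test), `network_prediction` plus `spin_null`
(does network layout matter beyond its spatial distribution?),
`eigenstrap` (surrogate maps with matched autocorrelation), and
`series_analyze`/`group_inference` (per-frame planar prediction with
Fisher-z, t-test and AR(1)-adjusted inference).

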