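# slicocc

Functional supervoxel segmentation of PET drug-occupancy image series, and
precise EC50 parametric mapping.

## The problem

PET occupancy studies measure, voxel by voxel, the fraction of a drug's
target receptors that are occupied at a given plasma concentration. A series
of occupancy volumes acquired at V different plasma concentrations C relates
to the drug's effective affinity through the hyperbolic Emax model

    Occ(C) = Occ_max · C / (C + EC50)

where EC50 is the plasma concentration producing half-maximal occupancy (a
*high*-EC50 "hot spot" means *low* local affinity) and Occ_max is the
saturating occupancy. Fitting this model independently at every voxel yields
an EC50 image, but voxel-level occupancy curves are noisy and the resulting
EC50 estimates have a large coefficient of variation, CV(EC50) =
σ_fit/EC50.

`slicocc` implements SLIC-Occ: a modified SLIC supervoxel clustering that
groups voxels with similar occupancy curves, fits the Emax model once per
cluster on the cluster-mean curve, and broadcasts the fit back to the
voxels. Averaging ~N/K voxel curves per cluster shrinks the residual noise,
so cluster-level CV(EC50) drops several-fold relative to voxel-level
fitting, at the cost of a moderate, well-characterized EC50 bias near
region boundaries.

The clustering minimizes, per voxel, the combined distance

    D = sqrt(d_feature² + (d_spatial/S)² · m²),   S = ∛(N/K)

where d_feature is the Euclidean distance across the V occupancy channels,
d_spatial the 3D voxel distance to the cluster center, K the requested
number of clusters and m the compactness weight. Assignment is a localized
k-means restricted to a 2S×2S×2S search window per cluster center. The 1-
and 2-parameter Emax fits (Occ_max fixed vs free) are compared per curve by
the corrected Akaike information criterion, AICc = 2p + n·ln(SSE/n) +
(2p²+2p)/(n−p−1), and parameter precision comes from the least-squares
covariance σ_fit² = diag((JᵀJ)⁻¹ · RᵀR/(n−p)).

The package also ships a digital phantom: a geometric brain volume with
bilateral high-EC50 hot spots (25 and 50 ng/mL) over a 6–10 ng/mL
background, Occ_max = 0.85, occupancy-dependent Gaussian noise
(σ = −0.22·Occ + 0.25) and 3×3×3 Gaussian smoothing — so the full
precision/accuracy trade-off can be quantified against known truth.

## Worked example

```python
import numpy as np
from slicocc import (PhantomSpec, simulate_study, run_slic_occ,
                     fit_clusterwise, fit_voxelwise, region_summary, cv_reduction)

spec = PhantomSpec(seed=0)                       # 64^3 phantom, 10 concentrations
truth, series = simulate_study(spec)             # noisy, smoothed occupancy series
N = int(truth.brain_mask.sum())
labeling = run_slic_occ(series, K=round(N / 265.4), m=0.5)
cluster_maps, table = fit_clusterwise(series, labeling)

voxel_mask = truth.label_image >= 2              # fit voxels in the hot spots
voxel_maps = fit_voxelwise(series, voxel_mask=voxel_mask)

for level, maps in [("voxel", voxel_maps), ("cluster", cluster_maps)]:
    s = region_summary(maps, truth, "caudate")
    print(f"{level:8s} EC50 {s.ec50_mean:5.2f} +/- {s.ec50_sd:5.2f}  "
          f"CV {s.cv_mean:.3f}  bias {s.bias_percent:+.1f}%")
ratio, red = cv_reduction(voxel_maps, cluster_maps, truth, "caudate")
print(f"CV fold-reduction {ratio:.1f}x ({red:.0f}%)")
```

prints

```
voxel    EC50 28.37 +/- 11.34  CV 0.218  bias +13.5%
cluster  EC50 23.08 +/-  1.93  CV 0.039  bias -7.7%
CV fold-reduction 5.6x (82%)
```

Read: in the caudate-like hot spot (true EC50 = 25 ng/mL), voxel-level
fitting overestimates the region mean (28.4) with a wide voxel spread and a
CV(EC50) of 0.22; clustering first (m = 0.5, ~265-voxel clusters) gives a
slight underestimate (23.1) but cuts the CV more than five-fold to 0.039 —
precision is traded for a small, systematic boundary bias.

The same pipeline runs from the shell on NIfTI inputs:

```sh
slicocc simulate --config study.yaml --out run/
slicocc cluster  --series run/series/occupancy_smoothed.nii.gz \
                 --mask run/series/brain_mask.nii.gz \
                 --conc run/series/concentrations.csv --K 412 --m 0.5 --out run/clusters
slicocc fit      --series ... --labels run/clusters/cluster_labels.nii.gz --out run/maps
slicocc run      --config study.yaml --out run/       # full pipeline + manifest
```

The estimators also compose with scikit-learn: `SLICOcc(n_clusters=412,
compactness=0.5).fit(series)` and `EmaxRegressor().fit(conc, occ)` follow
the usual `get_params`/fitted-attribute conventions.

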