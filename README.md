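# stdac

Spatial-temporal data augmentation for classifying functional brain networks
built from ROI-level resting-state fMRI time series.

## The problem

Clinical rs-fMRI cohorts are small — often a few dozen subjects per
diagnostic class — while the standard feature representation is large: with
m atlas regions, the functional brain network (FBN) is the m x m Pearson
correlation matrix of the regional time series, giving m(m-1)/2 edge
features (6,670 for the 116-region AAL parcellation). Classifiers trained on
such data under- or over-fit. `stdac` attacks the sample-size problem with
two augmentation rules tailored to ROI time series, plus a fusion step:

1. **Spatial augmentation.** Each node's series x_i is replaced by the mean
   over a neighbor set C_i containing the node and up to k nearest nodes
   strictly within a radius r·D (D = atlas diameter):
   `|C_i| ≤ k+1`, `d(i,s) < d(i,j)` for kept s vs. excluded j, `d(i,s) < r·D`.
   Varying k = 1..degree yields `degree` new samples per subject.
2. **Temporal augmentation.** A new sample keeps l < t time points drawn
   uniformly *without* replacement — deliberately discontinuous, unlike
   sliding windows — with the same index set applied to every region. By the
   jackknife argument, correlation matrices of such subsamples scatter
   around the full-sample matrix, so each draw is a distinct but faithful
   training sample; the degree (default 100) sets how many draws per subject.
3. **Score fusion.** One classifier is trained per augmented set. For a test
   subject's original FBN features, each branch emits a per-class
   probability vector, and the fused feature is the z-scored flattened outer
   product `ω = f(s_spatial s_temporalᵀ)` (length c² for c classes), which a
   final classifier maps to the label.

Evaluation is leakage-safe stratified k-fold cross-validation: augmentation
is applied inside training folds only, and every training sample's
provenance is checked against the test fold (a violation is a hard error).
Four schemes are compared — `original` (no augmentation), `sda` (spatial
only), `tda` (temporal only), `stdac` (both + fusion). Trained classifiers
also yield discriminative-connection rankings: per-edge importances are
integrated across models, min-max normalized, ranked top-k, and accumulated
onto regions (candidate biomarkers; BrainNet Viewer exports included).

A synthetic-cohort generator with planted group-dependent correlations makes
every stage testable without access-restricted clinical data.

## Worked example

```python
import numpy as np
from stdac import (SimulationSpec, simulate_cohort, CVConfig, SpatialConfig,
                   TemporalConfig, run_cv_schemes)

spec = SimulationSpec(n_per_class=10, m=20, t=100,
                      planted_edges=((0, 1, (0.0, 0.6)), (4, 5, (0.0, 0.5))),
                      seed=42)
subjects, geometry, truth = simulate_cohort(spec)
config = CVConfig(n_folds=5, classifier="svm",
                  spatial=SpatialConfig(degree=4),
                  temporal=TemporalConfig(degree=20, seed=42), seed=42)
results = run_cv_schemes(subjects, geometry, config)
for scheme, res in results.items():
    print(f"{scheme:9s} accuracy {res.accuracy:6.2f}%  AUC {res.auc:.3f}")
```

prints

```
original  accuracy 100.00%  AUC 1.000
sda       accuracy  65.00%  AUC 0.750
tda       accuracy 100.00%  AUC 1.000
stdac     accuracy 100.00%  AUC 1.000
```

Accuracy is the mean over the 5 test folds; AUC is the trapezoidal area
under the pooled ROC with "patient" as the positive class. The two planted
correlation deltas (0.6 and 0.5 on edges 0–1 and 4–5) are strong enough that
the unaugmented and temporally augmented schemes already separate the
classes perfectly here; spatial averaging alone blurs part of the signal
(65%), while the fusion scheme recovers the full performance of its stronger
branch. On a null cohort (`spec.null()`, identical class covariances) every
scheme drops to ~50% chance.

The same pipeline runs from the shell:

```bash
stdac simulate --seed 42 --out-dir cohort/
stdac evaluate --manifest cohort/manifest.csv --atlas cohort/atlas.csv \
      --scheme stdac --folds 10 --seed 42 --out metrics.json
stdac train --manifest cohort/manifest.csv --atlas cohort/atlas.csv \
      --classifier svm --seed 42 --model-out model.joblib
```

Real data enters through the same three text formats the simulator writes: a
manifest CSV (`subject_id,path,label`), an atlas CSV (`roi_name,x,y,z` in
mm, or a BrainNet `.node` file), and one delimited t x m time-series table
per subject.

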