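# crmkit

Cross-subject consistency metrics for facial-expression recordings.

When a cohort of subjects watches the same stimulus, their facial responses
synchronize.  `crmkit` quantifies that synchronization frame by frame from
two kinds of input:

* **Tracked facial keypoints** (66 landmarks per frame, DISFA-style layout).
  After geometric normalization (frontalization, affine registration to a
  shared reference, part-wise similarity registration), per-frame keypoint
  movement vectors are tested against the null of "no movement from
  neutral", yielding five metrics: `avg_t`, `max_t` (per-coordinate
  one-sample t-scores), `avg_t2`, `max_t2` (per-keypoint Hotelling
  T-square), and `pca_t2` (Hotelling T-square on PCA-reduced movement).
* **FACS action-unit codes** (12 AUs, intensity 0–5 per frame).  The
  reference metric `au_consistency` is the percentage of subjects showing
  the same AU, maximized over AUs.

The analysis layer splits any metric series into four consistency classes
at its 30/60/90th sample percentiles, builds per-emotion-segment class
distribution tables, and compares keypoint metrics against the AU
reference by OLS agreement (R²) and row-wise averaged KL divergence.

A synthetic-cohort simulator (`crmkit.simulate`) generates landmark
trajectories with known ground truth — per-subject shape variation,
AU-like displacement epochs with configurable participation probability,
positional jitter, and in-plane head-pose nuisance — so the whole pipeline
is testable without restricted data.

## CLI

```bash
# generate a synthetic cohort (landmarks, AU labels, segments, ground truth)
crmkit simulate --out cohort/ --seed 1 --subjects 27 --frames 600

# geometric normalization -> per-subject movement (KPM) files
crmkit preprocess --cohort cohort/ --out work/

# per-frame metric series
crmkit metrics --kpm work/kpm --out work/metrics --metrics avg_t,max_t,avg_t2,max_t2,pca_t2

# class boundaries, distribution tables, R² and KL comparison report
crmkit analyze --cohort cohort/ --metrics-dir work/metrics --out work/

# or everything at once
crmkit compare --cohort cohort/ --out work/
```

Options can also be given in a YAML config (`--config run.yaml`) with
sections `simulation`, `registration`, `metrics`, `analysis`; unknown keys
are rejected.  Exit codes: 0 success, 1 runtime failure, 2 usage error.

### File formats

* landmarks: CSV, header `frame,x_0,...,x_65,y_0,...,y_65`, one row per frame
* AU labels: CSV, header `frame,AU1,AU2,AU4,...,AU26`, intensity codes 0–5
* segments: CSV `name,start_frame,end_frame,emotion` (inclusive bounds)
* metric series / KPM: TSV with header

## Library example

```python
from crmkit import analysis, au, geometry, metrics, simulate

cohort = simulate.simulate_cohort(simulate.default_structured_config(seed=1))
result = geometry.preprocess_cohort(cohort.dataset)
avg_t = metrics.metric_timeseries(result.kpm, "avg_t")
mu = au.binarize_au(cohort.dataset.au_labels, threshold=1)
kappa_au = au.au_consistency_series(mu)
report = analysis.compare_metrics(
    kappa_au.overall, {"avg_t": avg_t.values}, cohort.dataset.segments
)
print(report["metrics"]["avg_t"]["r2"])
```
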