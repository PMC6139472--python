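# fcmvpa

Task-dependent functional-connectivity multivariate pattern analysis
(fcMVPA) for event-related fMRI, with a fully synthetic test bench.

The pipeline answers a question of the form: *can two groups of
participants (here: postpartum women, PP, vs age-matched controls,
CTRL) be told apart from how their brain regions co-activate during
subjective recollection?*  Participants perform a Remember/Know
recognition test in the scanner (120 studied + 60 new words,
back-to-back 4-s trials, TR = 2 s, 360 volumes); 16 cube-shaped nodes
(3×3×3 voxels) mark the subjective-recollection network; and each
subject is summarised by the pairwise correlations between the nodes'
*task-dependent* time-series.

## Method

For each node the 27 voxel-wise BOLD series x(t) are turned into one
PPI-style (psychophysiological interaction) series:

1. **Deconvolution** — estimate the neural-level signal n(t) from
   x = H n, where H is the causal Toeplitz operator of the canonical
   double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6, 32 s long).
   The inverse is ridge-regularized, `n̂ = (HᵀH + λI)⁻¹Hᵀx`, with λ
   chosen per series by generalized cross-validation.
2. **Psychological factor** — ψ(t) = +1 at Remember-hit onsets, −1 at
   Know-hit onsets, 0 elsewhere (sticks binned to the nearest TR).
3. **Interaction** — the product n̂(t)·ψ(t) is re-convolved with the
   HRF and detrended; the 27 voxel series are averaged.

The lower triangle of the 16×16 Pearson correlation matrix of these
series gives 120 edge features per subject (raw r, no Fisher z).  A
linear SVM (C = 1) is then trained under leave-one-out
cross-validation, repeatedly, with the top-k features for k = 1…120
(features ordered by absolute two-sample t between groups), and the
accuracy curve is compared against a permutation null (labels
shuffled, ranking recomputed, whole curve rebuilt per permutation).
The edges included at the peak are reported with their within-group
mean r values and a direction flag (CTRL>PP / PP>CTRL).

Because the underlying human dataset is not public, the package ships
a generator of synthetic cohorts in which inter-node coupling switches
with the trial condition: on chosen "effect" edges, Remember-hit
epochs of the PP group are generated at correlation `base_rho +
delta_rho` while everything else stays at `base_rho` — so the
Remember-minus-Know coupling contrast the pipeline measures is a known
quantity, and recovery can be verified end to end.

## Worked example

Simulate a 10 + 10 cohort with two injected effect edges
(delta_rho = 0.5 on edges 0–1 and 2–3), run the analysis, and classify:

```python
from fcmvpa import PipelineConfig, run_simulate, run_connectivity, run_classify

cfg = PipelineConfig(
    cohort_dir="cohort", out_dir="results",
    n_ctrl=10, n_pp=10, grid_shape=(24, 24, 15), noise_sd=0.1,
    effect_edges=(((0, 1), 0.5), ((2, 3), 0.5)),
    n_perm=200, sim_seed=42, seed=7,
)
run_simulate(cfg)       # cohort/: 4D NIfTI + events TSV per subject
run_connectivity(cfg)   # results/features/: 120 edge r values per subject
run_classify(cfg)       # results/: curve.csv, results.json, edge_report.csv, plot
```

`results/results.json` from this exact run:

```json
{"peak_k": 4, "peak_accuracy": 1.0, "accuracy_all_features": 0.75,
 "n_subjects": 20, "n_features": 120, "n_perm": 200, "seed": 7,
 "chance_level": 0.5, "majority_class_proportion": 0.5,
 "ranking_method": "ttest", "svm_C": 1.0}
```

The classifier separates the groups perfectly with 4 features, while
the 200-permutation null hovers near 0.86 ± 0.09 at that region of the
curve (`curve.csv`).  The top of `edge_report.csv` recovers both
injected edges, with the correct direction and group means close to
the generative values (base 0.1 vs base + delta weighted by the
Remember-hit epoch fraction):

```
rank,edge,edge_index,mean_r_CTRL,mean_r_PP,direction
1,node00 ~ node01,0,0.08,0.34,PP>CTRL
2,node02 ~ node03,5,0.17,0.41,PP>CTRL
```

The same workflow is available from the shell:

```bash
fcmvpa simulate --cohort-dir cohort --n-ctrl 10 --n-pp 10 --seed 42
fcmvpa connectivity --cohort-dir cohort --out-dir results
fcmvpa classify --cohort-dir cohort --out-dir results --n-perm 200 --seed 7
```

Node coordinates are a CSV input (`name,x,y,z,space` with space TAL or
MNI; Talairach coordinates are converted with the Lacadie best-fit
affine).  The packaged 16-region table uses synthetic stand-in
coordinates — supply your own for real data.

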