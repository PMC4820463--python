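# plastec

Evolutionary detection of **plastic sub-regional pairs** between two fMRI
regions of interest across two scan sessions.

## The problem

Longitudinal fMRI studies often ask how the functional relationship between
two investigator-defined ROIs (say, frontal components of the default mode
and executive control networks) changes between two sessions — during
learning, development, or recovery from injury. The conventional approach
correlates the ROI-*mean* signals, but averaging over heterogeneous voxels
hides changes that happen at a finer spatial scale: a small cluster of
voxels in ROI-A may gain or lose synchronization with a small cluster in
ROI-B while the ROI-level means barely move, and gains in one cluster pair
can cancel losses in another when only the total edge count is tracked.

plastec implements a voxel-level alternative: a recursive evolutionary
search that finds, per subject, all pairs of spatially connected sub-regions
(one per ROI) whose voxel-wise connectivity changes significantly between
sessions — including both the direction of each change and a subject-level
estimate of overall positive and negative plasticity.

## The method

1. **Binary connectivity matrices.** For each session, all |A| x |B|
   voxel-pair Pearson correlations are computed from the BOLD series;
   p-values failing a Benjamini–Hochberg FDR test at q = 0.05 and
   non-positive correlations are zeroed, the survivors set to 1, giving
   M1 and M2.
2. **Chromosome encoding.** A candidate solution is 8 genes
   (X1, Y1, Z1, L1, X2, Y2, Z2, L2): a mm-space point per ROI, decoded to the
   nearest ROI voxel (the *root*), plus a quantized size gene; the
   sub-region is the root and the first L voxels enqueued by a deterministic
   breadth-first search over 6-neighbor adjacency (smallest z, then y, then
   x on ties).
3. **Objective.** For a candidate pair with edge counts NC1, NC2 and
   TC = |subA| * |subB| possible connections,

       P1 = NC1/TC,  EC2 = P1 * TC,  SD = sqrt(TC * P1 * (1 - P1)),
       fitness = |Z| = |(NC2 - EC2) / SD|

   — a binomial z-score treating the session-1 edge fraction as the null
   rate for session 2. The sign of Z gives the direction of plasticity.
4. **Search.** Each generation every parent produces offspring by bounded
   uniform mutation (±6 mm per spatial gene, ±4 lattice steps per size
   gene); parents and offspring are pooled and the top half by fitness kept
   (population-elitist selection), until complete convergence or 100
   generations without improvement.
5. **Recursion with edge blocking.** Each detected pair's edges are zeroed
   in both matrices and the search repeats, so successive pairs use disjoint
   edges; recursion stops when the best |Z| drops below 1. Recorded pairs
   are Bonferroni-corrected; survivors need corrected p < 0.05.
6. **Plasticity estimates.** Percent of the |A| x |B| possible connections
   gained (positive plasticity) and lost (negative plasticity) across
   surviving pairs, plus their sum gl1. Baselines (ROI-averaging
   correlation, total-edge-count change gl2) and run-to-run reliability
   metrics (max-matched Sorenson-dice, adjusted Rand index over voxel-pair
   labelings, voxel-pair membership consistency) are included.

## Worked example

Synthetic subject with one planted sub-regional pair (40 x 60 voxels) whose
edge density rises from 5% to 90% between sessions, on ROIs of 120 and 150
voxels:

```python
from plastec import ECConfig, detect_all_srps, estimate_plasticity
from plastec.synthetic import preset_matrix_subject

grid, roi_a, roi_b, truth, m1, m2 = preset_matrix_subject(seed=1)
cfg = ECConfig(population_size=60, stall_generations=20,
               l_min=1, l_step=1, rng_seed=7)
result = detect_all_srps(m1, m2, roi_a, roi_b, cfg, grid=grid)
for srp in result.srps:
    print(f"level {srp.level}: sign {srp.sign:+d}  NC1={srp.NC1}  "
          f"NC2={srp.NC2}  TC={srp.TC}  |Z|={srp.fitness:.1f}")
est = estimate_plasticity(result.srps, len(roi_a), len(roi_b))
print(f"positive plasticity: {est.pct_positive:.2f}%  "
      f"negative: {est.pct_negative:.2f}%  gl1={est.gl1}")
```

prints

```
level 1: sign +1  NC1=190  NC2=2209  TC=4745  |Z|=149.5
positive plasticity: 11.22%  negative: 0.00%  gl1=2019
```

The search recovered one positively plastic pair closely covering the
planted block: it gained 2019 edges out of 18000 possible ROI-pair
connections, i.e. 11.22% positive plasticity, and found no negative
plasticity — the planted truth.

The same analysis runs from the shell on NIfTI inputs:

```sh
plastec simulate --preset timeseries --seed 2 --out subject/
plastec run --session1 subject/session1.nii.gz \
            --session2 subject/session2.nii.gz \
            --labels subject/labels.nii.gz \
            --roi-a 1 --roi-b 2 --runs 5 --seed 7 --out results/
plastec compare results/run-* 
```

`run` writes `srps.tsv` (one row per surviving pair), `summary.json`
(plasticity estimates), `baseline.tsv` (averaging and edge-count
baselines) and `manifest.json` per run, plus aggregate mean/SD estimates
and overlap metrics across runs.

## Layout

| module                 | role                                                 |
| ---------------------- | ---------------------------------------------------- |
| `plastec.io`           | grids, ROI definitions, NIfTI/TSV reading & writing  |
| `plastec.connectivity` | per-session binary connectivity matrices             |
| `plastec.encoding`     | chromosome decoding: nearest root + BFS growth       |
| `plastec.search`       | fitness, mutation, selection, recursion and blocking |
| `plastec.plasticity`   | subject-level positive/negative plasticity estimates |
| `plastec.baselines`    | ROI-averaging and total-edge-count comparisons       |
| `plastec.consistency`  | dice / ARI / voxel-pair run-to-run reliability       |
| `plastec.synthetic`    | planted-truth generators for matrices and series     |
| `plastec.cli`          | `plastec run / simulate / compare / report`          |

See `docs/methods.md` for the full model description, parameter defaults
and numerical conventions.
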