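# Methods

## Data model and assumptions

plastec consumes *preprocessed* two-session BOLD data: two 4D volumes per
subject, already motion-corrected, normalized to a common grid and
denoised, plus a 3D integer label volume defining the two ROIs on that same
grid. All three volumes must agree in shape and affine to within 1e-6
elementwise; disagreement is a hard error rather than a resampling step,
because silent regridding would change voxel identity between sessions.
ROI voxel order is fixed at load time (ascending i, then j, then k) and is
the row/column identity of every matrix downstream.

The method assumes the two sessions sample the same anatomy so that a
voxel-pair (a, b) means the same thing at both time points. It makes no
assumption about hemodynamics beyond what Pearson correlation of the
series captures.

## Connectivity matrices

For one ROI pair (A, B) and one session, all |A| x |B| Pearson correlations
are computed. Two-sided p-values use the classical t transform
t = r sqrt(T-2) / sqrt(1-r^2) with T-2 degrees of freedom (T >= 3 required;
the conventional session length is T = 145 volumes). The family of
|A| x |B| p-values is screened by Benjamini–Hochberg at q = 0.05 — the FDR
family is one matrix (one subject, one session, one ROI pair), since each
session's matrix is an independent construction. Cells failing FDR or with
r <= 0 are zeroed; survivors become 1. Negative edges are deliberately
discarded (the analysis targets change in *positive* synchronization); a
future sign policy could admit them. Zero-variance voxels yield no edges
and a logged warning instead of aborting, so partially degenerate synthetic
inputs still run.

## Chromosome encoding and decoding

A chromosome is (X1, Y1, Z1, L1, X2, Y2, Z2, L2). Spatial genes live in mm
inside the axis-aligned bounding cuboid of the ROI's voxel centers
(inclusive); they decode to the ROI voxel with the nearest center
(Euclidean, ties broken by smallest z, then y, then x center coordinate).
Size genes live on the lattice {L_min, L_min + L_step, ...} capped at the
ROI size; defaults L_min = 64 (a 4x4x4-voxel sub-region) and L_step = 5.
The sub-region is the root plus the first L voxels enqueued by FIFO BFS
over 6-neighbor adjacency restricted to the ROI, with unvisited neighbors
enqueued in ascending (z, y, x) order *at every frontier expansion* — this
makes the grown shape a pure, deterministic function of (root, L), which
matters more than the particular shape (the shape itself carries little
meaning without structural information). |members| = L + 1 capped at the
root's connected component; a disconnected ROI therefore caps growth at
the component rather than aborting. Since the BFS enqueue order from a
given root does not depend on L, decoding caches one full order per root
and takes prefixes, which is what makes the search loop cheap.

## Objective

For a candidate pair, NC1 and NC2 count the 1-cells of its
|subA| x |subB| submatrix in M1 and M2, and TC = |subA| * |subB| — TC is
purely combinatorial and still counts cells blocked at earlier recursion
levels (those cells simply contribute 0 to both NC1 and NC2).

    P1 = NC1 / TC        (session-1 edge fraction, the null rate)
    EC2 = P1 * TC = NC1  (expected session-2 count)
    SD = sqrt(TC * P1 * (1 - P1))
    fitness = |Z| = |(NC2 - EC2) / SD|

Degenerate baselines (NC1 = 0 or NC1 = TC) have SD = 0; P1 is clamped to
[0.5/TC, 1 - 0.5/TC] (a continuity correction) before the formulas, so a
total gain from an empty baseline — exactly what a newly synchronized
sub-region pair looks like — scores very high instead of dividing by zero,
while NC2 = NC1 is always fitness 0 ("no change, no plasticity")
regardless of degeneracy.

## Search

One level is a (mu + lambda) evolutionary loop: genes initialize uniformly
over their ranges; every parent produces `offspring_per_parent` children
(default 1, so the pool is exactly 2N and "keep the top 50%" applies
literally) by bounded uniform mutation — each spatial gene uniform in
±(dx, dy, dz) mm then clamped to the cuboid, each size gene's lattice
*index* uniform in ±dl then clamped. dl counts lattice steps, not voxels:
at L_step = 5, ±4 raw voxels would be smaller than one step and leave the
size gene immutable. Selection pools parents (first) and offspring and
keeps the N highest fitnesses with a stable sort, so ties at the cutoff
favor parents. A level stops on complete convergence — all chromosomes
decode to the same *voxel-set pair*, not the same raw genes, since
distinct genes can decode identically — or when the best-ever fitness has
not improved by more than 1e-12 for `stall_generations` generations.

Defaults mirror the production setting: population 400, spatial offsets
6 mm (two voxels at 3 mm isotropic), dl = 4, stall 100. One RNG stream
(numpy PCG64, seeded from the config) drives the whole run; recursion
levels consume it sequentially, so a fixed seed reproduces results
bit-identically.

Recursion: if a level's best |Z| >= z_stop (default 1.0), the pair is
recorded and its cells zeroed in working copies of both matrices (edge
*blocking*), then a fresh level runs; otherwise detection stops. Blocking
guarantees every recorded pair's counted edges are disjoint from all
earlier pairs' (the sub-region rectangles may still overlap — blocked
cells just count 0). Recorded pairs get two-sided standard-normal
p-values from |Z| and a Bonferroni correction with m = the number of pairs
recorded in this run for this ROI pair (not across subjects or ROI
pairs); survivors need corrected p < alpha = 0.05. `max_recursion`
(default unbounded) caps runaway recursion with a logged warning.

## Plasticity estimates and baselines

Over surviving pairs, gains = sum of NC2 - NC1 where positive, losses =
the mirror sum; positive/negative plasticity are 100 * gains / (|A||B|)
and 100 * losses / (|A||B|), and gl1 = gains + losses. Pairs with
NC1 = NC2 contribute to neither (they cannot survive correction anyway,
having fitness 0). Reference point: ROIs of 100 and 500 voxels with pairs
at +10000, +1000 and -5000 give 22% positive and 10% negative plasticity.

The averaging baseline correlates the two ROI-mean series (Fisher z for
group tests); the simple voxel-level baseline counts total edges per
session. gl2 is defined here as |sum(M2) - sum(M1)| — the total-count
analysis supports no finer derivation, which is precisely its documented
weakness: equal gains and losses cancel to gl2 ~ 0 while gl1 stays large.
Group utilities (paired t on Fisher z, paired Wilcoxon on counts) are thin
wrappers over scipy implementing the standard definitions.

## Reliability metrics

Between two independent runs: (1) each surviving pair's voxel set is the
ROI-*tagged* union of its two sub-regions — tagging prevents accidental
collisions when both ROIs contain the same grid coordinate index — and
each pair is scored by its maximal Sorenson-dice match in the other run,
averaging over both directions; undefined (reported missing, not 0) if
either run is empty. (2) The adjusted Rand index between the label fields
the runs induce on all |A| x |B| voxel pairs (label 0 = in no surviving
pair; later pairs overwrite earlier ones on the rare overlapping cells).
(3) Voxel-pair consistency: percent agreement of binary membership,
averaged over all unordered pairs of >= 2 runs — pairwise agreement was
chosen over agreement-with-majority, matching how the overlap metrics are
also aggregated over run pairs.

## Synthetic data

The generator emulates the structural premise of the method — two disjoint
6-connected ROIs on a 3D grid with block-structured inter-ROI coupling
that changes between sessions — at desk scale (default ROIs of 120 and 150
voxels on a 12x12x12 grid of 3 mm voxels; sessions of T = 145 samples,
the production session length).

Matrix generator: one uniform draw per cell *shared by both sessions*,
thresholded at the session's density (background default 3%, planted
blocks per their densities). This common-random-numbers coupling models
session-to-session edge persistence: equal densities give literally
identical matrices, and a monotone density change gives nested edge sets.
Time-series generator: per block and session, one latent Gaussian signal
added to member voxels of both ROIs with the session's coupling amplitude,
over i.i.d. unit-variance noise; sessions are independent draws.

Planted sub-regions are grown with the same deterministic BFS rule the
decoder uses, so every planted block is exactly representable by a
chromosome and recovery tests are well posed. Blocks placed within one
truth have disjoint A-side supports, hence disjoint edge supports.

What passing synthetic tests do *not* show: the generators have no
hemodynamic response, physiological noise, motion artifacts, spatial
autocorrelation from smoothing, or anatomically shaped ROIs, so recovery
rates here do not predict sensitivity/specificity on real data.

One empirical caveat the synthetic experiments expose: when both sessions
carry equal (nonzero) coupling, the FDR stage still admits ~q-proportion
false background edges independently per session, and the search — which
optimizes adversarially — can collect small sets of session-2-only cells
into nominally significant pairs. At desk scale with a dense L lattice
this produces a small false-positive floor (total detected plasticity
under 2% of possible edges, versus ~18% for a genuinely planted change);
the production-scale L_min = 64 suppresses it by forcing TC >= 65^2, which
makes empty-baseline cherry-picking statistically impossible. Identical
inputs (M2 = M1) yield exactly zero detections at recursion level 1.

## Numerical and design choices

- FDR method: Benjamini–Hochberg (the standard reading of "FDR at 0.05"),
  via statsmodels; applied per matrix.
- Correlation matrices are computed by a standardized matrix product with
  clipping to [-1, 1]; |r| = 1 maps to p = 0.
- Nearest-root lookups use a KD-tree; batch queries take the unambiguous
  nearest neighbor and fall back to the exact (z, y, x) tie-break whenever
  the two nearest centers are within 1e-9 mm.
- Stall detection tracks the *best-ever* fitness (not best-of-generation)
  with strict improvement tolerance 1e-12.
- Elitist selection ties resolve by pool position, parents first.
- Matrices are dense uint8; at production scale (500 x 1800) this is ~1 MB.
- Tests run the search at reduced scale (ROIs of tens to ~150 voxels,
  populations 60–200, stall 20–60, L lattice starting at 1) — chosen as
  the package's desk-scale study conditions, with search effort scaled to
  the decodable space the way the production parameters are scaled to
  theirs. Recovering a planted block *exactly* (rather than merely
  localizing it) needs the more thorough end of that range, consistent
  with the principle that a sufficiently large population is the guard
  against converging on partial solutions.

## Limitations

- Single-process search; the algorithm is embarrassingly parallel across
  chromosomes but this implementation does not exploit it (the API does
  not preclude it).
- Binarized edges discard correlation magnitude by design; weighted
  variants are out of scope.
- Anisotropic grids are accepted, but the mm mutation offsets are not
  rescaled per axis; whether they should be is an open question.
- Group-level inference is reporting-only: the paired tests operate on
  whatever per-subject tables the user assembles and make no claims about
  cohort-level reproducibility.
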