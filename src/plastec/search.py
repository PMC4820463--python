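"""Evolutionary search for significantly plastic sub-regional pairs.

The objective treats the session-1 edge fraction of a candidate pair as the
null rate of a binomial for session 2:

    P1 = NC1 / TC,  EC2 = P1 * TC = NC1,  SD = sqrt(TC * P1 * (1 - P1)),
    fitness = |Z| = |(NC2 - EC2) / SD|

where NC1 and NC2 count edges of the candidate's |subA| x |subB| submatrix
in the binary matrices M1 and M2, and TC = |subA| * |subB|.

One search level runs a (mu + lambda)-style loop: every parent produces
offspring by bounded uniform mutation of its 8 genes, parents and offspring
are pooled, and the top half by fitness survives (population-elitist
selection).  The level stops on complete convergence (all chromosomes decode
to the same voxel-set pair) or when the best-ever fitness has not improved
for a fixed span of generations.

The full detection is recursive: if the level's best pair reaches the
recording threshold (|Z| >= z_stop), its edges are zeroed in working copies
of both matrices (edge blocking) and a fresh level runs on the remainder;
otherwise recursion stops.  Recorded pairs then pass through a Bonferroni
filter over the number of recorded pairs, and only pairs with corrected
p < alpha survive.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .connectivity import BinaryConnectivityMatrix
from .encoding import Chromosome, ROISearchSpace, SubRegionalPair
from .io import ROIDefinition, VoxelGrid

__all__ = [
    "ECConfig",
    "ECResult",
    "fitness_zscore",
    "count_connections",
    "mutate",
    "select_population_elitist",
    "run_ec_level",
    "detect_all_srps",
    "bonferroni_filter",
]

logger = logging.getLogger(__name__)

_IMPROVE_TOL = 1e-12


@dataclasses.dataclass
class ECConfig:
    """Tunable parameters of the evolutionary search.

    Defaults follow the production-scale settings: population 400, 6 mm
    spatial mutation offsets (two voxels at 3 mm isotropic), size-gene
    offsets of 4 lattice steps, a 100-generation stall criterion, recording
    threshold z_stop = 1, and alpha = 0.05 for the Bonferroni filter.
    The size-gene lattice starts at 64 (a 4x4x4-voxel sub-region) with step
    5; tiny synthetic ROIs use l_min=1, l_step=1.
    """

    population_size: int = 400
    dx1: float = 6.0
    dy1: float = 6.0
    dz1: float = 6.0
    dx2: float = 6.0
    dy2: float = 6.0
    dz2: float = 6.0
    dl1: int = 4
    dl2: int = 4
    offspring_per_parent: int = 1
    stall_generations: int = 100
    z_stop: float = 1.0
    alpha: float = 0.05
    l_min: int = 64
    l_step: int = 5
    max_recursion: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if any(d < 0 for d in (self.dx1, self.dy1, self.dz1, self.dx2, self.dy2, self.dz2)):
            raise ValueError("spatial offsets must be >= 0")
        if self.dl1 < 0 or self.dl2 < 0:
            raise ValueError("L offsets must be >= 0")
        if self.offspring_per_parent < 1:
            raise ValueError("offspring_per_parent must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ECLevel:
    """Bookkeeping for one recursion level."""

    best: SubRegionalPair
    generations_run: int
    best_fitness_trace: list[float]
    converged: bool


@dataclasses.dataclass
class ECResult:
    """Outcome of the recursive detection for one subject / ROI pair."""

    srps: list[SubRegionalPair]  # Bonferroni survivors, detection order
    detected: list[SubRegionalPair]  # all recorded pairs (|Z| >= z_stop)
    levels: list[ECLevel]
    rng_seed: int
    config: ECConfig

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def fitness_zscore(NC1: int, NC2: int, TC: int) -> tuple[float, float, float, float]:
    """Signed Z, fitness=|Z|, expected session-2 count, and binomial SD.

    When NC1 is 0 or TC the binomial SD degenerates to 0; P1 is then clamped
    to [0.5/TC, 1 - 0.5/TC] (a continuity correction) so that a total gain
    or loss from an empty/full baseline still scores, while NC2 == NC1 is
    always fitness 0 (no change).
    """
    if TC < 1:
        raise ValueError("TC must be >= 1")
    if not (0 <= NC1 <= TC and 0 <= NC2 <= TC):
        raise ValueError("edge counts must lie in [0, TC]")
    p1 = min(max(NC1 / TC, 0.5 / TC), 1.0 - 0.5 / TC)
    ec2 = p1 * TC
    sd = float(np.sqrt(TC * p1 * (1.0 - p1)))
    z = 0.0 if NC2 == NC1 else (NC2 - ec2) / sd
    return z, abs(z), ec2, sd


def count_connections(pair: SubRegionalPair, M: BinaryConnectivityMatrix | np.ndarray) -> int:
    """Number of 1-cells of ``M`` in the pair's |subA| x |subB| submatrix."""
    m = M.M if isinstance(M, BinaryConnectivityMatrix) else np.asarray(M)
    return int(m[np.ix_(pair.subA.members, pair.subB.members)].sum())


# ---------------------------------------------------------------------------
# gene-array helpers (internal population representation)
#
# A population is a pair of arrays: ``spatial`` (N, 6) mm coordinates
# (x1, y1, z1, x2, y2, z2) and ``lidx`` (N, 2) integer indices into the two
# L lattices.  All operators below are exactly the per-chromosome semantics,
# vectorised.


def _random_population(
    n: int, spaceA: ROISearchSpace, spaceB: ROISearchSpace, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    lo = np.r_[spaceA.bounds_lo, spaceB.bounds_lo]
    hi = np.r_[spaceA.bounds_hi, spaceB.bounds_hi]
    spatial = rng.uniform(lo, hi, size=(n, 6))
    lidx = np.c_[
        rng.integers(0, len(spaceA.lattice), size=n),
        rng.integers(0, len(spaceB.lattice), size=n),
    ]
    return spatial, lidx


def _mutate_arrays(
    spatial: np.ndarray,
    lidx: np.ndarray,
    cfg: ECConfig,
    spaceA: ROISearchSpace,
    spaceB: ROISearchSpace,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([cfg.dx1, cfg.dy1, cfg.dz1, cfg.dx2, cfg.dy2, cfg.dz2])
    lo = np.r_[spaceA.bounds_lo, spaceB.bounds_lo]
    hi = np.r_[spaceA.bounds_hi, spaceB.bounds_hi]
    child_sp = np.clip(rng.uniform(spatial - d, spatial + d), lo, hi)
    dl = np.array([cfg.dl1, cfg.dl2])
    child_li = rng.integers(lidx - dl, lidx + dl + 1)
    child_li = np.clip(child_li, 0, [len(spaceA.lattice) - 1, len(spaceB.lattice) - 1])
    return child_sp, child_li


def mutate(
    parent: Chromosome,
    cfg: ECConfig,
    rng: np.random.Generator,
    spaceA: ROISearchSpace,
    spaceB: ROISearchSpace,
) -> Chromosome:
    """Bounded uniform mutation of a single chromosome.

    Spatial genes move uniformly within +-(dx, dy, dz) mm and are clamped to
    the ROI's bounding cuboid; size genes move uniformly within +-dl lattice
    steps and are clamped to the lattice range.
    """
    spatial = np.array([[parent.x1, parent.y1, parent.z1, parent.x2, parent.y2, parent.z2]])
    lidx = np.array(
        [[spaceA.lattice.index_of(parent.l1), spaceB.lattice.index_of(parent.l2)]]
    )
    sp, li = _mutate_arrays(spatial, lidx, cfg, spaceA, spaceB, rng)
    return Chromosome(
        x1=sp[0, 0], y1=sp[0, 1], z1=sp[0, 2],
        l1=int(spaceA.lattice.values[li[0, 0]]),
        x2=sp[0, 3], y2=sp[0, 4], z2=sp[0, 5],
        l2=int(spaceB.lattice.values[li[0, 1]]),
    )


def select_population_elitist(pool: list[tuple], n_keep: int | None = None) -> list:
    """Keep the ``n_keep`` highest-fitness entries of a (chromosome, fitness) pool.

    Ties at the cutoff are broken by earlier pool position (stable order:
    parents before offspring).
    """
    if n_keep is None:
        n_keep = len(pool) // 2
    fit = np.array([f for _, f in pool], dtype=float)
    order = np.argsort(-fit, kind="stable")[:n_keep]
    return [pool[i][0] for i in order]


class _Evaluator:
    """Decode + count + score, memoised on the decoded voxel-set pair."""

    def __init__(self, M1: np.ndarray, M2: np.ndarray, spaceA: ROISearchSpace, spaceB: ROISearchSpace):
        self.M1 = M1
        self.M2 = M2
        self.spaceA = spaceA
        self.spaceB = spaceB
        self.cache: dict[tuple, tuple] = {}

    def _score(self, key: tuple) -> float:
        hit = self.cache.get(key)
        if hit is None:
            rootA, nA, rootB, nB = key
            mA = self.spaceA.members(rootA, nA - 1)
            mB = self.spaceB.members(rootB, nB - 1)
            sub1 = self.M1[mA]
            sub2 = self.M2[mA]
            nc1 = int(sub1[:, mB].sum())
            nc2 = int(sub2[:, mB].sum())
            z, fit, ec2, sd = fitness_zscore(nc1, nc2, nA * nB)
            hit = (fit, z, nc1, nc2, ec2, sd)
            self.cache[key] = hit
        return hit[0]

    def evaluate_batch(self, spatial: np.ndarray, lidx: np.ndarray) -> tuple[list[tuple], np.ndarray]:
        """Decoded keys and fitnesses for a whole gene-array population."""
        roots_a = self.spaceA.nearest_roots_batch(spatial[:, :3])
        roots_b = self.spaceB.nearest_roots_batch(spatial[:, 3:])
        ls_a = self.spaceA.lattice.values[lidx[:, 0]]
        ls_b = self.spaceB.lattice.values[lidx[:, 1]]
        keys = []
        fit = np.empty(len(spatial))
        for i in range(len(spatial)):
            ra, rb = int(roots_a[i]), int(roots_b[i])
            key = (
                ra,
                min(int(ls_a[i]) + 1, len(self.spaceA.bfs_order(ra))),
                rb,
                min(int(ls_b[i]) + 1, len(self.spaceB.bfs_order(rb))),
            )
            keys.append(key)
            fit[i] = self._score(key)
        return keys, fit

    def make_pair(self, key: tuple) -> SubRegionalPair:
        rootA, nA, rootB, nB = key
        fit, z, nc1, nc2, ec2, sd = self.cache[key]
        pair = SubRegionalPair(
            subA=self.spaceA.subregion(rootA, nA - 1),
            subB=self.spaceB.subregion(rootB, nB - 1),
            NC1=nc1, NC2=nc2, EC2=ec2, SD=sd, Z=z, fitness=fit,
            sign=int(np.sign(nc2 - nc1)),
        )
        return pair


def _as_matrix(M) -> np.ndarray:
    return M.M if isinstance(M, BinaryConnectivityMatrix) else np.asarray(M)


def run_ec_level(
    M1,
    M2,
    spaceA: ROISearchSpace,
    spaceB: ROISearchSpace,
    cfg: ECConfig,
    rng: np.random.Generator,
) -> ECLevel:
    """One evolutionary search level; returns the best-ever sub-regional pair."""
    M1 = _as_matrix(M1)
    M2 = _as_matrix(M2)
    if M1.shape != (len(spaceA.roi), len(spaceB.roi)) or M1.shape != M2.shape:
        raise ValueError("matrix dimensions do not match the ROI sizes")
    ev = _Evaluator(M1, M2, spaceA, spaceB)

    n = cfg.population_size
    spatial, lidx = _random_population(n, spaceA, spaceB, rng)
    keys, fit = ev.evaluate_batch(spatial, lidx)

    best_fit = -np.inf
    best_key = None
    stall = 0
    trace: list[float] = []
    generations = 0
    converged = False

    def _update_best() -> None:
        nonlocal best_fit, best_key, stall
        i = int(np.argmax(fit))
        if fit[i] > best_fit + _IMPROVE_TOL:
            best_fit = float(fit[i])
            best_key = keys[i]
            stall = 0
        else:
            stall += 1

    _update_best()
    trace.append(best_fit)

    while stall < cfg.stall_generations:
        if all(k == keys[0] for k in keys):
            converged = True
            break
        # reproduction: every parent yields offspring_per_parent children
        kids_sp = []
        kids_li = []
        for _ in range(cfg.offspring_per_parent):
            sp, li = _mutate_arrays(spatial, lidx, cfg, spaceA, spaceB, rng)
            kids_sp.append(sp)
            kids_li.append(li)
        child_sp = np.vstack(kids_sp)
        child_li = np.vstack(kids_li)
        child_keys, child_fit = ev.evaluate_batch(child_sp, child_li)

        # population-elitist selection over the pooled set (parents first)
        pool_sp = np.vstack([spatial, child_sp])
        pool_li = np.vstack([lidx, child_li])
        pool_fit = np.r_[fit, child_fit]
        pool_keys = keys + child_keys
        order = np.argsort(-pool_fit, kind="stable")[:n]
        spatial = pool_sp[order]
        lidx = pool_li[order]
        fit = pool_fit[order]
        keys = [pool_keys[i] for i in order]

        generations += 1
        _update_best()
        trace.append(best_fit)

    best = ev.make_pair(best_key)
    logger.debug(
        "level finished: %d generations, best |Z|=%.3f, converged=%s",
        generations, best_fit, converged,
    )
    return ECLevel(best=best, generations_run=generations, best_fitness_trace=trace, converged=converged)


def bonferroni_filter(srps: list[SubRegionalPair], alpha: float = 0.05) -> list[SubRegionalPair]:
    """Two-sided normal-tail p-values, Bonferroni-corrected over the recorded set.

    ``m`` is the number of pairs recorded in this run; survivors have
    corrected p < alpha.  Sets ``p_raw`` and ``p_corrected`` on every input.
    """
    m = len(srps)
    survivors = []
    for srp in srps:
        srp.p_raw = float(2.0 * stats.norm.sf(abs(srp.Z)))
        srp.p_corrected = float(min(1.0, m * srp.p_raw))
        if srp.p_corrected < alpha:
            survivors.append(srp)
    return survivors


def detect_all_srps(
    M1,
    M2,
    roiA: ROIDefinition | ROISearchSpace,
    roiB: ROIDefinition | ROISearchSpace,
    cfg: ECConfig,
    grid: VoxelGrid | None = None,
) -> ECResult:
    """Recursive detection of all significantly plastic sub-regional pairs.

    Levels run until the best fitness drops below ``cfg.z_stop``; each
    recorded pair's edges are zeroed in working copies of both matrices
    before the next level (edge blocking), so recorded pairs have pairwise
    disjoint edge support.  Recorded pairs are then Bonferroni-filtered.
    """
    spaceA = roiA if isinstance(roiA, ROISearchSpace) else ROISearchSpace(
        roiA, grid, l_min=cfg.l_min, l_step=cfg.l_step
    )
    spaceB = roiB if isinstance(roiB, ROISearchSpace) else ROISearchSpace(
        roiB, grid, l_min=cfg.l_min, l_step=cfg.l_step
    )
    M1w = _as_matrix(M1).copy()
    M2w = _as_matrix(M2).copy()

    rng = np.random.default_rng(cfg.rng_seed)
    levels: list[ECLevel] = []
    recorded: list[SubRegionalPair] = []
    while True:
        level = run_ec_level(M1w, M2w, spaceA, spaceB, cfg, rng)
        levels.append(level)
        if level.best.fitness < cfg.z_stop:
            break
        srp = level.best
        srp.level = len(levels)
        recorded.append(srp)
        logger.info(
            "level %d: recorded SRP |A|=%d |B|=%d NC1=%d NC2=%d |Z|=%.2f",
            srp.level, len(srp.subA), len(srp.subB), srp.NC1, srp.NC2, srp.fitness,
        )
        block = np.ix_(srp.subA.members, srp.subB.members)
        M1w[block] = 0
        M2w[block] = 0
        if cfg.max_recursion is not None and len(recorded) >= cfg.max_recursion:
            logger.warning("max_recursion=%d reached; stopping early", cfg.max_recursion)
            break

    survivors = bonferroni_filter(recorded, alpha=cfg.alpha)
    return ECResult(
        srps=survivors, detected=recorded, levels=levels,
        rng_seed=cfg.rng_seed, config=cfg,
    )
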