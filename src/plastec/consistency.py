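"""Run-to-run reliability of the detected sub-regional pairs.

Three complementary views of agreement between independent runs on the same
subject and ROI pair:

* max-matched Sorenson-dice overlap of the pairs' voxel sets (each pair's
  set is the ROI-tagged union of its two sub-regions, so a ROI-A voxel can
  never collide with the same grid coordinate in ROI-B);
* adjusted Rand index between the voxel-pair labelings the two runs induce
  on the full |A| x |B| grid of voxel pairs (label 0 = in no surviving pair);
* voxel-pair membership consistency: the percentage of voxel pairs whose
  binary in-any-surviving-pair status agrees, averaged over all unordered
  pairs of runs.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .encoding import SubRegionalPair

__all__ = [
    "RunComparison",
    "tagged_voxel_set",
    "dice",
    "dice_overlap_runs",
    "ari_voxel_pair_labelings",
    "voxelpair_consistency",
    "compare_runs",
]


@dataclasses.dataclass(frozen=True)
class RunComparison:
    dice_mean: float | None
    ari: float
    voxelpair_consistency_pct: float


def tagged_voxel_set(srp: SubRegionalPair) -> frozenset:
    """ROI-tagged union of the pair's two sub-regions' member indices."""
    return frozenset(("A", int(v)) for v in srp.subA.members) | frozenset(
        ("B", int(v)) for v in srp.subB.members
    )


def dice(x: frozenset | set, y: frozenset | set) -> float:
    """Sorenson-dice index 2|X∩Y|/(|X|+|Y|)."""
    if not x and not y:
        return 1.0
    return 2.0 * len(x & y) / (len(x) + len(y))


def dice_overlap_runs(
    srps_run1: list[SubRegionalPair], srps_run2: list[SubRegionalPair]
) -> float | None:
    """Mean of the maximal dice overlaps, both directions pooled.

    Every pair in run 1 is scored by its best dice match in run 2 and vice
    versa; the mean runs over all these maxima.  Undefined (None) if either
    run detected nothing.
    """
    if not srps_run1 or not srps_run2:
        return None
    sets1 = [tagged_voxel_set(s) for s in srps_run1]
    sets2 = [tagged_voxel_set(s) for s in srps_run2]
    maxima = [max(dice(x, y) for y in sets2) for x in sets1]
    maxima += [max(dice(y, x) for x in sets1) for y in sets2]
    return float(np.mean(maxima))


def _labeling(srps: list[SubRegionalPair], n_a: int, n_b: int) -> np.ndarray:
    """Voxel-pair labels over A x B: 0 outside, SRP index (1-based) inside.

    Edge supports of surviving pairs are disjoint by blocking, so the label
    of a voxel pair is well defined.
    """
    lab = np.zeros((n_a, n_b), dtype=np.int32)
    for s, srp in enumerate(srps, start=1):
        lab[np.ix_(srp.subA.members, srp.subB.members)] = s
    return lab.ravel()


def ari_voxel_pair_labelings(
    srps_run1: list[SubRegionalPair],
    srps_run2: list[SubRegionalPair],
    n_a: int,
    n_b: int,
) -> float:
    """Adjusted Rand index between two runs' voxel-pair labelings."""
    t = _labeling(srps_run1, n_a, n_b)
    u = _labeling(srps_run2, n_a, n_b)
    return float(adjusted_rand_score(t, u))


def voxelpair_consistency(
    runs: list[list[SubRegionalPair]], n_a: int, n_b: int
) -> float:
    """Mean pairwise percent agreement of binary voxel-pair membership."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    member = [(_labeling(r, n_a, n_b) > 0) for r in runs]
    pcts = [
        100.0 * float(np.mean(mi == mj))
        for mi, mj in itertools.combinations(member, 2)
    ]
    return float(np.mean(pcts))


def compare_runs(runs: list[list[SubRegionalPair]], n_a: int, n_b: int) -> dict:
    """Summary dict over all unordered run pairs: dice, ARI (mean +- sd), consistency."""
    dices = []
    aris = []
    for r1, r2 in itertools.combinations(runs, 2):
        d = dice_overlap_runs(r1, r2)
        if d is not None:
            dices.append(d)
        aris.append(ari_voxel_pair_labelings(r1, r2, n_a, n_b))
    return {
        "n_runs": len(runs),
        "dice_mean": float(np.mean(dices)) if dices else None,
        "dice_sd": float(np.std(dices)) if dices else None,
        "ari_mean": float(np.mean(aris)),
        "ari_sd": float(np.std(aris)),
        "voxelpair_consistency_pct": voxelpair_consistency(runs, n_a, n_b),
    }
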