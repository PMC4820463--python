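"""Subject-level plasticity estimates from surviving sub-regional pairs.

The percentage of all possible voxel-wise connections between the ROI pair
that contribute to positive (edges gained) and negative (edges lost)
plasticity, plus the overall gained+lost count gl1.  Worked example: ROIs of
100 and 500 voxels (50000 possible connections) with three surviving pairs
gaining 10000 and 1000 and losing 5000 give 22% positive and 10% negative
plasticity.
"""

from __future__ import annotations

import dataclasses

from .encoding import SubRegionalPair

__all__ = ["PlasticityEstimate", "estimate_plasticity"]


@dataclasses.dataclass(frozen=True)
class PlasticityEstimate:
    pct_positive: float
    pct_negative: float
    gl1: int
    total_possible: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def estimate_plasticity(
    srps: list[SubRegionalPair], n_roi_a: int, n_roi_b: int
) -> PlasticityEstimate:
    """Percent of possible ROI-pair edges contributing to each plasticity sign.

    ``srps`` are the Bonferroni survivors; pairs with NC1 == NC2 contribute
    to neither sign.  Edge supports are disjoint by blocking, so the two
    percentages sum to at most 100.
    """
    total = n_roi_a * n_roi_b
    if total == 0:
        raise ValueError("ROI sizes must be positive")
    gains = sum(srp.delta for srp in srps if srp.delta > 0)
    losses = sum(-srp.delta for srp in srps if srp.delta < 0)
    return PlasticityEstimate(
        pct_positive=100.0 * gains / total,
        pct_negative=100.0 * losses / total,
        gl1=int(gains + losses),
        total_possible=int(total),
    )
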