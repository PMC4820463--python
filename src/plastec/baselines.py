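"""Baseline analyses: ROI-signal averaging and simple total-edge-count change.

These are the two conventional approaches the sub-regional search improves
on.  Averaging collapses each ROI to its mean time course and correlates the
two means (Fisher z for group tests); the simple voxel-level approach counts
total binary edges per session, whose absolute net change is gl2.  When
gains and losses roughly cancel, gl2 is near zero even though substantial
plasticity exists — the motivating failure mode of net-change summaries.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import BinaryConnectivityMatrix
from .io import SessionTimeSeries

__all__ = [
    "BaselineResult",
    "averaging_connectivity",
    "edge_count_change",
    "paired_ttest_fisher",
    "paired_wilcoxon",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BaselineResult:
    method: str  # "averaging" or "edge_count"
    session1_stat: float
    session2_stat: float
    gl2: int | None = None


def averaging_connectivity(tsA: SessionTimeSeries, tsB: SessionTimeSeries) -> tuple[float, float]:
    """Pearson r between the two ROI-mean signals and its Fisher z transform.

    A constant mean series is degenerate: returns (nan, nan) with a warning.
    Perfect correlation maps to an infinite Fisher z, which is passed through
    for the caller to flag.
    """
    a = np.asarray(tsA.data, dtype=float).mean(axis=0)
    b = np.asarray(tsB.data, dtype=float).mean(axis=0)
    if a.shape != b.shape:
        raise ValueError("sessions disagree in number of time points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant ROI-mean series; averaging connectivity undefined")
        return float("nan"), float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    r = min(max(r, -1.0), 1.0)
    with np.errstate(divide="ignore"):
        z = float(np.arctanh(r))
    return r, z


def edge_count_change(M1: BinaryConnectivityMatrix | np.ndarray, M2) -> int:
    """gl2: absolute net change in total edge count between sessions."""
    m1 = M1.M if isinstance(M1, BinaryConnectivityMatrix) else np.asarray(M1)
    m2 = M2.M if isinstance(M2, BinaryConnectivityMatrix) else np.asarray(M2)
    if m1.shape != m2.shape:
        raise ValueError("matrices must have equal dimensions")
    return int(abs(int(m2.sum()) - int(m1.sum())))


# ---------------------------------------------------------------------------
# thin group-level reporting utilities over per-subject tables


def paired_ttest_fisher(r1: np.ndarray, r2: np.ndarray) -> pd.Series:
    """Paired t-test on Fisher-z transformed per-subject correlations."""
    z1 = np.arctanh(np.asarray(r1, dtype=float))
    z2 = np.arctanh(np.asarray(r2, dtype=float))
    res = stats.ttest_rel(z1, z2)
    return pd.Series({"statistic": float(res.statistic), "pvalue": float(res.pvalue), "n": len(z1)})


def paired_wilcoxon(x1: np.ndarray, x2: np.ndarray) -> pd.Series:
    """Paired Wilcoxon signed-rank test on per-subject statistics."""
    res = stats.wilcoxon(np.asarray(x1, dtype=float), np.asarray(x2, dtype=float))
    return pd.Series({"statistic": float(res.statistic), "pvalue": float(res.pvalue), "n": len(x1)})
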