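"""Per-session binary voxel-level connectivity matrices.

For a ROI pair (A, B) and one session, every voxel of A is correlated with
every voxel of B (Pearson).  The |A| x |B| field of p-values is screened with
a Benjamini-Hochberg FDR test at q = 0.05 over the full family of |A| x |B|
tests, negative correlations are discarded, and the surviving cells are set
to 1.  The resulting binary matrices M1 (session 1) and M2 (session 2) are
the only inputs the evolutionary search consumes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SessionTimeSeries

__all__ = [
    "BinaryConnectivityMatrix",
    "pearson_with_pvalue",
    "pearson_matrix",
    "bh_fdr_mask",
    "build_binary_matrix",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BinaryConnectivityMatrix:
    """|A| x |B| matrix of FDR-surviving positive voxel-wise edges."""

    session_id: int
    M: np.ndarray  # uint8, entries in {0, 1}
    n_samples: int

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        if M.ndim != 2:
            raise ValueError("connectivity matrix must be 2-D")
        if not np.isin(M, (0, 1)).all():
            raise ValueError("connectivity matrix entries must be 0 or 1")
        object.__setattr__(self, "M", M.astype(np.uint8))

    @property
    def n_edges(self) -> int:
        return int(self.M.sum())


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value for a single voxel pair.

    The p-value is the classical t-transform ``t = r sqrt(T-2)/sqrt(1-r^2)``
    with T-2 degrees of freedom.  Zero-variance input is degenerate and
    returns (nan, 1.0); the matrix builder treats it as "no edge".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance series in correlation; treated as no edge")
        return float("nan"), 1.0
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_matrix(tsA: SessionTimeSeries, tsB: SessionTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlations between two ROIs' voxel series.

    Returns (R, P): |A| x |B| correlation and two-sided p-value matrices.
    Rows with zero variance yield nan correlation and p = 1.
    """
    A = np.asarray(tsA.data, dtype=float)
    B = np.asarray(tsB.data, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"sessions disagree in T: {A.shape[1]} vs {B.shape[1]}")
    T = A.shape[1]

    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A**2).sum(axis=1))
    sb = np.sqrt((B**2).sum(axis=1))
    dead_a = sa == 0
    dead_b = sb == 0
    if dead_a.any() or dead_b.any():
        logger.warning(
            "%d ROI-A and %d ROI-B voxels have zero variance; their edges are dropped",
            int(dead_a.sum()),
            int(dead_b.sum()),
        )
    sa[dead_a] = 1.0
    sb[dead_b] = 1.0

    R = (A / sa[:, None]) @ (B / sb[:, None]).T
    np.clip(R, -1.0, 1.0, out=R)
    R[dead_a, :] = np.nan
    R[:, dead_b] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((T - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(t), df=T - 2)
    P[np.isnan(R)] = 1.0
    P[np.abs(R) >= 1.0] = 0.0  # perfectly collinear pair
    return R, P


def bh_fdr_mask(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of surviving hypotheses."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject.reshape(np.shape(pvalues))


def build_binary_matrix(
    tsA: SessionTimeSeries,
    tsB: SessionTimeSeries,
    q: float = 0.05,
    session_id: int | None = None,
) -> BinaryConnectivityMatrix:
    """Build the binary connectivity matrix for one session of one ROI pair.

    All |A| x |B| correlations are computed, the FDR mask is applied over the
    full family of p-values, cells with non-positive correlation are zeroed,
    and the survivors are set to 1.
    """
    R, P = pearson_matrix(tsA, tsB)
    keep = bh_fdr_mask(P, q=q)
    with np.errstate(invalid="ignore"):
        keep &= R > 0
    return BinaryConnectivityMatrix(
        session_id=session_id if session_id is not None else tsA.session_id,
        M=keep.astype(np.uint8),
        n_samples=tsA.n_samples,
    )
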