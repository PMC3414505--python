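"""Benjamini-Hochberg FDR thresholding and map binarisation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThresholdResult", "bh_fdr", "binarize"]


@dataclass
class ThresholdResult:
    """Outcome of an FDR thresholding pass."""

    q: float
    p_threshold: float  # largest rejected p-value (0.0 if nothing rejected)
    reject: np.ndarray  # bool, same shape as the input p-values
    n_rejected: int


def bh_fdr(pvals: np.ndarray, q: float) -> ThresholdResult:
    """Benjamini-Hochberg step-up at level ``q``.

    Finds the largest k with p_(k) <= k*q/m and rejects every p-value at or
    below p_(k) (ties at the threshold are rejected).  NaN entries (invalid
    voxels) are excluded from m and never rejected.  Valid under
    independence or positive dependence of the tests.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value collection")
    flat = pvals.ravel()
    valid = ~np.isnan(flat)
    if not valid.any():
        raise ValueError("no valid p-values")
    pv = flat[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = pv.size
    order = np.sort(pv)
    crit = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(order <= crit)
    if passing.size == 0:
        reject = np.zeros(flat.shape, dtype=bool)
        return ThresholdResult(q=q, p_threshold=0.0, reject=reject.reshape(pvals.shape), n_rejected=0)
    p_thr = order[passing[-1]]
    reject = np.zeros(flat.shape, dtype=bool)
    reject[valid] = pv <= p_thr
    reject = reject.reshape(pvals.shape)
    return ThresholdResult(
        q=q, p_threshold=float(p_thr), reject=reject, n_rejected=int(reject.sum())
    )


def binarize(stat: np.ndarray, threshold: float, direction: str = ">=") -> np.ndarray:
    """Binary activation map: 1 where the statistic passes the threshold.

    ``direction`` is one of ``">="``, ``">"``, ``"<="``, ``"<"``.  NaN
    entries never pass.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    stat = np.asarray(stat, dtype=float)
    ops = {
        ">=": np.greater_equal,
        ">": np.greater,
        "<=": np.less_equal,
        "<": np.less,
    }
    try:
        op = ops[direction]
    except KeyError:
        raise ValueError(f"unknown direction {direction!r}") from None
    with np.errstate(invalid="ignore"):
        out = op(stat, threshold)
    out &= ~np.isnan(stat)
    return out.astype(np.uint8)
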