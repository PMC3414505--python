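"""Inter-subject correlation statistic and its resampling null.

The ISC statistic at a voxel is the average of the Pearson correlations
between all subject pairs' time-series there: with N_s subjects that is
N_s*(N_s-1)/2 pairwise coefficients (666 for the 37-subject study cohort).
Because averaged correlations of temporally autocorrelated series do not
follow a textbook null, inference is non-parametric: a null distribution of
the statistic is built by independently circular-time-shifting each
subject's series, which destroys any inter-subject alignment while
preserving every series' autocorrelation (its periodogram) exactly.  One
pooled null, sampled over a random subset of in-mask voxels, is shared
across voxels; right-tail p-values use the add-one permutation convention
p = (#{null >= observed} + 1) / (B + 1).

Vectorisation note: each series is centred and scaled to unit Euclidean
norm once, after which any pairwise correlation is a plain dot product and
the sum over all pairs at a voxel is (||sum_j u_j||^2 - N_s) / 2.  Circular
shifting commutes with that normalisation, so the null reuses the same
standardised arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "pairwise_corr",
    "n_pairs",
    "isc_statistic",
    "NullDistribution",
    "resample_null",
    "pvalues",
]


def pairwise_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation between two equal-length time-courses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(np.sum(xc**2))
    ny = np.sqrt(np.sum(yc**2))
    # relative tolerance: a constant series may miss exact zero by rounding
    tol_x = 1e-10 * np.abs(x).max() if x.size else 0.0
    tol_y = 1e-10 * np.abs(y).max() if y.size else 0.0
    if nx <= tol_x or ny <= tol_y or nx == 0 or ny == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.dot(xc, yc) / (nx * ny))


def n_pairs(n_subjects: int) -> int:
    """Number of subject pairs averaged by the ISC statistic."""
    return n_subjects * (n_subjects - 1) // 2


def _standardize(data: np.ndarray) -> np.ndarray:
    """Centre and unit-norm each (subject, voxel) series; NaN where constant.

    A constant series can miss a zero norm by floating-point rounding of its
    mean, so degeneracy is judged relative to the series' magnitude.
    """
    u = data - data.mean(axis=-1, keepdims=True)
    norms = np.sqrt(np.sum(u**2, axis=-1, keepdims=True))
    tol = 1e-10 * np.abs(data).max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(norms > tol, u / norms, np.nan)
    return u


def _isc_from_standardized(u: np.ndarray) -> np.ndarray:
    n_sub = u.shape[0]
    total = np.sum(np.sum(u, axis=0) ** 2, axis=-1)
    return (total - n_sub) / (2.0 * n_pairs(n_sub))


def isc_statistic(data: np.ndarray) -> np.ndarray:
    """ISC map for ``data`` of shape (n_subjects, n_voxels, T).

    Returns the per-voxel average over all subject pairs' correlations.
    Voxels where any subject's series has zero variance are NaN (excluded
    from analysis by mask policy).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (n_subjects, n_voxels, T) data")
    if data.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if data.shape[-1] < 3:
        raise ValueError("need at least 3 time samples")
    return _isc_from_standardized(_standardize(data))


@dataclass
class NullDistribution:
    """Sorted resampling sample of the ISC statistic."""

    values: np.ndarray  # sorted, length B

    @property
    def b(self) -> int:
        return self.values.size


def resample_null(
    data: np.ndarray,
    b: int,
    seed,
    n_sample_voxels: int = 5000,
    min_shift: int = 10,
    highpass_cutoff: float | None = None,
    tr: float | None = None,
) -> NullDistribution:
    """Pooled circular-shift null of the ISC statistic.

    Each resampling round draws one independent circular shift offset per
    subject (uniform over [min_shift, T - min_shift]), recomputes the ISC
    statistic at the sampled voxels, and pools the values; rounds are
    repeated until ``b`` realizations are collected.  Shifting preserves
    each series' periodogram exactly, so the null respects the temporal
    autocorrelation of the data.

    High-pass filtering is not invariant under circular shifts (the drift
    basis is not periodic), so surrogates must be built by shifting FIRST
    and filtering after, exactly as the observed data were filtered.  When
    ``highpass_cutoff`` (and ``tr``) are given, ``data`` must be the
    pre-high-pass series and every surrogate is filtered after shifting;
    the observed statistic should then be computed from
    ``highpass(data, highpass_cutoff, tr)``.  Without a cutoff the input is
    used as-is.
    """
    if b < 1000:
        raise ValueError("need at least 1000 null realizations")
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (n_subjects, n_voxels, T) data")
    n_sub, _, n_t = data.shape
    if n_t <= 2 * min_shift:
        raise ValueError(
            f"series length {n_t} too short for min_shift {min_shift}"
        )
    rng = np.random.default_rng(seed)
    u = _standardize(data)
    valid = ~np.isnan(u).any(axis=(0, 2))
    if not valid.any():
        raise ValueError("no voxels with nonzero variance")
    idx = np.flatnonzero(valid)
    if idx.size > n_sample_voxels:
        idx = rng.choice(idx, size=n_sample_voxels, replace=False)

    if highpass_cutoff is not None:
        if tr is None:
            raise ValueError("tr is required with highpass_cutoff")
        from .preprocess import _residual_projector

        proj = _residual_projector(n_t, float(tr), float(highpass_cutoff)).T
        raw = data[:, idx, :]
    else:
        proj = None
        u = u[:, idx, :]

    n_voxels = idx.size
    n_rounds = int(np.ceil(b / n_voxels))
    chunks = []
    for _ in range(n_rounds):
        shifts = rng.integers(min_shift, n_t - min_shift, endpoint=True, size=n_sub)
        shifted_sum = np.zeros((n_voxels, n_t))
        if proj is None:
            for j in range(n_sub):
                shifted_sum += np.roll(u[j], shifts[j], axis=-1)
        else:
            for j in range(n_sub):
                surrogate = np.roll(raw[j], shifts[j], axis=-1) @ proj
                shifted_sum += _standardize(surrogate[None])[0]
        total = np.sum(shifted_sum**2, axis=-1)
        chunks.append((total - n_sub) / (2.0 * n_pairs(n_sub)))
    values = np.concatenate(chunks)[:b]
    values.sort()
    return NullDistribution(values=values)


def pvalues(isc: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Right-tail add-one p-values of observed ISC values against the null.

    p = (#{null >= observed} + 1) / (B + 1); NaN (invalid) voxels propagate.
    """
    isc = np.asarray(isc, dtype=float)
    if null.b == 0:
        raise ValueError("empty null distribution")
    flat = isc.ravel()
    out = np.full(flat.shape, np.nan)
    finite = np.isfinite(flat)
    ge = null.b - np.searchsorted(null.values, flat[finite], side="left")
    out[finite] = (ge + 1.0) / (null.b + 1.0)
    return out.reshape(isc.shape)
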