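"""Reference model-based analysis: per-subject GLM and group z-map.

Each subject's voxel time-series is regressed on a design matrix holding the
high-passed boxcar-convolved-with-HRF task regressor, its temporal
derivative (a nuisance column absorbing small latency differences) and an
intercept.  Serial correlation is handled by voxel-wise AR(1) prewhitening:
the lag-1 autocorrelation of the OLS residuals is estimated and the model is
refit on Cochrane-Orcutt transformed data.  Group inference is the
summary-statistics approach: a one-sample t across subjects' task betas per
voxel, converted to a z statistic by matching tail probabilities and capped
at +/- 8.2 so later map comparisons never meet an infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .design import DesignSpec, boxcar_from_events
from .hrf import HRFParams, make_hrf_kernel
from .preprocess import PreprocParams, highpass

__all__ = [
    "DesignMatrix",
    "SubjectGLMResult",
    "build_design",
    "design_matrix_from_events",
    "fit_subject",
    "group_zmap",
    "zmap_pvalues",
    "Z_CAP",
]

Z_CAP = 8.2


@dataclass(frozen=True)
class DesignMatrix:
    """Columns: task regressor, temporal derivative, intercept."""

    matrix: np.ndarray  # (n_volumes, 3)
    names: tuple[str, ...] = ("task", "task_derivative", "intercept")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SubjectGLMResult:
    """Per-voxel task-effect estimate from one subject's fit."""

    beta: np.ndarray  # (n_voxels,) effect of the task regressor
    variance: np.ndarray  # (n_voxels,) estimated var(beta)
    dof: int
    ar_coef: np.ndarray | None = None  # (n_voxels,) AR(1) estimate, if prewhitened


def design_matrix_from_events(
    events: np.ndarray,
    n_volumes: int,
    tr: float,
    hrf: HRFParams,
    preproc: PreprocParams | None = None,
) -> DesignMatrix:
    """Design matrix for an arbitrary retained-volume timeline.

    The task column is the high-passed boxcar*HRF; the derivative column is
    the high-passed finite difference of the pre-high-pass task column.  The
    same high-pass operator used on the data must be applied to the model,
    so ``preproc`` defaults to the study's 60-s cutoff.
    """
    if preproc is None:
        preproc = PreprocParams()
    boxcar = boxcar_from_events(events, n_volumes, tr)
    kernel = make_hrf_kernel(hrf, tr)
    main_raw = np.convolve(boxcar, kernel)[:n_volumes]
    deriv_raw = np.gradient(main_raw, tr)
    main = highpass(main_raw, preproc.highpass_cutoff, tr)
    deriv = highpass(deriv_raw, preproc.highpass_cutoff, tr)
    if np.allclose(main, main[0]):
        raise ValueError("task regressor is constant; design is degenerate")
    matrix = np.column_stack([main, deriv, np.ones(n_volumes)])
    return DesignMatrix(matrix=matrix)


def build_design(
    events: np.ndarray,
    design: DesignSpec,
    hrf: HRFParams,
    preproc: PreprocParams | None = None,
) -> DesignMatrix:
    """Build the design matrix for a block design's retained timeline."""
    return design_matrix_from_events(
        events, design.n_volumes, design.tr, hrf, preproc
    )


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched OLS of (V, T) data on (T, p) design; returns beta, resid, var."""
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T  # (V, p)
    resid = y - beta @ x.T
    dof = x.shape[0] - x.shape[1]
    sigma2 = np.sum(resid**2, axis=-1) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    var_main = sigma2 * xtx_inv[0, 0]
    return beta, resid, var_main


def fit_subject(
    data: np.ndarray,
    design: DesignMatrix | np.ndarray,
    prewhiten: bool = True,
    ar_coef: float | np.ndarray | None = None,
) -> SubjectGLMResult:
    """Fit the GLM at every voxel of one subject.

    ``data`` is any array with time in the last axis; it is flattened to
    (n_voxels, T).  With ``prewhiten`` the AR(1) coefficient is estimated
    from the OLS residuals per voxel and a Cochrane-Orcutt refit is
    performed; voxels with a negligible coefficient keep the plain fit.
    ``ar_coef`` overrides the estimate (diagnostics/testing).
    """
    x = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design, float)
    if x.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    n_t, n_p = x.shape
    if np.linalg.matrix_rank(x) < n_p:
        raise ValueError("design matrix is rank deficient")
    y = np.asarray(data, dtype=float)
    if y.shape[-1] != n_t:
        raise ValueError(
            f"time axis ({y.shape[-1]}) does not match design rows ({n_t})"
        )
    y = y.reshape(-1, n_t)

    beta, resid, var_main = _ols(y, x)
    dof = n_t - n_p
    if not prewhiten:
        return SubjectGLMResult(beta=beta[:, 0], variance=var_main, dof=dof)

    if ar_coef is None:
        denom = np.sum(resid**2, axis=-1)
        denom = np.where(denom == 0, 1.0, denom)
        rho = np.sum(resid[:, 1:] * resid[:, :-1], axis=-1) / denom
        rho = np.clip(rho, -0.99, 0.99)
    else:
        rho = np.broadcast_to(np.asarray(ar_coef, dtype=float), y.shape[:1]).copy()

    out_beta = beta[:, 0].copy()
    out_var = var_main.copy()
    needs = np.abs(rho) >= 1e-8
    if np.any(needs):
        ys = y[needs, 1:] - rho[needs, None] * y[needs, :-1]
        xs = x[None, 1:, :] - rho[needs, None, None] * x[None, :-1, :]
        xtx = np.einsum("vtp,vtq->vpq", xs, xs)
        xty = np.einsum("vtp,vt->vp", xs, ys)
        beta_w = np.linalg.solve(xtx, xty[..., None])[..., 0]
        resid_w = ys - np.einsum("vtp,vp->vt", xs, beta_w)
        dof_w = (n_t - 1) - n_p
        sigma2 = np.sum(resid_w**2, axis=-1) / dof_w
        cov = np.linalg.inv(xtx)
        out_beta[needs] = beta_w[:, 0]
        out_var[needs] = sigma2 * cov[:, 0, 0]
    return SubjectGLMResult(
        beta=out_beta, variance=out_var, dof=(n_t - 1) - n_p, ar_coef=rho
    )


def group_zmap(
    results: Sequence[SubjectGLMResult] | np.ndarray, cap: float = Z_CAP
) -> np.ndarray:
    """Group z statistic per voxel from the subjects' task betas.

    One-sample t across subjects, converted to z by matching upper-tail
    probabilities of the t and standard-normal distributions, then capped at
    ``+/- cap``.  Voxels where every subject's beta is zero give z = 0;
    nonzero mean with zero spread hits the cap.
    """
    if isinstance(results, np.ndarray):
        betas = np.asarray(results, dtype=float)
    else:
        betas = np.stack([r.beta for r in results])
    if betas.ndim != 2:
        raise ValueError("expected betas of shape (n_subjects, n_voxels)")
    n = betas.shape[0]
    if n < 2:
        raise ValueError("group analysis needs at least two subjects")
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p_tail = stats.t.sf(np.abs(t), df)
    z = -special.ndtri(p_tail)  # positive magnitude; ndtri(0) -> -inf, capped below
    z = np.sign(t) * z
    z[np.isnan(t)] = np.where(mean[np.isnan(t)] == 0, 0.0, np.inf)
    z[(sd == 0) & (mean != 0)] = np.inf * np.sign(mean[(sd == 0) & (mean != 0)])
    return np.clip(z, -cap, cap)


def zmap_pvalues(z: np.ndarray) -> np.ndarray:
    """One-sided (activation direction) p-values for a z-map."""
    return stats.norm.sf(np.asarray(z, dtype=float))
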