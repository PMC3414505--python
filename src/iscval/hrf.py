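"""Canonical haemodynamic response function and expected BOLD time-courses.

The HRF is parameterised by its temporal moments (mean lag and standard
deviation) and realised as a gamma density: mean = k*theta and variance =
k*theta**2 give shape k = (lag/sd)**2 and scale theta = sd**2/lag, i.e. the
default lag 6 s / sd 3 s kernel is a gamma with shape 4 and scale 1.5 s.
The discrete kernel is normalised to unit sum so that a sustained boxcar
plateaus at the boxcar amplitude, which keeps the SNR bookkeeping of the
simulations interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignSpec, make_boxcar

__all__ = ["HRFParams", "make_hrf_kernel", "make_signal"]


@dataclass(frozen=True)
class HRFParams:
    """Moment parameterisation of the haemodynamic response.

    Parameters
    ----------
    phase
        Onset delay in seconds before the response begins.
    sd
        Standard deviation (temporal dispersion) of the response, seconds.
    mean_lag
        First moment of the response, seconds.
    kernel_length
        Support of the discrete kernel, seconds.
    """

    phase: float = 0.0
    sd: float = 3.0
    mean_lag: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.mean_lag <= 0:
            raise ValueError("mean_lag must be positive")
        if self.kernel_length <= 0:
            raise ValueError("kernel_length must be positive")

    @property
    def gamma_shape(self) -> float:
        return (self.mean_lag / self.sd) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.sd**2 / self.mean_lag


def make_hrf_kernel(hrf: HRFParams, tr: float) -> np.ndarray:
    """Sample the gamma HRF at the repetition time and unit-sum normalise."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, hrf.kernel_length + 0.5 * tr, tr)
    kernel = stats.gamma.pdf(t - hrf.phase, a=hrf.gamma_shape, scale=hrf.gamma_scale)
    total = kernel.sum()
    if total <= 0:
        raise ValueError("HRF kernel has no mass on the sampled support")
    return kernel / total


def make_signal(design: DesignSpec, hrf: HRFParams) -> np.ndarray:
    """Expected BOLD time-course: boxcar convolved with the HRF kernel.

    Causal convolution truncated to the retained-volume length; there is no
    pre-stimulus padding, so the response to the first block ramps up from
    zero exactly as it would in a run starting at rest.
    """
    boxcar = make_boxcar(design).astype(float)
    if boxcar.size == 0:
        return boxcar
    kernel = make_hrf_kernel(hrf, design.tr)
    return np.convolve(boxcar, kernel)[: boxcar.size]
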