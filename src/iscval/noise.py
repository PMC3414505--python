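"""Pink (1/f) noise synthesis and SNR-calibrated rescaling.

Pink noise is generated by spectral synthesis: a white Gaussian spectrum is
shaped by 1/sqrt(f) (so the power spectral density falls as 1/f), the DC bin
is zeroed, and the series is returned to the time domain.  This gives exact
control of the PSD slope over the whole resolvable band, which is what the
noise model is meant to encode about empirical BOLD noise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pink_noise", "pink_noise_matrix", "signal_power", "scale_noise_to_snr"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def pink_noise_matrix(n_series: int, n_samples: int, seed) -> np.ndarray:
    """Generate ``n_series`` independent zero-mean pink-noise rows.

    All rows are drawn from a single generator stream, so a fixed seed gives
    a bit-identical matrix.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples for a resolvable 1/f band")
    rng = _as_rng(seed)
    white = rng.standard_normal((n_series, n_samples))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum *= shaping
    series = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    series -= series.mean(axis=-1, keepdims=True)
    return series


def pink_noise(n_samples: int, seed) -> np.ndarray:
    """One zero-mean pink-noise series of length ``n_samples``."""
    return pink_noise_matrix(1, n_samples, seed)[0]


def signal_power(x: np.ndarray) -> float:
    """Mean-square power of a time-course (DC included)."""
    x = np.asarray(x, dtype=float)
    return float(np.mean(np.square(x)))


def scale_noise_to_snr(
    signal: np.ndarray, noise: np.ndarray, snr: float
) -> np.ndarray:
    """Rescale ``noise`` so power(noise) = power(signal) / snr exactly.

    ``snr`` is the signal-to-noise power ratio; the study's noise levels
    100/200/500/1000x the signal power correspond to snr 0.01 ... 0.001.
    Rescaling is a scalar multiplication, so the noise's correlation
    structure is untouched.  ``noise`` may be 1-D or (n_series, n_samples);
    in the latter case every row is calibrated individually.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    p_signal = signal_power(signal)
    if p_signal == 0:
        raise ValueError("signal has zero power; SNR is undefined")
    noise = np.asarray(noise, dtype=float)
    p_noise = np.mean(np.square(noise), axis=-1, keepdims=noise.ndim > 1)
    if np.any(p_noise == 0):
        raise ValueError("noise has zero power; cannot rescale")
    return noise * np.sqrt(p_signal / snr / p_noise)
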