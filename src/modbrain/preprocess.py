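"""Temporal denoising and empirical covariance structures.

The denoising chain, applied row-wise (per ROI), is: linear detrend ->
zero-phase band-pass (default 0.0025-0.05 Hz) -> zero-phase spectral notch
(default 0.03 +/- 0.002 Hz) -> confound regression -> z-scoring.  The notch
is realized in the frequency domain by zeroing DFT bins inside the notch
band, which is zero-phase by construction; the band-pass is a Butterworth
design applied forward-backward.  The per-run covariance structure is
K = X X', optionally divided by t so that z-scored rows give unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "CovarianceStructure",
    "bandpass_notch_filter",
    "denoise_timeseries",
    "empirical_covariance",
    "truncate_run",
    "LOW_HZ",
    "HIGH_HZ",
    "NOTCH_HZ",
    "NOTCH_HALF_WIDTH_HZ",
]

LOW_HZ = 0.05         # low-pass cutoff
HIGH_HZ = 0.0025      # high-pass cutoff
NOTCH_HZ = 0.03       # artifactual pure frequency removed from all runs
NOTCH_HALF_WIDTH_HZ = 0.002
FILTER_ORDER = 2      # even-order Butterworth, applied forward-backward


@dataclass
class CovarianceStructure:
    """Symmetric PSD p-by-p covariance of one run."""

    K: np.ndarray
    t_used: int
    normalized: bool

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K must be symmetric")

    @property
    def p(self) -> int:
        return self.K.shape[0]


def min_filterable_length(order: int = FILTER_ORDER) -> int:
    """Shortest series the forward-backward band-pass accepts."""
    sos = signal.butter(order, [0.1, 0.4], btype="bandpass", output="sos")
    # sosfiltfilt requires t > padlen = 3 * (2 * n_sections + 1)
    return 3 * (2 * sos.shape[0] + 1) + 1


def bandpass_notch_filter(X: np.ndarray, tr_seconds: float, *,
                          low_hz: float = LOW_HZ, high_hz: float = HIGH_HZ,
                          notch_hz: float | None = NOTCH_HZ,
                          notch_half_width_hz: float = NOTCH_HALF_WIDTH_HZ,
                          order: int = FILTER_ORDER) -> np.ndarray:
    """Detrend, band-pass and notch-filter rows of ``X``; all stages zero-phase.

    Returns the filtered matrix without confound regression or z-scoring;
    useful for inspecting the filter response itself.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = X.shape[1]
    fs = 1.0 / tr_seconds
    nyquist = fs / 2.0
    if low_hz >= nyquist:
        raise ValueError(f"sampling rate {fs:.4f} Hz cannot resolve {low_hz} Hz low-pass")

    Y = signal.detrend(X, axis=1, type="linear")

    sos = signal.butter(order, [high_hz / nyquist, low_hz / nyquist],
                        btype="bandpass", output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if t <= padlen:
        raise ValueError(f"series too short for the filter: t={t} <= padlen={padlen}")
    Y = signal.sosfiltfilt(sos, Y, axis=1, padlen=padlen)

    if notch_hz is not None:
        freqs = np.fft.rfftfreq(t, d=tr_seconds)
        spectrum = np.fft.rfft(Y, axis=1)
        band = np.abs(freqs - notch_hz) <= notch_half_width_hz
        spectrum[:, band] = 0.0
        Y = np.fft.irfft(spectrum, n=t, axis=1)
    return Y


def regress_confounds(X: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize rows of ``X`` against the column space of ``confounds``."""
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != X.shape[1]:
        raise ValueError(f"confounds have {C.shape[0]} rows, expected t={X.shape[1]}")
    design = np.column_stack([np.ones(C.shape[0]), C])
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    return X - (design @ beta).T


def denoise_timeseries(X: np.ndarray, tr_seconds: float,
                       confounds: np.ndarray | None = None, **filter_kwargs) -> np.ndarray:
    """Full temporal denoising: filter chain, confound regression, z-scoring.

    Raises if any row is constant after filtering (z-scoring is undefined).
    """
    Y = bandpass_notch_filter(X, tr_seconds, **filter_kwargs)
    if confounds is not None:
        Y = regress_confounds(Y, confounds)
    Y = Y - Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1)
    if np.any(sd < 1e-12):
        bad = np.where(sd < 1e-12)[0]
        raise ValueError(f"constant rows after filtering (indices {bad.tolist()})")
    return Y / sd[:, None]


def empirical_covariance(X: np.ndarray, normalize: bool = True) -> CovarianceStructure:
    """Per-run covariance structure K = X X' (divided by t when ``normalize``).

    Symmetry is enforced by averaging K with its transpose, which removes
    floating-point asymmetry without changing the exact value.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    t = X.shape[1]
    K = X @ X.T
    if normalize:
        K = K / t
    K = (K + K.T) / 2.0
    return CovarianceStructure(K=K, t_used=t, normalized=normalize)


def truncate_run(X: np.ndarray, duration_tr: int) -> np.ndarray:
    """First ``duration_tr`` columns of ``X``; denoising must be re-run after."""
    X = np.asarray(X)
    if not 1 <= duration_tr <= X.shape[1]:
        raise ValueError(f"duration_tr={duration_tr} outside [1, {X.shape[1]}]")
    return X[:, :duration_tr].copy()
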