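"""Cross-spectral density estimation from BOLD time series.

The data feature fitted by the subject-level inversion is the Hermitian
cross-spectral density matrix over a grid of positive frequencies below
the Nyquist bound 1/(2 TR).  Two estimators are provided: the Welch
averaged cross-periodogram (default) and a multivariate autoregressive
(VAR) spectral estimate, which is smoother for short series.

All densities are two-sided (units: signal^2 / Hz), so a white series of
variance sigma^2 sampled at TR has flat density sigma^2 * TR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ArgumentError, DataError
from .model import CrossSpectra

__all__ = ["SpectralConfig", "estimate_csd"]

MIN_TIMEPOINTS = 64


@dataclass
class SpectralConfig:
    """Settings for CSD estimation.

    method: 'welch' or 'var'.
    nperseg: Welch segment length (defaults to min(n, 64)).
    noverlap: Welch segment overlap (scipy default nperseg // 2).
    smooth: odd Daniell span; > 1 averages adjacent frequency bins to
        trade resolution for variance.
    fmin, fmax: optional grid bounds in Hz (fmax capped at Nyquist).
    n_freq: optional number of retained frequencies (uniform subsample
        for Welch, grid size for VAR).
    var_order: VAR lag order (default 8, reduced if the series is short).
    """

    method: str = "welch"
    nperseg: int | None = None
    noverlap: int | None = None
    smooth: int = 1
    fmin: float | None = None
    fmax: float | None = None
    n_freq: int | None = None
    var_order: int = 8


def estimate_csd(y: np.ndarray, tr: float,
                 config: SpectralConfig | None = None,
                 node_labels=None) -> CrossSpectra:
    """Estimate the cross-spectral density of a (time x nodes) series."""
    if tr <= 0:
        raise ArgumentError("TR must be positive")
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n_time, n = y.shape
    if n_time < MIN_TIMEPOINTS:
        raise DataError(
            f"need at least {MIN_TIMEPOINTS} time points, got {n_time}")
    cfg = config or SpectralConfig()
    fs = 1.0 / tr
    if cfg.method == "welch":
        freqs, S = _welch_csd(y, fs, cfg)
    elif cfg.method == "var":
        freqs, S = _var_csd(y, tr, cfg)
    else:
        raise ArgumentError(f"unknown CSD method {cfg.method!r}")

    fmax = min(cfg.fmax if cfg.fmax is not None else np.inf, fs / 2)
    keep = (freqs > (cfg.fmin or 0.0)) & (freqs <= fmax + 1e-12)
    freqs, S = freqs[keep], S[keep]
    if cfg.n_freq is not None and cfg.method == "welch" and freqs.size > cfg.n_freq:
        idx = np.unique(np.linspace(0, freqs.size - 1, cfg.n_freq).round().astype(int))
        freqs, S = freqs[idx], S[idx]
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))
    return CrossSpectra(freqs=freqs, S=S, node_labels=node_labels)


def _welch_csd(y: np.ndarray, fs: float, cfg: SpectralConfig):
    n_time, n = y.shape
    nperseg = min(cfg.nperseg or 64, n_time)
    # S[i, j] = E[X_i X_j*]; scipy conjugates its first argument, so node j
    # must be the first operand.  Broadcast all pairs at once.
    freqs, S = signal.csd(y.T[None, :, :], y.T[:, None, :], fs=fs,
                          nperseg=nperseg, noverlap=cfg.noverlap,
                          detrend="constant",
                          return_onesided=False, axis=-1)
    order = np.argsort(freqs)
    freqs, S = freqs[order], np.moveaxis(S, -1, 0)[order]
    if cfg.smooth > 1:
        if cfg.smooth % 2 == 0:
            raise ArgumentError("smooth span must be odd")
        kern = np.ones(cfg.smooth) / cfg.smooth
        flat = S.reshape(freqs.size, -1)
        sm = np.empty_like(flat)
        for c in range(flat.shape[1]):
            sm[:, c] = np.convolve(flat[:, c], kern, mode="same")
        half = cfg.smooth // 2
        freqs, S = freqs[half:-half], sm.reshape(S.shape)[half:-half]
    return freqs, S


def _var_csd(y: np.ndarray, tr: float, cfg: SpectralConfig):
    from statsmodels.tsa.api import VAR

    n_time, n = y.shape
    order = max(1, min(cfg.var_order, (n_time - 1) // (2 * n)))
    res = VAR(y - y.mean(axis=0)).fit(maxlags=order, trend="n")
    coefs = res.coefs                       # (p, n, n)
    sigma = res.sigma_u
    n_freq = cfg.n_freq or 32
    nyq = 1.0 / (2 * tr)
    freqs = np.linspace(nyq / n_freq, nyq, n_freq)
    eye = np.eye(n)
    S = np.empty((n_freq, n, n), dtype=complex)
    for k, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f * tr)
        Az = eye - sum(coefs[p] * z ** (p + 1) for p in range(coefs.shape[0]))
        H = np.linalg.inv(Az)
        S[k] = tr * H @ sigma @ np.conj(H.T)
    return freqs, S
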