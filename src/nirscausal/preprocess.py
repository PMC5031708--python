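"""The [oxy-Hb] preprocessing chain: HRF low-pass, detrending, baseline fit.

The chain mirrors the standard NIRS pipeline for task recordings:

1. :func:`hrf_lowpass` - each channel is convolved (causally, with reflect
   padding) with the canonical double-gamma hemodynamic response function,
   acting as a physiologically shaped low-pass filter that suppresses
   cardiac/respiratory bands.
2. :func:`detrend` - slow global drift is removed; the default is a
   discrete-cosine high-pass with a 128 s cutoff period, and a wavelet
   variant (multiresolution decomposition with MDL-selected coarse
   coefficients treated as trend) is available behind the same interface.
3. :func:`baseline_correct` - per channel, the straight line through the
   mean of the 2 s pre-task window and the mean of the 2 s post-task window
   is subtracted, so both baseline windows average to zero.

The order is fixed (low-pass -> detrend -> baseline) and recorded in the
recording's provenance; all steps are strictly per-channel, so preprocessing
commutes with channel permutation, and re-running the chain on an
already-preprocessed recording is rejected.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

from .errors import ConfigurationError, DegenerateInputError, PreconditionError
from .recording import Recording

__all__ = [
    "hrf_kernel",
    "hrf_lowpass",
    "detrend",
    "baseline_correct",
    "preprocess",
]

#: canonical double-gamma parameters: peak delay, undershoot delay,
#: dispersions, and peak:undershoot amplitude ratio
HRF_PEAK_DELAY = 6.0
HRF_UNDER_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDER_DISP = 1.0
HRF_RATIO = 6.0


def hrf_kernel(fs: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``fs``, normalized to unit sum.

    The positive lobe is a gamma density with shape ``HRF_PEAK_DELAY`` and
    unit scale (mode at 5 s), the undershoot a gamma with shape
    ``HRF_UNDER_DELAY`` scaled by 1/6.  ``duration_s`` defaults to 32 s so
    the undershoot is fully covered.
    """
    if fs <= 0 or duration_s <= 0:
        raise ConfigurationError("fs and duration_s must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    h = _gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP) \
        - _gamma.pdf(t, HRF_UNDER_DELAY / HRF_UNDER_DISP, scale=HRF_UNDER_DISP) / HRF_RATIO
    return h / h.sum()


def _convolve_causal(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal same-length convolution with reflect padding at the onset.

    Reflect padding avoids the onset transient a zero-padded causal filter
    would inject into the autoregressive fits downstream.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty channel")
    k = len(kernel)
    if k <= 1:
        return x.copy()
    pad = min(k - 1, x.size - 1)
    front = x[1:pad + 1][::-1]
    if pad < k - 1:  # series shorter than the kernel: extend with edge value
        front = np.concatenate([np.full(k - 1 - pad, x[0]), front])
    return np.convolve(np.concatenate([front, x]), kernel, mode="valid")


def hrf_lowpass(rec: Recording, duration_s: float = 32.0) -> Recording:
    """Convolve every channel with the unit-sum HRF kernel (same length out)."""
    kern = hrf_kernel(rec.fs, duration_s)
    out = np.column_stack(
        [_convolve_causal(rec.data[:, c], kern) for c in range(rec.n_channels)]
    )
    return rec.with_data(out, step=f"hrf_lowpass(duration_s={duration_s:g})")


def _dct_basis(n: int, k_max: int) -> np.ndarray:
    t = np.arange(n)
    ks = np.arange(1, k_max + 1)
    return np.cos(np.pi * np.outer(t + 0.5, ks) / n)


def _detrend_dct(x: np.ndarray, fs: float, cutoff_s: float) -> np.ndarray:
    n = len(x)
    if cutoff_s >= n / fs:
        raise ConfigurationError(
            f"cutoff period {cutoff_s:g}s must be shorter than the session "
            f"({n / fs:g}s)"
        )
    k_max = max(1, int(np.floor(2.0 * (n / fs) / cutoff_s)))
    # constant + linear + cosine set: polynomial terms catch ramp-like drift
    # exactly, cosines catch the slow oscillatory components
    linear = np.linspace(-1.0, 1.0, n)
    basis = np.column_stack([np.ones(n), linear, _dct_basis(n, k_max)])
    beta, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ beta


def _mdl_select(coeffs: np.ndarray, n: int) -> int:
    """Number of largest-magnitude coefficients to keep as 'trend' by a
    minimum-description-length score: n/2*log(RSS/n) + k/2*log(n)."""
    a2 = np.sort(np.abs(coeffs))[::-1] ** 2
    total = a2.sum()
    best_k, best_score = 0, np.inf
    rss = total
    for k in range(len(a2) + 1):
        score = 0.5 * n * np.log(max(rss, 1e-300) / n) + 0.5 * k * np.log(n)
        if score < best_score:
            best_score, best_k = score, k
        if k < len(a2):
            rss -= a2[k]
    return best_k


def _detrend_wavelet(x: np.ndarray, fs: float, cutoff_s: float) -> np.ndarray:
    import pywt

    n = len(x)
    if cutoff_s >= n / fs:
        raise ConfigurationError("cutoff period must be shorter than the session")
    # approximation level whose band lies below 1/cutoff Hz
    level = max(1, int(np.ceil(np.log2(fs * cutoff_s) - 1)))
    level = min(level, pywt.dwt_max_level(n, "db4"))
    coeffs = pywt.wavedec(x, "db4", level=level, mode="periodization")
    approx = coeffs[0]
    keep = _mdl_select(approx, n)
    trend_coeffs = [np.zeros_like(c) for c in coeffs]
    order = np.argsort(np.abs(approx))[::-1][:keep]
    trend_coeffs[0][order] = approx[order]
    trend = pywt.waverec(trend_coeffs, "db4", mode="periodization")[:n]
    out = x - trend
    return out - out.mean()


def detrend(rec: Recording, method: str = "dct_highpass",
            cutoff_s: float = 128.0) -> Recording:
    """Remove slow global drift from every channel.

    ``method`` is ``"dct_highpass"`` (default; discrete-cosine regression
    with all periods above ``cutoff_s`` removed, including the mean) or
    ``"wavelet_mdl"`` (wavelet decomposition; MDL-thresholded coarse
    coefficients reconstructed and subtracted as the trend).
    """
    if method == "dct_highpass":
        fn = _detrend_dct
    elif method == "wavelet_mdl":
        fn = _detrend_wavelet
    else:
        raise ConfigurationError(f"unknown detrend method {method!r}")
    out = np.column_stack(
        [fn(rec.data[:, c], rec.fs, cutoff_s) for c in range(rec.n_channels)]
    )
    return rec.with_data(out, step=f"detrend(method={method}, cutoff_s={cutoff_s:g})")


def baseline_correct(rec: Recording, window_s: float = 2.0) -> Recording:
    """Subtract, per channel, the line through the pre- and post-task
    baseline means.

    The two anchors are (center of first ``window_s``, mean of first
    ``window_s``) and (center of last ``window_s``, mean of last
    ``window_s``); after subtraction both window means are exactly zero.
    """
    w = int(round(window_s * rec.fs))
    if w < 1 or rec.n_samples < 2 * w:
        raise PreconditionError(
            f"recording too short for {window_s:g}s pre/post baseline windows"
        )
    n = rec.n_samples
    t = np.arange(n, dtype=float)
    t_pre = (w - 1) / 2.0
    t_post = (n - 1) - (w - 1) / 2.0
    m_pre = rec.data[:w].mean(axis=0)
    m_post = rec.data[-w:].mean(axis=0)
    slope = (m_post - m_pre) / (t_post - t_pre)
    line = m_pre[None, :] + slope[None, :] * (t[:, None] - t_pre)
    return rec.with_data(rec.data - line, step=f"baseline_correct(window_s={window_s:g})")


def preprocess(rec: Recording, detrend_method: str = "dct_highpass",
               cutoff_s: float = 128.0, hrf_duration_s: float = 32.0,
               baseline_window_s: float = 2.0) -> Recording:
    """Run the full fixed-order chain and mark the output as preprocessed."""
    if rec.preprocessed:
        raise PreconditionError("recording is already preprocessed")
    out = hrf_lowpass(rec, hrf_duration_s)
    out = detrend(out, method=detrend_method, cutoff_s=cutoff_s)
    out = baseline_correct(out, window_s=baseline_window_s)
    out.preprocessed = True
    return out
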