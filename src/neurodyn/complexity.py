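"""Complexity metrics: Higuchi fractal dimension, permutation entropy,
Wiener entropy (spectral flatness), spectral structure variability, and the
uniform folded complexity scale.

Low values of these metrics indicate highly regular, low-information
signals; the highest values indicate noise-like signals.  Both extremes are
atypical for healthy resting-state EEG, so subject-level values are mapped
onto a uniform scale where the mid-range (complex, critical dynamics) is
high and both extremes are low: values are z-scored across subjects and the
high tail (z above the fold threshold, default 1.2 SD) is sign-reversed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "higuchi_fd", "permutation_entropy", "wiener_entropy",
    "spectral_structure_variability", "uniform_complexity_scale",
    "ComplexityVector", "complexity_vector",
]


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension.

    Mean curve length L(k) is computed over k offset sub-series at delays
    k = 1..kmax; the FD is the slope of log L(k) against log(1/k).  A line
    gives 1, uncorrelated noise approaches 2.  Constant input is degenerate
    and returns exactly 1.0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 * kmax:
        raise ValueError(f"series too short for kmax={kmax} (need >= {4 * kmax})")
    if np.ptp(x) == 0:
        return 1.0
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lk), 1)[0]
    return float(slope)


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1,
                        normalize: bool = True) -> float:
    """Permutation entropy of the ordinal-pattern distribution
    (Bandt-Pompe), natural log, ties broken by temporal order.

    Normalized by ln(order!) so the value lies in [0, 1]; a strictly
    monotone series gives 0, i.i.d. noise approaches 1.
    """
    x = np.asarray(x, dtype=float)
    if order < 2:
        raise ValueError("order must be >= 2")
    n_windows = len(x) - (order - 1) * delay
    if n_windows < 1:
        raise ValueError("series too short for the given order and delay")
    # embedding: rows = windows, stable argsort breaks ties by time
    strides = np.arange(order) * delay
    emb = x[np.arange(n_windows)[:, None] + strides[None, :]]
    patterns = np.argsort(emb, axis=1, kind="stable")
    # encode each permutation as an integer
    weights = (order ** np.arange(order))[::-1]
    codes = patterns @ weights
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    if normalize:
        h /= lgamma(order + 1)  # ln(order!)
    return float(h)


def wiener_entropy(psd: np.ndarray, floor: float = 1e-30) -> float:
    """Spectral flatness: geometric mean over arithmetic mean of PSD bins.

    1 for a flat (white) spectrum, -> 0 for a pure tone.  Zero bins are
    floored at `floor` so the geometric mean stays defined.
    """
    psd = np.asarray(psd, dtype=float)
    if psd.ndim != 1 or len(psd) == 0:
        raise ValueError("psd must be a non-empty 1-D array")
    if np.any(psd < 0):
        raise ValueError("psd must be non-negative")
    am = psd.mean()
    if am == 0:
        raise ValueError("all-zero spectrum")
    gm = np.exp(np.mean(np.log(np.maximum(psd, floor))))
    return float(gm / am)


def spectral_structure_variability(x: np.ndarray, fs: float, window: float = 2.0,
                                   overlap: float = 0.5) -> float:
    """Mean cosine distance between unit-norm spectra of consecutive
    short-time windows.

    0 for a stationary narrowband signal; approaches 1 when consecutive
    windows occupy near-orthogonal spectral supports.
    """
    x = np.asarray(x, dtype=float)
    nper = int(round(window * fs))
    step = max(1, int(round(nper * (1.0 - overlap))))
    n_windows = 1 + (len(x) - nper) // step if len(x) >= nper else 0
    if n_windows < 3:
        raise ValueError("need at least 3 windows for SSV")
    win = np.hanning(nper)
    spectra = []
    for w in range(n_windows):
        seg = x[w * step: w * step + nper] * win
        mag = np.abs(np.fft.rfft(seg))
        norm = np.linalg.norm(mag)
        spectra.append(mag / norm if norm > 0 else mag)
    spectra = np.asarray(spectra)
    cos = np.sum(spectra[:-1] * spectra[1:], axis=1)
    return float(np.mean(1.0 - cos))


def uniform_complexity_scale(values: np.ndarray, fold: float = 1.2) -> np.ndarray:
    """Map raw per-subject metric values onto the uniform complexity scale.

    Values are z-scored across subjects; z-scores above ``+fold`` (the high,
    noise-like tail) are sign-reversed so that both extremes of the raw
    scale come out low and the mid-range (normal, complex dynamics) comes
    out high.  By construction no folded value exceeds ``+fold``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least 2 values")
    sd = values.std()
    if sd == 0:
        raise ValueError("zero variance: folded scale undefined")
    z = (values - values.mean()) / sd
    return np.where(z > fold, -z, z)


@dataclass
class ComplexityVector:
    """Raw complexity metrics for the ROIs of one recording."""

    labels: list[str]
    fd: np.ndarray
    pe: np.ndarray
    we: np.ndarray
    ssv: np.ndarray


def complexity_vector(data: np.ndarray, fs: float, labels: list[str],
                      kmax: int = 8, pe_order: int = 3, pe_delay: int = 1,
                      ssv_window: float = 2.0, ssv_overlap: float = 0.5,
                      band: tuple[float, float] = (0.5, 40.0)) -> ComplexityVector:
    """All four metrics per ROI row of a standardized recording.

    Wiener entropy is computed on the Welch spectrum restricted to the
    analysis band (1-s Hanning segments, 50% overlap, padded to 2 s).
    """
    n_rois = data.shape[0]
    nper = int(round(fs))
    freqs, psd = sp_signal.welch(data, fs=fs, window="hann", nperseg=nper,
                                 noverlap=nper // 2, nfft=2 * nper, axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    out = {m: np.empty(n_rois) for m in ("fd", "pe", "we", "ssv")}
    for i in range(n_rois):
        out["fd"][i] = higuchi_fd(data[i], kmax=kmax)
        out["pe"][i] = permutation_entropy(data[i], order=pe_order, delay=pe_delay)
        out["we"][i] = wiener_entropy(psd[i, sel])
        out["ssv"][i] = spectral_structure_variability(data[i], fs, window=ssv_window,
                                                       overlap=ssv_overlap)
    return ComplexityVector(labels=list(labels), **out)
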