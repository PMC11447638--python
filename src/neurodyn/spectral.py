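"""Spectral analysis: Welch PSD/nPSD, canonical and subject-specific band
powers anchored at the individual alpha frequency (IAF) and the theta/alpha
transition frequency (TF), and Lorentzian aperiodic parameterization.

The aperiodic (non-oscillatory, 1/f-like) component is modelled in
log10-power space as

    A(F) = b - log10(k + F**chi)

with offset ``b``, knee ``k`` and exponent ``chi``; the reported slope is
``a = -chi``, so flatter spectra have a less negative slope.  Oscillatory
peaks are modelled as Gaussians on top of A(F) and removed before the final
aperiodic fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.optimize import curve_fit

__all__ = [
    "SpectralProfile", "AperiodicFit", "welch_psd", "detect_landmarks",
    "band_powers", "fit_aperiodic", "CANONICAL_BANDS", "subject_bands",
]

#: canonical band edges, half-open [lo, hi) on the 0.5-Hz grid (the top
#: band is closed at the grid maximum)
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.5, 6.5),
    "theta": (6.5, 8.5),
    "alpha1": (8.5, 10.5),
    "alpha2": (10.5, 12.5),
    "beta1": (12.5, 18.5),
    "beta2": (18.5, 21.5),
    "beta3": (21.5, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class SpectralProfile:
    """One ROI's spectrum on the 0.5-Hz analysis grid (0.5-40 Hz)."""

    freqs: np.ndarray
    psd: np.ndarray
    npsd: np.ndarray = field(init=False)
    iaf: float | None = None
    tf: float | None = None
    landmark_fallback: bool = False

    def __post_init__(self) -> None:
        total = self.psd.sum()
        if total <= 0:
            raise ValueError("PSD must have positive total power")
        self.npsd = self.psd / total


def welch_psd(x: np.ndarray, fs: float, seg: float = 1.0, overlap: float = 0.5,
              pad_to: float = 2.0, band: tuple[float, float] = (0.5, 40.0)
              ) -> SpectralProfile:
    """Welch PSD with Hanning segments, zero-padded to the analysis window.

    Defaults follow the pipeline: 1-s segments, 50% overlap, padded to 2 s,
    giving a 0.5-Hz grid; the profile is restricted to 0.5-40 Hz.
    """
    x = np.asarray(x, dtype=float)
    nper = int(round(seg * fs))
    if len(x) < int(round(pad_to * fs)):
        raise ValueError(f"need at least {pad_to} s of signal")
    freqs, psd = sp_signal.welch(
        x, fs=fs, window="hann", nperseg=nper,
        noverlap=int(round(nper * overlap)), nfft=int(round(pad_to * fs)),
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return SpectralProfile(freqs=freqs[sel], psd=psd[sel])


def detect_landmarks(sp: SpectralProfile,
                     iaf_window: tuple[float, float] = (7.5, 12.5),
                     tf_window: tuple[float, float] = (4.0, 8.0),
                     fallback: tuple[float, float] = (10.0, 6.0)) -> tuple[float, float]:
    """Locate the IAF (maximum normalized power in the alpha window) and the
    TF (minimum normalized power in the theta window, below the IAF).

    A landmark sitting on its search-window edge is not a local extremum —
    the spectrum is then treated as peakless and the canonical defaults
    (IAF 10 Hz, TF 6 Hz) are used, with ``landmark_fallback`` set.
    The landmarks are stored on the profile and returned.
    """
    f, npsd = sp.freqs, sp.npsd
    sel_a = (f >= iaf_window[0]) & (f <= iaf_window[1])
    fa, pa = f[sel_a], npsd[sel_a]
    i = int(np.argmax(pa))
    iaf, fb = (fa[i], False) if 0 < i < len(pa) - 1 else (fallback[0], True)

    sel_t = (f >= tf_window[0]) & (f <= tf_window[1]) & (f < iaf)
    ft, pt = f[sel_t], npsd[sel_t]
    if len(ft) >= 3:
        j = int(np.argmin(pt))
        tf, fb_t = (ft[j], False) if 0 < j < len(pt) - 1 else (fallback[1], True)
    else:
        tf, fb_t = fallback[1], True
    sp.iaf, sp.tf = float(iaf), float(tf)
    sp.landmark_fallback = fb or fb_t
    return sp.iaf, sp.tf


def subject_bands(iaf: float, tf: float) -> dict[str, tuple[float, float]]:
    """Subject-specific bands anchored at TF and IAF; beta/gamma stay
    canonical."""
    bands = {
        "delta": (tf - 4.0, tf - 2.0),
        "theta": (tf - 2.0, tf),
        "alpha_low": (tf, iaf),
        "alpha_high": (iaf, iaf + 2.0),
    }
    bands.update({k: CANONICAL_BANDS[k] for k in ("beta1", "beta2", "beta3", "gamma")})
    return bands


def band_powers(sp: SpectralProfile, scheme: str = "canonical",
                bands: dict[str, tuple[float, float]] | None = None
                ) -> dict[str, dict[str, float]]:
    """Per-band mean nPSD ("equivalent percent power") and relative power
    density (percent of total nPSD in the band).

    Bands are closed-left half-open intervals on the grid; a band whose hi
    edge is the grid maximum is closed.  An empty band (bad landmarks)
    yields NaNs and a ``flagged`` marker.
    """
    if bands is None:
        if scheme == "canonical":
            bands = CANONICAL_BANDS
        elif scheme == "subject-specific":
            if sp.iaf is None or sp.tf is None:
                raise ValueError("landmarks required for subject-specific bands")
            bands = subject_bands(sp.iaf, sp.tf)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    fmax = sp.freqs[-1]
    out: dict[str, dict[str, float]] = {}
    for name, (lo, hi) in bands.items():
        sel = (sp.freqs >= lo) & ((sp.freqs <= hi) if hi >= fmax else (sp.freqs < hi))
        if not sel.any():
            out[name] = {"equivalent_percent_power": np.nan,
                         "relative_power_density": np.nan, "flagged": True}
            continue
        out[name] = {
            "equivalent_percent_power": float(sp.npsd[sel].mean()),
            "relative_power_density": float(100.0 * sp.npsd[sel].sum() / sp.npsd.sum()),
            "flagged": False,
        }
    return out


# ---------------------------------------------------------------------------
# Aperiodic parameterization
# ---------------------------------------------------------------------------

@dataclass
class AperiodicFit:
    """Lorentzian aperiodic parameters and detected oscillatory peaks."""

    offset: float
    knee: float
    exponent: float
    peaks: list[tuple[float, float, float]]  # (centre Hz, height log10, width Hz)
    r_squared: float
    converged: bool = True

    @property
    def slope(self) -> float:
        """Reported 1/f slope, a = -chi."""
        return -self.exponent


def _lorentzian(f: np.ndarray, b: float, k: float, chi: float) -> np.ndarray:
    return b - np.log10(k + f ** chi)


def _gauss(f: np.ndarray, h: float, c: float, w: float) -> np.ndarray:
    return h * np.exp(-((f - c) ** 2) / (2.0 * w ** 2))


_AP_BOUNDS = ([-20.0, 0.0, 0.0], [20.0, 1e4, 8.0])


def _fit_lorentzian(f: np.ndarray, lp: np.ndarray, p0=None) -> np.ndarray:
    if p0 is None:
        chi0 = float(np.clip((lp[0] - lp[-1]) / np.log10(f[-1] / f[0]), 0.1, 7.5))
        b0 = float(lp[0] + np.log10(1e-3 + f[0] ** chi0))
        p0 = [b0, 1e-3, chi0]
    popt, _ = curve_fit(_lorentzian, f, lp, p0=p0, bounds=_AP_BOUNDS, maxfev=10000)
    return popt


def fit_aperiodic(sp: SpectralProfile, max_peaks: int = 6,
                  peak_threshold_sd: float = 2.0,
                  width_bounds: tuple[float, float] = (0.5, 12.0)) -> AperiodicFit:
    """Iterative aperiodic + peaks fit in log10-power space.

    (1) robust initial Lorentzian fit (a refit that down-weights the bins
    oscillatory peaks push upward); (2) Gaussian peaks fitted to the
    residual, largest first, while the residual maximum exceeds
    ``peak_threshold_sd`` standard deviations; (3) the peak-subtracted
    spectrum is refit for the final (offset, knee, exponent).  R-squared is
    reported in log space for the full (aperiodic + peaks) model.
    """
    f = sp.freqs
    if np.any(sp.psd <= 0):
        raise ValueError("PSD must be strictly positive on the fit range")
    lp = np.log10(sp.psd)
    try:
        popt = _fit_lorentzian(f, lp)
        resid = lp - _lorentzian(f, *popt)
        # robust pass: refit on the bins not pushed up by peaks
        keep = resid <= np.percentile(resid, 75)
        if keep.sum() >= 10:
            popt = _fit_lorentzian(f[keep], lp[keep], p0=list(popt))

        peaks: list[tuple[float, float, float]] = []
        resid = lp - _lorentzian(f, *popt)
        flat = resid.copy()
        for _ in range(max_peaks):
            sd = flat.std()
            i = int(np.argmax(flat))
            if sd < 1e-6 or flat[i] < peak_threshold_sd * sd or flat[i] <= 0:
                break
            c0, h0 = f[i], flat[i]
            try:
                p_popt, _ = curve_fit(
                    _gauss, f, flat, p0=[h0, c0, 1.0],
                    bounds=([0.0, f[0], width_bounds[0]],
                            [np.inf, f[-1], width_bounds[1]]),
                    maxfev=5000,
                )
            except RuntimeError:
                break
            peaks.append((float(p_popt[1]), float(p_popt[0]), float(p_popt[2])))
            flat = flat - _gauss(f, *p_popt)

        peak_model = np.zeros_like(f)
        for c, h, w in peaks:
            peak_model += _gauss(f, h, c, w)
        popt = _fit_lorentzian(f, lp - peak_model, p0=list(popt))
        model = _lorentzian(f, *popt) + peak_model
        ss_res = float(np.sum((lp - model) ** 2))
        ss_tot = float(np.sum((lp - lp.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        # peaks sorted by height, largest first
        peaks.sort(key=lambda p: -p[1])
        return AperiodicFit(offset=float(popt[0]), knee=float(popt[1]),
                            exponent=float(popt[2]), peaks=peaks, r_squared=r2)
    except RuntimeError:
        warnings.warn("aperiodic fit did not converge", stacklevel=2)
        return AperiodicFit(offset=np.nan, knee=np.nan, exponent=np.nan,
                            peaks=[], r_squared=np.nan, converged=False)
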