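"""Overall Data Quality (OQD) index.

Each 1-s epoch of a z-scored recording is tested against four criteria:

(i)   constant amplitude on any channel, or missing/infinite voltages;
(ii)  unusual amplitudes — any |z| above ``z_max`` or a near-zero
      peak-to-peak range;
(iii) high-frequency noise — power in the ``hf_band`` exceeding
      ``hf_ratio_max`` of total analysis-band power on any channel;
(iv)  low inter-channel correlation — more than ``corr_channel_fraction``
      of channels whose best absolute Pearson correlation with every other
      channel stays below ``corr_min``.

An epoch is bad iff any criterion fires.  OQD is the percentage of good
epochs, binned 'excellent' (>= 90), 'good' (>= 80), 'poor' (>= 60), 'bad'
(< 60).  Quality is reported and used as a covariate; no data are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochedRecording

__all__ = ["QualityThresholds", "QualityReport", "epoch_quality_flags", "oqd_summary",
           "oqd_category", "quality_report"]


@dataclass
class QualityThresholds:
    """Criterion thresholds, in z-score units where applicable.  The source
    criteria are published without numbers; these defaults are the package's
    own calibration and are config-overridable."""

    z_max: float = 5.0
    ptp_min: float = 1e-6
    hf_band: tuple[float, float] = (25.0, 40.0)
    total_band: tuple[float, float] = (0.5, 40.0)
    hf_ratio_max: float = 0.5
    corr_min: float = 0.2
    corr_channel_fraction: float = 0.25


@dataclass
class QualityReport:
    flags: np.ndarray           # [epochs x 4] criterion fired
    bad: np.ndarray             # [epochs] combined
    oqd: float                  # percent good, [0, 100]
    category: str
    params: QualityThresholds = field(default_factory=QualityThresholds)


def _band_power(epochs: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Periodogram band power per (epoch, channel)."""
    n = epochs.shape[2]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    power = np.abs(np.fft.rfft(epochs, axis=2)) ** 2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return power[:, :, sel].sum(axis=2)


def epoch_quality_flags(ep: EpochedRecording,
                        params: QualityThresholds | None = None) -> np.ndarray:
    """Evaluate the four criteria per epoch; returns a boolean [epochs x 4]
    array.  Input is expected z-scored (amplitude thresholds are z units)."""
    p = params or QualityThresholds()
    x = ep.epochs
    n_epochs = x.shape[0]
    flags = np.zeros((n_epochs, 4), dtype=bool)

    finite = np.isfinite(x)
    ptp = np.where(finite, x, np.nan)
    ptp = np.nanmax(ptp, axis=2) - np.nanmin(ptp, axis=2)  # [epochs x ch]
    # (i) non-finite samples or a constant channel
    flags[:, 0] = (~finite).any(axis=(1, 2)) | np.nan_to_num(ptp == 0).any(axis=1)

    xf = np.nan_to_num(x)
    # (ii) unusual amplitudes
    flags[:, 1] = (np.abs(xf) > p.z_max).any(axis=(1, 2)) | (ptp < p.ptp_min).any(axis=1)

    # (iii) high-frequency noise
    hf = _band_power(xf, ep.fs, p.hf_band)
    total = _band_power(xf, ep.fs, p.total_band)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, hf / total, 0.0)
    flags[:, 2] = (ratio > p.hf_ratio_max).any(axis=1)

    # (iv) decorrelated channels
    n_ch = x.shape[1]
    if n_ch >= 2:
        for e in range(n_epochs):
            with np.errstate(invalid="ignore"):
                c = np.abs(np.corrcoef(xf[e]))
            np.fill_diagonal(c, 0.0)
            best = np.nan_to_num(c).max(axis=1)
            flags[e, 3] = (best < p.corr_min).mean() > p.corr_channel_fraction
    return flags


def oqd_category(oqd: float) -> str:
    """Categorical label at the published cut-points (90/80/60)."""
    if oqd >= 90:
        return "excellent"
    if oqd >= 80:
        return "good"
    if oqd >= 60:
        return "poor"
    return "bad"


def oqd_summary(flags: np.ndarray, params: QualityThresholds | None = None) -> QualityReport:
    """Summarise per-epoch criterion flags into OQD percent and category."""
    flags = np.asarray(flags, dtype=bool)
    if flags.ndim != 2 or flags.shape[0] == 0:
        raise ValueError("need at least one epoch of flags")
    bad = flags.any(axis=1)
    oqd = 100.0 * float((~bad).sum()) / flags.shape[0]
    return QualityReport(flags=flags, bad=bad, oqd=oqd, category=oqd_category(oqd),
                         params=params or QualityThresholds())


def quality_report(ep: EpochedRecording,
                   params: QualityThresholds | None = None) -> QualityReport:
    """Convenience: flags + summary in one call."""
    return oqd_summary(epoch_quality_flags(ep, params), params)
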