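"""Signal standardization and harmonization.

Recordings are band-pass filtered 0.5-40 Hz with an 8th-order zero-phase
Butterworth response (a 4th-order filter applied forward and backward),
resampled to 512 Hz by the polyphase method, truncated to the first five
minutes, z-scored per channel (per recruitment centre bookkeeping), merged
from atlas regions to ROIs, and segmented into contiguous 1-s epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from fractions import Fraction

from scipy import signal

from .core_io import Recording, RoiMap, ALL_ROIS_LABEL, log_stage

__all__ = [
    "EpochedRecording", "standardize_recording", "zscore_harmonize",
    "map_to_rois", "epoch_signal",
]


@dataclass
class EpochedRecording:
    """Contiguous non-overlapping epochs: tensor [epochs x ROIs x samples]."""

    epochs: np.ndarray
    epoch_length: float
    fs: float
    labels: list[str]
    meta: dict

    def __post_init__(self) -> None:
        expected = int(round(self.epoch_length * self.fs))
        if self.epochs.ndim != 3 or self.epochs.shape[2] != expected:
            raise ValueError("epochs must be [epochs x channels x epoch_length*fs]")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _butter_bandpass_sos(low: float, high: float, fs: float, order: int):
    # order // 2 each way: forward-backward application doubles the
    # effective order, giving the net zero-phase response
    return signal.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")


def filtfilt_power_response(freqs: np.ndarray, low: float, high: float,
                            fs: float, order: int = 8) -> np.ndarray:
    """Power-spectral gain of the zero-phase band-pass at `freqs`.

    Forward-backward filtering scales the PSD by |H(f)|^4 of the one-pass
    filter.  Dividing a Welch estimate by this response removes the edge
    rolloff the standardization filter imprints on the analysis band, which
    otherwise biases the aperiodic fit.
    """
    sos = _butter_bandpass_sos(low, high, fs, order)
    _, h = signal.sosfreqz(sos, worN=2.0 * np.pi * np.asarray(freqs, float) / fs)
    return np.abs(h) ** 4


def standardize_recording(rec: Recording, low: float = 0.5, high: float = 40.0,
                          order: int = 8, target_fs: float = 512.0,
                          max_duration: float = 300.0) -> Recording:
    """Band-pass filter (zero-phase), resample to `target_fs`, and truncate
    to the first `max_duration` seconds.

    The filter is a Butterworth of half the stated `order` run forward and
    backward (``sosfiltfilt``), so the magnitude response is that of an
    `order`-th-order filter with exactly zero phase.  Resampling is
    polyphase.  Inputs sampled below 2*`high` are resampled before
    filtering; fast inputs (>= 1024 Hz) are filtered first.
    """
    if rec.duration < 1.0:
        raise ValueError("recording shorter than one epoch")
    data = rec.data
    fs = rec.fs

    def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
        if fs_in == fs_out:
            return x
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        return signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)

    if fs < 2 * high or fs < 1024:
        data = _resample(data, fs, target_fs)
        fs = target_fs
        sos = _butter_bandpass_sos(low, high, fs, order)
        data = signal.sosfiltfilt(sos, data, axis=1)
    else:
        sos = _butter_bandpass_sos(low, high, fs, order)
        data = signal.sosfiltfilt(sos, data, axis=1)
        data = _resample(data, fs, target_fs)
        fs = target_fs

    max_samples = int(round(max_duration * fs))
    if data.shape[1] > max_samples:
        data = data[:, :max_samples]
    log_stage("standardize", n_channels=data.shape[0], n_samples=data.shape[1],
              fs=fs, band=(low, high), order=order)
    return rec.copy_with(data=np.ascontiguousarray(data), fs=fs,
                         meta={"standardized": True,
                               "filter": {"low": low, "high": high, "order": order}})


def zscore_harmonize(recs: list[Recording]) -> list[Recording]:
    """Per-channel z-scoring, applied separately for each recruitment centre.

    The transform is per channel — (v - mean) / sd within that channel — so
    centre grouping only affects bookkeeping; it is retained to mirror the
    multi-centre harmonisation protocol.  Constant channels cannot be
    z-scored: they are left untouched and flagged in
    ``meta["bad_channels"]``.
    """
    out = []
    for rec in recs:
        data = rec.data.copy()
        mean = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        bad = np.where(sd[:, 0] == 0)[0]
        sd_safe = np.where(sd == 0, 1.0, sd)
        data = (data - mean) / sd_safe
        if len(bad):
            data[bad] = rec.data[bad]
        out.append(rec.copy_with(
            data=data,
            meta={"zscored": True, "bad_channels": [rec.labels[i] for i in bad]},
        ))
    log_stage("zscore_harmonize", n_recordings=len(recs),
              centres=sorted({r.centre_id for r in recs}))
    return out


def map_to_rois(rec: Recording, roi_map: RoiMap, add_all_rois: bool = True,
                strict: bool = True) -> Recording:
    """Average member-region rows into one row per ROI.

    If the recording is already ROI-labelled the identity is returned
    (with the "all ROIs" mean row appended when requested).  Unmapped
    labels raise in strict mode and are dropped otherwise.
    """
    already_rois = set(rec.labels) <= set(roi_map.rois)
    if already_rois:
        rows = list(rec.data)
        labels = list(rec.labels)
    else:
        unmapped = [l for l in rec.labels if l not in roi_map.region_to_roi]
        if unmapped and strict:
            raise KeyError(f"unmapped region labels: {unmapped[:5]}")
        rows, labels = [], []
        for roi in roi_map.rois:
            idx = [i for i, l in enumerate(rec.labels)
                   if roi_map.region_to_roi.get(l) == roi]
            if idx:
                rows.append(rec.data[idx].mean(axis=0))
                labels.append(roi)
    if add_all_rois:
        source = rec.data if not already_rois else np.asarray(rows)
        rows = list(rows) + [source.mean(axis=0)]
        labels = labels + [ALL_ROIS_LABEL]
    log_stage("map_to_rois", n_in=rec.n_channels, n_out=len(labels))
    return rec.copy_with(data=np.asarray(rows), labels=labels,
                         meta={"roi_mapped": True})


def epoch_signal(rec: Recording, epoch_length: float = 1.0) -> EpochedRecording:
    """Segment into floor(duration / epoch_length) contiguous epochs;
    any partial trailing epoch is dropped."""
    if epoch_length <= 0:
        raise ValueError("epoch_length must be > 0")
    spe = int(round(epoch_length * rec.fs))
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    trimmed = rec.data[:, : n_epochs * spe]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochedRecording(
        epochs=np.ascontiguousarray(epochs), epoch_length=epoch_length,
        fs=rec.fs, labels=list(rec.labels),
        meta={**rec.meta, "parent_samples": rec.n_samples},
    )
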