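"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import neurodyn as nd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def write_minimal_edf(path: Path, data: np.ndarray, fs: int,
                      labels: list[str] | None = None) -> None:
    """Write a minimal valid EDF file (int16 samples, microvolt units).

    Test-only helper: the package reads EDF through mne but ships no
    writer, so fixtures are produced here from first principles.
    """
    n_sig, n_samp = data.shape
    assert n_samp % fs == 0, "need whole 1-s records"
    n_records = n_samp // fs
    labels = labels or [f"ch{i}" for i in range(n_sig)]
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2020 X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (n_sig + 1)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(n_sig), 4),
    ])
    fields = [
        [pad(l, 16) for l in labels],
        [pad("", 80)] * n_sig,
        [pad("uV", 8)] * n_sig,
        [pad(str(phys_min), 8)] * n_sig,
        [pad(str(phys_max), 8)] * n_sig,
        [pad(str(dig_min), 8)] * n_sig,
        [pad(str(dig_max), 8)] * n_sig,
        [pad("", 80)] * n_sig,
        [pad(str(fs), 8)] * n_sig,
        [pad("", 32)] * n_sig,
    ]
    sig_header = b"".join(b"".join(f) for f in fields)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data - phys_min) * scale + dig_min),
                      dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            for s in range(n_sig):
                fh.write(digital[s, r * fs:(r + 1) * fs].tobytes())


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_recording():
    """Deterministic 4-channel 8-s recording at 256 Hz."""
    gen = np.random.default_rng(7)
    return nd.Recording(data=gen.standard_normal((4, 2048)), fs=256.0,
                        labels=["a", "b", "c", "d"], centre_id="toy")


@pytest.fixture(scope="session")
def standardized_recording():
    """60-s 10-ROI synthetic recording through standardization + z-scoring."""
    rec = nd.simulate_recording(nd.SignalSpec(duration=60.0), n_rois=10, seed=99)
    std = nd.standardize_recording(rec)
    return nd.zscore_harmonize([std])[0]
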