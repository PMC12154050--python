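"""Shared fixtures: tiny recordings and an on-the-fly minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from cohgram.io import CHANNELS_10_20, Recording


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng) -> Recording:
    """Four channels, 4 s at 500 Hz, white noise."""
    return Recording(
        subject_id="subj-a",
        label="ctrl",
        channel_names=["c0", "c1", "c2", "c3"],
        sfreq=500.0,
        data=rng.standard_normal((4, 2000)),
    )


def write_minimal_edf(
    path: Path,
    data: np.ndarray,
    channel_names: list[str],
    sfreq: int,
) -> Path:
    """Write a minimal EDF file (16-bit, one data record per second).

    Test scaffolding only: enough of the EDF spec for readers to parse
    the header and reconstruct the signal; data must divide evenly into
    1 s records and fit the int16 digital range after scaling.
    """
    n_sig, n_samp = data.shape
    assert n_samp % sfreq == 0
    n_rec = n_samp // sfreq
    pmax = max(1.0, float(np.abs(data).max()) * 1.05)
    dmax = 32767
    digital = np.round(data / pmax * dmax).astype("<i2")

    def field(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        assert len(b) <= width, text
        return b.ljust(width)

    hdr = b"".join([
        field("0", 8),
        field("X X X X", 80),
        field("Startdate 01-JAN-2020 X X X", 80),
        field("01.01.20", 8),
        field("00.00.00", 8),
        field(str(256 * (n_sig + 1)), 8),
        field("", 44),
        field(str(n_rec), 8),
        field("1", 8),
        field(str(n_sig), 4),
    ])
    for writer, width in [
        (lambda n: n, 16),                 # label
        (lambda n: "", 80),                # transducer
        (lambda n: "uV", 8),               # physical dimension
        (lambda n: f"{-pmax:.4g}", 8),     # physical min
        (lambda n: f"{pmax:.4g}", 8),      # physical max
        (lambda n: str(-dmax), 8),         # digital min
        (lambda n: str(dmax), 8),          # digital max
        (lambda n: "", 80),                # prefiltering
        (lambda n: str(sfreq), 8),         # samples per record
        (lambda n: "", 32),                # reserved
    ]:
        hdr += b"".join(field(writer(name), width) for name in channel_names)
    assert len(hdr) == 256 * (n_sig + 1)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for s in range(n_sig):
                fh.write(digital[s, r * sfreq:(r + 1) * sfreq].tobytes())
    return path


@pytest.fixture
def edf_path(tmp_path, rng) -> tuple[Path, np.ndarray]:
    """A 19-channel, 10 s, 500 Hz EDF file plus the signal written."""
    data = rng.standard_normal((19, 5000)) * 50.0
    path = write_minimal_edf(tmp_path / "rec.edf", data,
                             list(CHANNELS_10_20), 500)
    return path, data
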