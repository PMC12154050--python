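"""Reading and writing multichannel EEG recordings.

A :class:`Recording` is the canonical in-memory container used by every
downstream stage: a channels x samples float array plus channel names,
sampling rate and subject/label metadata.  Recordings are read from EDF
(via MNE) or from the package's own NPZ schema, which round-trips
losslessly.

The canonical 19-electrode order of the international 10-20 system used
throughout (``CHANNELS_10_20``) fixes the identity of every channel pair
and therefore of every pixel row of a connectogram image.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .errors import ConfigurationError, InputError

#: The 19 scalp electrodes of the international 10-20 system, in the
#: canonical order used for pair indexing.  Mastoid references (A1/A2)
#: are not analysis channels and are excluded.
CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclasses.dataclass
class Recording:
    """One subject's multichannel signal.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    label : str or None
        Class label (e.g. a diagnostic group), or None if unlabeled.
    channel_names : list of str
        One name per row of ``data``, in row order.
    sfreq : float
        Sampling frequency in Hz; must be positive.
    data : ndarray of shape (n_channels, n_samples)
        The signal in its original physical units.
    """

    subject_id: str
    label: str | None
    channel_names: list[str]
    sfreq: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 2:
            raise InputError("Recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise InputError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.data.shape[0] < 2:
            raise InputError("a Recording needs at least 2 channels")
        if not self.sfreq > 0:
            raise InputError(f"sfreq must be positive, got {self.sfreq}")
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            names = [self.channel_names[i] for i in np.flatnonzero(bad)]
            raise InputError(
                f"non-finite samples in channel(s): {', '.join(names)}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


def read_recording(
    path: str | Path,
    subject_id: str | None = None,
    label: str | None = None,
) -> Recording:
    """Read a Recording from an EDF or NPZ file.

    The format is chosen by extension (``.edf`` / ``.npz``).  For NPZ,
    metadata stored in the file is used unless overridden by the
    ``subject_id`` / ``label`` arguments.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return _read_edf(path, subject_id or path.stem, label)
    if suffix == ".npz":
        return _read_npz(path, subject_id, label)
    raise InputError(f"unsupported recording format {suffix!r}: {path}")


def _read_edf(path: Path, subject_id: str, label: str | None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise InputError(f"reading {path} requires mne") from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise InputError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data()
    try:
        return Recording(
            subject_id=subject_id,
            label=label,
            channel_names=list(raw.ch_names),
            sfreq=float(raw.info["sfreq"]),
            data=data,
        )
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def _read_npz(path: Path, subject_id: str | None, label: str | None) -> Recording:
    with np.load(path, allow_pickle=False) as npz:
        missing = {"data", "channel_names", "sfreq"} - set(npz.files)
        if missing:
            raise InputError(
                f"{path}: missing NPZ field(s): {', '.join(sorted(missing))}"
            )
        stored_subject = (
            str(npz["subject_id"]) if "subject_id" in npz.files else None
        )
        stored_label = str(npz["label"]) if "label" in npz.files else None
        if stored_label == "":
            stored_label = None
        try:
            return Recording(
                subject_id=subject_id or stored_subject or path.stem,
                label=label if label is not None else stored_label,
                channel_names=[str(n) for n in npz["channel_names"]],
                sfreq=float(npz["sfreq"]),
                data=np.asarray(npz["data"], dtype=np.float64),
            )
        except InputError as exc:
            raise InputError(f"{path}: {exc}") from exc


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to the package NPZ schema (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        data=rec.data,
        channel_names=np.array(rec.channel_names),
        sfreq=np.float64(rec.sfreq),
        subject_id=np.str_(rec.subject_id),
        label=np.str_(rec.label if rec.label is not None else ""),
    )
    return path


def select_channels(rec: Recording, names: Sequence[str]) -> Recording:
    """Subset/reorder channels to exactly ``names``, in the given order.

    Downstream pair indexing depends on this order, so it is applied
    verbatim.  A missing name raises :class:`InputError` naming it.
    """
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise InputError(f"channel(s) not in recording: {', '.join(missing)}")
    rows = [index[n] for n in names]
    return Recording(
        subject_id=rec.subject_id,
        label=rec.label,
        channel_names=list(names),
        sfreq=rec.sfreq,
        data=rec.data[rows],
    )


def bandpass(
    rec: Recording,
    f_lo: float = 0.5,
    f_hi: float = 45.0,
    order: int = 4,
) -> Recording:
    """Optional zero-phase Butterworth band-pass (off by default everywhere).

    Applied forward-backward (``sosfiltfilt``), so the effective order is
    doubled and the phase response is zero.
    """
    nyq = rec.sfreq / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ConfigurationError(
            f"band ({f_lo}, {f_hi}) Hz invalid for sfreq {rec.sfreq} Hz"
        )
    sos = _signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=rec.sfreq,
                         output="sos")
    return Recording(
        subject_id=rec.subject_id,
        label=rec.label,
        channel_names=list(rec.channel_names),
        sfreq=rec.sfreq,
        data=_signal.sosfiltfilt(sos, rec.data, axis=1),
    )
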