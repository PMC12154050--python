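"""Magnitude-squared coherence adjacency matrices.

For two equal-length signals x and y the magnitude-squared coherence is

    Coh(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))   in [0, 1],

with P_xy the cross-spectral density and P_xx, P_yy the power spectral
densities, all estimated by Welch's method: tapered, overlapping
sub-segments whose periodograms are averaged.  At least two sub-segments
(M >= 2) are mandatory — with a single sub-segment the estimate is
identically 1 for any pair of signals.

A 0.4 s analysis window at 500 Hz is 200 samples; the default Welch
configuration (100-sample Hann sub-segments, 50% overlap, constant
detrend) yields M = 3 sub-segments and a 5 Hz frequency resolution.
The frequency-resolved coherence is reduced to one scalar per channel
pair by an unweighted mean over the broad EEG band 0.5-45 Hz (DC bin
excluded); a sub-band can be configured instead.

Estimator bias: for independent Gaussian signals the expected MSC
estimate is approximately 1/M per frequency bin, and for true coherence
kappa it is roughly kappa + (1 - kappa)^2 / M.  This floor is inherent
to small-M Welch estimation, not a defect; downstream classifiers see a
consistent bias across all pairs.
"""

from __future__ import annotations

import cmath
import dataclasses
import math

import numpy as np
from scipy import signal as _signal

from .errors import ConfigurationError, EstimationError

__all__ = [
    "SpectralConfig",
    "CoherenceMatrix",
    "msc_spectrum",
    "band_average",
    "window_adjacency",
    "oracle_msc",
]


@dataclasses.dataclass
class SpectralConfig:
    """Welch estimation choices for coherence.

    subwin_samples : Welch sub-segment length (samples).
    subwin_overlap : fractional overlap between sub-segments.
    taper          : taper name understood by scipy.signal.get_window.
    band           : inclusive (f_lo, f_hi) averaging band in Hz.
    detrend        : 'constant' removes each sub-segment's mean; 'none'
                     leaves sub-segments untouched.
    """

    subwin_samples: int = 100
    subwin_overlap: float = 0.5
    taper: str = "hann"
    band: tuple[float, float] = (0.5, 45.0)
    detrend: str = "constant"

    def __post_init__(self) -> None:
        if self.subwin_samples < 8:
            raise ConfigurationError("subwin_samples must be >= 8")
        if not 0 <= self.subwin_overlap < 1:
            raise ConfigurationError("subwin_overlap must be in [0, 1)")
        if self.detrend not in ("constant", "none"):
            raise ConfigurationError("detrend must be 'constant' or 'none'")
        f_lo, f_hi = self.band
        if not 0 <= f_lo < f_hi:
            raise ConfigurationError(f"invalid band {self.band}")

    @property
    def noverlap(self) -> int:
        return int(round(self.subwin_samples * self.subwin_overlap))

    @property
    def step(self) -> int:
        return self.subwin_samples - self.noverlap

    def n_subsegments(self, n_samples: int) -> int:
        if n_samples < self.subwin_samples:
            return 0
        return (n_samples - self.subwin_samples) // self.step + 1

    def validate_for(self, n_samples: int, sfreq: float) -> None:
        m = self.n_subsegments(n_samples)
        if m < 2:
            raise EstimationError(
                f"only {m} Welch sub-segment(s) fit in {n_samples} samples; "
                "MSC needs >= 2 (a single-segment estimate is identically 1)"
            )
        if self.band[1] > sfreq / 2:
            raise ConfigurationError(
                f"band upper edge {self.band[1]} Hz above Nyquist {sfreq / 2} Hz"
            )


@dataclasses.dataclass
class CoherenceMatrix:
    """Symmetric channels x channels coherence adjacency for one window;
    entries in [0, 1], diagonal exactly 1."""

    values: np.ndarray
    window_index: int
    band: tuple[float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigurationError("coherence values must be square")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def msc_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    sfreq: float,
    cfg: SpectralConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch magnitude-squared coherence between two signals.

    Returns ``(frequencies, coherence)`` with every coherence value in
    [0, 1].  Raises :class:`EstimationError` when fewer than two Welch
    sub-segments fit (degenerate estimate) or an input has zero variance.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise EstimationError("x and y must be equal-length 1-D arrays")
    cfg.validate_for(x.size, sfreq)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EstimationError("zero-variance input signal")
    freqs, coh = _signal.coherence(
        x, y, fs=sfreq,
        window=cfg.taper,
        nperseg=cfg.subwin_samples,
        noverlap=cfg.noverlap,
        detrend=False if cfg.detrend == "none" else cfg.detrend,
    )
    return freqs, np.clip(coh, 0.0, 1.0)


def band_average(
    freqs: np.ndarray,
    coh: np.ndarray,
    band: tuple[float, float],
) -> float:
    """Unweighted mean of coherence over f_lo <= f <= f_hi, excluding DC."""
    freqs = np.asarray(freqs, dtype=np.float64)
    mask = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not mask.any():
        raise ConfigurationError(
            f"band {band} contains no estimated frequency bins (after DC "
            f"exclusion); grid spacing is {freqs[1] - freqs[0]:.3g} Hz"
        )
    return float(np.asarray(coh)[mask].mean())


def window_adjacency(
    window: np.ndarray,
    sfreq: float,
    cfg: SpectralConfig | None = None,
    channel_names: list[str] | None = None,
    window_index: int = 0,
) -> CoherenceMatrix:
    """Band-averaged coherence adjacency over all channel pairs.

    Entry (i, j) equals ``band_average(msc_spectrum(ch_i, ch_j))``; the
    computation is vectorised over pairs (one tapered FFT per channel
    sub-segment, cross-spectra by outer product) and is numerically
    equivalent to the pairwise route.  Symmetric by construction,
    diagonal set to exactly 1.
    """
    cfg = cfg or SpectralConfig()
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or window.shape[0] < 2:
        raise EstimationError("window must be channels x samples with >= 2 channels")
    c, n = window.shape
    cfg.validate_for(n, sfreq)
    flat = np.ptp(window, axis=1) == 0
    if flat.any():
        names = channel_names or [f"ch{i}" for i in range(c)]
        raise EstimationError(
            "zero-variance channel(s) in window "
            f"{window_index}: {', '.join(names[i] for i in np.flatnonzero(flat))}"
        )

    m = cfg.n_subsegments(n)
    starts = np.arange(m) * cfg.step
    # (c, m, subwin) stack of sub-segments
    segs = np.stack([window[:, s:s + cfg.subwin_samples] for s in starts], axis=1)
    if cfg.detrend == "constant":
        segs = segs - segs.mean(axis=2, keepdims=True)
    taper = _signal.get_window(cfg.taper, cfg.subwin_samples)
    spec = np.fft.rfft(segs * taper, axis=2)  # (c, m, f)
    freqs = np.fft.rfftfreq(cfg.subwin_samples, d=1.0 / sfreq)

    # averaged auto/cross periodograms; scaling constants cancel in the ratio
    pxx = (spec.real ** 2 + spec.imag ** 2).mean(axis=1)           # (c, f)
    pxy = np.einsum("imf,jmf->ijf", spec, spec.conj()) / m         # (c, c, f)
    msc = (pxy.real ** 2 + pxy.imag ** 2) / (pxx[:, None, :] * pxx[None, :, :])
    msc = np.clip(msc, 0.0, 1.0)

    mask = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1]) & (freqs > 0)
    if not mask.any():
        raise ConfigurationError(f"band {cfg.band} is empty on the Welch grid")
    values = msc[:, :, mask].mean(axis=2)
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    np.fill_diagonal(values, 1.0)
    return CoherenceMatrix(
        values=values,
        window_index=window_index,
        band=cfg.band,
        channel_names=list(channel_names) if channel_names
        else [f"ch{i}" for i in range(c)],
    )


def oracle_msc(
    x: np.ndarray,
    y: np.ndarray,
    sfreq: float,
    cfg: SpectralConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force Welch MSC by explicit loops and discrete Fourier sums.

    Independent of :func:`msc_spectrum` (no shared spectral code); used
    as a test oracle.  O(M * n_freq * subwin) — fine for short signals.
    """
    cfg = cfg or SpectralConfig()
    x = [float(v) for v in np.asarray(x).ravel()]
    y = [float(v) for v in np.asarray(y).ravel()]
    if len(x) != len(y):
        raise EstimationError("x and y must have equal length")
    nper = cfg.subwin_samples
    step = cfg.step
    m = cfg.n_subsegments(len(x))
    if m < 2:
        raise EstimationError("fewer than 2 sub-segments")
    if max(x) == min(x) or max(y) == min(y):
        raise EstimationError("zero-variance input signal")

    # periodic taper, matching scipy.signal.get_window(cfg.taper, nper)
    taper = [float(w) for w in _signal.get_window(cfg.taper, nper)]
    n_freq = nper // 2 + 1
    pxx = [0.0] * n_freq
    pyy = [0.0] * n_freq
    pxy = [0j] * n_freq
    for seg in range(m):
        xs = x[seg * step:seg * step + nper]
        ys = y[seg * step:seg * step + nper]
        if cfg.detrend == "constant":
            mx = sum(xs) / nper
            my = sum(ys) / nper
            xs = [v - mx for v in xs]
            ys = [v - my for v in ys]
        xs = [v * w for v, w in zip(xs, taper)]
        ys = [v * w for v, w in zip(ys, taper)]
        for k in range(n_freq):
            xk = 0j
            yk = 0j
            for t in range(nper):
                e = cmath.exp(-2j * math.pi * k * t / nper)
                xk += xs[t] * e
                yk += ys[t] * e
            pxx[k] += abs(xk) ** 2 / m
            pyy[k] += abs(yk) ** 2 / m
            pxy[k] += xk * yk.conjugate() / m
    coh = [abs(pxy[k]) ** 2 / (pxx[k] * pyy[k]) for k in range(n_freq)]
    freqs = np.array([k * sfreq / nper for k in range(n_freq)])
    return freqs, np.clip(np.array(coh), 0.0, 1.0)
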