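"""Synthetic multichannel EEG with planted coherence structure.

Each recording is built from latent band-limited Gaussian sources shared
by groups of channels plus independent white Gaussian noise per channel:

    x_i(t) = sum_{g : i in g} s_g(t) + sigma * n_i(t)

Sources are white noise passed through a zero-phase band-pass and scaled
to unit sample variance; band-limited Gaussian noise (rather than
sinusoids) keeps magnitude-squared coherence stable across the averaging
band instead of degenerate at line frequencies.  For two channels that
share a single unit-power source whose band matches the noise band, the
population coherence within the band is (1/(1 + sigma^2))^2, which makes
the generator an analytic oracle for the spectral estimators downstream.

A cohort is a list of labeled recordings, several subjects per class,
each class with its own :class:`CouplingModel`.  One global seed expands
to per-subject sub-seeds through a fixed counter scheme, so any single
subject's signal is reproducible independent of generation order.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .errors import ConfigurationError
from .io import CHANNELS_10_20, Recording

__all__ = [
    "CouplingModel",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "default_cohort_spec",
]


@dataclasses.dataclass
class CouplingModel:
    """Generative model for one class of recordings.

    Parameters
    ----------
    n_channels : int
        Number of channels (default 19, the 10-20 montage).
    coupled_groups : list of sets of int
        Channel-index groups; each group shares one latent source.
    source_band : (float, float) or None
        Passband of each latent source in Hz.  ``None`` means a white
        (full-band) source, for which the shared-source coherence
        closed form (1/(1+sigma^2))^2 holds exactly per frequency bin.
    noise_sigma : float
        Standard deviation of the independent white noise added to each
        channel, relative to the unit-variance sources.
    sfreq : float
        Sampling frequency in Hz.
    seed : int
        Seed used when a recording is generated directly from the model.
    """

    n_channels: int = 19
    coupled_groups: Sequence[frozenset[int] | set[int]] = ()
    source_band: tuple[float, float] | None = (4.0, 30.0)
    noise_sigma: float = 1.0
    sfreq: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not self.sfreq > 0:
            raise ConfigurationError("sfreq must be positive")
        if self.source_band is not None:
            lo, hi = self.source_band
            if not (0 < lo < hi < self.sfreq / 2):
                raise ConfigurationError(
                    f"source_band {self.source_band} outside (0, {self.sfreq / 2})"
                )
        groups = []
        for g in self.coupled_groups:
            g = frozenset(int(i) for i in g)
            if len(g) < 2:
                raise ConfigurationError("each coupled group needs >= 2 channels")
            if any(i < 0 or i >= self.n_channels for i in g):
                raise ConfigurationError(f"group {sorted(g)} has out-of-range indices")
            groups.append(g)
        self.coupled_groups = tuple(groups)


@dataclasses.dataclass
class CohortSpec:
    """A multi-class cohort: ``classes`` is a list of
    (label, CouplingModel, n_subjects) triples."""

    classes: Sequence[tuple[str, CouplingModel, int]]
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.classes]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("duplicate class labels in CohortSpec")
        if any(n < 1 for _, _, n in self.classes):
            raise ConfigurationError("n_subjects must be >= 1 for every class")
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be positive")


def _band_limited_source(
    rng: np.random.Generator,
    n_samples: int,
    sfreq: float,
    band: tuple[float, float] | None,
) -> np.ndarray:
    """Unit-sample-variance Gaussian source, optionally band-limited by a
    zero-phase 4th-order Butterworth band-pass."""
    x = rng.standard_normal(n_samples)
    if band is not None:
        sos = _signal.butter(4, list(band), btype="bandpass", fs=sfreq,
                             output="sos")
        x = _signal.sosfiltfilt(sos, x)
    sd = x.std()
    if sd == 0:  # pragma: no cover - degenerate only for pathological bands
        raise ConfigurationError("source band produced a zero-variance signal")
    return x / sd


def generate_recording(
    model: CouplingModel,
    duration_s: float,
    subject_id: str,
    label: str | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Generate one recording from a coupling model.

    Channel i is the sum of the unit-variance sources of every group
    containing i, plus ``noise_sigma`` times independent standard white
    noise.  Deterministic given the model's seed (or the ``rng`` passed
    by :func:`generate_cohort`).
    """
    if not duration_s > 0:
        raise ConfigurationError("duration_s must be positive")
    n_samples = int(round(duration_s * model.sfreq))
    if n_samples < 2:
        raise ConfigurationError("duration too short for even two samples")
    if rng is None:
        rng = np.random.default_rng(model.seed)

    data = np.zeros((model.n_channels, n_samples))
    for group in model.coupled_groups:
        src = _band_limited_source(rng, n_samples, model.sfreq, model.source_band)
        for i in group:
            data[i] += src
    if model.noise_sigma > 0:
        data += model.noise_sigma * rng.standard_normal(data.shape)
    return Recording(
        subject_id=subject_id,
        label=label,
        channel_names=_channel_names(model.n_channels),
        sfreq=model.sfreq,
        data=data,
    )


def _channel_names(n: int) -> list[str]:
    if n == len(CHANNELS_10_20):
        return list(CHANNELS_10_20)
    return [f"ch{i:02d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate one Recording per subject for every class in the spec.

    Subject sub-seeds are spawned from the global seed by subject counter
    (class-major order), so each subject's signal is reproducible no
    matter how many other subjects are generated.
    """
    recordings: list[Recording] = []
    counter = 0
    for label, model, n_subjects in spec.classes:
        for j in range(n_subjects):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(counter,))
            rng = np.random.default_rng(ss)
            subject_id = f"{label}-s{j:02d}"
            recordings.append(
                generate_recording(model, spec.duration_s, subject_id,
                                   label=label, rng=rng)
            )
            counter += 1
    return recordings


#: Channel blocks of the 10-20 montage, by index into CHANNELS_10_20.
FRONTAL_BLOCK = frozenset(range(0, 7))        # Fp1..F8
POSTERIOR_BLOCK = frozenset(range(8, 19))     # C3..O2 (central-posterior)
OCCIPITAL_BLOCK = frozenset(range(12, 19))    # T5..O2


def default_cohort_spec(
    n_subjects: int = 6,
    duration_s: float = 60.0,
    seed: int = 0,
) -> CohortSpec:
    """Two-class study cohort with contrasting planted coupling.

    Both classes share a central-posterior coupled block; the
    dementia-like class has higher independent noise and therefore
    uniformly reduced pairwise coherence, emulating the coherence
    reduction seen in dementia EEG relative to controls.
    """
    ctrl = CouplingModel(coupled_groups=[POSTERIOR_BLOCK], noise_sigma=1.0)
    dem = CouplingModel(coupled_groups=[POSTERIOR_BLOCK], noise_sigma=2.5)
    return CohortSpec(
        classes=[("ctrl", ctrl, n_subjects), ("dem", dem, n_subjects)],
        duration_s=duration_s,
        seed=seed,
    )
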