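"""Connectogram-COH images: coherence graphs tiled over time.

Each sliding window's symmetric adjacency matrix is reduced to its
strictly-upper triangle, flattened in row-major pair order
(0,1), (0,2), ..., (0,c-1), (1,2), ..., (c-2,c-1) into a c(c-1)/2-long
vector — one pixel column.  Columns are tiled horizontally in window
order, so the horizontal axis is time and the vertical axis indexes
channel pairs.  For 19 channels the column height is 171; a 30 s segment
at the default windowing gives 149 columns, i.e. a 171 x 149 image.

Coherence is already in [0, 1], so no per-image normalisation is applied:
the grayscale mapping is absolute and images are comparable.  The float
NPZ form is canonical (classifiers consume it); 8-bit PNG export is for
inspection and interchange.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

from .coherence import CoherenceMatrix, SpectralConfig, window_adjacency
from .errors import ContractError, InputError
from .split import Segment, WindowSpec, slide_windows

__all__ = [
    "ConnectogramImage",
    "n_pairs",
    "pair_order",
    "flatten_upper",
    "unflatten_upper",
    "build_connectogram",
    "write_png",
    "write_npz",
    "read_npz",
]


def n_pairs(c: int) -> int:
    """Number of unordered channel pairs, c(c-1)/2."""
    return c * (c - 1) // 2


def pair_order(c: int) -> list[tuple[int, int]]:
    """Row-major strictly-upper pair order (i < j)."""
    rows, cols = np.triu_indices(c, k=1)
    return list(zip(rows.tolist(), cols.tolist()))


@dataclasses.dataclass
class ConnectogramImage:
    """pairs x windows real matrix in [0, 1] plus provenance metadata."""

    pixels: np.ndarray
    subject_id: str
    label: str | None
    segment_index: int
    pair_order: list[tuple[int, int]]
    window_spec: WindowSpec
    band: tuple[float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise InputError("pixels must be 2-D (pairs x windows)")
        if p.shape[0] != len(self.pair_order):
            raise InputError(
                f"{p.shape[0]} pixel rows but {len(self.pair_order)} pairs"
            )
        if p.size and (p.min() < 0 or p.max() > 1):
            raise InputError("pixel values must lie in [0, 1]")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def flatten_upper(mat: CoherenceMatrix | np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Strictly-upper triangle of a symmetric matrix as a row-major vector.

    For c channels the result has length c(c-1)/2 (171 for c=19).  An
    asymmetry beyond ``atol`` raises :class:`ContractError`.
    """
    values = mat.values if isinstance(mat, CoherenceMatrix) else np.asarray(mat)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ContractError("expected a square matrix")
    c = values.shape[0]
    if c < 2:
        raise ContractError("need at least 2 channels")
    if not np.allclose(values, values.T, atol=atol, rtol=0):
        raise ContractError("matrix is asymmetric beyond tolerance")
    iu, ju = np.triu_indices(c, k=1)
    return values[iu, ju].copy()


def unflatten_upper(vec: np.ndarray, c: int) -> np.ndarray:
    """Inverse of :func:`flatten_upper`: symmetric matrix, unit diagonal."""
    vec = np.asarray(vec, dtype=np.float64).ravel()
    if vec.size != n_pairs(c):
        raise InputError(
            f"vector length {vec.size} != c(c-1)/2 = {n_pairs(c)} for c={c}"
        )
    mat = np.eye(c)
    iu, ju = np.triu_indices(c, k=1)
    mat[iu, ju] = vec
    mat[ju, iu] = vec
    return mat


def build_connectogram(
    seg: Segment,
    wspec: WindowSpec | None = None,
    scfg: SpectralConfig | None = None,
    channel_names: list[str] | None = None,
) -> ConnectogramImage:
    """Transform one segment into its Connectogram-COH image.

    Column j is the flattened upper triangle of window j's coherence
    adjacency; columns run left to right in increasing time.
    """
    wspec = wspec or WindowSpec()
    scfg = scfg or SpectralConfig()
    windows = slide_windows(seg, wspec)
    c = seg.data.shape[0]
    columns = np.empty((n_pairs(c), len(windows)))
    for j, win in enumerate(windows):
        adj = window_adjacency(win, seg.sfreq, scfg,
                               channel_names=channel_names, window_index=j)
        columns[:, j] = flatten_upper(adj)
    return ConnectogramImage(
        pixels=columns,
        subject_id=seg.subject_id,
        label=seg.label,
        segment_index=seg.segment_index,
        pair_order=pair_order(c),
        window_spec=wspec,
        band=scfg.band,
    )


def quantize(values: np.ndarray) -> np.ndarray:
    """Map [0, 1] floats to 8-bit gray: clamp(floor(v*255 + 0.5), 0, 255)."""
    return np.clip(np.floor(values * 255.0 + 0.5), 0, 255).astype(np.uint8)


def write_png(img: ConnectogramImage, path: str | Path) -> Path:
    """8-bit grayscale PNG; top row = first pair, left column = first window."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(quantize(img.pixels), mode="L").save(path, format="PNG")
    return path


def write_npz(img: ConnectogramImage, path: str | Path) -> Path:
    """Lossless canonical NPZ form including all metadata fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        pixels=img.pixels,
        subject_id=np.str_(img.subject_id),
        label=np.str_(img.label if img.label is not None else ""),
        segment_index=np.int64(img.segment_index),
        pair_order=np.array(img.pair_order, dtype=np.int64),
        window_s=np.float64(img.window_spec.window_s),
        step_s=np.float64(img.window_spec.step_s),
        band=np.array(img.band, dtype=np.float64),
    )
    return path


def read_npz(path: str | Path) -> ConnectogramImage:
    """Read a ConnectogramImage from the canonical NPZ schema."""
    path = Path(path)
    required = {"pixels", "subject_id", "label", "segment_index",
                "pair_order", "window_s", "step_s", "band"}
    with np.load(path, allow_pickle=False) as npz:
        missing = required - set(npz.files)
        if missing:
            raise InputError(
                f"{path}: missing NPZ field(s): {', '.join(sorted(missing))}"
            )
        label = str(npz["label"])
        return ConnectogramImage(
            pixels=np.asarray(npz["pixels"], dtype=np.float64),
            subject_id=str(npz["subject_id"]),
            label=label if label else None,
            segment_index=int(npz["segment_index"]),
            pair_order=[tuple(p) for p in npz["pair_order"].tolist()],
            window_spec=WindowSpec(float(npz["window_s"]), float(npz["step_s"])),
            band=tuple(npz["band"].tolist()),
        )
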