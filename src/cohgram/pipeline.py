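"""End-to-end pipeline: simulate -> split -> transform -> train/evaluate.

Each stage reads and writes plain files (NPZ recordings and images, CSV
manifests, JSON reports) under a run directory, so stages can be run in
isolation or chained; a run-metadata JSON records the configuration, a
config hash, package versions and the global seed for traceability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .coherence import SpectralConfig
from .errors import ConfigurationError
from .evaluate import TrainConfig, subject_wise_cv
from .image import build_connectogram, read_npz, write_npz, write_png
from .io import Recording, read_recording, write_recording
from .models import ModelSpec
from .split import SplitPlan, WindowSpec, assign_folds, segment_recording
from .synthetic import CohortSpec, default_cohort_spec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "simulate_stage", "split_stage",
           "transform_stage", "train_stage"]


@dataclasses.dataclass
class RunConfig:
    """All stage parameters for one pipeline run."""

    outdir: Path = Path("cohgram-run")
    seed: int = 0
    # cohort
    n_subjects: int = 6
    duration_s: float = 60.0
    # segmentation / windowing
    segment_length_s: float = 10.0
    window: WindowSpec = dataclasses.field(default_factory=WindowSpec)
    spectral: SpectralConfig = dataclasses.field(default_factory=SpectralConfig)
    # CV / model / training
    k: int = 5
    model: ModelSpec = dataclasses.field(
        default_factory=lambda: ModelSpec(architecture="shallow_resnet",
                                          input_shape=(171, 49), n_classes=2))
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    write_pngs: bool = True

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        if "window" in raw:
            kwargs["window"] = WindowSpec(**raw.pop("window"))
        if "spectral" in raw:
            spec = raw.pop("spectral")
            if "band" in spec:
                spec["band"] = tuple(spec["band"])
            kwargs["spectral"] = SpectralConfig(**spec)
        if "model" in raw:
            m = raw.pop("model")
            if "input_shape" in m:
                m["input_shape"] = tuple(m["input_shape"])
            kwargs["model"] = ModelSpec(**m)
        if "training" in raw:
            kwargs["training"] = TrainConfig(**raw.pop("training"))
        if "outdir" in raw:
            kwargs["outdir"] = Path(raw.pop("outdir"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulate_stage(cfg: RunConfig, spec: CohortSpec | None = None) -> Path:
    """Generate the synthetic cohort and write one NPZ per subject plus
    a manifest CSV."""
    spec = spec or default_cohort_spec(
        n_subjects=cfg.n_subjects, duration_s=cfg.duration_s, seed=cfg.seed)
    cohort_dir = cfg.outdir / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in generate_cohort(spec):
        path = cohort_dir / f"{rec.subject_id}.npz"
        write_recording(rec, path)
        rows.append({
            "subject_id": rec.subject_id,
            "label": rec.label,
            "path": str(path),
            "sfreq": rec.sfreq,
            "n_channels": rec.n_channels,
            "duration_s": rec.duration_s,
        })
    manifest = cfg.outdir / "cohort" / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def split_stage(cfg: RunConfig, manifest: Path | None = None) -> Path:
    """Assign subjects to folds (stratified by label) and write folds.csv."""
    manifest = manifest or cfg.outdir / "cohort" / "manifest.csv"
    df = pd.read_csv(manifest)
    plan = assign_folds(
        list(zip(df["subject_id"], df["label"])), k=cfg.k, seed=cfg.seed)
    out = cfg.outdir / "folds.csv"
    pd.DataFrame([
        {"subject_id": sid, "label": lab, "fold": plan.assignment[sid]}
        for sid, lab in zip(df["subject_id"], df["label"])
    ]).to_csv(out, index=False)
    return out


def transform_stage(cfg: RunConfig, manifest: Path | None = None) -> Path:
    """Segment every recording and write one connectogram NPZ (and
    optionally PNG) per segment plus an image manifest."""
    manifest = manifest or cfg.outdir / "cohort" / "manifest.csv"
    df = pd.read_csv(manifest)
    img_dir = cfg.outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in df.itertuples():
        label = None if pd.isna(row.label) else str(row.label)
        rec: Recording = read_recording(row.path, subject_id=row.subject_id,
                                        label=label)
        for seg in segment_recording(rec, cfg.segment_length_s):
            img = build_connectogram(seg, cfg.window, cfg.spectral,
                                     channel_names=rec.channel_names)
            stem = f"{seg.subject_id}_seg{seg.segment_index:03d}"
            npz_path = write_npz(img, img_dir / f"{stem}.npz")
            if cfg.write_pngs:
                write_png(img, img_dir / f"{stem}.png")
            rows.append({
                "path": str(npz_path),
                "subject_id": seg.subject_id,
                "label": seg.label,
                "segment_index": seg.segment_index,
                "height": img.shape[0],
                "width": img.shape[1],
            })
    out = img_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def train_stage(
    cfg: RunConfig,
    image_manifest: Path | None = None,
    folds_csv: Path | None = None,
) -> Path:
    """Run subject-wise k-fold CV on the transformed images and write
    per-fold reports (JSON + confusion CSVs) and the aggregate."""
    image_manifest = image_manifest or cfg.outdir / "images" / "manifest.csv"
    folds_csv = folds_csv or cfg.outdir / "folds.csv"
    df = pd.read_csv(image_manifest)
    folds = pd.read_csv(folds_csv)
    plan = SplitPlan(k=cfg.k, assignment=dict(
        zip(folds["subject_id"], folds["fold"].astype(int))))
    images = np.stack([read_npz(p).pixels for p in df["path"]])
    reports, aggregate = subject_wise_cv(
        images, df["label"].astype(str).tolist(),
        df["subject_id"].tolist(), plan, cfg.model, cfg.training)
    rep_dir = cfg.outdir / "reports"
    rep_dir.mkdir(parents=True, exist_ok=True)
    for i, rep in enumerate(reports):
        (rep_dir / f"fold{i}.json").write_text(
            json.dumps(rep.to_dict(), indent=2))
        pd.DataFrame(rep.confusion, index=rep.classes,
                     columns=rep.classes).to_csv(rep_dir / f"fold{i}_confusion.csv")
    out = rep_dir / "aggregate.json"
    out.write_text(json.dumps(aggregate, indent=2))
    return out


def run_pipeline(cfg: RunConfig, cohort: CohortSpec | None = None) -> Path:
    """Run every stage in order; returns the run directory."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "cohgram_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    (cfg.outdir / "run.json").write_text(json.dumps(meta, indent=2))
    manifest = simulate_stage(cfg, cohort)
    split_stage(cfg, manifest)
    transform_stage(cfg, manifest)
    train_stage(cfg)
    return cfg.outdir
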