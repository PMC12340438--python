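"""Segment readers/writers and the YAML run configuration.

On-disk contracts:

* NPZ — arrays ``segments`` (n x L) and optionally ``labels`` (n,), the
  format :func:`seiznet.synth.save_dataset` writes;
* CSV — one row per segment, columns ``s0..s{L-1}``, optional trailing
  ``label`` column;
* run config — versioned YAML with ``model:`` / ``synth:`` sections whose
  keys map 1:1 onto :class:`ModelConfig` / :class:`SynthConfig`; unknown
  keys are errors, not warnings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelConfig
from .spectral import EEGBatch
from .synth import SynthConfig

__all__ = ["read_segments", "write_segments", "RunConfig", "load_run_config"]

CONFIG_VERSION = 1


def _read_npz(path: Path) -> EEGBatch:
    with np.load(path, allow_pickle=False) as archive:
        if "segments" not in archive.files:
            raise ValueError(f"{path}: NPZ is missing the 'segments' array")
        segments = archive["segments"]
        labels = archive["labels"] if "labels" in archive.files else None
    return EEGBatch(data=segments, labels=labels)


def _read_csv(path: Path) -> EEGBatch:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed CSV ({exc})") from None
    if frame.empty:
        raise ValueError(f"{path}: no segment rows")
    labels = None
    if "label" in frame.columns:
        labels = frame.pop("label").to_numpy()
    bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric columns {bad}")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing/ragged values at row {row}")
    return EEGBatch(data=frame.to_numpy(dtype=np.float64), labels=labels)


def read_segments(path, format: str | None = None,
                  expected_length: int | None = None,
                  require_labels: bool = False) -> EEGBatch:
    """Load an (n x L) segment matrix (+ optional labels) from NPZ or CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: file is empty")
    fmt = format or ("npz" if path.suffix.lower() == ".npz" else "csv")
    if fmt == "npz":
        batch = _read_npz(path)
    elif fmt == "csv":
        batch = _read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'npz' or 'csv'")
    if expected_length is not None and batch.segment_length != expected_length:
        raise ValueError(
            f"{path}: segments have length {batch.segment_length}, "
            f"expected {expected_length}"
        )
    if require_labels and batch.labels is None:
        raise ValueError(f"{path}: labelled mode requires a labels column/array")
    return batch


def write_segments(path, segments: np.ndarray, labels: np.ndarray | None = None,
                   format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("npz" if path.suffix.lower() == ".npz" else "csv")
    segments = np.atleast_2d(np.asarray(segments, dtype=np.float64))
    if fmt == "npz":
        arrays = {"segments": segments}
        if labels is not None:
            arrays["labels"] = np.asarray(labels)
        np.savez(path, **arrays)
    elif fmt == "csv":
        frame = pd.DataFrame(segments,
                             columns=[f"s{i}" for i in range(segments.shape[1])])
        if labels is not None:
            frame["label"] = np.asarray(labels)
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


@dataclass
class RunConfig:
    """Everything one CLI run needs: model + generator settings and paths."""

    model: ModelConfig = field(default_factory=ModelConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    paths: dict = field(default_factory=dict)
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return {
            "version": CONFIG_VERSION,
            "model": dataclasses.asdict(self.model),
            "synth": self.synth.to_manifest(),
            "paths": dict(self.paths),
            "verbosity": self.verbosity,
        }


def _build_section(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
    if cls is SynthConfig:
        return SynthConfig.from_manifest(section)
    return cls(**section)


def load_run_config(path) -> RunConfig:
    """Parse and validate a versioned YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    version = raw.pop("version", None)
    if version != CONFIG_VERSION:
        raise ValueError(
            f"{path}: unsupported config version {version!r} "
            f"(expected {CONFIG_VERSION})"
        )
    allowed = {"model", "synth", "paths", "verbosity"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    return RunConfig(
        model=_build_section(ModelConfig, raw.get("model", {}), "model"),
        synth=_build_section(SynthConfig, raw.get("synth", {}), "synth"),
        paths=dict(raw.get("paths", {})),
        verbosity=str(raw.get("verbosity", "info")),
    )


def round_trip_check(config: RunConfig) -> bool:
    """A run config must serialise losslessly (YAML -> dict -> YAML)."""
    dumped = yaml.safe_dump(config.to_dict())
    reloaded = yaml.safe_load(dumped)
    return reloaded == config.to_dict()
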