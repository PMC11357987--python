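"""On-disk formats, run configuration and data-hygiene filters.

Recordings travel as channels x time matrices in either delimited text
(CSV/TSV, header row of channel labels, one column per channel) or a binary
array container (``.npz``); both carry a JSON sidecar (``<path>.json``) with
the sampling interval, labels and provenance. Neuroimaging container
formats are deliberately not parsed — users export plain matrices.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import Recording
from .errors import FormatError, InvalidParameterError

__all__ = ["read_matrix", "write_matrix", "filter_nan_segments", "RunConfig",
           "ReportBundle"]

logger = logging.getLogger(__name__)

_KNOWN_FAMILIES = ("zero", "linear", "subspace", "manifold", "mmse", "mlp")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_matrix(recording: Recording, path: str | Path,
                 format: str = "delimited", delimiter: str = ",") -> None:
    """Write a Recording plus its JSON sidecar (sampling interval, labels)."""
    path = Path(path)
    meta = {"sampling_interval": recording.sampling_interval,
            "labels": list(recording.labels),
            "n_channels": recording.n_channels,
            "n_samples": recording.n_samples}
    if format == "binary":
        np.savez(path, values=recording.values)
    elif format == "delimited":
        df = pd.DataFrame(recording.values.T, columns=recording.labels)
        df.to_csv(path, index=False, sep=delimiter, float_format="%.17g")
    else:
        raise InvalidParameterError(f"unknown format {format!r}")
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_matrix(path: str | Path, format: str = "delimited",
                sampling_interval: float | None = None,
                delimiter: str = ",") -> Recording:
    """Read a Recording; the sampling interval comes from the sidecar unless
    given explicitly. Binary round-trips are bit-exact."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    labels = None
    if sampling_interval is None or labels is None:
        sc = _sidecar(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
            sampling_interval = sampling_interval or meta.get("sampling_interval")
            labels = meta.get("labels")
    if sampling_interval is None:
        raise FormatError(
            f"{path}: sampling interval missing (no sidecar {_sidecar(path)} "
            "and none given)")
    if format == "binary":
        values = np.load(path)["values"]
    elif format == "delimited":
        df = pd.read_csv(path, sep=delimiter)
        bad = df.apply(pd.to_numeric, errors="coerce")
        if bad.isna().values.any() and not df.isna().values.any():
            r, c = np.argwhere(bad.isna().values)[0]
            raise FormatError(
                f"{path}: non-numeric cell at row {r + 1}, column "
                f"{df.columns[c]!r} (value {df.iloc[r, c]!r})")
        try:
            values = df.to_numpy(dtype=float).T
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric data ({exc})") from exc
        labels = labels or list(df.columns)
    else:
        raise InvalidParameterError(f"unknown format {format!r}")
    return Recording(values, float(sampling_interval), labels)


def filter_nan_segments(segments: list[Recording | np.ndarray]
                        ) -> tuple[list, list[dict]]:
    """Drop any segment containing a non-finite value (NaN or infinity).

    Returns (kept segments, report of dropped segments with their indices).
    """
    kept, dropped = [], []
    for idx, seg in enumerate(segments):
        values = seg.values if isinstance(seg, Recording) else np.asarray(seg)
        if np.all(np.isfinite(values)):
            kept.append(seg)
        else:
            n_bad = int(np.size(values) - np.isfinite(values).sum())
            dropped.append({"index": idx, "non_finite_entries": n_bad})
            logger.info("dropped segment %d (%d non-finite entries)",
                        idx, n_bad)
    if segments and not kept:
        raise InvalidParameterError("all segments contained non-finite values")
    return kept, dropped


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one benchmark run."""

    family: str = "zero"
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    modality: str = "fmri-like"
    train_fraction: float = 0.8
    seed: int = 0
    whiteness_lags: int | None = None
    n_shuffles: int = 100
    data_paths: list[str] = dataclasses.field(default_factory=list)
    data_format: str = "delimited"

    def __post_init__(self) -> None:
        if self.family not in _KNOWN_FAMILIES:
            raise InvalidParameterError(
                f"unknown family {self.family!r}; valid: {_KNOWN_FAMILIES}")
        if self.modality not in ("fmri-like", "ieeg-like", "custom"):
            raise InvalidParameterError(f"unknown modality {self.modality!r}")
        if not (0 < self.train_fraction < 1):
            raise InvalidParameterError("train_fraction must lie in (0, 1)")
        if self.seed < 0 or self.seed >= 2**31:
            raise InvalidParameterError("seed must lie in [0, 2^31)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


@dataclasses.dataclass
class ReportBundle:
    """Everything needed to re-run an experiment plus its results."""

    config: dict
    scores: list[dict]
    extras: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "scores": self.scores,
                           "extras": self.extras}, indent=1, sort_keys=True,
                          default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "ReportBundle":
        raw = json.loads(text)
        return cls(raw["config"], raw["scores"], raw.get("extras", {}))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
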