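"""File I/O: trajectories and datasets as CSV, configs as YAML/JSON, reports.

Conventions are pinned for reproducibility: comma-separated, '.' decimal,
header row, UTF-8; the time column is minutes throughout.  CSV bodies are
deterministic (repr-roundtrip floats), so equal configs give byte-identical
files; run metadata (package version, resolved config and its hash) goes to
a JSON sidecar, never into the CSV body.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .datasets import BSPDataset
from .model import FractionalConfig, LiverParams, Trajectory

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_dataset",
    "write_dataset",
    "write_report",
    "params_from_dict",
    "config_from_dict",
]

_CONFIG_KEYS = {
    "alpha", "beta", "delta", "R0", "W0", "vartheta", "rho", "normalization",
}


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as ``time,R,W`` CSV (deterministic body)."""
    lines = ["time,R,W"]
    for t, r, w in zip(traj.times, traj.R, traj.W):
        lines.append(f"{_fmt(t)},{_fmt(r)},{_fmt(w)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trajectory(path: str | Path, provenance: str = "unknown") -> Trajectory:
    times, R, W = _read_columns(path, ("time", "R", "W"))
    return Trajectory(times, R, W, provenance=provenance)


def write_dataset(data: BSPDataset, path: str | Path, sidecar: bool = True) -> None:
    """Write a dataset as ``time,blood[,liver]`` CSV plus a JSON metadata sidecar.

    A liver channel on a different grid is written as empty cells at blood
    times without a liver sample.
    """
    has_liver = data.liver is not None
    header = "time,blood,liver" if has_liver else "time,blood"
    liver_map = (
        {float(t): v for t, v in zip(data.liver_times, data.liver)} if has_liver else {}
    )
    all_times = sorted(set(map(float, data.times)) | set(liver_map))
    blood_map = {float(t): v for t, v in zip(data.times, data.blood)}
    lines = [header]
    for t in all_times:
        cells = [_fmt(t)]
        cells.append(_fmt(blood_map[t]) if t in blood_map else "")
        if has_liver:
            cells.append(_fmt(liver_map[t]) if t in liver_map else "")
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if sidecar:
        meta = {"label": data.label, "noise_sd": data.noise_sd, **data.meta}
        Path(str(path) + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
        )


def read_dataset(path: str | Path, label: str | None = None) -> BSPDataset:
    """Read a ``time,blood[,liver]`` CSV; validates monotone times per row."""
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    header = [h.strip() for h in text[0].split(",")]
    if header[:2] != ["time", "blood"]:
        raise ValueError(f"expected header 'time,blood[,liver]', got {text[0]!r}")
    has_liver = len(header) > 2 and header[2] == "liver"
    times, blood, ltimes, liver = [], [], [], []
    prev = -np.inf
    for i, line in enumerate(text[1:], start=2):
        cells = line.split(",")
        t = float(cells[0])
        if t <= prev:
            raise ValueError(f"non-monotone time at row {i}: {line!r}")
        prev = t
        if cells[1].strip() != "":
            times.append(t)
            blood.append(float(cells[1]))
        if has_liver and len(cells) > 2 and cells[2].strip() != "":
            ltimes.append(t)
            liver.append(float(cells[2]))
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return BSPDataset(
        times=np.array(times),
        blood=np.array(blood),
        liver=np.array(liver) if liver else None,
        liver_times=np.array(ltimes) if liver else None,
        noise_sd=meta.get("noise_sd"),
        label=label if label is not None else meta.get("label", str(path)),
        meta={k: v for k, v in meta.items() if k not in {"label", "noise_sd"}},
    )


def _read_columns(path: str | Path, names: tuple[str, ...]):
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    header = [h.strip() for h in text[0].split(",")]
    if header != list(names):
        raise ValueError(f"expected header {','.join(names)!r}, got {text[0]!r}")
    cols = [[] for _ in names]
    for line in text[1:]:
        for c, cell in zip(cols, line.split(",")):
            c.append(float(cell))
    return tuple(np.array(c) for c in cols)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Flat, serializable model + fractional configuration.

    Keys: alpha, beta, delta, R0, W0, vartheta, rho, normalization.
    Unknown keys are rejected on parse; serialize/parse round-trips exactly.
    """

    alpha: float
    beta: float
    delta: float
    R0: float
    W0: float = 0.0
    vartheta: float = 1.0
    rho: float = 1.0
    normalization: str = "unit"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"alpha", "beta", "delta", "R0"} - set(d)
        if missing:
            raise ValueError(f"missing config keys: {sorted(missing)}")
        cfg = cls(**d)
        cfg.params()  # validate ranges eagerly
        cfg.fractional()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        d = yaml.safe_load(text)  # YAML parses JSON too
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    def params(self) -> LiverParams:
        return LiverParams(self.alpha, self.beta, self.delta, self.R0, self.W0)

    def fractional(self) -> FractionalConfig:
        return FractionalConfig(self.vartheta, rho=self.rho, normalization=self.normalization)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def params_from_dict(d: dict[str, Any]) -> LiverParams:
    return RunConfig.from_dict(d).params()


def config_from_dict(d: dict[str, Any]) -> FractionalConfig:
    return RunConfig.from_dict(d).fractional()


def write_report(path: str | Path, config: RunConfig | None, payload: dict[str, Any]) -> None:
    """JSON report embedding the package version and resolved-config hash."""
    body = {
        "package": "fracliver",
        "version": __version__,
        "config": config.to_dict() if config else None,
        "config_hash": config.digest() if config else None,
        **payload,
    }
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True), encoding="utf-8")
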