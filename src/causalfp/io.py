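"""Plain-text readers/writers for recordings, partitions and signatures.

Formats
-------
Time series
    CSV with ``p`` rows and ``T + 2`` columns: parcel label, then the
    ``T + 1`` activity values. A JSON sidecar (same stem, ``.json``)
    carries the sampling interval ``{"dt": 0.72}``.
Partition
    JSON ``{"state": [labels...], "input": [labels...]}``.
Signature
    Directory with ``manifest.json`` (m, n, dt, lambda, residual, mode)
    and ``Q.csv``, ``A.csv``, ``B1.csv``, ``B2.csv``.
Landscape
    ``values.csv`` (region, value, normalized) and ``grid.csv`` (12 x 12,
    masked cells empty).

All numeric round trips are lossless at full printed precision (%.17g).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .dynamics import CausalSignature
from .reachability import ReachabilityLandscape
from .timeseries import ParcellatedTimeSeries, PartitionSpec

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_partition",
    "write_partition",
    "read_signature",
    "write_signature",
    "write_landscape",
]

_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_timeseries(ts: ParcellatedTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for label, row in zip(ts.parcel_labels, ts.values):
            w.writerow([label] + [_FMT % v for v in row])
    _sidecar(path).write_text(json.dumps({"dt": ts.dt}) + "\n")


def read_timeseries(path: str | Path) -> ParcellatedTimeSeries:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar {side} (must contain the sampling interval dt)"
        )
    meta = json.loads(side.read_text())
    if "dt" not in meta:
        raise ValueError(f"{side}: sidecar JSON has no 'dt' entry")

    labels: list[str] = []
    rows: list[list[float]] = []
    width = None
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec:
                continue
            if width is None:
                width = len(rec)
            elif len(rec) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(rec)} columns, expected {width})"
                )
            label = rec[0]
            if label in labels:
                raise ValueError(f"{path}:{lineno}: duplicate parcel label {label!r}")
            try:
                rows.append([float(v) for v in rec[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            labels.append(label)
    if not rows:
        raise ValueError(f"{path}: empty time-series file")
    return ParcellatedTimeSeries(
        values=np.array(rows), dt=float(meta["dt"]), parcel_labels=labels
    )


def write_partition(
    state_labels: list[str], input_labels: list[str], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({"state": list(state_labels), "input": list(input_labels)}, indent=1)
        + "\n"
    )


def read_partition(
    path: str | Path, ts: ParcellatedTimeSeries
) -> PartitionSpec:
    """Resolve a label-based partition file against a time series."""
    spec = json.loads(Path(path).read_text())
    for key in ("state", "input"):
        if key not in spec:
            raise ValueError(f"{path}: partition JSON has no {key!r} list")
    return PartitionSpec.from_labels(ts, spec["state"], spec["input"])


def write_signature(sig: CausalSignature, dirpath: str | Path) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    manifest = {
        "m": sig.m,
        "n": sig.n,
        "dt": sig.dt,
        "lambda": sig.lambda_reg,
        "residual": sig.residual_norm,
        "mode": sig.mode,
    }
    if sig.partition is not None:
        manifest["state_idx"] = sig.partition.state_idx
        manifest["input_idx"] = sig.partition.input_idx
    (dirpath / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    for name in ("Q", "A", "B1", "B2"):
        np.savetxt(dirpath / f"{name}.csv", getattr(sig, name), delimiter=",", fmt=_FMT)


def read_signature(dirpath: str | Path) -> CausalSignature:
    dirpath = Path(dirpath)
    manifest = json.loads((dirpath / "manifest.json").read_text())
    m, n = int(manifest["m"]), int(manifest["n"])
    blocks = {}
    for name in ("Q", "A", "B1", "B2"):
        if name in ("B1", "B2") and n == 0:
            blocks[name] = np.zeros((m, 0))
            continue
        blocks[name] = np.loadtxt(dirpath / f"{name}.csv", delimiter=",", ndmin=2)
    part = None
    if "state_idx" in manifest:
        part = PartitionSpec(
            state_idx=manifest["state_idx"], input_idx=manifest.get("input_idx", [])
        )
    return CausalSignature(
        **blocks,
        dt=float(manifest["dt"]),
        lambda_reg=float(manifest.get("lambda", 0.0)),
        residual_norm=float(manifest.get("residual", 0.0)),
        partition=part,
        mode=manifest.get("mode", "ridge"),
    )


def write_landscape(land: ReachabilityLandscape, dirpath: str | Path) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    flat = land.grid.data.ravel()
    mask = land.grid.mask.ravel()
    with open(dirpath / "values.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region", "value", "normalized"])
        for i, v in enumerate(land.values):
            w.writerow([i, _FMT % v, _FMT % flat[i]])
    with open(dirpath / "grid.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        side = land.grid.shape[0]
        for r in range(side):
            w.writerow(
                ["" if land.grid.mask[r, c] else _FMT % land.grid.data[r, c] for c in range(side)]
            )
    (dirpath / "landscape.json").write_text(
        json.dumps(
            {
                "horizon": land.horizon,
                "norm_model": land.norm_model,
                "normalization": land.normalization,
                "m": int(land.m),
            },
            indent=1,
        )
        + "\n"
    )
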