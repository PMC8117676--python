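"""Readers, writers and run records for reduced scattering data.

Curve files are whitespace-delimited ASCII with ``#``-prefixed header
lines carrying metadata (``# key: value``).  Reflectivity files hold
four columns ``q R dR dq`` (q in Å⁻¹, dq as Gaussian fwhm); SANS files
hold ``q I dI [dq]`` with I in cm⁻¹.  Readers accept their own
writers' output bit-identically at the declared precision and reject
malformed rows with their line number.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .contrast_refinement import ContrastDataset
from .nanodisc_sans import SansCurve, SansDataset
from .slab_reflectivity import ReflectivityCurve

__all__ = [
    "read_curve",
    "write_curve",
    "read_nr_dataset",
    "read_sans_dataset",
    "write_nr_dataset",
    "write_sans_dataset",
    "RunRecord",
]

_PRECISION = "%.8e"


def _parse_headers(lines) -> dict[str, str]:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, value = body.split(":", 1)
            meta[key.strip()] = value.strip()
    return meta


def read_curve(path) -> tuple[np.ndarray, dict[str, str]]:
    """Parse a curve file into a (n, 3|4) column array plus header metadata.

    Raises ``ValueError`` naming the offending line for malformed rows,
    non-positive q, or fewer than three columns.
    """
    path = Path(path)
    headers, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                headers.append(stripped)
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 numeric columns, "
                    f"got {len(fields)}")
            try:
                values = [float(f) for f in fields[:4]]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value in {fields!r}"
                ) from None
            if values[0] <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive q {values[0]}")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncols = min(len(r) for r in rows)
    data = np.array([r[:ncols] for r in rows], dtype=float)
    if data.shape[1] < 3:
        raise ValueError(f"{path}: uncertainty column missing "
                         "(fits require weights)")
    return data, _parse_headers(headers)


def _write_columns(path, columns, meta) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        data = np.column_stack(columns)
        for row in data:
            fh.write(" ".join(_PRECISION % v for v in row) + "\n")


def write_curve(path, curve, meta: dict | None = None) -> None:
    """Write a ReflectivityCurve or SansCurve with self-describing headers."""
    meta = dict(meta or {})
    if isinstance(curve, ReflectivityCurve):
        meta.setdefault("kind", "reflectivity")
        meta.setdefault("columns", "q(1/A) R dR dq_fwhm(1/A)")
        _write_columns(path, (curve.q, curve.R, curve.dR, curve.dq), meta)
    elif isinstance(curve, SansCurve):
        meta.setdefault("kind", "sans")
        if curve.dq is not None:
            meta.setdefault("columns", "q(1/A) I(1/cm) dI dq_fwhm(1/A)")
            _write_columns(path, (curve.q, curve.I, curve.dI, curve.dq), meta)
        else:
            meta.setdefault("columns", "q(1/A) I(1/cm) dI")
            _write_columns(path, (curve.q, curve.I, curve.dI), meta)
    else:
        raise TypeError(f"unsupported curve type {type(curve)!r}")


def write_nr_dataset(path, dataset: ContrastDataset) -> None:
    write_curve(path, dataset.curve, {
        "contrast": dataset.label,
        "d2o_fraction": repr(dataset.d2o_fraction),
    })


def write_sans_dataset(path, dataset: SansDataset) -> None:
    write_curve(path, dataset.curve, {
        "contrast": dataset.label,
        "d2o_fraction": repr(dataset.d2o_fraction),
        "background": repr(dataset.background),
    })


def _require_d2o(meta, path) -> float:
    if "d2o_fraction" not in meta:
        raise ValueError(f"{path}: header lacks 'd2o_fraction'")
    return float(meta["d2o_fraction"])


def read_nr_dataset(path) -> ContrastDataset:
    """Read a 4-column reflectivity file into a ContrastDataset."""
    data, meta = read_curve(path)
    if data.shape[1] < 4:
        data = np.column_stack([data, np.zeros(len(data))])
    curve = ReflectivityCurve(q=data[:, 0], R=data[:, 1], dR=data[:, 2],
                              dq=data[:, 3])
    return ContrastDataset(
        label=meta.get("contrast", Path(path).stem),
        d2o_fraction=_require_d2o(meta, path),
        curve=curve,
    )


def read_sans_dataset(path) -> SansDataset:
    """Read a 3- or 4-column SANS file into a SansDataset."""
    data, meta = read_curve(path)
    curve = SansCurve(q=data[:, 0], I=data[:, 1], dI=data[:, 2],
                      dq=data[:, 3] if data.shape[1] > 3 else None)
    return SansDataset(
        label=meta.get("contrast", Path(path).stem),
        d2o_fraction=_require_d2o(meta, path),
        curve=curve,
        background=float(meta.get("background", 0.0)),
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one CLI run, sufficient to reproduce its outputs."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    software: str = field(default_factory=lambda: _version_string())

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _digest(path)

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest()[:16],
            "inputs": self.inputs,
            "outputs": self.outputs,
            "started": self.started,
            "software": self.software,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _version_string() -> str:
    from . import __version__

    return f"liposcatter {__version__} / python {platform.python_version()}"
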