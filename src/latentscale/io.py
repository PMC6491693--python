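"""Delimited-text readers/writers and run manifests shared by all commands.

Matrices travel as comma- or tab-separated text: square covariance or
correlation matrices carry a header row of variable names (symmetry is
validated on read); loading matrices carry a header row of factor names and
an index column of variable names.  Reports are written either as delimited
tables (floats at 6 significant digits) or as JSON with full precision.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import DimensionError

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "write_report",
    "read_report",
    "RunManifest",
]

_SYMMETRY_TOL = 1e-6


class MatrixParseError(ValueError):
    """A delimited matrix file could not be parsed or failed validation."""


def _detect_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in head else ","


def read_matrix(path, kind: str = "covariance") -> pd.DataFrame:
    """Read a delimited matrix with names attached.

    ``kind`` is ``covariance`` or ``correlation`` (square, header row of
    variable names, symmetry enforced) or ``loadings`` (header row of factor
    names, first column of variable names).
    """
    if kind not in ("covariance", "correlation", "loadings"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path)
    index_col = 0 if kind == "loadings" else None
    try:
        df = pd.read_csv(path, sep=sep, index_col=index_col)
    except Exception as exc:  # ragged rows, decode errors
        raise MatrixParseError(f"{path}: {exc}") from exc

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise MatrixParseError(
                f"{path}: non-numeric cell at row {row + 1}, column {col!r}"
            )
        df[col] = coerced
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise MatrixParseError(
            f"{path}: non-finite cell at row {i + 1}, column {df.columns[j]!r}"
        )

    if kind in ("covariance", "correlation"):
        if df.shape[0] != df.shape[1]:
            raise MatrixParseError(
                f"{path}: expected a square matrix, got {df.shape[0]} x {df.shape[1]}"
            )
        df.index = pd.Index(df.columns, name=None)
        asym = np.abs(values - values.T)
        if np.max(asym, initial=0.0) > _SYMMETRY_TOL:
            i, j = map(int, np.unravel_index(np.argmax(asym), asym.shape))
            raise MatrixParseError(
                f"{path}: asymmetric beyond {_SYMMETRY_TOL} at "
                f"({df.columns[i]!r}, {df.columns[j]!r})"
            )
    return df


def write_matrix(df: pd.DataFrame, path, kind: str = "covariance") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=(kind == "loadings"))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results, path, format: str = "structured") -> None:
    """Write a module report deterministically.

    ``delimited`` expects a DataFrame (or dict of columns) and renders floats
    at 6 significant digits; ``structured`` writes JSON at full precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        df.to_csv(path, float_format="%.6g")
    elif format == "structured":
        with open(path, "w") as fh:
            json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path):
    """Read back a structured (JSON) report."""
    with open(path) as fh:
        return json.load(fh)


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    options: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    seed: int | None = None
    tool_version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")

    @classmethod
    def for_run(cls, command: str, inputs: dict, options: dict, seed: int | None = None):
        digests = {name: _digest(p) for name, p in inputs.items() if Path(p).exists()}
        return cls(command=command, options=_jsonable(options), input_digests=digests, seed=seed)

    def write(self, path) -> None:
        write_report(asdict(self), path, format="structured")
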