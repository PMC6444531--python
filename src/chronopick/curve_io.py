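"""Reading and writing of time-course matrices and selection results.

The on-disk curve format is a plain CSV/TSV table whose header row holds the
(strictly increasing) sampling times and whose subsequent rows hold one curve
each.  An optional final column named ``weight`` carries per-curve importance
weights.  Selections are serialised as JSON with 1-based time-point indices,
matching the τ₁..τ_N convention used throughout the user-facing interfaces.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import __version__


class GridError(ValueError):
    """Raised when a sampling grid violates its invariants."""


class ParseError(ValueError):
    """Raised when an input table cannot be parsed."""


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing sampling grid τ₁..τ_N (arbitrary time units)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise GridError("times must be one-dimensional")
        if t.size < 3:
            raise GridError(f"need at least 3 time points, got {t.size}")
        if not np.all(np.isfinite(t)):
            raise GridError("times contain NaN or infinite values")
        if not np.all(np.diff(t) > 0):
            raise GridError("times must be strictly increasing")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def is_unit(self, tol: float = 1e-12) -> bool:
        return abs(self.times[0]) <= tol and abs(self.times[-1] - 1.0) <= tol


@dataclass(frozen=True)
class AffineMap:
    """u = (t - offset) / scale, mapping a grid onto [0, 1]."""

    offset: float
    scale: float

    def forward(self, t: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(t, dtype=float) - self.offset) / self.scale

    def inverse(self, u: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(u, dtype=float) * self.scale + self.offset


def normalize_grid(grid: TimeGrid) -> tuple[TimeGrid, AffineMap]:
    """Map a grid affinely onto [0, 1]; returns the unit grid and the map."""
    t = grid.times
    span = float(t[-1] - t[0])
    if span <= 0:
        raise GridError("degenerate grid: first and last times coincide")
    amap = AffineMap(offset=float(t[0]), scale=span)
    u = np.asarray(amap.forward(t), dtype=float)
    u[0], u[-1] = 0.0, 1.0
    return TimeGrid(u), amap


@dataclass
class CurveSet:
    """A set of curves sampled on a common grid, with optional weights."""

    grid: TimeGrid
    values: np.ndarray
    weights: Optional[np.ndarray] = None
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != self.grid.n:
            raise ValueError(
                f"value matrix has {v.shape[1]} columns but grid has {self.grid.n} times"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values contain NaN or infinite entries")
        self.values = v
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (v.shape[0],):
                raise ValueError("weights length must equal the number of curves")
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("weights must be non-negative and not all zero")
            self.weights = w
        if self.labels is not None and len(self.labels) != v.shape[0]:
            raise ValueError("labels length must equal the number of curves")

    @property
    def n_curves(self) -> int:
        return int(self.values.shape[0])

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.n_curves)
        return self.weights

    def subset(self, rows: Sequence[int]) -> "CurveSet":
        rows = list(rows)
        return CurveSet(
            grid=self.grid,
            values=self.values[rows],
            weights=None if self.weights is None else self.weights[rows],
            labels=None if self.labels is None else [self.labels[r] for r in rows],
        )


@dataclass(frozen=True)
class Selection:
    """An ordered subset of time-point indices (1-based) with provenance."""

    indices: tuple[int, ...]
    times: Optional[tuple[float, ...]] = None
    criterion: str = "f1"
    objective_estimate: Optional[float] = None
    n_samples: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(idx) == 0:
            raise ValueError("selection must contain at least one index")
        if any(i < 1 for i in idx):
            raise ValueError("indices are 1-based and must be >= 1")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        if self.times is not None:
            object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if self.objective_estimate is not None:
            if not (self.objective_estimate >= 0):
                raise ValueError("objective_estimate must be >= 0")

    @property
    def indices0(self) -> tuple[int, ...]:
        """0-based indices for internal array use."""
        return tuple(i - 1 for i in self.indices)

    @property
    def m(self) -> int:
        return len(self.indices)


def _dialect_for(path: str | os.PathLike, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    return "tsv" if str(path).endswith((".tsv", ".tab", ".txt")) else "csv"


def read_curves(path: str | os.PathLike, dialect: Optional[str] = None) -> CurveSet:
    """Read a curve matrix (header row = times, one row per curve).

    An optional trailing ``weight`` column is consumed into per-curve weights;
    an optional leading non-numeric column is treated as curve labels.
    """
    sep = "\t" if _dialect_for(path, dialect) == "tsv" else ","
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=sep) if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ParseError("file must contain a header row and at least one curve")
    header = [c.strip() for c in rows[0]]

    has_labels = bool(header) and not _is_number(header[0]) and header[0].lower() in ("", "label", "id", "gene", "name")
    has_weights = bool(header) and header[-1].lower() == "weight"
    lo = 1 if has_labels else 0
    hi = len(header) - 1 if has_weights else len(header)
    try:
        times = np.array([float(c) for c in header[lo:hi]])
    except ValueError as exc:
        raise ParseError(f"header row does not parse as numeric times: {exc}") from exc
    grid = TimeGrid(times)  # raises GridError on duplicates / disorder

    values, weights, labels = [], [], []
    for ridx, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"row {ridx}: expected {len(header)} cells, got {len(row)}")
        try:
            values.append([float(c) for c in row[lo:hi]])
            if has_weights:
                weights.append(float(row[-1]))
        except ValueError as exc:
            raise ParseError(f"row {ridx}: non-numeric cell ({exc})") from exc
        if has_labels:
            labels.append(row[0].strip())
    return CurveSet(
        grid=grid,
        values=np.array(values),
        weights=np.array(weights) if has_weights else None,
        labels=labels if has_labels else None,
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_curves(curves: CurveSet, path: str | os.PathLike, dialect: Optional[str] = None) -> None:
    """Write a CurveSet in the standard header-row-of-times format."""
    sep = "\t" if _dialect_for(path, dialect) == "tsv" else ","
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        header = [repr(float(t)) for t in curves.grid.times]
        if curves.labels is not None:
            header = ["label"] + header
        if curves.weights is not None:
            header = header + ["weight"]
        w.writerow(header)
        for i in range(curves.n_curves):
            row = [repr(float(v)) for v in curves.values[i]]
            if curves.labels is not None:
                row = [curves.labels[i]] + row
            if curves.weights is not None:
                row = row + [repr(float(curves.weights[i]))]
            w.writerow(row)


def write_selection(sel: Selection, path: str | os.PathLike) -> None:
    """Serialise a Selection as JSON (1-based indices, original time units)."""
    doc = {
        "indices": list(sel.indices),
        "times": None if sel.times is None else list(sel.times),
        "criterion": sel.criterion,
        "objective_estimate": sel.objective_estimate,
        "n_samples": sel.n_samples,
        "seed": sel.seed,
        "version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_selection(path: str | os.PathLike) -> Selection:
    with open(path) as fh:
        doc = json.load(fh)
    return Selection(
        indices=tuple(doc["indices"]),
        times=None if doc.get("times") is None else tuple(doc["times"]),
        criterion=doc.get("criterion", "f1"),
        objective_estimate=doc.get("objective_estimate"),
        n_samples=doc.get("n_samples"),
        seed=doc.get("seed"),
    )
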