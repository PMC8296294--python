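"""Reading and writing the delimited-text formats of the pipeline.

All tables are comma-separated, dot-decimal, UTF-8, with a header row:

* resistance grid — header ``speed,<angle>,<angle>,...``; one row per
  flow speed, cells in newtons;
* decision matrix — first column alternative labels, remaining columns
  criterion values; criterion directions/weights come from a YAML
  config;
* kinematic curve — two columns ``time,value`` at a uniform rate.

Malformed input raises :class:`ParseError` naming the file and line.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from .hydro import DragCoefficientGrid
from .kinematics import SampledCurve
from .mcda import CriterionSpec, DecisionMatrix

__all__ = [
    "ParseError",
    "fixture_path",
    "read_resistance_grid",
    "write_coefficient_grid",
    "read_criteria",
    "read_decision_matrix",
    "write_topsis_result",
    "read_curve",
    "write_curve",
    "read_table",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def fixture_path(name: str) -> Path:
    """Path to a packaged data fixture (e.g. ``palm_resistance_grid.csv``)."""
    return Path(resources.files("swimdyn") / "data" / name)


def _rows(path: PathLike) -> list[tuple[int, list[str]]]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    with open(path, newline="", encoding="utf-8") as fh:
        out = [(i, row) for i, row in enumerate(csv.reader(fh), start=1) if row]
    if not out:
        raise ParseError(f"{path}: file is empty")
    return out


def _num(cell: str, path: PathLike, line: int, col: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"{path}, line {line}: non-numeric value {cell!r} in column {col!r}"
        ) from None


def read_resistance_grid(path: PathLike) -> DragCoefficientGrid:
    """Resistance grid CSV -> :class:`DragCoefficientGrid` (no coefficients yet)."""
    rows = _rows(path)
    line0, header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}, line {line0}: expected speed column plus angles")
    angles = [_num(c, path, line0, "header") for c in header[1:]]
    speeds, matrix = [], []
    for line, row in rows[1:]:
        if len(row) != len(header):
            raise ParseError(
                f"{path}, line {line}: expected {len(header)} cells, got {len(row)}"
            )
        speeds.append(_num(row[0], path, line, header[0]))
        matrix.append([_num(c, path, line, h) for c, h in zip(row[1:], header[1:])])
    if not speeds:
        raise ParseError(f"{path}: no data rows")
    return DragCoefficientGrid(
        speeds=np.array(speeds),
        spread_angles=np.array(angles),
        resistance=np.array(matrix),
    )


def write_coefficient_grid(grid: DragCoefficientGrid, path: PathLike) -> None:
    """Write speeds x angles coefficient matrix as CSV."""
    if grid.coefficient is None:
        raise ValueError("grid has no coefficient matrix; run coefficient_grid first")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["speed"] + [f"{a:g}" for a in grid.spread_angles])
        for v, row in zip(grid.speeds, grid.coefficient):
            w.writerow([f"{v:g}"] + [f"{c:.6f}" for c in row])


def read_criteria(path: PathLike) -> list[CriterionSpec]:
    """YAML criteria config -> ordered list of :class:`CriterionSpec`.

    Format::

        criteria:
          right_knee: {direction: maximize, weight: 0.25}
          right_thigh:
            direction: interval
            weight: 0.25
            interval_bounds: [-50, -44, -60, -36]
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "criteria" not in doc:
        raise ParseError(f"{path}: expected a top-level 'criteria' mapping")
    specs = []
    for name, spec in doc["criteria"].items():
        spec = spec or {}
        bounds = spec.get("interval_bounds")
        specs.append(
            CriterionSpec(
                name=str(name),
                direction=spec.get("direction", "maximize"),
                weight=float(spec.get("weight", 1.0)),
                interval_bounds=tuple(bounds) if bounds is not None else None,
            )
        )
    if not specs:
        raise ParseError(f"{path}: no criteria defined")
    return specs


def read_decision_matrix(
    path: PathLike, criteria: Sequence[CriterionSpec]
) -> DecisionMatrix:
    """Decision-matrix CSV plus criteria specs -> :class:`DecisionMatrix`.

    The CSV's criterion columns are matched to ``criteria`` by header
    name; extra CSV columns (e.g. a stroke label) are ignored.
    """
    rows = _rows(path)
    line0, header = rows[0]
    col_index = {}
    for spec in criteria:
        if spec.name not in header:
            raise ParseError(
                f"{path}, line {line0}: missing criterion column {spec.name!r}"
            )
        col_index[spec.name] = header.index(spec.name)
    labels, values = [], []
    for line, row in rows[1:]:
        if len(row) != len(header):
            raise ParseError(
                f"{path}, line {line}: expected {len(header)} cells, got {len(row)}"
            )
        labels.append(row[0])
        values.append(
            [_num(row[col_index[s.name]], path, line, s.name) for s in criteria]
        )
    if not labels:
        raise ParseError(f"{path}: no data rows")
    return DecisionMatrix(
        alternatives=labels, criteria=list(criteria), values=np.array(values)
    )


def write_topsis_result(result, path: PathLike) -> None:
    """Write per-alternative D+, D-, closeness and rank as CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["alternative", "distance_to_best", "distance_to_worst", "closeness", "rank"]
        )
        for i, name in enumerate(result.alternatives):
            w.writerow(
                [
                    name,
                    f"{result.separation_best[i]:.10f}",
                    f"{result.separation_worst[i]:.10f}",
                    f"{result.closeness[i]:.10f}",
                    int(result.rank[i]),
                ]
            )


def read_curve(path: PathLike) -> SampledCurve:
    """Two-column (time, value) CSV -> :class:`SampledCurve`.

    The sampling rate is inferred from the time column, which must be
    uniform.
    """
    rows = _rows(path)
    _, header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: expected two columns (time, value)")
    times, values = [], []
    for line, row in rows[1:]:
        times.append(_num(row[0], path, line, header[0]))
        values.append(_num(row[1], path, line, header[1]))
    if len(times) < 3:
        raise ParseError(f"{path}: need at least 3 samples")
    t = np.array(times)
    dt = np.diff(t)
    if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ParseError(f"{path}: time column must be uniformly increasing")
    return SampledCurve(
        values=np.array(values), sampling_rate=1.0 / dt[0], start_time=t[0]
    )


def write_curve(curve: SampledCurve, path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "value"])
        for t, v in zip(curve.times, curve.values):
            w.writerow([f"{t:.6f}", f"{v:.8f}"])


def read_table(path: PathLike, schema: str, criteria=None):
    """Schema-dispatched reader: ``resistance``, ``matrix`` or ``curve``."""
    if schema == "resistance":
        return read_resistance_grid(path)
    if schema == "matrix":
        if criteria is None:
            raise ValueError("schema 'matrix' requires criteria specs")
        return read_decision_matrix(path, criteria)
    if schema == "curve":
        return read_curve(path)
    raise ValueError(f"unknown schema {schema!r}")
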