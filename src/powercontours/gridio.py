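"""Plain-text serialization for trial tables and power grids.

Trial tables are CSV with header ``participant,condition,trial,value``
(complex data adds a ``value_imag`` column); ``#`` starts a comment line.

Power grids are CSV with a one-line JSON header carrying the provenance
metadata (alpha, test_label, reps, seed), then a matrix whose first row
is the k axis and whose first column is the n axis.  A pure-JSON variant
is used for ``.json`` paths.  Floats are written with 17 significant
digits so round trips are bit-exact; missing cells serialize as ``nan``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PowerGrid
from .subsample import TrialTable

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_grid",
    "write_grid",
]

_FMT = "%.17g"


def write_trial_table(table: TrialTable, path) -> None:
    path = Path(path)
    data = table.data
    is_complex = np.iscomplexobj(data["value"].to_numpy())
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["participant", "condition", "trial", "value"]
        if is_complex:
            header.append("value_imag")
        writer.writerow(header)
        for row in data.itertuples(index=False):
            v = row.value
            out = [row.participant, row.condition, int(row.trial)]
            if is_complex:
                out += [_FMT % v.real, _FMT % v.imag]
            else:
                out.append(_FMT % float(v))
            writer.writerow(out)


def read_trial_table(path) -> TrialTable:
    """Parse a trial-table CSV, validating structure row by row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    records = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                required = ["participant", "condition", "trial", "value"]
                if header[: len(required)] != required:
                    raise ValueError(
                        f"{path}:{lineno}: header must start with "
                        f"{','.join(required)}, got {','.join(header)}"
                    )
                has_imag = "value_imag" in header
                continue
            expected = 5 if has_imag else 4
            if len(fields) != expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected} fields, "
                    f"got {len(fields)}"
                )
            try:
                trial = int(fields[2])
                real = float(fields[3])
                imag = float(fields[4]) if has_imag else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            value = complex(real, imag) if has_imag else real
            records.append((fields[0], fields[1], trial, value))
    if header is None or not records:
        raise ValueError(f"{path}: no data rows found")
    frame = pd.DataFrame(records,
                         columns=["participant", "condition", "trial",
                                  "value"])
    return TrialTable(frame)  # duplicate keys rejected by the constructor


def _grid_meta(grid: PowerGrid) -> dict:
    return {
        "alpha": grid.alpha,
        "test_label": grid.test_label,
        "reps": int(grid.reps),
        "seed": grid.seed,
    }


def write_grid(grid: PowerGrid, path) -> None:
    """Write a grid as CSV (default) or JSON (``.json`` suffix)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = dict(_grid_meta(grid))
        payload["n_values"] = grid.n_values.tolist()
        payload["k_values"] = grid.k_values.tolist()
        payload["power"] = [
            [None if math.isnan(v) else v for v in row]
            for row in grid.power.tolist()
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    with path.open("w", newline="") as fh:
        fh.write("# " + json.dumps(_grid_meta(grid)) + "\n")
        writer = csv.writer(fh)
        writer.writerow(["n\\k"] + [str(int(k)) for k in grid.k_values])
        for n, row in zip(grid.n_values, grid.power):
            writer.writerow([str(int(n))] + [_FMT % v for v in row])


def read_grid(path) -> PowerGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"grid file not found: {path}")
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        power = np.array([
            [np.nan if v is None else v for v in row]
            for row in payload["power"]
        ], dtype=float)
        return PowerGrid(
            np.asarray(payload["n_values"], dtype=int),
            np.asarray(payload["k_values"], dtype=int),
            power, alpha=payload["alpha"],
            test_label=payload["test_label"], reps=payload["reps"],
            seed=payload["seed"],
        )
    meta = None
    rows = []
    k_values = None
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if meta is None:
                    meta = json.loads(line.lstrip("# "))
                continue
            fields = next(csv.reader([line]))
            if k_values is None:
                k_values = [int(f) for f in fields[1:]]
                continue
            rows.append(fields)
    if meta is None or k_values is None or not rows:
        raise ValueError(f"{path}: not a grid file (missing header or matrix)")
    n_values = [int(r[0]) for r in rows]
    power = np.array([[float(v) for v in r[1:]] for r in rows])
    if power.shape[1] != len(k_values):
        raise ValueError(
            f"{path}: matrix has {power.shape[1]} columns but the header "
            f"row lists {len(k_values)} k values"
        )
    return PowerGrid(np.asarray(n_values), np.asarray(k_values), power,
                     alpha=meta["alpha"], test_label=meta["test_label"],
                     reps=meta["reps"], seed=meta["seed"])
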