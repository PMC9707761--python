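"""CSV and structured-text I/O.

Two CSV dialects are used throughout:

* point-set CSV — header ``x_um,y_um,z_um`` (optionally ``cell_name``,
  ``frame``, ``embryo_id``); one point per row, coordinates in
  micrometers, round-trip lossless to 9 significant digits.
* labeled-corpus CSV — header ``cell_name,x_um,y_um,z_um,frame,
  embryo_id`` with cell names like ``H0L``/``H0R`` .. ``TL``/``TR``.

Point indices in ranked-hypothesis output are 1-based (the documented
external convention); all in-memory indices are 0-based.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .features import CANONICAL_PAIR_NAMES, LabeledPosture

__all__ = [
    "read_pointset",
    "write_pointset",
    "read_corpus",
    "write_corpus",
    "write_results",
]

_COORD_COLS = ["x_um", "y_um", "z_um"]


def read_pointset(path) -> np.ndarray:
    """Read an (n, 3) point array from CSV; errors name the offending
    row (1-based, header excluded)."""
    df = pd.read_csv(path)
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    coords = np.empty((len(df), 3))
    for i, row in enumerate(df.itertuples(index=False)):
        for j, col in enumerate(_COORD_COLS):
            val = getattr(row, col)
            try:
                val = float(val)
            except (TypeError, ValueError):
                raise ValueError(f"{path}: non-numeric coordinate in row {i + 1}") from None
            if not np.isfinite(val):
                raise ValueError(f"{path}: non-finite coordinate in row {i + 1}")
            coords[i, j] = val
    return coords


def write_pointset(points: np.ndarray, path, extra: dict | None = None) -> None:
    points = np.asarray(points, dtype=float)
    df = pd.DataFrame(points, columns=_COORD_COLS)
    for col, vals in (extra or {}).items():
        df[col] = vals
    df.to_csv(path, index=False, float_format="%.9g")


def write_corpus(samples: Sequence[tuple[str, int, LabeledPosture]], path) -> None:
    """Write (embryo_id, frame, posture) records as a labeled-corpus CSV."""
    rows = []
    for embryo_id, frame, posture in samples:
        for i, name in enumerate(posture.names):
            for side, coords in (("L", posture.left[i]), ("R", posture.right[i])):
                rows.append(
                    {
                        "cell_name": f"{name}{side}",
                        "x_um": coords[0],
                        "y_um": coords[1],
                        "z_um": coords[2],
                        "frame": frame,
                        "embryo_id": embryo_id,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_corpus(path) -> list[tuple[float, LabeledPosture, str]]:
    """Read a labeled-corpus CSV into (time, posture, embryo_id) records.

    Normalized time is ``(frame - min_frame) / (max_frame - min_frame)``
    per embryo (a single-frame embryo gets t=0).
    """
    df = pd.read_csv(path)
    required = ["cell_name", "x_um", "y_um", "z_um", "frame", "embryo_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for embryo_id, edf in df.groupby("embryo_id", sort=True):
        fmin, fmax = edf["frame"].min(), edf["frame"].max()
        span = max(fmax - fmin, 1)
        for frame, fdf in edf.groupby("frame", sort=True):
            t = float((frame - fmin) / span)
            cells = {str(r.cell_name): np.array([r.x_um, r.y_um, r.z_um]) for r in fdf.itertuples()}
            names = [n for n in CANONICAL_PAIR_NAMES if f"{n}L" in cells]
            for n in names:
                if f"{n}R" not in cells:
                    raise ValueError(f"{path}: embryo {embryo_id} frame {frame} missing {n}R")
            left = np.array([cells[f"{n}L"] for n in names])
            right = np.array([cells[f"{n}R"] for n in names])
            out.append((t, LabeledPosture(tuple(names), left, right, t), str(embryo_id)))
    return out


def write_results(results, path) -> None:
    """Ranked-hypothesis output: JSON-lines, one record per hypothesis
    with sample id, rank, cost, and 1-based cell-to-point indices."""
    with open(path, "w") as fh:
        for res in results:
            for rank, (assignment, cost) in enumerate(res.hypotheses, start=1):
                record = {
                    "sample_id": res.sample_id,
                    "rank": rank,
                    "cost": cost,
                    "proved_optimal": res.proved_optimal,
                    "assignment": {
                        (res.vertex_labels[v] if res.vertex_labels else str(v + 1)): p + 1
                        for v, p in enumerate(assignment.points)
                    },
                }
                fh.write(json.dumps(record) + "\n")
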