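"""CSV and manifest plumbing shared by the command-line entry points.

All CSVs use full double precision, ``.`` decimal separator and no thousands
separators, so writer output round-trips bit-identically through the readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .abm import ABMResult
from .calibration import ViewSeries, cumulative_from_daily
from .dynamics import Trajectory

__all__ = [
    "read_view_csv",
    "read_trajectory_csv",
    "read_abm_csv",
    "write_manifest",
]


class FormatError(ValueError):
    """Input file does not match the expected CSV dialect."""


def _require_columns(frame: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{what} is missing column(s) {', '.join(repr(c) for c in missing)}; "
            f"expected header {','.join(columns)}"
        )


def read_view_csv(path) -> ViewSeries:
    """Read a `day,views` CSV (integer days from 0, nonnegative views)."""
    frame = pd.read_csv(path)
    _require_columns(frame, ("day", "views"), f"view-count file {path}")
    frame = frame.sort_values("day").reset_index(drop=True)
    days = frame["day"].to_numpy()
    if not np.array_equal(days, np.arange(len(days))):
        raise FormatError(f"view-count file {path} must cover consecutive days 0..n")
    return cumulative_from_daily(frame["views"].to_numpy())


def read_trajectory_csv(path, params=None) -> Trajectory:
    """Read a `t,S,I,R` trajectory CSV; N is recovered from the first row."""
    frame = pd.read_csv(path)
    _require_columns(frame, ("t", "S", "I", "R"), f"trajectory file {path}")
    S, I, R = (frame[c].to_numpy(dtype=float) for c in ("S", "I", "R"))
    return Trajectory(frame["t"].to_numpy(dtype=float), S, I, R,
                      N=float(S[0] + I[0] + R[0]), params=params)


def read_abm_csv(path) -> ABMResult:
    """Read a `t,O,P,Q,typeA,typeB` agent-based result CSV."""
    frame = pd.read_csv(path)
    _require_columns(frame, ("t", "O", "P", "Q", "typeA", "typeB"), f"ABM file {path}")
    return ABMResult(
        frame["t"].to_numpy(dtype=float),
        *(frame[c].to_numpy(dtype=np.int64) for c in ("O", "P", "Q", "typeA", "typeB")),
    )


def write_manifest(path, entries: dict) -> None:
    """Plain-text `key=value` manifest of every resolved parameter and seed.

    Rerunning the same subcommand with exactly these values reproduces the
    run; floats are written with repr precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]!r}\n")
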