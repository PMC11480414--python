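"""Readers and writers for the pipeline's external formats.

Dialects (all documented in the README):

* photometry CSV: columns ``time_s, ch405, ch470``;
* behavior events CSV (BORIS-style export): columns
  ``subject, behavior, start_s, stop_s, stress, social`` — point events
  (stop == start) are accepted and expanded by the ethogram downstream;
* trajectory CSV: columns ``time_s, body_x, body_y, head_x, head_y``;
* counts: MatrixMarket coordinate MTX (genes x cells) + ``genes.tsv`` +
  ``barcodes.tsv`` (one name per line) + ``clusters.csv``
  (columns ``cell, cluster``).

Readers reject malformed input (naming the offending row/label) rather than
coercing it; every writer produces files its reader accepts unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .core import (
    ETHOGRAM_LABELS,
    BehaviorEvent,
    DffTrace,
    PhotometryRecording,
    Trajectory,
    ValidationError,
)

__all__ = [
    "read_photometry", "write_photometry",
    "read_events", "write_events",
    "read_trajectory", "write_trajectory",
    "read_dff", "write_dff",
    "read_counts", "write_counts",
]

PHOTOMETRY_COLUMNS = ("time_s", "ch405", "ch470")
EVENT_COLUMNS = ("subject", "behavior", "start_s", "stop_s", "stress", "social")
TRAJECTORY_COLUMNS = ("time_s", "body_x", "body_y", "head_x", "head_y")
DFF_COLUMNS = ("time_s", "dff")


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip float parsing: writer/reader pairs must be bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy() & df[col].notna().to_numpy())
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ValidationError(f"{name}: empty cell in {col!r} at data row {row}")
        if bad.size:
            raise ValidationError(
                f"{name}: non-numeric value {df[col].iloc[bad[0]]!r} in "
                f"{col!r} at data row {int(bad[0])}"
            )
        df[col] = converted
    return df


def read_photometry(path) -> PhotometryRecording:
    """Read a two-channel photometry CSV; rate is implied by the timestamps."""
    df = _numeric(_read_table(path, PHOTOMETRY_COLUMNS), PHOTOMETRY_COLUMNS,
                  Path(path).name)
    t = df["time_s"].to_numpy()
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValidationError(
                f"{Path(path).name}: time not strictly increasing at data "
                f"row {int(bad[0]) + 1}"
            )
        rate = 1.0 / float(np.median(dt))
    else:
        rate = 30.0
    return PhotometryRecording(t, df["ch405"].to_numpy(),
                               df["ch470"].to_numpy(), rate_hz=rate)


def write_photometry(rec: PhotometryRecording, path) -> None:
    pd.DataFrame({
        "time_s": rec.time_s, "ch405": rec.ch405, "ch470": rec.ch470,
    }).to_csv(path, index=False)


def read_events(path) -> list[BehaviorEvent]:
    """Read a BORIS-style behavior event CSV into validated events."""
    df = _read_table(path, EVENT_COLUMNS)
    df = _numeric(df, ("start_s", "stop_s"), Path(path).name)
    events = []
    for i, row in df.iterrows():
        label = str(row["behavior"])
        if label not in ETHOGRAM_LABELS:
            raise ValidationError(
                f"{Path(path).name}: unregistered behavior label {label!r} "
                f"at data row {i}; ethogram registers {ETHOGRAM_LABELS}"
            )
        try:
            events.append(BehaviorEvent(
                subject=str(row["subject"]), label=label,
                onset_s=float(row["start_s"]), offset_s=float(row["stop_s"]),
                stress_condition=str(row["stress"]),
                social_condition=str(row["social"]),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{Path(path).name}: data row {i}: {exc}") from None
    return events


def write_events(events: list[BehaviorEvent], path) -> None:
    pd.DataFrame([{
        "subject": e.subject, "behavior": e.label,
        "start_s": e.onset_s, "stop_s": e.offset_s,
        "stress": e.stress_condition, "social": e.social_condition,
    } for e in events], columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = _numeric(_read_table(path, TRAJECTORY_COLUMNS), TRAJECTORY_COLUMNS,
                  Path(path).name)
    return Trajectory(
        df["time_s"].to_numpy(),
        df[["body_x", "body_y"]].to_numpy(),
        df[["head_x", "head_y"]].to_numpy(),
    )


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({
        "time_s": traj.time_s,
        "body_x": traj.body_xy[:, 0], "body_y": traj.body_xy[:, 1],
        "head_x": traj.head_xy[:, 0], "head_y": traj.head_xy[:, 1],
    }).to_csv(path, index=False)


def read_dff(path) -> DffTrace:
    df = _numeric(_read_table(path, DFF_COLUMNS), DFF_COLUMNS, Path(path).name)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) >= 2 else 30.0
    return DffTrace(t, df["dff"].to_numpy(), rate_hz=rate)


def write_dff(trace: DffTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "dff": trace.dff}).to_csv(path, index=False)


def read_counts(mtx_path, genes_path, cells_path, clusters_path):
    """Load a clustered counts matrix; returns (csr matrix, genes, cells, labels).

    Dimension mismatches between the matrix and the name files, and cluster
    tables that do not cover every cell, are errors stating both sizes.
    """
    matrix = sparse.csr_matrix(mmread(mtx_path))
    genes = [ln.split("\t")[0] for ln in _read_lines(genes_path)]
    cells = [ln.split("\t")[0] for ln in _read_lines(cells_path)]
    if matrix.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix is {matrix.shape[0]} x {matrix.shape[1]} but name files "
            f"list {len(genes)} genes and {len(cells)} cells"
        )
    clusters = pd.read_csv(clusters_path)
    for col in ("cell", "cluster"):
        if col not in clusters.columns:
            raise ValidationError(f"clusters table missing column {col!r}")
    lookup = dict(zip(clusters["cell"].astype(str), clusters["cluster"].astype(str)))
    missing = [c for c in cells if c not in lookup]
    if missing:
        raise ValidationError(
            f"clusters table covers {len(lookup)} cells but matrix has "
            f"{len(cells)}; first missing cell: {missing[0]!r}"
        )
    labels = pd.DataFrame({"cell": cells,
                           "cluster": [lookup[c] for c in cells]})
    return matrix, genes, cells, labels


def _read_lines(path) -> list[str]:
    text = Path(path).read_text().splitlines()
    return [ln for ln in text if ln.strip()]


def write_counts(matrix, genes, cells, labels: pd.DataFrame,
                 mtx_path, genes_path, cells_path, clusters_path) -> None:
    mmwrite(str(mtx_path), sparse.coo_matrix(matrix))
    Path(genes_path).write_text("\n".join(genes) + "\n")
    Path(cells_path).write_text("\n".join(cells) + "\n")
    labels.to_csv(clusters_path, index=False)
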