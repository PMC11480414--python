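"""Scoring of the 3-phase social interaction test from tracked trajectories.

Phases (open field, acclimation, interaction) each last 180 s. Scores per
phase: distance traveled (body-point path length), center time (body inside
the rectangle inset 14 cm from every wall), social approach (body within
8 cm of the wire-cage footprint) and vigilance (body outside the interaction
zone with the body-to-head vector oriented within a half-angle of the cage
center). All geometry is on the floor plane; the arena height is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ArenaGeometry, Trajectory

__all__ = ["PhaseScores", "score_phase", "summarize_cohort",
           "in_interaction_zone", "in_center_zone", "is_vigilant"]

log = logging.getLogger(__name__)

PHASES = ("open_field", "acclimation", "interaction")
PHASE_DURATION_S = 180.0


@dataclass(frozen=True)
class PhaseScores:
    phase: str
    distance_cm: float
    center_time_s: float
    approach_time_s: float
    vigilance_time_s: float


def _dist_to_cage(xy: np.ndarray, geom: ArenaGeometry) -> np.ndarray:
    """Euclidean distance from points to the cage footprint rectangle.

    Distance is to the rectangle boundary region (0 inside), matching the
    "within 8 cm of the wire cage" zone definition.
    """
    x0, y0, x1, y1 = geom.cage_rect
    dx = np.maximum(np.maximum(x0 - xy[:, 0], 0.0), xy[:, 0] - x1)
    dy = np.maximum(np.maximum(y0 - xy[:, 1], 0.0), xy[:, 1] - y1)
    return np.hypot(dx, dy)


def in_interaction_zone(xy: np.ndarray, geom: ArenaGeometry) -> np.ndarray:
    return _dist_to_cage(np.atleast_2d(xy), geom) <= geom.interaction_radius


def in_center_zone(xy: np.ndarray, geom: ArenaGeometry) -> np.ndarray:
    xy = np.atleast_2d(xy)
    m = geom.center_margin
    return (
        (xy[:, 0] >= m) & (xy[:, 0] <= geom.arena_w - m)
        & (xy[:, 1] >= m) & (xy[:, 1] <= geom.arena_h - m)
    )


def is_vigilant(body: np.ndarray, head: np.ndarray, geom: ArenaGeometry) -> np.ndarray:
    """Body outside the interaction zone, head direction toward the cage.

    The head direction is the body-to-head vector; vigilance requires its
    angle to the body-to-cage-center vector to be at most the configured
    half-angle. Frames with a degenerate (zero-length) head vector never
    count as vigilant.
    """
    body = np.atleast_2d(body)
    head = np.atleast_2d(head)
    outside = ~in_interaction_zone(body, geom)
    hv = head - body
    tv = np.asarray(geom.cage_center) - body
    hn = np.linalg.norm(hv, axis=1)
    tn = np.linalg.norm(tv, axis=1)
    ok = (hn > 0) & (tn > 0)
    cosang = np.full(len(body), -1.0)
    cosang[ok] = np.einsum("ij,ij->i", hv[ok], tv[ok]) / (hn[ok] * tn[ok])
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return outside & ok & (angle <= geom.vigilance_half_angle_deg)


def score_phase(
    traj: Trajectory,
    geom: ArenaGeometry,
    phase: str = "interaction",
) -> PhaseScores:
    """Score one phase of the test from its trajectory.

    Zone membership uses the body point; vigilance additionally uses the
    head point. Times accrue one frame period per qualifying frame; the frame
    period is the median inter-frame interval. An empty trajectory yields
    all-zero scores with a warning.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if len(traj) == 0:
        log.warning("empty trajectory for phase %r: all scores zero", phase)
        return PhaseScores(phase, 0.0, 0.0, 0.0, 0.0)
    if len(traj) == 1:
        frame_s = 1.0 / 30.0
    else:
        frame_s = float(np.median(np.diff(traj.time_s)))
    dist = float(np.sum(np.linalg.norm(np.diff(traj.body_xy, axis=0), axis=1)))
    approach = float(in_interaction_zone(traj.body_xy, geom).sum() * frame_s)
    center = float(in_center_zone(traj.body_xy, geom).sum() * frame_s)
    vigil = float(is_vigilant(traj.body_xy, traj.head_xy, geom).sum() * frame_s)
    return PhaseScores(
        phase=phase, distance_cm=dist, center_time_s=center,
        approach_time_s=approach, vigilance_time_s=vigil,
    )


def summarize_cohort(
    scores: list[PhaseScores],
    labels: list[dict] | None = None,
) -> pd.DataFrame:
    """One row per scored phase with group labels, ready for the stats layer."""
    if labels is not None and len(labels) != len(scores):
        raise ValueError("labels and scores lengths differ")
    rows = []
    for i, sc in enumerate(scores):
        row = dict(labels[i]) if labels else {}
        row.update(
            phase=sc.phase, distance_cm=sc.distance_cm,
            center_time_s=sc.center_time_s, approach_time_s=sc.approach_time_s,
            vigilance_time_s=sc.vigilance_time_s,
        )
        rows.append(row)
    return pd.DataFrame(rows)
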