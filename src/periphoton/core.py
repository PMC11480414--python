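"""Core data containers shared across the pipeline.

Units: time in seconds, coordinates in centimetres, fluorescence in arbitrary
units (au), dF/F in percent. Sample indexing is 0-based and event intervals
are closed-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Behavior labels the ethogram registers. ``avoidance`` may arrive as a point
#: event (offset == onset) and is expanded downstream; ``freezing`` bouts
#: shorter than 1 s are dropped downstream.
ETHOGRAM_LABELS = ("avoidance", "boxing", "freezing", "approach")

STRESS_LEVELS = ("pre", "post")
SOCIAL_LEVELS = ("non-aggressive", "aggressive")
TIMEPOINT_LEVELS = ("baseline", "before", "after")


class ValidationError(ValueError):
    """Malformed input data (bad file contents, inconsistent containers)."""


@dataclass
class PhotometryRecording:
    """Aligned two-channel fluorescence time series.

    ``ch405`` is the isosbestic (calcium-independent) channel, ``ch470`` the
    calcium-dependent signal channel. ``rate_hz`` must agree with the median
    inter-sample interval within 1%.
    """

    time_s: np.ndarray
    ch405: np.ndarray
    ch470: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ch405 = np.asarray(self.ch405, dtype=float)
        self.ch470 = np.asarray(self.ch470, dtype=float)
        n = len(self.time_s)
        if len(self.ch405) != n or len(self.ch470) != n:
            raise ValidationError(
                f"channel lengths differ: time={n}, "
                f"ch405={len(self.ch405)}, ch470={len(self.ch470)}"
            )
        if n >= 2:
            dt = np.diff(self.time_s)
            bad = np.flatnonzero(dt <= 0)
            if bad.size:
                raise ValidationError(
                    f"time not strictly increasing at row {bad[0] + 1}"
                )
            implied = 1.0 / float(np.median(dt))
            if abs(implied - self.rate_hz) > 0.01 * self.rate_hz:
                raise ValidationError(
                    f"rate_hz={self.rate_hz:g} inconsistent with median "
                    f"inter-sample interval (implies {implied:g} Hz)"
                )

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) else 0.0


@dataclass(frozen=True)
class BehaviorEvent:
    """One labeled behavior interval for one subject in one session."""

    subject: str
    label: str
    onset_s: float
    offset_s: float
    stress_condition: str = "pre"
    social_condition: str = "non-aggressive"

    def __post_init__(self) -> None:
        if self.label not in ETHOGRAM_LABELS:
            raise ValidationError(
                f"unregistered behavior label {self.label!r}; "
                f"ethogram registers {ETHOGRAM_LABELS}"
            )
        if self.offset_s < self.onset_s:
            raise ValidationError(
                f"event {self.label!r} at t={self.onset_s:g}: "
                f"offset {self.offset_s:g} precedes onset"
            )
        if self.stress_condition not in STRESS_LEVELS:
            raise ValidationError(
                f"unknown stress condition {self.stress_condition!r}"
            )
        if self.social_condition not in SOCIAL_LEVELS:
            raise ValidationError(
                f"unknown social condition {self.social_condition!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class DffTrace:
    """Motion/bleach-corrected dF/F trace, in percent, at the video rate."""

    time_s: np.ndarray
    dff: np.ndarray
    rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.time_s) != len(self.dff):
            raise ValidationError("time and dff lengths differ")
        if not np.all(np.isfinite(self.dff)):
            raise ValidationError("dff contains non-finite values")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class Trajectory:
    """Tracked body and head points on the arena floor plane (cm)."""

    time_s: np.ndarray
    body_xy: np.ndarray  # (n, 2)
    head_xy: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.body_xy = np.asarray(self.body_xy, dtype=float).reshape(-1, 2)
        self.head_xy = np.asarray(self.head_xy, dtype=float).reshape(-1, 2)
        n = len(self.time_s)
        if len(self.body_xy) != n or len(self.head_xy) != n:
            raise ValidationError("trajectory arrays have differing lengths")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena and zone description for the 3-phase social interaction test.

    The wire cage sits against the middle of the bottom wall (y = 0); its
    footprint is a ``cage_w`` x ``cage_d`` rectangle. The interaction zone is
    every point within ``interaction_radius`` of that footprint; the center
    zone is the rectangle inset ``center_margin`` from every wall. Vigilance
    is scored when the body is outside the interaction zone and the body-to-
    head vector points within ``vigilance_half_angle_deg`` of the cage center.
    """

    arena_w: float = 89.0
    arena_h: float = 63.0
    cage_w: float = 10.0
    cage_d: float = 10.0
    interaction_radius: float = 8.0
    center_margin: float = 14.0
    vigilance_half_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.center_margin >= min(self.arena_w, self.arena_h) / 2:
            raise ValidationError("center zone empty: margin too large")
        if self.cage_w > self.arena_w or self.cage_d > self.arena_h:
            raise ValidationError("cage footprint larger than arena")

    @property
    def cage_center(self) -> tuple[float, float]:
        return (self.arena_w / 2.0, self.cage_d / 2.0)

    @property
    def cage_rect(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the cage footprint."""
        half = self.cage_w / 2.0
        return (self.arena_w / 2.0 - half, 0.0, self.arena_w / 2.0 + half, self.cage_d)
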