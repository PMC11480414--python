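"""Ethogram rules, peri-event extraction, z-scores and windowed AUC.

Each behavior onset anchors three windows on the dF/F trace: baseline
(-8 to -6 s), before (-2 to 0 s) and after (0 to +2 s). The trace segment is
z-scored against the baseline window's own mean and standard deviation, and
the area under the z-trace is integrated over each window by the trapezoidal
rule, giving values in z*seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    TIMEPOINT_LEVELS,
    BehaviorEvent,
    DffTrace,
    ValidationError,
)

__all__ = [
    "PeriEventWindowSpec",
    "PeriEventResult",
    "EventExcluded",
    "apply_ethogram",
    "extract_peri_event",
    "extract_peri_events",
    "window_auc",
    "tabulate_auc",
]

log = logging.getLogger(__name__)

#: Duration of the interval an avoidance point event expands to (seconds):
#: the scored behavior is the 2 s following the turn-away moment.
AVOIDANCE_SPAN_S = 2.0
#: Minimum freezing bout duration (seconds); shorter bouts are dropped.
MIN_FREEZE_S = 1.0


@dataclass(frozen=True)
class PeriEventWindowSpec:
    """Analysis windows in seconds relative to the behavior onset."""

    baseline: tuple[float, float] = (-8.0, -6.0)
    before: tuple[float, float] = (-2.0, 0.0)
    after: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        for name, (a, b) in self.items():
            if b <= a:
                raise ValueError(f"window {name!r} is empty: {(a, b)}")
        if not (self.baseline[1] <= self.before[0] and self.before[1] <= self.after[0]):
            raise ValueError("windows must be ordered baseline < before < after")

    def items(self):
        return (("baseline", self.baseline), ("before", self.before), ("after", self.after))

    @property
    def span(self) -> tuple[float, float]:
        return (self.baseline[0], self.after[1])


@dataclass
class PeriEventResult:
    """Z-scored peri-event trace and its three windowed AUCs (z*s)."""

    event: BehaviorEvent
    time_rel_s: np.ndarray
    z_trace: np.ndarray
    auc_baseline: float
    auc_before: float
    auc_after: float
    baseline_mean: float
    baseline_sd: float

    def auc(self, timepoint: str) -> float:
        return {"baseline": self.auc_baseline,
                "before": self.auc_before,
                "after": self.auc_after}[timepoint]


class EventExcluded(ValueError):
    """Event cannot be analyzed (window outside recording, zero variance)."""


def apply_ethogram(raw_events: list[BehaviorEvent]) -> list[BehaviorEvent]:
    """Apply the operational behavior definitions.

    Avoidance point events (offset == onset, the turn-away moment) expand to
    the 2 s interval that follows; freezing bouts shorter than 1 s are
    dropped; boxing and approach pass through unchanged. Dropped events are
    logged with the reason.
    """
    out: list[BehaviorEvent] = []
    for ev in raw_events:
        if ev.label == "avoidance" and ev.offset_s == ev.onset_s:
            ev = BehaviorEvent(
                ev.subject, ev.label, ev.onset_s, ev.onset_s + AVOIDANCE_SPAN_S,
                ev.stress_condition, ev.social_condition,
            )
        if ev.label == "freezing" and ev.duration_s < MIN_FREEZE_S:
            log.info(
                "dropping freezing bout at t=%.3f s: duration %.3f s < %g s",
                ev.onset_s, ev.duration_s, MIN_FREEZE_S,
            )
            continue
        out.append(ev)
    return out


def window_auc(time_s: np.ndarray, values: np.ndarray, a: float, b: float) -> float:
    """Integral of the linear interpolant of ``values`` over ``[a, b]``.

    Interior samples are kept at their timestamps and the window edges are
    filled by linear interpolation, so a trace identically 1 over a 2 s
    window integrates to exactly 2 regardless of how samples align with the
    edges. Requires the trace to cover ``[a, b]``.
    """
    if a < time_s[0] or b > time_s[-1]:
        raise ValueError(f"window [{a:g}, {b:g}] not covered by trace")
    inside = (time_s > a) & (time_s < b)
    ts = np.concatenate(([a], time_s[inside], [b]))
    vs = np.concatenate((
        [np.interp(a, time_s, values)],
        values[inside],
        [np.interp(b, time_s, values)],
    ))
    return float(np.trapezoid(vs, ts))


def extract_peri_event(
    dff: DffTrace,
    event: BehaviorEvent,
    spec: PeriEventWindowSpec | None = None,
    sd_ddof: int = 1,
) -> PeriEventResult:
    """Z-score and integrate the peri-event segment for one event.

    The z-score uses the mean and SD of the same event's baseline window:
    z = (dF/F - mean_baseline) / sd_baseline. Raises :class:`EventExcluded`
    when the analysis span exits the recording or the baseline has zero
    variance (padding or substituting would bias the baseline statistics).
    """
    spec = spec or PeriEventWindowSpec()
    t0, t1 = event.onset_s + spec.span[0], event.onset_s + spec.span[1]
    if t0 < dff.time_s[0] or t1 > dff.time_s[-1]:
        raise EventExcluded(
            f"{event.label!r} at t={event.onset_s:g} s: analysis span "
            f"[{t0:g}, {t1:g}] exits the recording "
            f"[{dff.time_s[0]:g}, {dff.time_s[-1]:g}]"
        )
    rel = dff.time_s - event.onset_s
    b0, b1 = spec.baseline
    base_mask = (rel >= b0) & (rel < b1)
    base = dff.dff[base_mask]
    if len(base) < 2:
        raise EventExcluded(
            f"{event.label!r} at t={event.onset_s:g} s: "
            f"baseline window holds {len(base)} samples"
        )
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=sd_ddof))
    if sd == 0.0:
        raise EventExcluded(
            f"{event.label!r} at t={event.onset_s:g} s: zero variance in the "
            "baseline window — z-score undefined"
        )
    seg_mask = (rel >= spec.span[0]) & (rel < spec.span[1])
    z_seg = (dff.dff[seg_mask] - mu) / sd
    z_full = (dff.dff - mu) / sd
    aucs = {
        name: window_auc(rel, z_full, a, b) for name, (a, b) in spec.items()
    }
    return PeriEventResult(
        event=event,
        time_rel_s=rel[seg_mask],
        z_trace=z_seg,
        auc_baseline=aucs["baseline"],
        auc_before=aucs["before"],
        auc_after=aucs["after"],
        baseline_mean=mu,
        baseline_sd=sd,
    )


def extract_peri_events(
    dff: DffTrace,
    events: list[BehaviorEvent],
    spec: PeriEventWindowSpec | None = None,
) -> tuple[list[PeriEventResult], list[tuple[BehaviorEvent, str]]]:
    """Extract all analyzable events; excluded ones are returned with reasons.

    Overlapping events are all retained; the overlap fraction is logged.
    """
    spec = spec or PeriEventWindowSpec()
    results, excluded = [], []
    for ev in events:
        try:
            results.append(extract_peri_event(dff, ev, spec))
        except EventExcluded as exc:
            log.info("excluding event: %s", exc)
            excluded.append((ev, str(exc)))
    n_overlap = _count_overlaps(events)
    if events and n_overlap:
        log.info("%d/%d events overlap another event", n_overlap, len(events))
    return results, excluded


def _count_overlaps(events: list[BehaviorEvent]) -> int:
    ivs = sorted((e.onset_s, e.offset_s) for e in events)
    n = 0
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 < a1:
            n += 1
    return n


def tabulate_auc(
    results: list[PeriEventResult],
    subject_col: str = "mouse",
) -> pd.DataFrame:
    """Long-format AUC table for the mixed model: one row per event x window.

    Columns: mouse, stress, social, timepoint (baseline/before/after), label,
    event_onset_s, auc. Row count is 3x the number of included events.
    """
    rows = []
    for res in results:
        ev = res.event
        for tp in TIMEPOINT_LEVELS:
            rows.append({
                subject_col: ev.subject,
                "stress": ev.stress_condition,
                "social": ev.social_condition,
                "timepoint": tp,
                "label": ev.label,
                "event_onset_s": ev.onset_s,
                "auc": res.auc(tp),
            })
    cols = [subject_col, "stress", "social", "timepoint", "label",
            "event_onset_s", "auc"]
    return pd.DataFrame(rows, columns=cols)
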