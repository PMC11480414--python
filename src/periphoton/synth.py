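"""Synthetic-data generators with known ground truth for every pipeline stage.

Emulated structure:

* two-channel photometry with biexponential photobleaching per channel, a
  shared band-limited motion artifact entering both channels with a
  per-channel gain, white measurement noise, and GCaMP6f-like calcium
  transients (difference-of-exponentials kernel, 0.2 s rise / 1.0 s decay)
  that ride only on the 470 nm channel — spontaneously as a homogeneous
  Poisson process and deterministically at behavior onsets;
* within-subject behavior event schedules across pre/post-stress sessions
  and two target-mouse conditions, with onsets separated by >= 10 s so the
  -8 s baseline window never overlaps the previous event's response;
* AUC observations drawn directly from the mixed-model data-generating
  process (fixed effects + per-mouse random intercept + residual noise) for
  calibration of the inferential layer;
* arena trajectories realizing a planned zone-occupancy schedule;
* sparse overdispersed (negative-binomial) gene x cell count matrices with
  cluster-specific expression.

Every generator is a pure function of its scenario and seed: identical
inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

from .core import (
    SOCIAL_LEVELS,
    STRESS_LEVELS,
    TIMEPOINT_LEVELS,
    ArenaGeometry,
    BehaviorEvent,
    PhotometryRecording,
    Trajectory,
)

__all__ = [
    "BleachParams",
    "PhotometryScenario",
    "SessionDesign",
    "transient_kernel",
    "generate_photometry",
    "generate_event_schedule",
    "generate_auc_table",
    "generate_trajectory",
    "generate_counts",
]

MIN_EVENT_SPACING_S = 10.0


@dataclass(frozen=True)
class BleachParams:
    """Biexponential photobleaching curve a1*e^(-t/tau1)+a2*e^(-t/tau2)+c (au)."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    c: float

    def curve(self, t: np.ndarray) -> np.ndarray:
        return (self.a1 * np.exp(-t / self.tau1)
                + self.a2 * np.exp(-t / self.tau2) + self.c)


@dataclass(frozen=True)
class PhotometryScenario:
    """Everything that defines one synthetic photometry session.

    Default bleaching curves share time constants across channels with
    proportional amplitudes — both channels watch the same fluorophore
    bleach, so the isosbestic curve maps onto the signal channel by an
    affine rescale. The raw rate of 1017 Hz (a common acquisition rate)
    makes the 30 Hz downsampling stage non-trivial.
    """

    duration_s: float = 600.0
    raw_rate_hz: float = 1017.0
    bleach_405: BleachParams = BleachParams(30.0, 60.0, 60.0, 600.0, 80.0)
    bleach_470: BleachParams = BleachParams(45.0, 60.0, 90.0, 600.0, 150.0)
    motion_sd: float = 0.0          # au, shared artifact amplitude
    motion_gain_470: float = 1.0    # per-channel gain on the shared waveform
    motion_smooth_s: float = 0.2    # band limit of the artifact
    noise_sd: float = 0.0           # au, per-channel white noise
    rise_tau_s: float = 0.2         # transient kernel rise
    decay_tau_s: float = 1.0        # transient kernel decay
    spontaneous_rate_hz: float = 0.0
    spontaneous_amp: float = 2.0    # au, peak of spontaneous transients
    event_response_amp: dict = field(default_factory=dict)  # au per label
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.raw_rate_hz < 30:
            raise ValueError("raw_rate_hz must be >= 30 (video rate)")
        for tau in (self.bleach_405.tau1, self.bleach_405.tau2,
                    self.bleach_470.tau1, self.bleach_470.tau2,
                    self.rise_tau_s, self.decay_tau_s):
            if tau <= 0:
                raise ValueError("all time constants must be positive")


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak GCaMP-like kernel (1 - e^(-t/rise)) * e^(-t/decay), t >= 0."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-t / rise_tau)) * np.exp(-t / decay_tau), 0.0)
    t_peak = rise_tau * np.log((decay_tau + rise_tau) / rise_tau)
    peak = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    return k / peak


def kernel_support_s(rise_tau: float, decay_tau: float) -> float:
    """Duration after which the unit-peak kernel is negligible (< ~1e-5)."""
    return rise_tau + 12.0 * decay_tau


def generate_photometry(
    scenario: PhotometryScenario,
    events: list[BehaviorEvent] | None = None,
) -> tuple[PhotometryRecording, dict]:
    """Simulate one two-channel session; returns the recording and truth.

    The 405 nm channel carries bleach + shared motion + noise (no calcium);
    the 470 nm channel carries its own bleach + gain-scaled motion + noise +
    the transient train. Truth dict: transient times, amplitudes, sources,
    and the shared motion waveform.
    """
    events = events or []
    sc = scenario
    n = int(round(sc.duration_s * sc.raw_rate_hz))
    t = np.arange(n) / sc.raw_rate_hz
    for ev in events:
        if ev.onset_s < 0 or ev.onset_s > sc.duration_s:
            raise ValueError(
                f"event {ev.label!r} at t={ev.onset_s:g} s lies outside the "
                f"recording span [0, {sc.duration_s:g}] s"
            )
    root = np.random.SeedSequence(sc.rng_seed)
    rng_motion, rng_noise, rng_spont = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    ch405 = sc.bleach_405.curve(t)
    ch470 = sc.bleach_470.curve(t)

    motion = np.zeros(n)
    if sc.motion_sd > 0:
        raw = rng_motion.standard_normal(n)
        motion = gaussian_filter1d(raw, sigma=sc.motion_smooth_s * sc.raw_rate_hz)
        sd = motion.std()
        if sd > 0:
            motion *= sc.motion_sd / sd
        ch405 = ch405 + motion
        ch470 = ch470 + sc.motion_gain_470 * motion

    # transient train: behavior-locked (deterministic) + spontaneous (Poisson)
    times, amps, sources = [], [], []
    for ev in events:
        amp = float(sc.event_response_amp.get(ev.label, 0.0))
        if amp != 0.0:
            times.append(ev.onset_s)
            amps.append(amp)
            sources.append(ev.label)
    if sc.spontaneous_rate_hz > 0:
        k = rng_spont.poisson(sc.spontaneous_rate_hz * sc.duration_s)
        for ts in np.sort(rng_spont.uniform(0, sc.duration_s, size=k)):
            times.append(float(ts))
            amps.append(sc.spontaneous_amp)
            sources.append("spontaneous")
    support = kernel_support_s(sc.rise_tau_s, sc.decay_tau_s)
    for ts, amp in zip(times, amps):
        i0 = int(np.ceil(ts * sc.raw_rate_hz))
        i1 = min(n, int(np.ceil((ts + support) * sc.raw_rate_hz)))
        if i0 >= n:
            continue
        ch470[i0:i1] += amp * transient_kernel(
            t[i0:i1] - ts, sc.rise_tau_s, sc.decay_tau_s
        )

    if sc.noise_sd > 0:
        ch405 = ch405 + sc.noise_sd * rng_noise.standard_normal(n)
        ch470 = ch470 + sc.noise_sd * rng_noise.standard_normal(n)

    rec = PhotometryRecording(t, ch405, ch470, rate_hz=sc.raw_rate_hz)
    truth = {
        "transient_times_s": np.array(times),
        "transient_amps": np.array(amps),
        "transient_sources": sources,
        "kernel_support_s": support,
        "motion": motion,
    }
    return rec, truth


@dataclass(frozen=True)
class SessionDesign:
    """Within-subjects design: every mouse sees every (stress, social) cell.

    ``true_lmm_effects`` maps cleaned fixed-effect names (e.g.
    ``"timepoint[after]"``, ``"stress[post]:timepoint[after]"``,
    ``"Intercept"``) to coefficient values in z*s; unnamed terms are zero.
    """

    mice: tuple = tuple(f"m{i+1}" for i in range(7))
    events_per_label: int = 10
    label_set: tuple = ("avoidance",)
    true_lmm_effects: dict = field(default_factory=dict)
    random_intercept_sd: float = 0.5
    noise_sd: float = 1.0


def generate_event_schedule(
    design: SessionDesign,
    seed: int = 0,
    start_s: float = 10.0,
) -> dict[tuple, list[BehaviorEvent]]:
    """Event lists per (mouse, stress, social) session, onsets >= 10 s apart.

    Labels are interleaved in shuffled order; onsets step by 10 s plus a
    uniform 0-1 s jitter so bins never align trivially with the sample grid.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE7E)))
    sessions: dict[tuple, list[BehaviorEvent]] = {}
    for mouse in design.mice:
        for stress in STRESS_LEVELS:
            for social in SOCIAL_LEVELS:
                labels = list(design.label_set) * design.events_per_label
                rng.shuffle(labels)
                t = start_s
                evs = []
                for lab in labels:
                    onset = t + float(rng.uniform(0.0, 1.0))
                    dur = 2.0 if lab != "freezing" else float(rng.uniform(1.0, 3.0))
                    evs.append(BehaviorEvent(mouse, lab, onset, onset + dur,
                                             stress, social))
                    t = onset + MIN_EVENT_SPACING_S
                sessions[(mouse, stress, social)] = evs
    return sessions


def _term_indicator(term: str, row: dict) -> float:
    if term == "Intercept":
        return 1.0
    out = 1.0
    for part in term.split(":"):
        factor, level = part.rstrip("]").split("[")
        out *= 1.0 if str(row[factor]) == level else 0.0
    return out


def generate_auc_table(
    design: SessionDesign,
    seed: int = 0,
    subject_col: str = "mouse",
) -> pd.DataFrame:
    """Draw AUC observations directly from the mixed-model process.

    auc = sum(beta_term * indicator) + u_mouse + eps, with
    u ~ N(0, random_intercept_sd^2) shared within mouse and
    eps ~ N(0, noise_sd^2) per observation. One row per
    mouse x stress x social x label x event x timepoint.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA0C)))
    u = {m: rng.normal(0.0, design.random_intercept_sd) for m in design.mice}
    rows = []
    for mouse in design.mice:
        for stress in STRESS_LEVELS:
            for social in SOCIAL_LEVELS:
                for label in design.label_set:
                    for k in range(design.events_per_label):
                        for tp in TIMEPOINT_LEVELS:
                            row = {subject_col: mouse, "stress": stress,
                                   "social": social, "timepoint": tp,
                                   "label": label, "event": k}
                            mean = sum(
                                beta * _term_indicator(term, row)
                                for term, beta in design.true_lmm_effects.items()
                            )
                            row["auc"] = mean + u[mouse] + rng.normal(
                                0.0, design.noise_sd)
                            rows.append(row)
    return pd.DataFrame(rows)


#: Representative stationary body points per named zone, as functions of the
#: geometry. "interaction": inside the 8 cm cage zone; "center": arena
#: center; "outside": near a far corner, outside both zones.
def _zone_point(zone: str, geom: ArenaGeometry) -> np.ndarray:
    if zone == "interaction":
        # close to the cage so the point stays clear of the center zone
        return np.array([geom.arena_w / 2.0,
                         geom.cage_d + 0.25 * geom.interaction_radius])
    if zone == "center":
        return np.array([geom.arena_w / 2.0, geom.arena_h / 2.0])
    if zone == "outside":
        return np.array([geom.center_margin / 2.0,
                         geom.arena_h - geom.center_margin / 2.0])
    raise ValueError(f"unknown zone {zone!r}; expected interaction/center/outside")


def generate_trajectory(
    geom: ArenaGeometry,
    occupancy_plan: list[tuple[str, float, bool]],
    fps: float = 30.0,
    max_duration_s: float | None = None,
) -> Trajectory:
    """Piecewise-stationary trajectory realizing a zone-occupancy plan.

    Each plan entry is (zone, seconds, oriented): the body sits at the
    zone's representative point for round(seconds * fps) frames with the
    head placed 2 cm toward the cage center (oriented) or directly away
    (not oriented). Per-zone dwell times equal the plan within one frame.
    """
    total = sum(s for _, s, _ in occupancy_plan)
    if max_duration_s is not None and total > max_duration_s:
        raise ValueError(
            f"plan lasts {total:g} s, exceeding the session "
            f"duration {max_duration_s:g} s"
        )
    cage = np.asarray(geom.cage_center)
    body_rows, head_rows = [], []
    for zone, seconds, oriented in occupancy_plan:
        body = _zone_point(zone, geom)
        to_cage = cage - body
        unit = to_cage / np.linalg.norm(to_cage)
        head = body + (2.0 * unit if oriented else -2.0 * unit)
        nf = int(round(seconds * fps))
        body_rows.extend([body] * nf)
        head_rows.extend([head] * nf)
    n = len(body_rows)
    time = np.arange(n) / fps
    if n == 0:
        return Trajectory(time, np.empty((0, 2)), np.empty((0, 2)))
    return Trajectory(time, np.array(body_rows), np.array(head_rows))


def generate_counts(
    cluster_means: pd.DataFrame,
    n_cells_per_cluster: dict[str, int],
    dispersion: float = 2.0,
    rng_seed: int = 0,
) -> tuple[sparse.csr_matrix, list[str], list[str], pd.DataFrame]:
    """Negative-binomial gene x cell counts with cluster-specific rates.

    ``cluster_means`` is genes x clusters (mean counts per cell >= 0);
    ``dispersion`` is the NB shape theta (var = mu + mu^2/theta). Returns
    (matrix, gene names, cell names, labels table aligned to columns).
    """
    if (cluster_means.to_numpy() < 0).any():
        raise ValueError("expression rates must be >= 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0xC0)))
    genes = list(cluster_means.index)
    blocks, cells, labels = [], [], []
    for cluster in cluster_means.columns:
        n_cells = int(n_cells_per_cluster.get(cluster, 0))
        mu = cluster_means[cluster].to_numpy()[:, None]  # genes x 1
        p = dispersion / (dispersion + mu)
        block = np.where(
            mu > 0,
            rng.negative_binomial(dispersion, p, size=(len(genes), n_cells)),
            0,
        )
        blocks.append(block)
        start = len(cells)
        cells.extend(f"cell_{start + i:05d}" for i in range(n_cells))
        labels.extend([cluster] * n_cells)
    dense = np.concatenate(blocks, axis=1) if blocks else np.empty((len(genes), 0))
    matrix = sparse.csr_matrix(dense.astype(np.int64))
    label_df = pd.DataFrame({"cell": cells, "cluster": labels})
    return matrix, genes, cells, label_df
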