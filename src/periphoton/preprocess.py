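"""Photometry signal chain: downsample, biexponential detrend, dF/F.

The chain mirrors the standard isosbestic workflow: both channels are
downsampled to the 30 Hz video rate by non-overlapping bin means, a
biexponential photobleaching model is least-squares fitted to the 405 nm
isosbestic channel, affine-rescaled onto the 470 nm signal channel, and the
fractional change dF/F = 100*(ch470 - fitted)/fitted is computed in percent.
Motion artifacts shared between the channels are removed by regressing the
isosbestic residual (405 minus its smooth fit, which carries the motion
waveform but no calcium signal) out of the signal channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import DffTrace, PhotometryRecording

__all__ = [
    "BiexpModel",
    "FitError",
    "downsample",
    "fit_biexponential",
    "fit_single_exponential",
    "correct_and_dff",
]


class FitError(RuntimeError):
    """Detrending fit failed to converge; carries per-restart diagnostics."""


@dataclass
class BiexpModel:
    """v(t) = a1*exp(-t/tau1) + a2*exp(-t/tau2) + c, with tau1 <= tau2.

    ``scale``/``offset`` hold the affine map applied when the curve fitted on
    the isosbestic channel is rescaled onto the signal channel.
    """

    a1: float
    tau1: float
    a2: float
    tau2: float
    c: float
    scale: float = 1.0
    offset: float = 0.0
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        if self.tau1 > self.tau2:  # canonical order for identifiability
            self.a1, self.a2 = self.a2, self.a1
            self.tau1, self.tau2 = self.tau2, self.tau1

    def curve(self, time_s: np.ndarray) -> np.ndarray:
        """Evaluate the (unrescaled) bleaching curve."""
        t = np.asarray(time_s, dtype=float)
        return (
            self.a1 * np.exp(-t / self.tau1)
            + self.a2 * np.exp(-t / self.tau2)
            + self.c
        )

    def rescaled_curve(self, time_s: np.ndarray) -> np.ndarray:
        return self.scale * self.curve(time_s) + self.offset


def downsample(rec: PhotometryRecording, target_hz: float = 30.0) -> PhotometryRecording:
    """Reduce a recording to ``target_hz`` by non-overlapping bin means.

    Sample ``i`` belongs to bin ``floor(i * target_hz / rate_hz)``; each
    output value is the mean of its bin and its timestamp is the bin center
    ``t0 + (k + 0.5)/target_hz``. Bin means (rather than decimation) act as an
    anti-aliasing box filter. Raises if the recording is already at or below
    the target rate (no upsampling).
    """
    if rec.rate_hz < target_hz:
        raise ValueError(
            f"cannot downsample {rec.rate_hz:g} Hz to {target_hz:g} Hz: "
            "input rate below target"
        )
    n = len(rec)
    n_out = int(np.floor(n * target_hz / rec.rate_hz))
    if n_out == 0:
        raise ValueError("recording too short for one output bin")
    bins = np.floor(np.arange(n) * target_hz / rec.rate_hz).astype(np.intp)
    keep = bins < n_out  # drop the trailing partial bin
    counts = np.bincount(bins[keep], minlength=n_out)
    t0 = rec.time_s[0]
    time = t0 + (np.arange(n_out) + 0.5) / target_hz
    ch405 = np.bincount(bins[keep], weights=rec.ch405[keep], minlength=n_out) / counts
    ch470 = np.bincount(bins[keep], weights=rec.ch470[keep], minlength=n_out) / counts
    return PhotometryRecording(time, ch405, ch470, rate_hz=target_hz)


def _exp_residual(params: np.ndarray, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    a1, tau1, a2, tau2, c = params
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c - v


def fit_single_exponential(time_s: np.ndarray, values: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares fit of a*exp(-t/tau) + c; returns (a, tau, c, resnorm).

    Used as the nested reference model the biexponential fit must beat.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(values, dtype=float)
    t = t - t[0]
    duration = max(t[-1], 1e-9)

    def resid(p):
        a, tau, c = p
        return a * np.exp(-t / tau) + c - v

    best = None
    for tau0 in (duration / 10.0, duration / 3.0, duration):
        sol = least_squares(
            resid,
            x0=[max(v[0] - v.min(), 1e-9), tau0, v.min()],
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a, tau, c = best.x
    return float(a), float(tau), float(c), float(np.linalg.norm(resid(best.x)))


def fit_biexponential(
    time_s: np.ndarray,
    values: np.ndarray,
    n_restarts: int = 5,
    rel_tol: float = 1e-10,
) -> BiexpModel:
    """Fit the biexponential bleaching model, deterministically.

    Initialization: ``c0 = min(v)``, the remaining range split 80/20 between
    the two amplitudes, ``tau0 = (duration/10, duration)``. Up to
    ``n_restarts`` restarts with multiplicative jitter drawn from a fixed
    sub-seed follow if the residual has not already fallen below
    ``rel_tol * ||v||``; the lowest-residual solution wins and ties are broken
    by the canonical ``tau1 <= tau2`` order.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 50:
        raise ValueError(f"need >= 50 samples to fit, got {len(t)}")
    if np.any(v <= 0):
        raise ValueError("fluorescence values must be positive")
    t = t - t[0]
    duration = max(float(t[-1]), 1e-9)
    vnorm = float(np.linalg.norm(v))

    c0 = float(v.min())
    amp = max(float(v[0] - c0), 1e-6 * max(abs(c0), 1.0))
    x0 = np.array([0.8 * amp, duration / 10.0, 0.2 * amp, duration, c0])
    lb = np.array([-np.inf, 1e-9, -np.inf, 1e-9, -np.inf])
    ub = np.full(5, np.inf)

    rng = np.random.default_rng(np.random.SeedSequence(0xB1E9))
    best = None
    diagnostics = []
    starts = [x0]
    for x_start in range(n_restarts + 1):
        if x_start > 0:
            jitter = rng.lognormal(mean=0.0, sigma=0.5, size=5)
            starts.append(x0 * jitter + (x0 == 0) * 1e-6)
    for k, start in enumerate(starts):
        try:
            sol = least_squares(
                _exp_residual, start, args=(t, v), bounds=(lb, ub),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
            )
        except Exception as exc:  # pragma: no cover - scipy rarely raises here
            diagnostics.append(f"restart {k}: {exc}")
            continue
        diagnostics.append(f"restart {k}: cost={sol.cost:.3e} status={sol.status}")
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and np.sqrt(2 * best.cost) <= rel_tol * max(vnorm, 1e-12):
            break
    if best is None:
        raise FitError(
            "biexponential fit did not converge; " + "; ".join(diagnostics)
        )
    a1, tau1, a2, tau2, c = best.x
    return BiexpModel(
        a1=float(a1), tau1=float(tau1), a2=float(a2), tau2=float(tau2),
        c=float(c), residual_norm=float(np.linalg.norm(best.fun)),
    )


def _trimmed_affine(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of y on x with one MAD-trimmed refit.

    Sparse large-residual samples (calcium transients ride only on the signal
    channel) would otherwise bias the affine map; one trimming pass removes
    their leverage while leaving well-behaved data untouched.
    """

    def ols(xs, ys):
        xm, ym = xs.mean(), ys.mean()
        vx = np.mean((xs - xm) ** 2)
        if vx <= 0:
            return 0.0, float(ym)
        s = float(np.mean((xs - xm) * (ys - ym)) / vx)
        return s, float(ym - s * xm)

    s, o = ols(x, y)
    resid = y - (s * x + o)
    med = np.median(resid)
    sigma = 1.4826 * np.median(np.abs(resid - med))
    if sigma > 0:
        keep = np.abs(resid - med) <= 5.0 * sigma
        if keep.sum() >= 10 and keep.sum() < len(x):
            s, o = ols(x[keep], y[keep])
    return s, o


def correct_and_dff(
    rec30: PhotometryRecording,
    rescale_fitted: bool = True,
    motion_correction: bool = True,
    target_hz: float = 30.0,
) -> DffTrace:
    """Compute the motion/bleach-corrected dF/F trace in percent.

    The 405 nm channel is fitted to the biexponential model; the fitted curve
    is affine-rescaled onto the 470 nm channel (``rescale_fitted=False``
    divides by the raw fitted curve instead, the literal published formula).
    With ``motion_correction`` on, the isosbestic residual is regressed out of
    the signal channel before division. The fitted curve must be strictly
    positive everywhere — it is the denominator.
    """
    if abs(rec30.rate_hz - target_hz) > 0.01 * target_hz:
        raise ValueError(
            f"expected a {target_hz:g} Hz recording, got {rec30.rate_hz:g} Hz; "
            "run downsample() first"
        )
    model = fit_biexponential(rec30.time_s, rec30.ch405)
    base = model.curve(rec30.time_s - rec30.time_s[0])
    if rescale_fitted:
        scale, offset = _trimmed_affine(base, rec30.ch470)
    else:
        scale, offset = 1.0, 0.0
    model.scale, model.offset = scale, offset
    fitted = scale * base + offset
    if np.any(fitted <= 0):
        i = int(np.argmax(fitted <= 0))
        raise ValueError(
            f"fitted reference non-positive at t={rec30.time_s[i]:g} s; "
            "dF/F division contract violated"
        )
    signal = rec30.ch470.astype(float).copy()
    if motion_correction:
        motion = rec30.ch405 - base
        var = float(np.mean((motion - motion.mean()) ** 2))
        # below ~machine-level variance the residual is pure fit error
        if var > 1e-12 * max(float(np.var(rec30.ch405)), 1e-30):
            gain, _ = _trimmed_affine(motion, signal - fitted)
            signal = signal - gain * motion
    dff = 100.0 * (signal - fitted) / fitted
    return DffTrace(time_s=rec30.time_s.copy(), dff=dff, rate_hz=rec30.rate_hz)
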