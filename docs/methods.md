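# Methods notes

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions that were genuinely open.

## Photometry signal model

A two-channel recording is modeled as

    ch405(t) = B405(t) + m(t) + ε405(t)
    ch470(t) = B470(t) + g·m(t) + Σ_i A_i·k(t − t_i) + ε470(t)

where `B` are biexponential photobleaching curves, `m` is a shared
band-limited motion artifact with per-channel gain `g` (default 1), `ε` is
white measurement noise, and `k` is a unit-peak difference-of-exponentials
calcium-transient kernel

    k(t) ∝ (1 − e^(−t/τ_rise))·e^(−t/τ_decay),  τ_rise = 0.2 s, τ_decay = 1.0 s,

typical GCaMP6f kinetics. Transients ride only on the 470 nm channel:
behavior-locked ones are placed deterministically at event onsets with a
per-label amplitude, spontaneous ones follow a homogeneous Poisson process.
The default raw rate is 1017 Hz — a common acquisition rate that makes the
30 Hz downsampling stage non-trivial — and the default bleach curves share
time constants (60 s, 600 s) across channels with proportional amplitudes,
because both excitation wavelengths watch the same fluorophore pool bleach.
That proportionality is what makes an affine rescale of the isosbestic fit
onto the signal channel exact in the noiseless limit; channels with
unrelated bleaching dynamics would leave a slow residual in ΔF/F, which is
a real limitation of single-reference detrending, not of this
implementation.

## Signal chain

1. **Downsampling** to 30 Hz uses non-overlapping bin means (sample `i` goes
   to bin `floor(i·30/rate)`), which acts as a box anti-aliasing filter;
   decimation would alias noise into the peri-event band. Output timestamps
   are bin centers. No upsampling is ever performed.
2. **Biexponential fit** of the 405 nm channel by bounded least squares.
   Initialization is deterministic: `c0 = min(v)`, the remaining range split
   80/20 between the amplitudes, `τ0 = (duration/10, duration)`; up to 5
   restarts with multiplicative log-normal jitter from a fixed sub-seed run
   only if the residual has not reached 1e-10·‖v‖, and the best residual
   wins. Time constants are reported in canonical order τ1 ≤ τ2 (the two
   exponentials are exchangeable; the order is a tie-break, not physics).
   Non-convergence raises with per-restart diagnostics rather than falling
   back silently.
3. **Rescale and divide.** The fitted curve is mapped onto the 470 nm
   channel by ordinary least squares followed by one MAD-trimmed refit
   (|residual − median| > 5·1.4826·MAD dropped). The trimming matters:
   calcium transients are sparse, positive and live only in the signal
   channel, so a plain OLS tilts the reference toward them and leaves a
   baseline offset in ΔF/F. On transient-free data the trim is a no-op.
4. **Motion regression.** The isosbestic residual `ch405 − fit` carries the
   motion waveform but no calcium signal; its gain into the 470 channel is
   estimated by the same trimmed regression and subtracted. A smooth
   bleaching fit cannot absorb zero-mean motion, so without this step a
   shared artifact would pass straight into ΔF/F. The step is a config
   switch (`motion_correction`); turning it off yields the bare
   fit-subtract-divide formula. When the isosbestic residual variance is at
   numerical floor (noiseless synthetic data) the regression is skipped —
   the gain would be 0/0.
5. **ΔF/F** = 100·(signal − fitted)/fitted, in percent. The fitted curve
   must be strictly positive; a non-positive reference is an error, never a
   clipped division.

Measured on the default noise-free scenario, the residual |ΔF/F| outside
transient support is ~3e-5 % — the floor set by fitting a biexponential to
bin-means of a biexponential, not by the correction itself.

## Peri-event analysis

Windows relative to onset: baseline (−8, −6) s, before (−2, 0) s, after
(0, +2) s, all closed-open in time. The z-score uses the baseline window of
the same event (mean and sample SD, ddof = 1), so the baseline z-trace has
mean 0 and SD 1 by construction — that contract is asserted to 1e-9 in the
tests. Events whose analysis span exits the recording are excluded, not
padded: padding would bias the baseline statistics. A zero-variance
baseline excludes the event with an explicit diagnostic. Overlapping events
are all retained (no exclusion rule is imposed); the overlap count is
logged.

Windowed AUC is the exact integral of the linear interpolant of the trace
over the window — interior samples at their timestamps plus interpolated
edge values. This makes a trace identically 1 over a 2 s window integrate
to exactly 2 z·s regardless of sample/edge alignment, and agrees with a
10×-resolution Riemann oracle to ~0.1 % on band-limited traces. AUC is
computed on the z-scored trace by default (effects are reported in
z-units); computing it on raw ΔF/F is a one-line change at the call site
since `window_auc` is trace-agnostic.

## Inference

The AUC model is `auc ~ stress * social * timepoint` with a random
intercept per mouse, REML, Wald z per coefficient. Treatment coding with
references pre-stress / non-aggressive / baseline; coefficients are only
interpretable under a stated coding, so the cleaned term names
(`timepoint[after]`, `stress[post]:timepoint[after]`, …) carry the levels
explicitly. When the random-intercept variance sits on the zero boundary
some optimizers hit a singular Hessian; the fit falls through
lbfgs → powell → nm and reports a `converged` flag instead of raising.
Wald z tests are mildly liberal at 7 mice (measured type-I ≈ 5–7 % at
nominal 5 % over 500 null replicates) — the price of z rather than
small-sample-df t references.

Repeated-measures ANOVA (two within factors) averages replicate
observations per cell, demands a complete design (a missing cell is an
error naming mouse and condition), and uses within-subject error strata. An
effect whose numerator sum of squares vanishes (response identical across
its levels) is 0/0 in those strata and is reported as F = 0, p = 1 rather
than numerical noise. Cohen's d uses the (n−1)-weighted pooled SD.
Vigilance durations are log(x+1)-transformed — the data contain true zeros,
and the 1 s offset is the smallest round choice in the data's own units.
Planned pairwise comparisons are Welch-corrected and deliberately
uncorrected for multiplicity (they are planned, not post hoc) — callers
needing a correction should apply it to the returned p-values. Shapiro-Wilk
and Fligner-Killeen checks are emitted as diagnostics, never as gates.

## Arena scoring

The wire cage is modeled as a 10 × 10 cm footprint centered on the bottom
wall; "within 8 cm" is distance to the footprint boundary (zero inside),
not to its center. Approach and center-zone membership use the body point;
vigilance uses the body→head vector and requires the body to be outside the
interaction zone with the head within a 45° half-angle of the cage center.
The half-angle is configurable: the behavior was originally scored by eye,
so any angle threshold is a proxy for a human judgment, not a reproduction
of it. Times accrue one frame period (median inter-frame interval) per
qualifying frame; all geometry is on the floor plane.

## Census

Positivity is raw count > 0 — the "+"-subsetting convention. Average
expression is counts-per-10k log1p, averaged within cluster, then scaled
across clusters to zero mean and unit sample SD per gene (the DotPlot
convention; two clusters with one-sided expression scale to ±0.707). Empty
clusters are excluded with a warning; a single cluster reports scaled
values of 0 with an explicit flag. Clustering itself is an input, never
performed here. Whether published "+" counts used raw or normalized
thresholds is generally unstated; raw count > 0 is the default dialect and
both the threshold base and the normalization target are arguments.

## Synthetic generators: what they do and do not emulate

The generators reproduce the statistical structure the analysis assumes —
shared biexponential bleaching, channel-correlated motion, behavior-locked
kernels, within-subject factorial designs with ≥ 10 s event spacing (so the
−8 s baseline never overlaps the previous response), negative-binomial
overdispersed counts with cluster-specific rates. They do not emulate
hemodynamic artifacts, fiber autofluorescence, wavelength-dependent bleach
dynamics, behavior mis-scoring, tracking jitter, or ambient/batch structure
in counts. Passing tests therefore demonstrate correctness of the
computations under the assumed model, not robustness to every artifact of
real rigs. AUC observations for calibrating the mixed model are drawn
directly from the model's own data-generating process (fixed effects +
mouse intercept + iid noise); the full photometry route is exercised
separately with an injected effect of known amplitude.

Default study-scale choices: 7 mice, 2 × 2 within-subject conditions,
10 events per cell, residual SD 1 z·s, mouse-intercept SD 0.5 z·s, injected
after-window effect 3 z·s for recovery checks. Replicate counts in the
acceptance script (100 for coverage, 500 for type-I) balance binomial
resolution (~1 % SE at 500) against desk-scale runtime.

## Determinism

Every stochastic function takes a seed and spawns sub-streams via
`numpy.random.SeedSequence((seed, tag))`, so identical seeds give
bit-identical arrays, stages can be rerun in isolation, and the `run-all`
report is byte-identical across runs. File round-trips are bit-exact
(CSV written at repr precision and parsed with round-trip float
conversion).
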