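# Methods

This note documents the models, conventions, parameter defaults, and design
decisions behind `okretina`, in the spirit of a methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Direction-tuning statistics

Tuning curves sample 8 motion directions at 45° spacing in retinal
coordinates (visual-space direction is the 180° inversion through the eye's
optics; the conversion is a single explicit flip, never implicit).

- **Preferred direction (PD)**: direction of the complex resultant
  Σ m_k e^{iθ_k}. It need not coincide with the best single probed
  direction. Undefined (error) when the resultant vanishes.
- **DSI**: resultant magnitude over the scalar sum; 0 for circular curves,
  1 for a single active direction.
- **Areas**: the linear tuning-curve area is the circular trapezoidal
  integral (with the explicit 315°→360° wraparound segment) divided by
  360°; at equal spacing this equals the mean of the node values. The
  normalized area applies the same integral after dividing by the PD
  response, which is linearly interpolated in angle between the two probed
  directions flanking the PD. Whether the original analyses used trapezoid
  or rectangular integration is unknowable from published text; at equal
  spacing the two coincide except through the interpolated normalization,
  and the trapezoid is used throughout.
- **Zero-spike conventions**: an all-zero spike curve takes DSI = 1,
  linear area = 0, normalized area = 0 — the empirical limit of a cell
  whose last spikes are confined to the PD. The conventions apply to spike
  curves only; an all-zero subthreshold-voltage curve raises instead, since
  the convention has no meaning for continuous deflections. A perfectly
  uniform (nonzero) curve has an undefined PD but a well-defined normalized
  area of exactly 1.
- **Von Mises fit**: A·e^{κ cos(θ−μ)}/(2π I₀(κ)) with a free amplitude,
  fit by least squares with a deterministic multi-start (μ at the 8 probed
  directions × κ ∈ {0.5, 2, 8}); κ is optimized in log-space and the
  exponentially scaled Bessel function keeps large-κ evaluations stable.
- **Classification**: Superior/Inferior assignment requires DSI > 0.05 and
  a PD more than 30° from the temporal-nasal axis; the dorsal/ventral
  component of the PD decides the type. Cells failing either criterion are
  excluded.
- **Width at fraction**: the closed tuning curve is piecewise linear
  between nodes, so half-width crossings are solved exactly on the two
  segments nearest the PD (ties resolved toward the PD).

## Parallel-conductance model

A single compartment obeys

    C dV/dt = G_ex(t)(E_ex − V) + G_in(t)(E_in − V) + G_rest(E_rest − V) + I_inj

integrated by forward Euler at dt = 1 ms (halving dt changes per-direction
spike counts by ≤ 1 on the packaged synthetic set). In spiking mode a
threshold crossing registers a spike; the membrane is held at threshold for
the 3 ms refractory pause, then reset to E_rest. Because the reset also
perturbs the synaptic driving forces, a time-above-threshold proxy
(`proxy_spike_count`) is provided as an alternative spike-output measure;
the two agree qualitatively. Conductances extracted from voltage-clamp
currents via Ohm's law (the 5 mV junction correction cancels in the driving
force) are floored at zero with a logged count, since clamp noise can
produce unphysical negative values. Untuned excitation is the pointwise
maximum across the 8 recorded directions — space-clamp error biases
recorded excitatory currents downward, so the maximum is the least-biased
untuned estimate.

Membrane constants of the packaged synthetic set: E_rest = −54 mV,
C = 60 pF, G_rest = 5 nS (200 MΩ input resistance), E_ex = 0 mV,
V_thresh = −46.2 mV, values typical of mouse retinal ganglion cells and
consistent with a resting potential midway between the ±6 mV
current-injection conditions the physiology motivates.

**Threshold calibration** scans thresholds between E_rest and the peak
preferred-direction Vm, minimizing the equally weighted squared error of
the (DSI, normalized area) pair of the resulting spike curve. Spike-count
metrics are piecewise constant in threshold, so the objective has flat
runs and fine-scale fluctuations; the search therefore refines around
every near-optimal coarse grid point and reports the midpoint of the
minimal plateau. A minimum at the search boundary is flagged.

**Spike isolation** from current-clamp traces marks onsets where dV/dt
exceeds 10 mV/ms (configurable), merges events within the refractory
period, and takes the offset as the first post-peak sample at or below the
onset voltage whose slope has relaxed below 1 mV/ms for several samples —
so the after-hyperpolarization is bridged by the linear interpolation too.
Two spikes closer than the minimum refractory period merge into one event
by construction.

## Synthetic data: what it emulates, and what it does not

The generators encode the qualitative effect structure the pipeline is
designed to detect; defaults were fixed once, at design time.

- **Stimuli.** Oscillating gratings: 20 s static flank, 120 s sinusoidal
  position A sin(2πt/T) with A = 20°, T = 15 s (zero phase at motion
  onset — exactly 8 cycles), 20 s flank. Unidirectional gratings: 20 s
  static, 60 s drift at 10 °/s, 20 s static; 0.15 cycles/° spatial
  frequency. Velocity is the discrete derivative of position, so
  integration recovers position to machine precision.
- **Populations.** Per-cell 8-direction mean rates follow a Von Mises
  profile; Poisson trial noise (negative binomial available via a
  dispersion parameter — trial-to-trial variability of real oDSGCs is not
  characterized in published summaries, so count noise is a convention).
  Defaults: 30 cells/type, 5 trials, PD jitter SD 15° around the type
  axis; peak PD response 20 (Superior) vs 12 (Inferior) spikes; κ 1.3
  (Superior, broader) vs 2.2 (Inferior); low contrast scales amplitude by
  0.35 and multiplies κ by 1.6 (both types sharpen). These orderings —
  Superior larger and broader, hence higher area but *lower* DSI — are the
  configured ground truth that the population-level tests verify.
- **Conductance sets.** Alpha-function kernels (unit peak at τ after
  onset); inhibition (onset 0.4 s, τ 0.45 s) slightly leads excitation
  (onset 0.5 s, τ 0.4 s) and is direction-weighted by an inverted Von
  Mises (κ = 2): minimal at the PD, maximal at the null. Excitation is
  untuned, peak 1.2 nS (Superior) vs 0.9 nS (Inferior) — similar
  inhibition, greater excitation onto Superior cells. Inhibition reverses
  at E_in = −56 mV, just below rest: it acts mainly by shunting. This is a
  deliberate design choice: with strongly hyperpolarizing inhibition the
  Vm tuning of the model varies substantially with excitatory gain,
  whereas shunting inhibition keeps Vm deflections near-linear in gain so
  Vm tuning is nearly gain-invariant while spike tuning sharpens through
  the threshold — the dissociation the model exists to demonstrate.
- **Grating rates.** Population rates are half-wave-rectified copies of
  normalized stimulus velocity on a 5 ms grid (Superior active during the
  superior-motion half-cycle), with configurable gains, baseline, and
  seeded Gaussian noise.
- **Eye traces.** Slow-phase velocity = gain × stimulus velocity (+ drift
  + white noise); stage-specific gains emulate superior/inferior
  asymmetry. Resetting saccades (default 5°, 30 ms) occur at Poisson times
  directed back toward neutral; ground-truth intervals are retained.

What the generators do **not** emulate: retinal topography and
retinotopic PD rotation, adaptation and temporal dynamics of spike
responses within a sweep, correlated (non-Poisson) population noise, head
or body movement artifacts in eye traces, and blinks. Passing tests on
synthetic data therefore demonstrate the correctness and sensitivity of
the estimators under the configured effect structure — not that real
recordings will show these effects.

## Behavioral prediction

Bar-mode predictions bootstrap (10,000 iterations) the difference between
the median PD responses of the minuend type and median ND responses of the
other type, per condition; resampling is over cells (whether the original
analyses resampled cells or trials is unstated; cells is the natural unit
for a population median). Each cell contributes its own PD/ND responses,
determined from its high-contrast curve. Grating-mode predictions subtract
median population rates every 5 ms and integrate by the trapezoid rule from
0°. Predicted-velocity units are spike-rate differences; only orderings and
the fitted sigmoid map to °/s.

The sigmoid is implemented as v(r) = v_min + (v_max − v_min)/(1 +
10^{(r50−r)·m}) — the published form omits the division sign, but this is
the only reading for which v_min/v_max are asymptotes and r50 the
inflection (v(r50) = (v_min+v_max)/2). Fitting uses a deterministic
multi-start (r50 at the data quartiles × m ∈ {0.01, 0.05, 0.2}, asymptotes
initialized at the data extrema); bar mode appends the (0, 0) point.

The permutation analysis enumerates, by default, 4 independent options per
behavioral condition (which cell type is the minuend × which contrast's
responses are used), 4⁴ = 256 assignments, counting those that satisfy the
full ordering predicate (contrast effect in both directions, high-contrast
asymmetry, shrinking asymmetry). The enumeration convention is configurable;
the consistent count depends on it and on the synthetic population, so it
is reported, not asserted against any particular value.

## Eye kinematics

Saccade detection thresholds default to |velocity| > 50 °/s or
|acceleration| > 2,000 °/s², merged within 50 ms — conventional values for
mouse OKR; the original custom scripts are not published, so these are
configurable and recorded in output metadata. Saccade removal substitutes
the pre-onset velocity (0 °/s, flagged, when a saccade starts the trace)
and reintegrates. Slow-phase gain uses stage-mean velocities over each
half-oscillation (a regression-slope estimator is intentionally not the
default: the stage mean is the direct analog of "eye velocity over stimulus
velocity"). Baseline drift is the median velocity during static flanks and
is subtracted only for oscillating epochs, where the eye stays near neutral
(for unidirectional epochs the eye is far from neutral, making the
correction ill-defined).

## Mosaics

Fields are sampled by sequential rejection on a circular retina (default
radius 2 mm, soma radius 15 µm, 669 total cells — a realistic labeled
population). All pairs respect the 30 µm hard core; same-mosaic pairs
additionally respect an exclusion distance drawn per candidate as
Normal(d̄, 0.15·d̄) with d̄ = 0.5 × the hexagonal-lattice spacing at the
mosaic's density (exclusion zones of real mosaics are a fraction of the
regular spacing; a full-spacing exclusion would exceed the jamming density
of random sequential placement). Placement order is randomized; 10,000
retries per cell, with failure an error rather than a silent shortfall.

The DRP counts neighbors in 10 µm annuli (resolving the 30 µm hard core)
and divides by annulus areas summed over reference cells; areas are clipped
to the retina disc by exact circle-circle intersection geometry (a
no-correction mode reproduces the classical estimator, biased low near the
rim). The dip-filling statistic — mean density at 30–70 µm over field
density — discriminates 1, 2, and 4 overlaid mosaics at a fixed total.

Retina frames: the center/radius estimator takes the median circumcenter
and circumradius over all perimeter-point triples, skipping degenerate
ones; normalized coordinates are (distance/radius, angle from the dorsal
axis), with an exact inverse.

## Problem sizes and numerical choices

Simulations in the test suite and acceptance script use the defaults above:
3 s conductance traces at 1 ms (2,400–3,000 steps × 8 directions per sweep
point), 10-point gain grids, 10,000-iteration bootstraps, 100 Hz eye traces
of 160 s, 669-cell mosaics, and a few hundred CI-coverage replicates —
sizes chosen so a full analysis runs on a laptop in well under a minute per
component while keeping Monte-Carlo error far below the tested effect
sizes. Integration tolerances, tie-breaking, and degenerate-input behavior
(all-zero curves, saccades at trace onset, collinear perimeter triples,
zero-magnitude vector sums) are documented at each function and covered by
tests.

## Known limitations

- The membrane model is single-compartment: no dendritic nonlinearities,
  kinetic synapse models, or space-clamp correction.
- The subtraction algorithm is algorithmic, not mechanistic — it does not
  model accessory optic system circuitry or oculomotor plant dynamics.
- Saccade detection thresholds and the exclusion-zone noise model are
  conventions, configurable but not empirically fitted.
- Synthetic populations share one κ per type; real cells show
  heterogeneous widths correlated with response size beyond what the
  amplitude–width coupling here captures.
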