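# okretina

From retinal direction tuning to optokinetic eye movements.

`okretina` is a Python package for analyzing how the two vertically tuned
types of ON direction-selective retinal ganglion cells (oDSGCs) — the
*Superior* type, preferring dorsal-to-ventral motion on the retina, and the
*Inferior* type, preferring the reverse — encode vertical motion, and how
the difference of their outputs predicts the vertical optokinetic reflex
(OKR) in behaving animals. It is aimed at visual neurophysiologists and
computational neuroscientists who work with direction-tuned spike data,
conductance measurements, and eye-tracking recordings.

## What it computes

**Direction tuning** (`okretina.tuning`). For 8-direction tuning curves
m(θ_k): the vector-sum preferred direction, the direction selectivity index

    DSI = |Σ_k m_k e^{iθ_k}| / Σ_k m_k ∈ [0, 1],

linear and preferred-direction-normalized tuning-curve areas (circular
trapezoidal integral / 360°), widths at fractional response, Von Mises fits
A·e^{κ cos(θ−μ)} / (2π I₀(κ)), and the Superior/Inferior/excluded
classification rule (DSI > 0.05, preferred direction > 30° off the
temporal-nasal axis).

**Parallel-conductance model** (`okretina.conductance`). A
single-compartment leaky integrate-and-fire neuron driven by an untuned
excitatory conductance and direction-tuned inhibition:

    C dV/dt = G_ex(E_ex − V) + G_in(E_in − V) + G_rest(E_rest − V),

forward Euler at 1 ms, spike threshold with a 3 ms refractory pause and
reset. Includes Ohm's-law conductance extraction from clamp currents,
untuned-excitation construction (pointwise maximum across directions),
excitatory and joint-E/I gain sweeps, spike-threshold calibration against
target tuning statistics, spike removal from current-clamp traces, and
subthreshold-voltage tuning curves.

**Eye kinematics** (`okretina.eye`). Pupil-landmark → angular eye position
(θ = arcsin(Δy/R_p0), ϕ = arcsin(Δx/√(R_p0²−Δy²))), saccade detection by
velocity/acceleration thresholds, saccade removal by velocity substitution
and reintegration, per-half-cycle slow-phase gain (eye velocity / stimulus
velocity), and fast/slow nystagmus statistics with baseline-drift handling.

**Behavioral prediction** (`okretina.prediction`). The central subtraction
algorithm: bootstrap differences of median Superior and Inferior responses
per stimulus condition, instantaneous rate subtraction integrated to a
predicted eye trajectory p(t) = ∫(Sup − Inf) dt, a four-parameter base-10
sigmoid nonlinearity v(r) = v_min + (v_max − v_min)/(1 + 10^{(r50−r)m}),
and an exhaustive permutation-consistency analysis over scrambled condition
assignments.

**Mosaics** (`okretina.mosaics`). Hard-core + noisy-exclusion-zone mosaic
simulation in a circular model retina, Rodieck-style density recovery
profiles with exact disc-clipping edge correction, retina center/radius
estimation from perimeter-point circumcircles, and normalized polar retinal
coordinates.

**Synthetic data** (`okretina.synthetic`). Generators for every input:
grating/bar stimulus waveforms, oDSGC populations with the empirically
motivated effect structure (Superior responds more and is more broadly
tuned; both types sharpen at low contrast), conductance sets, oscillation
firing rates, and eye traces with ground-truth saccades. All generators are
pure functions of (parameters, seed).

## Worked example

Sweep the excitatory gain of the model oDSGC and watch the spike threshold
sharpen spike tuning while membrane-potential tuning barely moves:

```python
from okretina.synthetic import make_conductance_set
from okretina.conductance import sweep_gain

cset = make_conductance_set("Superior")
sweep = sweep_gain(cset, [0.4, 1.0, 1.6], mode="excitation-only")
for _, row in sweep.iterrows():
    print(f"gain {row.gain:.1f}: PD {row.pd_spikes:4.0f} spikes, "
          f"ND {row.nd_spikes:3.0f}, spike DSI {row.dsi_spk:.3f}, "
          f"Vm DSI {row.dsi_vm:.3f}")
```

```
gain 0.4: PD    0 spikes, ND   0, spike DSI 1.000, Vm DSI 0.178
gain 1.0: PD   33 spikes, ND   0, spike DSI 0.525, Vm DSI 0.129
gain 1.6: PD   83 spikes, ND  31, spike DSI 0.155, Vm DSI 0.111
```

At low gain no direction reaches threshold (an all-zero spike curve takes
DSI = 1 by convention). At unit gain the preferred direction spikes while
the null stays silent — maximal thresholding — and as gain rises further
the null direction breaks through and the spike curve broadens toward the
stable subthreshold (Vm) tuning. This divergence of spike and Vm tuning
across input gain is the core mechanism the package demonstrates, and the
reason OKR gain and its superior/inferior asymmetry fall together at low
stimulus contrast.

A command-line interface exposes the same pipeline (`okretina --help`):
`make-synthetic`, `simulate-model`, `sweep-gain`, `analyze-eye`,
`predict-okr`, `make-mosaic`, and `drp`, each writing CSV outputs plus a
provenance manifest with the config, seed, and file checksums.

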