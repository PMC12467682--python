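# Methods

This note documents the models implemented in `lungsim`, the physical and
numerical parameter choices, what the emulation does and does not capture,
and the design decisions taken where the device description leaves the
design open.

## 1. Active mode: dual-chamber respiratory mechanics

### Model

The respiratory system is the standard electrical analog: muscle pressure
`Pmus` acts through the chest-wall compliance `Ccw` on two parallel lung
branches (`Rl`–`Cll`, `Rr`–`Clr`) that rejoin and vent to atmosphere
through the upper-airway resistance `Rt`. The input–output relation from
muscle pressure to upper-airway flow is the circuit admittance; with the
auxiliary products

```
f1 = Rl·Rr·Cll·Clr          g1 = f1·Ccw + f3·Ccw·Rt
f2 = Rl·Cll + Rr·Clr        g2 = f3 + f2·Ccw + f4·Ccw·Rt
f3 = (Rl + Rr)·Cll·Clr      g3 = f4 + Ccw
f4 = Cll + Clr              g4 = f3·Ccw ,  g5 = f4·Ccw
```

the transfer function is `Q/Pmus = −60·(g4 s² + g5 s)/(g1 s² + g2 s + g3)`.

**Unit system.** All internal computation is in L, cmH2O and s.
Compliances quoted clinically in mL/cmH2O are divided by 1000 so that
every R·C product is a time constant in seconds. The −60 factor converts
L/s to the conventional L/min display scale and carries the sign
convention that *negative* (sub-atmospheric) muscle pressure produces
*positive* inspiratory flow; the simulator therefore feeds the negative of
the muscle-effort magnitude profile into the admittance. This is the only
unit assignment that makes the R·C products seconds and the flows land in
the physiological tens-of-L/min range.

The numerator has no constant term, so the DC gain is exactly zero:
sustained constant effort moves no steady flow. For positive parameters
the denominator is Hurwitz, so the model is unconditionally stable; the
constructor still verifies pole locations and refuses simulation
otherwise.

The construction is cross-checked in the test suite against an
*independent* phasor oracle that evaluates the circuit impedance element
by element (and against the single-compartment reduction for symmetric
lungs), to 1e-6 relative at sampled frequencies.

### Muscle profile

The device description fixes only the peak magnitude, the rate, and the
shape class "rises gradually, decays rapidly". The default profile is:

* concave quadratic rise to `Pmus_max` over `rise_fraction` (default 0.35)
  of the breath period — zero slope at the peak;
* exponential decay with time constant one third of the decay window
  (`decay_fraction`, default 0.15, of the period), offset-corrected so the
  profile reaches exactly zero at the end of the window (continuity);
* zero rest phase for the remainder.

The rise must last strictly longer than the decay; this asymmetry is what
makes the expiratory flow peak exceed the inspiratory one (54 vs 31 L/min
for the normal preset). All fractions are configurable per profile.

### Time-domain realization

The biproper admittance is realized in controllable canonical state space
and integrated with a fixed-step classical Runge–Kutta (RK4) scheme at
dt = 1 ms — the device's control cycle — from zero initial state. The RK4
step operators for the LTI system are precomputed, so the per-step cost is
a 2×2 matrix–vector product. The suite cross-checks the integrator against
`scipy.signal.lsim` (~1e-5 relative agreement; the residual is the
different input quadrature — piecewise-linear hold vs exact midpoint
sampling).

Tidal volume is the cumulative trapezoidal integral of flow (L/s × 10³ →
mL); intrapulmonary pressure uses the orifice law with sign `−sign(Q)`:
suction during inspiration, positive during expiration. The printed
pressure relation gives only a magnitude; the sign choice matches the
physiological convention and the device's displayed waveforms.

### Disease presets

The registry reproduces the device's published parameter grids
field-for-field: normal; an effort grid (peak muscle pressure 8/10/12
cmH2O); ARDS of graded severity (compliance falls 22.5 → 15 mL/cmH2O,
small-airway resistance rises 1 → 4); COPD of graded severity (upper- and
small-airway resistance rise up to 20 and 8, recoil falls). With these
inputs the simulator reproduces the expected clinical orderings, which the
suite asserts: tidal volume strictly increasing in drive, non-increasing
in severity for both disease families.

### Cylinder calibration and actuator emulation

Cylinder position is a bench-calibrated cubic in tidal volume,
`x(Vt) = −2.9205·Vt³ + 4.6297·Vt² + 5.6886·Vt + 0.423` (x in cm, Vt in
litres — the units are not documented by the device; this choice only
scales the virtual actuator and cancels in round-trip flow checks; the
fitted range is taken as 0–1 L and volumes outside it flag extrapolation).
The published open-loop speed law uses the secant gain `k = x/Vt`; its
home-offset term makes the ratio diverge like `0.423/Vt` near zero volume,
so at exactly zero volume the linear coefficient is used as the limit
slope. `actuation_plan` reports this published law by default. The
*actuator emulation*, however, uses the kinematically exact local gain
`dx/dVt` (bounded within 5.69–8.13 cm/L over the fitted range): the secant
gain would make the command/achieved-flow inversion ill-conditioned, and
only the slope makes the singularity genuinely removable.

The emulated actuation chain between commanded and achieved motion is

1. a transport delay (default 113 ms — the device's normal-condition
   response time; the dominant effect of its controller/communication/
   motor pipeline),
2. first-order smoothing with τ = 1 ms (one control cycle; a stepper
   follows its pulse-rate command within a cycle),
3. speed quantization of 0.01 cm/s (pulse-generator resolution).

The device reports its delay (response time, ≤200 ms) and its flow error
(≤3 L/min) as *separate* figures; they are mutually consistent with the
displayed waveform amplitudes only if the error is measured after the pure
delay is removed. `flow_tracking_error` therefore compensates the
cross-correlation-estimated delay by default (an uncompensated variant is
available). The delay estimator uses normalized cross-correlation with
per-lag local demeaning and scaling, which recovers an injected grid delay
exactly and is invariant to amplitude scaling.

A first-order actuator lag large enough to be interesting (tens of ms)
cannot keep the *uncompensated* pointwise error within 3 L/min on these
waveforms — the expiratory transient slews at ~750 L/min/s, and the
physical device itself does not track that peak — which is why the
emulation models the pipeline as delay + hold + quantization rather than a
large smoothing lag.

## 2. Orifice resistance model

The airway-resistance element is a thin-walled orifice: the jet is
turbulent at ventilation flows, so the pressure drop is quadratic,
`Δp = (r·Q)²`, and the setting is characterized by the single coefficient
`r = √Δp / Q`. Under this law `r`'s true dimensions are √cmH2O·s/L; the
conventional clinical label cmH2O/(L/s) is retained in reports for
comparability with commercial test lungs. (A linear definition
`R = Δp/Q` is *not* consistent with the device's own bench calibration —
the extracted linear resistance would grow with flow — so the quadratic
law is the operative definition throughout, including the ventilator
pressure balance.)

Coefficient extraction is refused below a configurable low-flow floor
(default 0.05 L/s): with flow in the denominator, sensor noise blows the
estimate up near zero flow, and the laminar/turbulent transition makes the
quadratic model itself unreliable there. `fit_coefficient` pools several
calibration points by least squares on `√Δp = r·Q` and flags the fit when
the worst per-point relative residual exceeds 10% (the coefficient of a
fixed throttle setting should be flow-independent). The throttle-radius
power law `R = 10.82·radius⁻¹·⁰¹` (calibrated at a constant 30 L/min
bench flow) converts between opening radius and resistance; its validity
away from that bench flow is not documented.

## 3. Passive mode: airbag plant

The airbag is an expandable volume driven by the motor: flow into the bag
is `Q = (v·sd + d)/1000` L/s with `sd` the base area (cm²), `v` the motor
speed (cm/s) and `d` a lumped internal disturbance (mL/s) standing in for
the bag's lateral elastic deformation. Gas compressibility is neglected.
The bag sits behind the orifice element, so its gauge pressure is
`p = Paw − sign(Q)·(r·Q)²`, and the controlled output is the device
compliance `C = V/p` with `V` the total volume (tidal + residual
`VF = PEEP·Cd`). Pressure is gauge — the only convention under which
`C = Cd` holds at PEEP with that residual volume. `p ≤ 0` is a collapsed-
airbag fault: the run is aborted and reported.

The ventilator source is a periodic square profile (Ppeak during the
inspiratory time TI, PEEP otherwise) with linear pressurisation/release
ramps. Default settings: Ppeak 15 cmH2O, PEEP 4 cmH2O, TI 1 s; 15
breaths/min for compliance-regulation runs, 20 for the pressure-supply
scenario. The ramp time is not documented; 0.15 s — a typical bilevel-
ventilator pressurisation ramp — is the default.

**Sensors.** Measured flow and pressure pass through a first-order
30 Hz bandwidth filter and acquire seeded zero-mean Gaussian noise
(σ_flow = 0.5 L/min, σ_p = 0.1 cmH2O). Breathing signal content lives
below ~10 Hz, so the filter does not distort the waveforms; it represents
the sensor/DAQ chain of the physical rig, and with it the closed-loop
compliance scatter lands in the same class as the physical device's
three-cycle measurement ranges (worst-case ~4.7% at Cd = 40, decreasing
with Cd). The controller consumes the sensor's band-limited output
directly; there is no additional software filtering. Measured volume is
the integral of measured flow from the known residual volume.

**Disturbance.** Default: a 5 mL/s, 0.25 Hz sinusoid (lateral-deformation
creep at breathing timescale); constant, filtered-noise and off variants
are available, all bit-reproducible given a seed. The observer cancels the
default disturbance almost completely — compliance accuracy is insensitive
to it.

## 4. Passive mode: SMC + LESO compliance controller

State: `x1 = V` (mL) with `ẋ1 = b·u + d`, `b = sd`. The LESO

```
z1 ← z1 + h1·(z2 + β1·fal(e1, α1, δ) + b·u)
z2 ← z2 + h1·β2·fal(e1, α2, δ),        e1 = V_meas − z1
```

estimates volume and the lumped disturbance; `fal` is the usual
power/linear nonlinearity ("large error, small gain; small error, large
gain"), taken with the standard threshold-at-δ branch structure and
realized odd and continuous. The controller tracks the moving target
`xd = Cd·p_meas` on the integral surface `s = e + k·∫e`, `e = z1 − xd`,
with the smooth reaching law and the control law

```
u = (1/b)·(−k1·s − sigmoid(s)·√|s|·sign(s) − z2 − β1·fal(e1, α1, δ) − e/p)
```

clamped to ±15 cm/s with a 200 cm/s² slew (acceleration) limit and
discretised at h1 = 1 ms. Gains: k = 10, k1 = 25, β1 = 100, β2 = 300,
α1 = 0.5, α2 = 0.25, δ = 0.01 — the device's tuned values. The fractional
power `s^0.5` is realized as the signed root `√|s|·sign(s)` (odd, finite-
time converging from both sides); the sigmoid is kept on its natural
(0, 1) range, which combined with the signed root remains stabilising for
negative s; the observer gains appearing in the control law are the same
β1/β2 as in the observer.

Design choices beyond the published description:

* **Speed clamp 15 cm/s.** The ideal compliance-tracking trajectory
  requires flow steps of `√(Ppeak−PEEP)/r ≈ 1.06 L/s` at phase
  transitions, i.e. ~10.6 cm/s of motor speed at sd = 100 cm²; a clamp
  below that makes every target unreachable within the inspiratory time.
* **Slew limit 200 cm/s².** A speed command that can step arbitrarily
  fast outruns the orifice-pressure feedback and sucks the bag below zero
  gauge pressure within one control cycle; a finite motor acceleration is
  both physically necessary and what stabilises the transition.
* **Anti-windup.** The surface integral uses clamping anti-windup
  (integration is reverted when the command saturates and the error keeps
  pushing into the clamp); without it the clamped transitions wind the
  integral up and the loop limit-cycles.
* **Timescales.** The observer settles a unit innovation in O(1/β1)
  ≈ 10–20 ms; the autonomous reaching law from s(0) = 400 reaches 1% in
  ≈ 0.18 s (convergence operationalized as first time |s| < 1% of |s(0)|,
  threshold configurable). The separation (observer ≪ surface ≪ breath)
  justifies the independent observer/controller design. Note that deep in
  the fal linear zone the z2 channel's slow eigenvalue is ≈ −9.6 /s, so
  "slow" disturbances are those well below ~0.5 rad/s.

**Reaching condition.** The printed control law leaves a residual
`(k − 1/p)·e` cross-term in ṡ, so the strict per-step sign condition
`s·ṡ < 0` is *not* a property of the closed tracking loop (nor can it be
under actuator saturation or exogenous ventilator forcing). The numerical
Lyapunov checks are therefore: strict sign condition for the autonomous
reaching law (asserted with zero violations outside the |s| > 0.1
boundary layer), and *practical reaching* for the closed loop — from a
200 mL initial volume offset with a constant target, s enters the
boundary layer within ~1 s and remains there.

**Metrics.** Compliance statistics are computed over three ventilation
cycles after two settling cycles, excluding a 0.3 s blanking window after
each phase transition — approximately the closed-loop error-dynamics
settling time 4/|Re λ| ≈ 0.32 s at the tuned gains (λ = −12.5 ± 9.7i),
and the counterpart of the "significant jitter" the physical device shows
at inhalation/exhalation onsets. The window is configurable;
`percent_error = max |C − Cd| / Cd · 100` over the retained samples.

## 5. What the emulation does and does not capture

Captured: the full closed-loop interaction of controller, motor limits,
orifice nonlinearity, sensor bandwidth/noise and disturbance; the active-
mode waveform physiology (flow/volume/pressure magnitudes and asymmetries,
disease-severity orderings); delay-dominated actuator behaviour.

Not captured, by design:

* volume-dependent (nonlinear) compliance — the device assumes linear
  compliance throughout;
* per-lung flow partition in active mode (the device reports upper-airway
  flow only), and asymmetric dual-chamber passive ventilation through a
  tee junction — those effects are three-dimensional flow phenomena
  outside a lumped-parameter model;
* gas compressibility in the airbag;
* hardware specifics: stepper electronics, LabVIEW host, physical
  sensors.

Consequences for interpreting green tests: passing the compliance-accuracy
checks shows the control design holds its spec under the *modelled* noise,
bandwidth and motor limits, with scatter calibrated to the class of the
physical device's measurements — not that any particular physical rig
meets it. The active-mode tracking figure likewise characterizes the
emulated delay/quantization pipeline, not real stepper dynamics.

Known quirks: during sustained filling/emptying the slew limiter and the
fal kink (δ = 0.01 on a mL scale) interact in a small ±0.2 cm/s command
limit cycle; it is invisible in the band-limited measured channels but
rectifies into a transient ~16% bias of the disturbance estimate z2 while
motion lasts (z2 recovers to ~1% once motion ceases). Disturbance-recovery
properties are therefore evaluated in the end-expiratory rest window.

## 6. Problem sizes and reproducibility

Closed-loop runs integrate 5 ventilation cycles (20 s) at 1 kHz; active
runs 4–6 breaths at 1 kHz. These sizes make every reported statistic
(three-cycle metrics after two settling cycles) well-defined while keeping
a full acceptance recomputation and the complete scenario grid in the
tens of seconds on one core. All stochastic components (sensor noise,
disturbance traces) derive from explicit seeds; identical seeds give
bit-identical traces, metrics and output files.
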