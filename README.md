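# lungsim

A software twin of a dual-chamber, stepper-motor-driven bionic lung
simulator for mechanical-ventilation research, ventilator bench testing and
respiratory teaching. The package reproduces both operating modes of the
physical device:

* **Active mode** — spontaneous breathing. A two-compartment
  lumped-parameter model of the respiratory system (left/right small-airway
  resistances `Rl`, `Rr` in series with lung compliances `Cll`, `Clr`,
  joined through the chest-wall compliance `Ccw` and venting through the
  upper-airway resistance `Rt`) is driven by a respiratory-muscle pressure
  profile `Pmus(t)` that rises gradually and decays rapidly. With `Pmus` as
  input and upper-airway flow `Q` as output, the model is the circuit
  admittance

  ```
  Q(s)/Pmus(s) = −60 · (g4·s² + g5·s) / (g1·s² + g2·s + g3)
  ```

  with `f/g` products of the seven mechanical parameters (units L, cmH2O,
  s; the −60 converts L/s to L/min and encodes the sub-atmospheric sign of
  inspiratory effort). Normal, ARDS (restrictive) and COPD (obstructive)
  parameter presets of graded severity are built in, plus a muscle-effort
  grid. Target waveforms are converted to electric-cylinder commands via a
  cubic position/volume calibration and pushed through an emulated
  actuation chain (transport delay, zero-order hold, speed quantization).

* **Passive mode** — ventilator-dependent operation. The device is an
  airbag behind a thin-walled-orifice resistance element whose pressure
  drop is quadratic in flow, `Δp = (r·Q)²`. A sliding-mode controller with
  a linear extended state observer (LESO) drives the motor so that the
  device compliance `C = V/p` holds a target `Cd` while a
  pressure-controlled ventilator cycles between PEEP and Ppeak. The LESO
  estimates the airbag volume and a lumped internal disturbance through the
  `fal` nonlinearity; the control law uses an integral sliding surface
  `s = e + k∫e` with the smooth reaching law
  `ṡ = −k1·s − sigmoid(s)·√|s|·sign(s)`.

The orifice resistance model (coefficient extraction `r = √Δp / Q`, the
quadratic pressure-drop law, and the throttle-radius power law
`R = 10.82·radius⁻¹·⁰¹`) is shared by both modes.

## Worked example

Simulate a normal spontaneous breath (peak muscle pressure 10 cmH2O,
16 breaths/min, lung compliances 35 mL/cmH2O each, chest wall 200
mL/cmH2O) and judge how well the emulated actuator reproduces it:

```
$ lungsim simulate-active --preset normal --out demo/
{
  "mode": "active",
  "tidal_volume_mL": [487.2, 487.2, 487.2],
  "insp_peak_flow_L_min": 31.5,
  "exp_peak_flow_L_min": 54.1,
  "insp_peak_pl_cmH2O": 2.2,
  "exp_peak_pl_cmH2O": 6.6,
  "max_flow_error_L_min": 0.45,
  "response_time_ms": 114.0
}
```

Each breath moves a tidal volume of about 487 mL. The expiratory flow peak
(54 L/min) exceeds the inspiratory one (31 L/min) because the muscle drive
decays much faster than it rises; intrapulmonary pressure swings from −2.2
cmH2O of inspiratory suction to +6.6 cmH2O during expiration. The emulated
actuation chain follows the target flow with a 114 ms transport delay and
a residual (delay-compensated) flow error of 0.45 L/min — within the
device's ≤200 ms / ≤3 L/min performance class.

A passive run regulating the device compliance to 80 mL/cmH2O under
pressure-controlled ventilation (Ppeak 15, PEEP 4 cmH2O, 15 breaths/min):

```
$ lungsim simulate-passive --cd 80 --seed 2
{
  "mode": "passive",
  "compliance_mean_mL_cmH2O": 79.9,
  "compliance_min_mL_cmH2O": 77.6,
  "compliance_max_mL_cmH2O": 82.2,
  "compliance_percent_error": 2.99
}
```

Over three post-settling ventilation cycles the measured compliance stays
within 3% of the 80 mL/cmH2O target (metrics exclude a 0.3 s
phase-transition blanking window, mirroring the jitter window of the
physical device).

Other entry points: `lungsim calibrate-resistance points.csv` fits the
orifice coefficient from bench flow/pressure pairs, and
`lungsim reproduce --all` re-runs the committed scenario grid in
`configs/` (compliance grid, resistance pair, effort grid, ARDS/COPD
severity grids) in under a minute.

## Layout

| module | contents |
| --- | --- |
| `lungsim.mechanics` | dual-chamber model, transfer function, muscle profiles, active simulation, cylinder calibration |
| `lungsim.orifice` | quadratic orifice law, coefficient extraction/fit, radius calibration |
| `lungsim.plant` | ventilator pressure source, airbag plant, sensor/disturbance models, compliance metrics |
| `lungsim.control` | `fal`, LESO, sliding surface, reaching/control law, closed-loop runner |
| `lungsim.experiments` | scenario configs, actuator emulation, tracking-error/response-time metrics |
| `lungsim.presets` | normal / effort-grid / ARDS / COPD parameter registry |
| `lungsim.cli` | `lungsim` command-line interface |

See `docs/methods.md` for the model derivations, parameter defaults and
known limitations.
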