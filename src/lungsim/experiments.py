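"""Scenario runner, actuator emulation and performance metrics.

Active-mode performance is judged the way the bench rig is judged: a target
flow waveform is converted to a cylinder-speed command, pushed through an
emulated actuation chain, converted back to an achieved flow, and compared
with the target.  The emulated chain is a transport delay (controller /
communication / motor pipeline; the dominant effect on the physical rig),
a zero-order hold with one-control-cycle first-order smoothing, and speed
quantization.  The two reported metrics decompose the discrepancy the same
way the device datasheet does: ``response_time`` is the pure delay
(cross-correlation lag of the flow traces) and ``flow_tracking_error`` is
the residual amplitude error after that delay has been compensated.  An
uncompensated variant is available via ``compensate_delay=False``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import correlate

from . import presets as presets_mod
from .control import ControllerParams, run_passive_closed_loop
from .mechanics import (
    MuscleProfile,
    RespiratoryMechanics,
    actuation_plan,
    calibration_slope,
    simulate_active,
)
from .plant import DEFAULT_BLANKING, DisturbanceSpec, PlantConfig, SensorSpec, VentilatorSettings
from .series import WaveformSeries

__all__ = [
    "ActuatorEmulation",
    "emulate_actuator",
    "flow_tracking_error",
    "response_time",
    "MetricsReport",
    "Scenario",
    "run_scenario",
    "load_scenario",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ActuatorEmulation:
    """Emulated actuation chain between commanded and achieved motion.

    delay_s : transport delay of the control/communication/motor pipeline
        (default 113 ms, the device's normal-condition response time).
    tau_s : first-order smoothing of the speed command; default one control
        cycle (the stepper follows its pulse-rate command within a cycle).
    quantum_cm_s : speed quantization step of the pulse generator.
    """

    delay_s: float = 0.113
    tau_s: float = 0.001
    quantum_cm_s: float = 0.01

    def __post_init__(self) -> None:
        if self.delay_s < 0 or self.tau_s < 0 or self.quantum_cm_s < 0:
            raise ValueError("actuator emulation parameters must be >= 0")


def emulate_actuator(
    target: WaveformSeries,
    emu: ActuatorEmulation | None = None,
) -> WaveformSeries:
    """Achieved waveform after the emulated actuation chain.

    The target flow is converted to a cylinder speed command via the
    position/volume calibration, delayed, smoothed, quantized, and
    converted back to flow through the same calibration evaluated at the
    *achieved* (self-consistently integrated) volume.
    """
    emu = emu or ActuatorEmulation()
    dt = target.dt
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        # speed command from the kinematically exact calibration slope:
        # the secant gain x/Vt diverges near zero volume and would make the
        # command/achieved inversion ill-conditioned
        _, v = actuation_plan(target, gain="slope", warn_extrapolation=False)

    lag = int(round(emu.delay_s / dt))
    v_ach = np.concatenate([np.zeros(lag), v[: v.size - lag]]) if lag else v.copy()

    if emu.tau_s > 0:
        a = 1.0 - np.exp(-dt / emu.tau_s)
        acc = 0.0
        out = np.empty_like(v_ach)
        for i, x in enumerate(v_ach):
            acc += a * (x - acc)
            out[i] = acc
        v_ach = out
    if emu.quantum_cm_s > 0:
        v_ach = np.round(v_ach / emu.quantum_cm_s) * emu.quantum_cm_s

    # achieved flow through the inverse kinematics at the achieved volume;
    # dx/dVt is bounded below over the calibration range so this is stable
    Q = np.empty_like(v_ach)
    vt = np.empty_like(v_ach)
    vt_L = 0.0
    for i, vc in enumerate(v_ach):
        Q[i] = 60.0 * vc / calibration_slope(vt_L)  # L/min
        vt_L += (Q[i] / 60.0) * dt
        vt[i] = vt_L
    vt_mL = vt * 1e3
    vt_mL -= vt_mL[0]
    return WaveformSeries(t=target.t, Q=Q, Pl=np.zeros_like(Q), Vt=vt_mL,
                          Pmus=target.Pmus)


def _common_grid_check(target: WaveformSeries, achieved: WaveformSeries) -> None:
    if target.t.size != achieved.t.size or not np.allclose(target.t, achieved.t):
        raise ValueError("target and achieved series must share a time grid")


def response_time(
    target: WaveformSeries,
    achieved: WaveformSeries,
    settle_s: float = 0.0,
    max_lag_s: float = 1.0,
) -> float:
    """Transport delay (ms) maximising the flow cross-correlation.

    Invariant to amplitude scaling of either trace; requires at least three
    breathing cycles of non-degenerate signal.
    """
    _common_grid_check(target, achieved)
    dt = target.dt
    m = target.t >= settle_s
    x = target.Q[m] - target.Q[m].mean()
    y = achieved.Q[m] - achieved.Q[m].mean()
    if np.allclose(x, 0) or np.allclose(y, 0):
        raise ValueError("degenerate (constant) flow signal: lag undefined")
    max_lag = int(round(max_lag_s / dt))
    if x.size <= 3 * max_lag:
        raise ValueError("signal too short for the requested lag search range")
    # normalised cross-correlation of a core target segment against the
    # achieved trace, with per-lag local demeaning and scaling: the NCC is
    # exactly 1 at the true alignment (Cauchy-Schwarz), so the flat-topped
    # raw correlation peak cannot be dragged off by window truncation or
    # amplitude/offset differences
    core = x[max_lag:-max_lag]
    core = core - core.mean()
    L = core.size
    num = correlate(y, core, mode="valid")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csq = np.concatenate([[0.0], np.cumsum(y * y)])
    seg_sum = csum[L:] - csum[:-L]
    seg_sq = csq[L:] - csq[:-L]
    var = np.maximum(seg_sq - seg_sum**2 / L, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(var > 0, num / np.sqrt(var * np.sum(core**2)), -np.inf)
    lag = int(np.argmax(ncc)) - max_lag
    return lag * dt * 1e3


def flow_tracking_error(
    target: WaveformSeries,
    achieved: WaveformSeries,
    settle_s: float = 0.0,
    compensate_delay: bool = True,
) -> float:
    """Max |target - achieved| flow error (L/min) over post-settling samples.

    By default the pure transport delay — reported separately by
    :func:`response_time` — is removed first by shifting the achieved trace
    by its cross-correlation lag; ``compensate_delay=False`` compares the
    raw traces sample-by-sample.
    """
    _common_grid_check(target, achieved)
    dt = target.dt
    qa = achieved.Q
    valid = np.ones(qa.size, dtype=bool)
    if compensate_delay:
        try:
            lag = int(round(response_time(target, achieved, settle_s=settle_s)
                            / 1e3 / dt))
        except ValueError:
            lag = 0
        if lag > 0:
            qa = np.concatenate([qa[lag:], np.full(lag, qa[-1])])
            valid[-lag:] = False  # shifted-in padding, not real data
        elif lag < 0:
            qa = np.concatenate([np.full(-lag, qa[0]), qa[:lag]])
            valid[:-lag] = False
    m = (target.t >= settle_s) & valid
    return float(np.max(np.abs(target.Q[m] - qa[m])))


@dataclass(frozen=True)
class MetricsReport:
    """Units-annotated summary of one scenario run."""

    mode: str
    tidal_volume_mL: tuple | None = None   # per post-settling cycle (active)
    insp_peak_flow_L_min: float | None = None
    exp_peak_flow_L_min: float | None = None
    insp_peak_pl_cmH2O: float | None = None   # magnitude of inspiratory suction
    exp_peak_pl_cmH2O: float | None = None
    max_flow_error_L_min: float | None = None
    response_time_ms: float | None = None
    compliance_mean_mL_cmH2O: float | None = None
    compliance_min_mL_cmH2O: float | None = None
    compliance_max_mL_cmH2O: float | None = None
    compliance_percent_error: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps({k: v for k, v in asdict(self).items() if v is not None},
                          indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _per_cycle_tidal_volumes(series: WaveformSeries, period: float,
                             settle_cycles: int) -> tuple:
    out = []
    n_cycles = int(np.floor((series.t[-1] + series.dt / 2) / period))
    for c in range(settle_cycles, n_cycles):
        m = (series.t >= c * period) & (series.t < (c + 1) * period)
        if m.any():
            vt = series.Vt[m]
            out.append(float(vt.max() - vt.min()))
    return tuple(out)


def active_metrics(
    target: WaveformSeries,
    achieved: WaveformSeries | None,
    period: float,
    settle_cycles: int = 2,
) -> MetricsReport:
    """Peak flows/pressures, per-cycle tidal volume, and tracking metrics."""
    settle_s = settle_cycles * period
    m = target.t >= settle_s
    q, pl = target.Q[m], target.Pl[m]
    report = MetricsReport(
        mode="active",
        tidal_volume_mL=_per_cycle_tidal_volumes(target, period, settle_cycles),
        insp_peak_flow_L_min=float(q.max()),
        exp_peak_flow_L_min=float(-q.min()),
        insp_peak_pl_cmH2O=float(-pl.min()),
        exp_peak_pl_cmH2O=float(pl.max()),
    )
    if achieved is not None:
        report = replace(
            report,
            max_flow_error_L_min=flow_tracking_error(target, achieved,
                                                     settle_s=settle_s),
            response_time_ms=response_time(target, achieved, settle_s=settle_s),
        )
    return report


@dataclass(frozen=True)
class Scenario:
    """A committed, seeded, fully-specified experiment configuration."""

    mode: str                       # active | passive | calibration
    name: str = "scenario"
    preset: str | None = None       # active: preset key
    mechanics: dict | None = None   # active: explicit parameter overrides
    profile: dict | None = None
    Cd: float | None = None         # passive: target compliance
    r: float | None = None          # passive: orifice coefficient
    ventilator: dict = field(default_factory=dict)
    actuator: dict = field(default_factory=dict)
    duration: float | None = None
    dt: float = 1e-3
    seed: int | None = None
    settle_cycles: int = 2
    measure_cycles: int = 3
    blanking: float = DEFAULT_BLANKING

    def __post_init__(self) -> None:
        if self.mode not in ("active", "passive"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        if self.mode == "active" and not (self.preset or self.mechanics):
            raise ValueError("active scenario needs a preset or explicit mechanics")
        if self.mode == "passive" and self.Cd is None:
            raise ValueError("passive scenario needs a target compliance Cd")


def load_scenario(path) -> Scenario:
    """Load and schema-check a YAML scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    version = doc.pop("version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported scenario schema version {version!r}")
    known = set(Scenario.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return Scenario(**doc)


def run_scenario(scenario: Scenario, outdir=None):
    """Execute a scenario; returns ``(result, MetricsReport)``.

    Deterministic given the scenario seeds.  When ``outdir`` is given,
    writes the waveform CSV, a metrics JSON and a run log echoing the full
    configuration.
    """
    if scenario.mode == "active":
        if scenario.preset:
            p = presets_mod.get_preset(scenario.preset)
            mech, profile = p.mechanics, p.profile
        else:
            mech = RespiratoryMechanics(**scenario.mechanics)
            profile = MuscleProfile(**(scenario.profile or
                                       {"Pmus_max": 10.0, "RR": mech.RR}))
        if scenario.profile and scenario.preset:
            profile = replace(profile, **scenario.profile)
        period = profile.period
        duration = scenario.duration or (scenario.settle_cycles
                                         + scenario.measure_cycles) * period
        target = simulate_active(mech, profile, duration, dt=scenario.dt)
        achieved = emulate_actuator(target, ActuatorEmulation(**scenario.actuator))
        report = active_metrics(target, achieved, period,
                                settle_cycles=scenario.settle_cycles)
        result = {"target": target, "achieved": achieved}
    else:
        vent = VentilatorSettings(**scenario.ventilator)
        plant_config = PlantConfig(r=scenario.r) if scenario.r is not None \
            else PlantConfig()
        run = run_passive_closed_loop(
            Cd=scenario.Cd, vent=vent, plant_config=plant_config,
            duration=scenario.duration, seed=scenario.seed,
            settle_cycles=scenario.settle_cycles,
            measure_cycles=scenario.measure_cycles, blanking=scenario.blanking,
        )
        met = run.metrics
        report = MetricsReport(
            mode="passive",
            compliance_mean_mL_cmH2O=met.mean,
            compliance_min_mL_cmH2O=met.min,
            compliance_max_mL_cmH2O=met.max,
            compliance_percent_error=met.percent_error,
        )
        result = run

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = scenario.name
        if scenario.mode == "active":
            result["target"].to_csv(outdir / f"{stem}_target.csv")
            result["achieved"].to_csv(outdir / f"{stem}_achieved.csv")
        else:
            result.to_csv(outdir / f"{stem}.csv")
        report.to_json(outdir / f"{stem}_metrics.json")
        (outdir / f"{stem}_run.yaml").write_text(
            yaml.safe_dump({"version": SCHEMA_VERSION, **asdict(scenario)},
                           sort_keys=False)
        )
    return result, report
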