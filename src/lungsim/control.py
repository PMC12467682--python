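"""Passive-mode compliance controller: sliding mode control + LESO.

The plant state is the airbag volume, ``x1 = V`` (mL), with dynamics
``x1' = b*u + d`` (``b = sd`` the bag base area, ``u`` the motor speed in
cm/s, ``d`` the lumped internal disturbance in mL/s).  A linear extended
state observer (LESO) estimates the volume (``z1``) and the disturbance as
an extended state (``z2``) through the `fal` nonlinearity — "large error,
small gain; small error, large gain".  The controller tracks the moving
volume target ``xd = Cd * p`` (so that the device compliance ``C = V/p``
equals the set-point ``Cd``) on an integral sliding surface

    s = e + k * ∫ e,     e = z1 - xd

with the smooth reaching law  ``s' = -k1*s - sigmoid(s)*sqrt(|s|)*sign(s)``.
The sigmoid replaces the discontinuous sign switch of classical SMC and
suppresses chattering while keeping full authority at large |s|.  The
continuous control law is discretised at the 1 ms control cycle.

Numerical conventions (where the published description of the device is
ambiguous): ``s**0.5`` is realised as the
odd signed root ``sqrt(|s|)*sign(s)`` so the reaching law is stabilising
from both sides; the sigmoid is kept on its natural (0, 1) range; the
observer gains used in the control law are the same beta1/beta2 as in the
observer itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .plant import (
    DEFAULT_BLANKING,
    AirbagPlant,
    ComplianceMetrics,
    DisturbanceSpec,
    PlantConfig,
    SensorSpec,
    VentilatorSettings,
    compliance_metrics,
    ventilator_pressure,
)

__all__ = [
    "ControllerParams",
    "ControllerState",
    "fal",
    "sigmoid",
    "leso_step",
    "sliding_surface",
    "reaching_term",
    "control_law",
    "reaching_law_trajectory",
    "convergence_time",
    "run_passive_closed_loop",
    "PassiveRunResult",
    "PASSIVE_CSV_COLUMNS",
]


@dataclass(frozen=True)
class ControllerParams:
    """Sliding-mode + LESO gains; defaults are the tuned device values.

    ``h1`` is the control cycle (s) and must be much shorter than the
    reaching timescale 1/k1 (1 ms vs 40 ms here) so discretisation does not
    reintroduce chattering.  ``b`` is the plant input gain (the airbag base
    area, cm^2).  ``u_max`` clamps the commanded motor speed (cm/s).
    """

    k: float = 10.0       # sliding-surface integral coefficient, 1/s
    k1: float = 25.0      # reaching-law proportional coefficient, 1/s
    beta1: float = 100.0  # observer gain (z1 channel)
    beta2: float = 300.0  # observer gain (z2 channel)
    alpha1: float = 0.5   # fal exponent, z1 channel
    alpha2: float = 0.25  # fal exponent, z2 channel
    delta: float = 0.01   # fal linear-zone half-width
    h1: float = 1e-3      # control cycle, s
    b: float = 100.0      # input gain = airbag base area, cm^2
    u_max: float = 15.0   # actuator speed clamp, cm/s
    du_max: float = 200.0  # actuator acceleration (slew) limit, cm/s^2
    switching: str = "sigmoid"  # "sigmoid" (smooth) or "sign" (hard)

    def __post_init__(self) -> None:
        for name in ("k", "k1", "beta1", "beta2", "alpha1", "alpha2",
                     "delta", "h1", "b", "u_max", "du_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.h1 * self.k1 < 0.1:
            raise ValueError(
                f"control cycle h1={self.h1}s too coarse for k1={self.k1} "
                "(needs h1 << 1/k1)"
            )
        if self.switching not in ("sigmoid", "sign"):
            raise ValueError("switching must be 'sigmoid' or 'sign'")


@dataclass
class ControllerState:
    """Observer and sliding-surface state between control cycles."""

    z1: float = 0.0     # observed volume, mL
    z2: float = 0.0     # observed disturbance, mL/s
    e_int: float = 0.0  # integral of tracking error, mL*s
    s: float = 0.0      # sliding variable, mL
    u: float = 0.0      # last commanded motor speed, cm/s
    e1: float = 0.0     # last observer innovation x1_meas - z1, mL

    @classmethod
    def reset(cls, V0: float) -> "ControllerState":
        """Reset protocol: all zeros except z1 seeded with the known volume."""
        return cls(z1=V0)


def fal(e, alpha: float, delta: float):
    """ADRC `fal` nonlinearity: power law outside, linear inside ``|e|<=delta``.

    ``|e| > delta -> |e|**alpha * sign(e)``;
    ``|e| <= delta -> e / delta**(1-alpha)``.
    Continuous at the threshold and odd in ``e``.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"fal exponent alpha must be in (0, 1], got {alpha}")
    if not delta > 0:
        raise ValueError(f"fal linear-zone width delta must be > 0, got {delta}")
    e = np.asarray(e, dtype=float)
    out = np.where(
        np.abs(e) > delta,
        np.abs(e) ** alpha * np.sign(e),
        e / delta ** (1.0 - alpha),
    )
    return float(out) if out.ndim == 0 else out


def sigmoid(s):
    """Logistic function 1/(1+exp(-s)) on its natural (0, 1) range."""
    s = np.asarray(s, dtype=float)
    out = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
    return float(out) if out.ndim == 0 else out


def leso_step(z, x1_meas: float, u: float, params: ControllerParams,
              dt: float | None = None):
    """One Euler step of the linear extended state observer.

    ``z1 <- z1 + h1*(z2 + beta1*fal(e1, alpha1, delta) + b*u)``
    ``z2 <- z2 + h1*beta2*fal(e1, alpha2, delta)``, with ``e1 = x1_meas - z1``.
    """
    h1 = params.h1 if dt is None else dt
    z1, z2 = z
    e1 = x1_meas - z1
    z1_new = z1 + h1 * (z2 + params.beta1 * fal(e1, params.alpha1, params.delta)
                        + params.b * u)
    z2_new = z2 + h1 * params.beta2 * fal(e1, params.alpha2, params.delta)
    return z1_new, z2_new


def sliding_surface(e: float, e_int: float, params: ControllerParams) -> float:
    """Integral sliding variable ``s = e + k * e_int``."""
    return e + params.k * e_int


def reaching_term(s, params: ControllerParams):
    """Switching part of the reaching law.

    Smooth default: ``sigmoid(s) * sqrt(|s|) * sign(s)`` (signed root keeps
    the term stabilising for s < 0).  ``switching="sign"`` substitutes the
    classical hard switch ``sign(s)`` for chattering comparisons.
    """
    s = np.asarray(s, dtype=float)
    if params.switching == "sigmoid":
        out = sigmoid(s) * np.sqrt(np.abs(s)) * np.sign(s)
    else:
        out = np.sign(s)
    return float(out) if out.ndim == 0 else out


def control_law(state: ControllerState, e: float, e_int: float,
                params: ControllerParams, c: float) -> float:
    """SMC law: commanded motor speed (cm/s), clamped to ``±u_max``.

    ``u = (1/b) * (-k1*s - reaching_term(s) - z2 - beta1*fal(e1) - c*e)``
    with ``c = 1/p`` the output gain and ``e1`` the current observer
    innovation (held on ``state``).  ``p`` must be positive for ``c`` to be
    finite; a collapsed plant propagates its fault before this is called.
    """
    s = sliding_surface(e, e_int, params)
    e1 = state.e1
    u = (1.0 / params.b) * (
        -params.k1 * s
        - reaching_term(s, params)
        - state.z2
        - params.beta1 * fal(e1, params.alpha1, params.delta)
        - c * e
    )
    return float(np.clip(u, -params.u_max, params.u_max))


def reaching_law_trajectory(s0: float, params: ControllerParams | None = None,
                            t_end: float = 1.0, dt: float = 1e-4):
    """Integrate the autonomous reaching law from ``s(0) = s0``.

    ``s' = -k1*s - sigmoid(s)*sqrt(|s|)*sign(s)`` via fixed-step RK4.
    Returns ``(t, s)`` arrays.
    """
    params = params or ControllerParams()

    def f(s):
        return -params.k1 * s - reaching_term(s, params)

    n = int(round(t_end / dt)) + 1
    t = np.arange(n) * dt
    s = np.empty(n)
    s[0] = s0
    x = float(s0)
    for i in range(n - 1):
        k1 = f(x)
        k2 = f(x + dt / 2 * k1)
        k3 = f(x + dt / 2 * k2)
        k4 = f(x + dt * k3)
        x += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        s[i + 1] = x
    return t, s


def convergence_time(t, s, fraction: float = 0.01) -> float:
    """First time |s| falls (and stays) below ``fraction`` of |s(0)|."""
    s = np.asarray(s, dtype=float)
    thresh = fraction * abs(s[0])
    below = np.abs(s) < thresh
    # require it to stay below from that point on
    stay = np.flip(np.logical_and.accumulate(np.flip(below)))
    idx = np.argmax(stay)
    if not stay[idx]:
        return float("inf")
    return float(np.asarray(t)[idx])


PASSIVE_CSV_COLUMNS = [
    "time_s", "paw_cmH2O", "flow_L_min", "p_cmH2O", "volume_mL",
    "compliance_mL_cmH2O", "u_cm_s", "z1", "z2", "s",
]


@dataclass
class PassiveRunResult:
    """Full trace and metrics of one closed-loop passive-mode run."""

    t: np.ndarray
    paw: np.ndarray          # ventilator pressure, cmH2O
    Q: np.ndarray            # true flow, L/min (into the bag positive)
    p: np.ndarray            # true bag pressure, cmH2O
    V: np.ndarray            # true bag volume, mL
    C_meas: np.ndarray       # measured compliance V_meas/p_meas, mL/cmH2O
    C_true: np.ndarray       # true compliance V/p, mL/cmH2O
    u: np.ndarray            # commanded motor speed, cm/s
    z1: np.ndarray
    z2: np.ndarray
    s: np.ndarray
    d: np.ndarray            # injected disturbance, mL/s
    Cd: float
    vent: VentilatorSettings
    params: ControllerParams
    metrics: ComplianceMetrics | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.t, "paw_cmH2O": self.paw, "flow_L_min": self.Q,
            "p_cmH2O": self.p, "volume_mL": self.V,
            "compliance_mL_cmH2O": self.C_meas, "u_cm_s": self.u,
            "z1": self.z1, "z2": self.z2, "s": self.s,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_passive_closed_loop(
    Cd: float,
    vent: VentilatorSettings | None = None,
    plant_config: PlantConfig | None = None,
    params: ControllerParams | None = None,
    duration: float | None = None,
    settle_cycles: int = 2,
    measure_cycles: int = 3,
    blanking: float = DEFAULT_BLANKING,
    seed: int | None = None,
    noise: bool = True,
    disturbance: bool = True,
    initial_volume_offset: float = 0.0,
) -> PassiveRunResult:
    """Run the SMC+LESO compliance loop against the airbag plant.

    Per control cycle: read the (band-limited, noisy) pressure and flow
    measurements, form the moving target ``xd = Cd * p_meas``, advance the
    observer, evaluate the control law, and step the plant with the clamped
    motor speed.  The residual volume is initialised to ``VF = PEEP * Cd``
    so the loop starts on-target at end-expiratory pressure.

    ``seed`` (if given) overrides the sensor/disturbance seeds for
    reproducibility; ``noise=False`` / ``disturbance=False`` switch those
    models off without touching the rest of the configuration.
    ``initial_volume_offset`` starts the bag away from its residual volume
    (a pure regulation transient, used for reaching-condition experiments).

    Returns the full trace plus Table-style compliance metrics over
    ``measure_cycles`` cycles after ``settle_cycles`` settling cycles.
    """
    if not Cd > 0:
        raise ValueError("Cd must be > 0")
    vent = vent or VentilatorSettings()
    plant_config = plant_config or PlantConfig()
    params = params or ControllerParams(b=plant_config.sd)
    if params.b != plant_config.sd:
        params = replace(params, b=plant_config.sd)
    if seed is not None:
        plant_config = replace(
            plant_config,
            sensors=replace(plant_config.sensors, seed=seed),
            disturbance=replace(plant_config.disturbance, seed=seed + 1),
        )
    if not noise:
        plant_config = replace(
            plant_config,
            sensors=replace(plant_config.sensors, sigma_flow=0.0, sigma_p=0.0),
        )
    if not disturbance:
        plant_config = replace(plant_config, disturbance=DisturbanceSpec(kind="none"))

    h1 = params.h1
    min_duration = (settle_cycles + measure_cycles) * vent.period
    if duration is None:
        duration = min_duration
    if duration < min_duration - 1e-9:
        raise ValueError(
            f"duration {duration}s shorter than settling + {measure_cycles} cycles "
            f"({min_duration}s)"
        )

    n = int(round(duration / h1))
    t = np.arange(n) * h1
    d_trace = plant_config.disturbance.sample(t, h1)
    paw_trace = ventilator_pressure(t, vent)

    VF = vent.PEEP * Cd
    V0 = VF + initial_volume_offset
    plant = AirbagPlant(plant_config, VF=VF, dt=h1)
    plant.state.V = V0
    ctrl = ControllerState.reset(V0)
    V_meas = V0

    rec = {name: np.empty(n) for name in
           ("Q", "p", "V", "C_meas", "C_true", "u", "z1", "z2", "s")}
    u = 0.0
    du = params.du_max * h1  # per-cycle speed change limit
    for i in range(n):
        m = plant.step(u, paw_trace[i], d_trace[i])
        V_meas += m.Q_meas * 1e3 * h1

        # observer, driven by the speed actually applied this cycle
        ctrl.z1, ctrl.z2 = leso_step((ctrl.z1, ctrl.z2), V_meas, u, params)
        ctrl.e1 = V_meas - ctrl.z1

        xd = Cd * m.p_meas
        e = ctrl.z1 - xd
        # tentative integration with clamping anti-windup: if the command
        # saturates and the error keeps pushing into the clamp, revert
        ctrl.e_int += e * h1
        u_raw = control_law(ctrl, e, ctrl.e_int, params, c=1.0 / m.p_meas)
        if abs(u_raw) >= params.u_max and np.sign(e) == -np.sign(u_raw):
            ctrl.e_int -= e * h1
            u_raw = control_law(ctrl, e, ctrl.e_int, params, c=1.0 / m.p_meas)
        ctrl.s = sliding_surface(e, ctrl.e_int, params)
        # motor acceleration limit: the stepper cannot change speed by more
        # than du_max*h1 within one control cycle
        u = float(np.clip(u_raw, u - du, u + du))
        ctrl.u = u

        rec["Q"][i] = m.Q * 60.0
        rec["p"][i] = m.p
        rec["V"][i] = plant.state.V
        rec["C_meas"][i] = V_meas / m.p_meas
        rec["C_true"][i] = m.C
        rec["u"][i] = u
        rec["z1"][i] = ctrl.z1
        rec["z2"][i] = ctrl.z2
        rec["s"][i] = ctrl.s

    metrics = None
    if duration >= min_duration - 1e-9:
        metrics = compliance_metrics(
            t, rec["C_meas"], Cd, vent, n_cycles=measure_cycles,
            settle_cycles=settle_cycles, blanking=blanking,
        )
    return PassiveRunResult(
        t=t, paw=paw_trace, Q=rec["Q"], p=rec["p"], V=rec["V"],
        C_meas=rec["C_meas"], C_true=rec["C_true"], u=rec["u"],
        z1=rec["z1"], z2=rec["z2"], s=rec["s"], d=d_trace,
        Cd=Cd, vent=vent, params=params, metrics=metrics,
    )
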