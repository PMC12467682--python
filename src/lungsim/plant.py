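"""Passive-mode plant: ventilator source, motor-driven airbag, sensors.

This module emulates the physical system the compliance controller acts on.
The airbag is an expandable volume whose top plate is driven by the motor:
with base area ``sd`` (cm^2) and motor speed ``v`` (cm/s) the airflow into
the bag is ``Q = (v*sd + d)/1000`` L/s, where ``d`` (mL/s) is an internal
disturbance standing in for the bag's lateral elastic deformation.  Gas
compressibility is neglected.  The bag sits behind the orifice resistance
element, so its internal gauge pressure is the ventilator pressure minus
the signed quadratic orifice drop,

    p = Paw - sign(Q) * (r*Q)**2

and the device compliance — the controlled output — is ``C = V/p`` with
``V`` the total bag volume in mL (tidal volume plus the residual volume
``VF = PEEP*Cd`` held at end-expiration).  ``p`` is gauge pressure: that is
the only convention under which ``C = Cd`` holds at PEEP with ``VF =
PEEP*Cd``.

Measured flow and pressure channels pass through a first-order
sensor-bandwidth filter and acquire seeded Gaussian noise, mirroring the
flow-pressure sensor + DAQ chain of the physical device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "DEFAULT_BLANKING",
    "VentilatorSettings",
    "DisturbanceSpec",
    "SensorSpec",
    "PlantConfig",
    "PlantState",
    "AirbagPlant",
    "PlantFault",
    "ventilator_pressure",
    "compliance_metrics",
    "ComplianceMetrics",
]


class PlantFault(RuntimeError):
    """Raised when the airbag collapses (internal pressure <= 0)."""


#: Default phase-transition blanking window, s.  Covers the pressurisation
#: ramp overlap and the closed-loop ring-down of the compliance controller
#: (error-dynamics settling time 4/|Re(lambda)| ~ 0.32 s at the tuned
#: gains); the physical device shows the same "significant jitter" at
#: inhalation/exhalation onsets.
DEFAULT_BLANKING = 0.3


@dataclass(frozen=True)
class VentilatorSettings:
    """Pressure-controlled ventilation cycle.

    Ppeak during the inspiratory window [0, TI), PEEP for the rest of the
    ``60/RR`` s cycle, with linear pressurisation/release ramps of
    ``rise_time`` seconds at each transition.
    """

    Ppeak: float = 15.0   # cmH2O
    PEEP: float = 4.0     # cmH2O
    RR: float = 15.0      # breaths/min
    TI: float = 1.0       # s
    rise_time: float = 0.15  # s

    def __post_init__(self) -> None:
        if not self.Ppeak > self.PEEP:
            raise ValueError(f"Ppeak ({self.Ppeak}) must exceed PEEP ({self.PEEP})")
        if self.PEEP < 0:
            raise ValueError(f"PEEP must be >= 0, got {self.PEEP}")
        if not self.RR > 0:
            raise ValueError(f"RR must be > 0, got {self.RR}")
        if not self.TI < 60.0 / self.RR:
            raise ValueError(f"TI ({self.TI}) must be shorter than the cycle (60/RR)")
        if self.rise_time < 0:
            raise ValueError("rise_time must be >= 0")

    @property
    def period(self) -> float:
        return 60.0 / self.RR


def ventilator_pressure(t, settings: VentilatorSettings):
    """Ventilator circuit pressure Paw (cmH2O) at time(s) ``t`` (s)."""
    s = settings
    phase = np.mod(np.asarray(t, dtype=float), s.period)
    span = s.Ppeak - s.PEEP
    rt = s.rise_time
    paw = np.full_like(phase, s.PEEP)
    if rt > 0:
        ramp_up = phase < rt
        paw = np.where(ramp_up, s.PEEP + span * phase / rt, paw)
        plateau = (phase >= rt) & (phase < s.TI)
        paw = np.where(plateau, s.Ppeak, paw)
        ramp_dn = (phase >= s.TI) & (phase < s.TI + rt)
        paw = np.where(ramp_dn, s.Ppeak - span * (phase - s.TI) / rt, paw)
    else:
        paw = np.where(phase < s.TI, s.Ppeak, paw)
    return float(paw) if paw.ndim == 0 else paw


@dataclass(frozen=True)
class DisturbanceSpec:
    """Internal airbag disturbance ``d`` (mL/s).

    Kinds: ``none``, ``constant``, ``sinusoid`` (default: slow lateral-
    deformation creep at breathing-cycle timescale), ``filtered-noise``
    (first-order-filtered Gaussian, reproducible given the seed).
    """

    kind: str = "sinusoid"
    amplitude: float = 5.0     # mL/s
    frequency: float = 0.25    # Hz (sinusoid) or cutoff (filtered-noise)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "constant", "sinusoid", "filtered-noise"):
            raise ValueError(f"unknown disturbance kind {self.kind!r}")

    def sample(self, t: np.ndarray, dt: float) -> np.ndarray:
        """Disturbance trace on the grid ``t`` (bit-reproducible per seed)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            return np.zeros_like(t)
        if self.kind == "constant":
            return np.full_like(t, self.amplitude)
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(2 * np.pi * self.frequency * t)
        rng = np.random.default_rng(self.seed)
        white = rng.standard_normal(t.size)
        a = 1.0 - np.exp(-2 * np.pi * self.frequency * dt)
        out = np.empty_like(white)
        acc = 0.0
        for i, w in enumerate(white):
            acc += a * (w - acc)
            out[i] = acc
        # rescale so the trace std equals the requested amplitude
        std = out.std() or 1.0
        return self.amplitude * out / std


@dataclass(frozen=True)
class SensorSpec:
    """Flow/pressure measurement chain: bandwidth limit plus Gaussian noise."""

    sigma_flow: float = 0.5     # L/min, std of flow noise
    sigma_p: float = 0.1        # cmH2O, std of pressure noise
    bandwidth_hz: float = 30.0  # first-order sensor/DAQ bandwidth; 0 disables
    seed: int | None = None


@dataclass
class PlantState:
    """Instantaneous airbag state."""

    V: float          # total volume, mL
    VF: float         # residual volume, mL
    p: float          # internal gauge pressure, cmH2O
    d: float = 0.0    # current disturbance, mL/s
    sd: float = 100.0  # base area, cm^2


@dataclass(frozen=True)
class PlantConfig:
    """Physical configuration of the airbag plant.

    ``sd`` (base area, cm^2) only rescales the commanded motor speed; it
    does not affect any pressure/volume/compliance output.
    """

    sd: float = 100.0
    r: float = 3.14  # orifice coefficient of the resistance element
    disturbance: DisturbanceSpec = field(default_factory=DisturbanceSpec)
    sensors: SensorSpec = field(default_factory=SensorSpec)

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be > 0")
        if self.r < 0:
            raise ValueError("r must be >= 0")


class Measurement(NamedTuple):
    Q: float   # true flow, L/s
    p: float   # true pressure, cmH2O
    C: float   # true compliance, mL/cmH2O
    Q_meas: float
    p_meas: float


class AirbagPlant:
    """Discrete-time airbag plant stepped at the controller cycle.

    The plant exposes the same interface as the physical rig: it accepts a
    motor speed command and returns true and measured flow/pressure plus
    the derived compliance.
    """

    def __init__(self, config: PlantConfig, VF: float, dt: float = 1e-3):
        if VF < 0:
            raise ValueError("residual volume VF must be >= 0")
        self.config = config
        self.dt = float(dt)
        self.state = PlantState(V=VF, VF=VF, p=0.0, sd=config.sd)
        self.t = 0.0
        self._rng = np.random.default_rng(config.sensors.seed)
        bw = config.sensors.bandwidth_hz
        self._alpha = 1.0 - np.exp(-2 * np.pi * bw * self.dt) if bw > 0 else 1.0
        self._q_filt = 0.0
        self._p_filt: float | None = None
        self._sigma_q_ls = config.sensors.sigma_flow / 60.0  # L/min -> L/s

    def step(self, v: float, Paw: float, d: float = 0.0) -> Measurement:
        """Advance one control cycle with motor speed ``v`` (cm/s).

        ``d`` is the instantaneous disturbance (mL/s), normally supplied
        from a pre-sampled :class:`DisturbanceSpec` trace.

        Raises :class:`PlantFault` if the bag pressure falls to or below
        zero (collapsed airbag).
        """
        cfg, st = self.config, self.state
        vdot = v * cfg.sd + d                 # mL/s
        Q = vdot / 1e3                        # L/s into the bag
        st.V += vdot * self.dt
        st.d = d
        p = Paw - np.sign(Q) * (cfg.r * Q) ** 2
        if p <= 0.0:
            raise PlantFault(
                f"collapsed airbag at t={self.t:.3f}s: internal pressure {p:.3f} cmH2O"
            )
        st.p = p
        self.t += self.dt

        q_noisy = Q + self._rng.normal(0.0, self._sigma_q_ls)
        p_noisy = p + self._rng.normal(0.0, cfg.sensors.sigma_p)
        if self._p_filt is None:
            self._p_filt = p_noisy
        self._q_filt += self._alpha * (q_noisy - self._q_filt)
        self._p_filt += self._alpha * (p_noisy - self._p_filt)
        return Measurement(Q=Q, p=p, C=st.V / p, Q_meas=self._q_filt, p_meas=self._p_filt)


@dataclass(frozen=True)
class ComplianceMetrics:
    """Summary of measured compliance over the evaluation cycles."""

    mean: float
    min: float
    max: float
    percent_error: float   # max |C - Cd| / Cd * 100 over retained samples
    n_samples: int
    n_cycles: int


def _transition_mask(t, vent: VentilatorSettings, blanking: float):
    """True for samples outside the phase-transition blanking windows."""
    phase = np.mod(np.asarray(t, dtype=float), vent.period)
    keep = np.ones(phase.shape, dtype=bool)
    if blanking > 0:
        keep &= ~(phase < blanking)                       # inspiration onset
        keep &= ~((phase >= vent.TI) & (phase < vent.TI + blanking))  # expiration onset
    return keep


def compliance_metrics(
    t,
    C,
    Cd: float,
    vent: VentilatorSettings,
    n_cycles: int = 3,
    settle_cycles: int = 2,
    blanking: float = DEFAULT_BLANKING,
) -> ComplianceMetrics:
    """Compliance statistics over ``n_cycles`` post-settling cycles.

    The first ``settle_cycles`` ventilation cycles are discarded, the next
    ``n_cycles`` evaluated.  A blanking window of ``blanking`` seconds after
    each phase transition (inspiration and expiration onset) is excluded
    from the error statistic, mirroring the significant jitter the physical
    device shows at phase starts; set ``blanking=0`` to keep everything.

    ``percent_error = max |C - Cd| / Cd * 100`` over the retained samples.
    """
    t = np.asarray(t, dtype=float)
    C = np.asarray(C, dtype=float)
    if n_cycles < 3:
        raise ValueError("compliance metrics require at least 3 evaluation cycles")
    T = vent.period
    t0, t1 = settle_cycles * T, (settle_cycles + n_cycles) * T
    dt = t[1] - t[0] if t.size >= 2 else 0.0
    if t[-1] + dt + 1e-9 < t1:
        raise ValueError(
            f"trace too short: need {t1:.1f}s ({settle_cycles}+{n_cycles} cycles), "
            f"got {t[-1]:.1f}s"
        )
    window = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
    keep = window & _transition_mask(t, vent, blanking)
    Ck = C[keep]
    if Ck.size == 0:
        raise ValueError("blanking removed every sample")
    err = float(np.max(np.abs(Ck - Cd)) / Cd * 100.0)
    return ComplianceMetrics(
        mean=float(Ck.mean()), min=float(Ck.min()), max=float(Ck.max()),
        percent_error=err, n_samples=int(Ck.size), n_cycles=n_cycles,
    )
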