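"""Dual-chamber lumped-parameter respiratory mechanics (active mode).

The lung is modelled as the electrical analog of a two-compartment circuit:
the respiratory muscle pressure Pmus acts through the chest-wall compliance
Ccw on two parallel lung branches (small-airway resistance Rl/Rr in series
with lung compliance Cll/Clr), which join and vent to atmosphere through the
upper-airway resistance Rt.  With Pmus as input and the upper-airway flow Q
as output the transfer function is the circuit admittance

    Q(s)/Pmus(s) = -60 * (g4 s^2 + g5 s) / (g1 s^2 + g2 s + g3)

where the f/g auxiliary products are formed from the seven mechanical
parameters (see :func:`tf_coefficients`).  Internal computation is in
L, cmH2O and s, so compliances given clinically in mL/cmH2O are divided by
1000 and every R*C product is a time constant in seconds.  The factor -60
converts L/s to the plotted L/min and encodes the sign convention that
sub-atmospheric (negative) muscle pressure produces positive inspiratory
flow; :func:`simulate_active` therefore drives the system with the negative
of the muscle-effort magnitude profile.

The numerator has no constant term, so the DC gain is exactly zero: a
sustained constant muscle pressure moves no steady flow (the compliances
charge up and flow stops).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .orifice import pressure_drop
from .series import WaveformSeries

__all__ = [
    "RespiratoryMechanics",
    "MuscleProfile",
    "RationalTransferFunction",
    "TFCoefficients",
    "tf_coefficients",
    "build_transfer_function",
    "muscle_profile",
    "simulate_active",
    "intrapulmonary_pressure",
    "actuation_plan",
    "CYLINDER_CALIBRATION",
]


@dataclass(frozen=True)
class RespiratoryMechanics:
    """The seven lumped parameters of the dual-chamber circuit.

    Parameters
    ----------
    Rt : float
        Upper-airway resistance, cmH2O/(L/s).
    Rl, Rr : float
        Left/right small-airway resistance, cmH2O/(L/s).
    Cll, Clr : float
        Left/right lung compliance, mL/cmH2O.
    Ccw : float
        Chest-wall compliance, mL/cmH2O.
    r : float
        Equivalent orifice coefficient of the physical upper-airway element
        (quadratic law dp = (r*Q)^2); the clinical label cmH2O/(L/s) is kept.
    RR : float
        Respiratory rate, breaths/min.

    All parameters must be positive.  Values outside the device's advertised
    operating envelope (Ccw <= 250, single-lung C <= 100, r in 2.01-14.67,
    small-airway R <= 200) trigger a soft warning, not an error.
    """

    Rt: float
    Rl: float
    Rr: float
    Cll: float
    Clr: float
    Ccw: float
    r: float
    RR: float

    def __post_init__(self) -> None:
        for name in ("Rt", "Rl", "Rr", "Cll", "Clr", "Ccw", "r", "RR"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for msg in self.envelope_warnings():
            warnings.warn(msg, UserWarning, stacklevel=2)

    def envelope_warnings(self) -> list[str]:
        """Soft checks against the device's advertised operating envelope."""
        out = []
        if self.Ccw > 250:
            out.append(f"Ccw={self.Ccw} above the 250 mL/cmH2O device envelope")
        for name in ("Cll", "Clr"):
            if getattr(self, name) > 100:
                out.append(f"{name}={getattr(self, name)} above the 100 mL/cmH2O envelope")
        if not (2.01 <= self.r <= 14.67):
            out.append(f"r={self.r} outside the 2.01-14.67 adjustable range")
        for name in ("Rl", "Rr"):
            if getattr(self, name) > 200:
                out.append(f"{name}={getattr(self, name)} above the 200 cmH2O/(L/s) envelope")
        return out


@dataclass(frozen=True)
class MuscleProfile:
    """Respiratory muscle effort profile: gradual rise, rapid decay.

    One breath of period ``60/RR`` s consists of a concave quadratic rise to
    ``Pmus_max`` over ``rise_fraction`` of the period, an exponential decay
    back to zero over ``decay_fraction`` of the period (time constant one
    third of the decay window, offset-corrected so the profile reaches
    exactly zero), and a quiescent rest phase.  The rise must last strictly
    longer than the decay — this asymmetry is what makes the expiratory flow
    peak exceed the inspiratory one.
    """

    Pmus_max: float
    RR: float
    rise_fraction: float = 0.35
    decay_fraction: float = 0.15
    shape: str = "quadratic-exponential"

    def __post_init__(self) -> None:
        if self.Pmus_max < 0:
            raise ValueError(f"Pmus_max must be >= 0, got {self.Pmus_max}")
        if not self.RR > 0:
            raise ValueError(f"RR must be > 0, got {self.RR}")
        if not self.rise_fraction > 0:
            raise ValueError("rise_fraction must be > 0")
        if not self.decay_fraction > 0:
            raise ValueError("decay_fraction must be > 0")
        if self.rise_fraction + self.decay_fraction > 1.0 + 1e-12:
            raise ValueError("rise_fraction + decay_fraction must be <= 1")
        if not self.rise_fraction > self.decay_fraction:
            raise ValueError(
                "rise duration must exceed decay duration "
                f"(rise_fraction={self.rise_fraction}, decay_fraction={self.decay_fraction})"
            )

    @property
    def period(self) -> float:
        return 60.0 / self.RR


class TFCoefficients(NamedTuple):
    """Auxiliary products of the circuit admittance (L/cmH2O/s units)."""

    f1: float
    f2: float
    f3: float
    f4: float
    g1: float
    g2: float
    g3: float
    g4: float
    g5: float


def tf_coefficients(mech: RespiratoryMechanics) -> TFCoefficients:
    """The nine auxiliary products of the dual-chamber admittance.

    Compliances are converted from mL/cmH2O to L/cmH2O so that every R*C
    product is in seconds.
    """
    Rl, Rr, Rt = mech.Rl, mech.Rr, mech.Rt
    Cll = mech.Cll / 1000.0
    Clr = mech.Clr / 1000.0
    Ccw = mech.Ccw / 1000.0

    f1 = Rl * Rr * Cll * Clr
    f2 = Rl * Cll + Rr * Clr
    f3 = Rl * Cll * Clr + Rr * Cll * Clr
    f4 = Cll + Clr
    g1 = f1 * Ccw + f3 * Ccw * Rt
    g2 = f3 + f2 * Ccw + f4 * Ccw * Rt
    g3 = f4 + Ccw
    g4 = f3 * Ccw
    g5 = f4 * Ccw
    return TFCoefficients(f1, f2, f3, f4, g1, g2, g3, g4, g5)


@dataclass(frozen=True)
class RationalTransferFunction:
    """Rational function of s with a unit-scaling gain factor.

    ``num``/``den`` are coefficient sequences in descending powers of s, the
    denominator normalised to a unit leading coefficient at construction.
    The full response is ``gain_factor * num(s)/den(s)``.
    """

    num: tuple
    den: tuple
    gain_factor: float = 1.0

    def __post_init__(self) -> None:
        num = tuple(float(c) for c in self.num)
        den = tuple(float(c) for c in self.den)
        if len(num) > len(den):
            raise ValueError("transfer function must be proper (deg num <= deg den)")
        if den[0] == 0:
            raise ValueError("denominator leading coefficient must be nonzero")
        lead = den[0]
        object.__setattr__(self, "num", tuple(c / lead for c in num))
        object.__setattr__(self, "den", tuple(c / lead for c in den))

    def __call__(self, s):
        """Evaluate the response at (complex) s."""
        s = np.asarray(s, dtype=complex)
        val = self.gain_factor * np.polyval(self.num, s) / np.polyval(self.den, s)
        return complex(val) if val.ndim == 0 else val

    def freqresp(self, omega):
        """Frequency response at angular frequencies ``omega`` (rad/s)."""
        return self(1j * np.asarray(omega, dtype=float))

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    def is_stable(self) -> bool:
        return bool(np.all(self.poles.real < 0))

    def to_statespace(self):
        """Controllable canonical (A, B, C, D) with the gain folded in."""
        den = np.asarray(self.den)
        num = np.concatenate([np.zeros(len(den) - len(self.num)), self.num])
        num = self.gain_factor * num
        n = len(den) - 1
        a = den[1:]  # monic denominator tail
        d = num[0]
        c = num[1:] - d * a
        A = np.zeros((n, n))
        A[:-1, 1:] = np.eye(n - 1)
        A[-1, :] = -a[::-1]
        B = np.zeros((n, 1))
        B[-1, 0] = 1.0
        C = c[::-1].reshape(1, n)
        D = np.array([[d]])
        return A, B, C, D


def build_transfer_function(mech: RespiratoryMechanics) -> RationalTransferFunction:
    """Admittance from muscle pressure (cmH2O) to upper-airway flow (L/min).

    ``-60 * (g4 s^2 + g5 s) / (g1 s^2 + g2 s + g3)`` — biproper, stable for
    any positive parameter set, with exactly zero DC gain (the numerator has
    no constant term).
    """
    c = tf_coefficients(mech)
    return RationalTransferFunction(
        num=(c.g4, c.g5, 0.0), den=(c.g1, c.g2, c.g3), gain_factor=-60.0
    )


def muscle_profile(profile: MuscleProfile, t):
    """Muscle-effort magnitude (cmH2O) at time(s) ``t`` (s).

    Periodic with period ``60/RR``; peaks at exactly ``Pmus_max`` at the end
    of the rise; continuous everywhere; identically zero in the rest phase.
    Returned as a positive magnitude — the simulator applies the
    physiological (sub-atmospheric) sign internally.
    """
    t = np.asarray(t, dtype=float)
    T = profile.period
    tr = profile.rise_fraction * T
    td = profile.decay_fraction * T
    tau = td / 3.0
    phase = np.mod(t, T)

    out = np.zeros_like(phase)
    rising = phase < tr
    x = np.where(rising, phase / tr, 0.0)
    out = np.where(rising, profile.Pmus_max * x * (2.0 - x), out)

    decaying = (phase >= tr) & (phase < tr + td)
    # offset-corrected exponential: exactly Pmus_max at tr and 0 at tr+td
    e_end = np.exp(-td / tau)
    dec = (np.exp(-(phase - tr) / tau) - e_end) / (1.0 - e_end)
    out = np.where(decaying, profile.Pmus_max * dec, out)
    return float(out) if out.ndim == 0 else out


def intrapulmonary_pressure(Q, r):
    """Target intrapulmonary pressure (cmH2O) for upper-airway flow ``Q`` (L/s).

    Magnitude ``(r*Q)**2`` with sign ``-sign(Q)``: suction (negative gauge
    pressure) during inspiration, positive pressure during expiration.
    """
    return -pressure_drop(Q, r)


def _rk4_update_operators(A, B, dt):
    """Constant matrices of one classical RK4 step of an LTI system.

    x+ = M x + m1*u(t) + m2*u(t+dt/2) + m3*u(t+dt), obtained by pushing unit
    basis vectors / unit inputs through the textbook RK4 stage algebra.
    """
    n = A.shape[0]
    I = np.eye(n)

    def step(x, u0, um, u1):
        k1 = A @ x + B[:, 0] * u0
        k2 = A @ (x + dt / 2 * k1) + B[:, 0] * um
        k3 = A @ (x + dt / 2 * k2) + B[:, 0] * um
        k4 = A @ (x + dt * k3) + B[:, 0] * u1
        return x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    M = np.column_stack([step(I[:, i], 0.0, 0.0, 0.0) for i in range(n)])
    z = np.zeros(n)
    m1 = step(z, 1.0, 0.0, 0.0)
    m2 = step(z, 0.0, 1.0, 0.0)
    m3 = step(z, 0.0, 0.0, 1.0)
    return M, m1, m2, m3


def simulate_active(
    mech: RespiratoryMechanics,
    profile: MuscleProfile | None = None,
    duration: float | None = None,
    dt: float = 1e-3,
) -> WaveformSeries:
    """Zero-initial-condition response of the lung model to the muscle drive.

    The admittance is realised in controllable canonical state space and
    integrated with a fixed-step classical 4th-order scheme at ``dt`` (the
    1 ms control cycle by default).  Outputs: flow Q in L/min (inspiration
    positive), tidal volume as the cumulative integral of the flow in mL,
    and intrapulmonary pressure from the orifice law with the inspiration-
    negative sign convention.

    Parameters
    ----------
    mech : RespiratoryMechanics
    profile : MuscleProfile, optional
        Defaults to ``MuscleProfile(Pmus_max=10, RR=mech.RR)``.
    duration : float, optional
        Simulation length, s; must cover at least one breath.  Defaults to
        five breaths.
    dt : float
        Fixed step, s; must not exceed the 1 ms control cycle.
    """
    if profile is None:
        profile = MuscleProfile(Pmus_max=10.0, RR=mech.RR)
    if profile.RR != mech.RR:
        profile = replace(profile, RR=mech.RR)
    if dt > 1e-3 + 1e-12:
        raise ValueError(f"dt must be <= 1 ms (the control cycle), got {dt}")
    T = profile.period
    if duration is None:
        duration = 5.0 * T
    if duration < T - 1e-9:
        raise ValueError("duration must cover at least one breath period")

    tf = build_transfer_function(mech)
    if not tf.is_stable():
        raise ValueError(
            f"unstable denominator (poles {tf.poles}): simulation refused"
        )
    A, B, C, D = tf.to_statespace()

    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    # physiological sign: effort magnitude acts as sub-atmospheric pressure
    u = -muscle_profile(profile, t)
    u_mid = -muscle_profile(profile, t[:-1] + dt / 2)

    M, m1, m2, m3 = _rk4_update_operators(A, B, dt)
    x = np.zeros(A.shape[0])
    states = np.empty((n, A.shape[0]))
    states[0] = x
    for k in range(n - 1):
        x = M @ x + m1 * u[k] + m2 * u_mid[k] + m3 * u[k + 1]
        states[k + 1] = x

    Q = states @ C[0] + D[0, 0] * u  # L/min
    Q_ls = Q / 60.0
    vt = np.concatenate([[0.0], np.cumsum((Q_ls[1:] + Q_ls[:-1]) / 2.0) * dt * 1e3])
    pl = intrapulmonary_pressure(Q_ls, mech.r)
    return WaveformSeries(t=t, Q=Q, Pl=pl, Vt=vt, Pmus=-u)


#: Cylinder position calibration polynomial x(Vt): position in cm as a cubic
#: in tidal volume in litres (bench calibration of the electric cylinder).
CYLINDER_CALIBRATION = np.array([-2.9205, 4.6297, 5.6886, 0.423])

#: Fitted range of the cylinder calibration, litres.  The bench fit range is
#: undocumented; volumes outside this span extrapolate the cubic.
CALIBRATION_VT_RANGE = (0.0, 1.0)


def cylinder_position(vt_L):
    """Cylinder position x (cm) for tidal volume ``vt_L`` (litres)."""
    return np.polyval(CYLINDER_CALIBRATION, np.asarray(vt_L, dtype=float))


def position_volume_ratio(vt_L):
    """The open-loop gain k = x/Vt (cm/L), guarded at Vt = 0.

    The ratio has a removable singularity at the origin; at exactly zero
    volume the linear coefficient of the calibration cubic is used as the
    limit slope.  Note the home-position offset (the cubic's constant term)
    makes this secant gain diverge like 0.423/Vt for *small but nonzero*
    volumes; :func:`calibration_slope` is the kinematically consistent
    local gain.
    """
    vt = np.asarray(vt_L, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(vt != 0.0, cylinder_position(vt) / np.where(vt != 0.0, vt, 1.0),
                     CYLINDER_CALIBRATION[2])
    return float(k) if k.ndim == 0 else k


def calibration_slope(vt_L):
    """Local calibration gain dx/dVt (cm/L) of the cylinder cubic.

    This is the exact kinematic relation between cylinder speed and flow,
    ``v = dx/dVt * Q/60``; it stays within [5.69, 8.13] cm/L over the
    fitted volume range (no singularity at zero volume).
    """
    vt = np.asarray(vt_L, dtype=float)
    slope = np.polyval(np.polyder(CYLINDER_CALIBRATION), vt)
    return float(slope) if slope.ndim == 0 else slope


def actuation_plan(series: WaveformSeries, gain: str = "secant",
                   warn_extrapolation: bool = True):
    """Open-loop cylinder position and speed traces realising a target flow.

    Position ``x = x(Vt)`` from the calibration cubic (Vt in litres, x in
    cm) and speed ``v = k * Q / 60`` (cm/s; Q in L/min) with ``k`` either
    the published secant gain ``x/Vt`` (``gain="secant"``, the default,
    guarded at Vt = 0 by the derivative limit) or the exact kinematic slope
    ``dx/dVt`` (``gain="slope"``) used by the actuator emulation.

    Returns ``(x, v)`` arrays aligned with ``series.t``.  Volumes outside
    the configured calibration range produce a single extrapolation warning.
    """
    if gain not in ("secant", "slope"):
        raise ValueError("gain must be 'secant' or 'slope'")
    vt_L = series.Vt / 1000.0
    lo, hi = CALIBRATION_VT_RANGE
    if warn_extrapolation and (np.any(vt_L < lo - 1e-9) or np.any(vt_L > hi + 1e-9)):
        warnings.warn(
            "tidal volume outside the cylinder calibration range "
            f"[{lo}, {hi}] L: positions are extrapolated", UserWarning,
        )
    x = cylinder_position(vt_L)
    k = position_volume_ratio(vt_L) if gain == "secant" else calibration_slope(vt_L)
    v = k * series.Q / 60.0
    return np.asarray(x, dtype=float), np.asarray(v, dtype=float)
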