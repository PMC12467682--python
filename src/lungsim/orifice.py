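"""Equivalent thin-walled-orifice airway resistance.

The simulator's adjustable airway-resistance element is a thin-walled
orifice.  At the flows used in ventilation the orifice jet is turbulent, so
the pressure drop across the element scales with the *square* of the flow,

    dp = (r * Q)**2        [dp in cmH2O, Q in L/s]

and the element is characterised by a single setting-specific coefficient
``r``.  Under this quadratic law the natural dimensions of ``r`` are
sqrt(cmH2O)*s/L; the conventional clinical label cmH2O/(L/s) is kept in
reports for comparability with commercial test lungs.

Note: the clinical *linear* definition R = dp/Q does not reproduce the
bench calibration of the reference device (the extracted linear "R" would
grow with flow); the quadratic law is the operative definition here and is
consistent with every calibration pair shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrificeCalibrationPoint",
    "OrificeModel",
    "OrificeFit",
    "LowFlowError",
    "DEFAULT_LOW_FLOW_FLOOR",
    "equivalent_coefficient",
    "pressure_drop",
    "radius_to_resistance",
    "resistance_to_radius",
    "fit_coefficient",
]

#: Flows below this floor (L/s) make coefficient extraction numerically
#: indeterminate: the measured dp/Q**2 ratio is dominated by sensor noise and
#: by the laminar/turbulent transition, so extraction is refused.
DEFAULT_LOW_FLOW_FLOOR = 0.05


class LowFlowError(ValueError):
    """Coefficient extraction refused: flow below the low-flow floor."""


@dataclass(frozen=True)
class OrificeCalibrationPoint:
    """One bench calibration measurement of the resistance element.

    Parameters
    ----------
    Q : float
        Flow through the element, L/s.  Must be positive.
    dp : float
        Pressure difference across the element, cmH2O.  Must be >= 0.
    """

    Q: float
    dp: float

    def __post_init__(self) -> None:
        if not self.Q > 0:
            raise ValueError(f"calibration flow Q must be > 0, got {self.Q}")
        if self.dp < 0:
            raise ValueError(f"pressure drop dp must be >= 0, got {self.dp}")


@dataclass(frozen=True)
class OrificeModel:
    """An orifice resistance element with coefficient ``r``.

    ``radius_mm`` optionally records the throttle opening radius the
    coefficient corresponds to (see :func:`radius_to_resistance`).
    """

    r: float
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.r >= 0:
            raise ValueError(f"orifice coefficient r must be >= 0, got {self.r}")
        if self.radius_mm is not None and not self.radius_mm > 0:
            raise ValueError(f"radius_mm must be > 0, got {self.radius_mm}")


def equivalent_coefficient(
    point: OrificeCalibrationPoint,
    low_flow_floor: float = DEFAULT_LOW_FLOW_FLOOR,
) -> float:
    """Extract the orifice coefficient from one (Q, dp) calibration pair.

    ``r = sqrt(dp) / Q`` — the unique value consistent with the quadratic
    orifice law ``dp = (r Q)**2``.

    Raises
    ------
    LowFlowError
        If ``Q`` is below ``low_flow_floor`` (resistance estimates blow up
        near zero flow).
    """
    if point.Q < low_flow_floor:
        raise LowFlowError(
            f"flow {point.Q} L/s below low-flow floor {low_flow_floor} L/s: "
            "coefficient extraction is indeterminate at low flow"
        )
    return float(np.sqrt(point.dp) / point.Q)


def pressure_drop(Q, model: OrificeModel | float):
    """Signed pressure drop across the orifice, ``sign(Q)*(r*Q)**2`` cmH2O.

    Odd in ``Q``: flow reversal reverses the drop.  ``Q`` may be a scalar or
    an array (L/s); ``model`` may be an :class:`OrificeModel` or a bare
    coefficient.
    """
    r = model.r if isinstance(model, OrificeModel) else float(model)
    Q = np.asarray(Q, dtype=float)
    dp = np.sign(Q) * (r * Q) ** 2
    return float(dp) if dp.ndim == 0 else dp


def radius_to_resistance(radius_mm: float) -> float:
    """Resistance implied by a throttle opening radius (mm).

    Power-law calibration of the resistance element at a constant bench flow
    of 30 L/min: ``R = 10.82 * radius_mm**-1.01`` cmH2O/(L/s).  Strictly
    decreasing in the radius.
    """
    if not radius_mm > 0:
        raise ValueError(f"radius_mm must be > 0, got {radius_mm}")
    return float(10.82 * radius_mm ** -1.01)


def resistance_to_radius(R: float) -> float:
    """Inverse of :func:`radius_to_resistance`: opening radius (mm) for ``R``."""
    if not R > 0:
        raise ValueError(f"resistance must be > 0, got {R}")
    return float((10.82 / R) ** (1.0 / 1.01))


@dataclass(frozen=True)
class OrificeFit:
    """Least-squares orifice coefficient over several calibration points."""

    r: float
    residuals: tuple = field(default_factory=tuple)  # per-point relative residuals
    max_relative_residual: float = 0.0
    flagged: bool = False  # True when the fit violates flow-independence

    def as_model(self) -> OrificeModel:
        return OrificeModel(r=self.r)


def fit_coefficient(
    points,
    low_flow_floor: float = DEFAULT_LOW_FLOW_FLOOR,
    flag_threshold: float = 0.10,
) -> OrificeFit:
    """Least-squares ``r`` over ``sqrt(dp) = r * Q`` for several points.

    The coefficient of a given throttle setting is flow-independent, so the
    per-point relative residuals should be small; the fit is ``flagged``
    when the worst residual exceeds ``flag_threshold`` (default 10%).

    Requires at least two points at or above the low-flow floor.
    """
    pts = [p for p in points if p.Q >= low_flow_floor]
    if len(pts) < 2:
        raise ValueError(
            f"need >= 2 calibration points above the low-flow floor "
            f"({low_flow_floor} L/s), got {len(pts)}"
        )
    Q = np.array([p.Q for p in pts])
    y = np.sqrt([p.dp for p in pts])
    r = float(Q @ y / (Q @ Q))
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(r > 0, (y / Q - r) / r, 0.0)
    max_resid = float(np.max(np.abs(resid)))
    return OrificeFit(
        r=r,
        residuals=tuple(float(x) for x in resid),
        max_relative_residual=max_resid,
        flagged=max_resid > flag_threshold,
    )
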