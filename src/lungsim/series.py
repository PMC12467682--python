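"""Uniformly sampled waveform record shared by all simulation modes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WaveformSeries", "WAVEFORM_CSV_COLUMNS"]

WAVEFORM_CSV_COLUMNS = ["time_s", "pmus_cmH2O", "flow_L_min", "pl_cmH2O", "vt_mL"]


@dataclass
class WaveformSeries:
    """Time/flow/pressure/volume traces on a uniform grid.

    Attributes
    ----------
    t : ndarray
        Time, s, uniform grid starting at 0.
    Q : ndarray
        Upper-airway flow, L/min, signed (inspiration positive).
    Pl : ndarray
        Intrapulmonary pressure, cmH2O gauge (negative during inspiration).
    Vt : ndarray
        Tidal volume, mL, cumulative integral of the flow; ``Vt[0] == 0``.
    Pmus : ndarray
        Driving (respiratory muscle) pressure magnitude, cmH2O.
    """

    t: np.ndarray
    Q: np.ndarray
    Pl: np.ndarray
    Vt: np.ndarray
    Pmus: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.t, self.Q, self.Pl, self.Vt, self.Pmus)]
        self.t, self.Q, self.Pl, self.Vt, self.Pmus = arrays
        n = self.t.size
        if any(a.size != n for a in arrays):
            raise ValueError("all waveform channels must have the same length")
        if n >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must be uniform")
        if n and abs(self.Vt[0]) > 1e-9:
            raise ValueError("Vt must start at 0")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else float("nan")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def after(self, t0: float) -> "WaveformSeries":
        """Sub-series with ``t >= t0`` (time re-zeroed, Vt offset kept)."""
        m = self.t >= t0 - 1e-12
        vt = self.Vt[m]
        return WaveformSeries(
            t=self.t[m] - self.t[m][0],
            Q=self.Q[m],
            Pl=self.Pl[m],
            Vt=vt - vt[0],
            Pmus=self.Pmus[m],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "pmus_cmH2O": self.Pmus,
                "flow_L_min": self.Q,
                "pl_cmH2O": self.Pl,
                "vt_mL": self.Vt,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WaveformSeries":
        df = pd.read_csv(path)
        missing = [c for c in WAVEFORM_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"waveform CSV missing columns: {missing}")
        return cls(
            t=df["time_s"].to_numpy(),
            Q=df["flow_L_min"].to_numpy(),
            Pl=df["pl_cmH2O"].to_numpy(),
            Vt=df["vt_mL"].to_numpy() - df["vt_mL"].iloc[0],
            Pmus=df["pmus_cmH2O"].to_numpy(),
        )
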