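"""Independent oracles for the respiratory-circuit admittance.

These evaluate the two-compartment circuit by direct complex impedance
arithmetic — element by element, with no reference to the f/g coefficient
algebra used by the package — so they serve as an independent cross-check
of the transfer-function construction.
"""

import numpy as np


def circuit_admittance(mech, s):
    """Phasor admittance Q(s)/Pmus(s) of the dual-chamber circuit, in L/s
    per cmH2O (no L/min scaling, no sign convention).

    Impedance path: upper airway Rt in series with the chest-wall
    compliance and the parallel pair of (small-airway R + lung C) branches.
    Compliances are converted from mL/cmH2O to L/cmH2O.
    """
    s = np.asarray(s, dtype=complex)
    Cll = mech.Cll / 1000.0
    Clr = mech.Clr / 1000.0
    Ccw = mech.Ccw / 1000.0
    Zl = mech.Rl + 1.0 / (s * Cll)
    Zr = mech.Rr + 1.0 / (s * Clr)
    Z = mech.Rt + 1.0 / (s * Ccw) + (Zl * Zr) / (Zl + Zr)
    return 1.0 / Z


def single_compartment_admittance(Rt, R, C_single, Ccw, s):
    """Reduction for symmetric lungs: series Rt + R/2, lumped 2*C, chest Ccw.

    ``C_single`` and ``Ccw`` in mL/cmH2O.
    """
    s = np.asarray(s, dtype=complex)
    C2 = 2.0 * C_single / 1000.0
    Ccw_L = Ccw / 1000.0
    Z = Rt + R / 2.0 + 1.0 / (s * C2) + 1.0 / (s * Ccw_L)
    return 1.0 / Z
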