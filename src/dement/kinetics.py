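"""Temperature-dependent Michaelis-Menten kinetics.

Enzymatic decay and cellular uptake both follow Michaelis-Menten
saturation, with Vmax and Km scaled by Arrhenius factors relative to a
reference temperature.  Decay of cellulose is additionally penalized by
the lignocellulose index of the local litter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_GAS = 8.314  # ideal gas constant, J mol^-1 K^-1
ZERO_CELSIUS = 273.0  # Kelvin offset used throughout


def arrhenius_factor(t, t_ref, ea):
    """Arrhenius temperature multiplier relative to ``t_ref``.

    Parameters
    ----------
    t, t_ref : float or array
        Temperatures in degrees Celsius (> -273).
    ea : float or array
        Activation energy in kJ mol^-1.

    Returns
    -------
    exp[(-Ea/R) * (1/(T+273) - 1/(T_ref+273))], dimensionless; equals 1 at
    ``t == t_ref`` and is strictly increasing in ``t`` for ``ea > 0``.
    """
    t = np.asarray(t, dtype=float)
    t_ref = np.asarray(t_ref, dtype=float)
    ea = np.asarray(ea, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(t_ref))
            and np.all(np.isfinite(ea))):
        raise ValueError("non-finite input to arrhenius_factor")
    if np.any(t <= -ZERO_CELSIUS) or np.any(t_ref <= -ZERO_CELSIUS):
        raise ValueError("temperature at or below absolute zero")
    out = np.exp(-(ea * 1e3 / R_GAS)
                 * (1.0 / (t + ZERO_CELSIUS) - 1.0 / (t_ref + ZERO_CELSIUS)))
    return float(out) if out.ndim == 0 else out


def mm_flux(v, s, km):
    """Michaelis-Menten flux V*S/(Km+S), elementwise.

    Returns 0 where ``Km + S == 0`` (the zero-substrate limit).
    """
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    km = np.asarray(km, dtype=float)
    if np.any(s < 0) or np.any(km < 0):
        raise ValueError("substrate and Km must be non-negative")
    denom = km + s
    out = np.divide(v * s, denom, out=np.zeros(np.broadcast_shapes(
        v.shape, s.shape, km.shape)), where=denom > 0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class KineticParams:
    """Michaelis-Menten parameters at the reference temperature."""

    vmax: float        # capacity at t_ref (units depend on the process)
    km: float          # half-saturation constant at t_ref (mg cm^-3)
    ea_vmax: float     # activation energy for Vmax (kJ mol^-1)
    ea_km: float       # activation energy for Km (kJ mol^-1)
    t_ref: float = 20.0

    def __post_init__(self) -> None:
        if self.vmax < 0 or self.km < 0:
            raise ValueError("Vmax and Km must be non-negative")


def temperature_adjust(p: KineticParams, t: float) -> tuple[float, float]:
    """(Vmax, Km) at temperature ``t``, each scaled by its own Arrhenius
    factor.  At ``t == p.t_ref`` the inputs are returned unchanged."""
    return (p.vmax * arrhenius_factor(t, p.t_ref, p.ea_vmax),
            p.km * arrhenius_factor(t, p.t_ref, p.ea_km))


def lignocellulose_index(lignin_c, cellulose_c):
    """LCI = lignin C / (lignin C + cellulose C); 0 when both pools are
    empty."""
    lignin_c = np.asarray(lignin_c, dtype=float)
    cellulose_c = np.asarray(cellulose_c, dtype=float)
    if np.any(lignin_c < 0) or np.any(cellulose_c < 0):
        raise ValueError("pools must be non-negative")
    tot = lignin_c + cellulose_c
    out = np.divide(lignin_c, tot,
                    out=np.zeros(np.broadcast_shapes(lignin_c.shape,
                                                     cellulose_c.shape)),
                    where=tot > 0)
    return float(out) if out.ndim == 0 else out


def lignocellulose_multiplier(lignin_c, cellulose_c, lci_slope=-0.8):
    """Multiplier in [0, 1] applied to cellulose decay: 1 + slope * LCI,
    clipped to [0, 1].  Equals 1 when no lignin is present."""
    lci = lignocellulose_index(lignin_c, cellulose_c)
    out = np.clip(1.0 + lci_slope * np.asarray(lci), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
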