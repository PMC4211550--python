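"""Closed-form rate-yield model of growth-maximizing CUE under warming.

A spatially and taxonomically homogeneous community grows at rate
G = U * eps, where uptake U = U_ref * f_A(T) follows Arrhenius temperature
scaling and realized carbon use efficiency eps declines linearly with
temperature.  Intrinsic CUE (the CUE at the reference temperature) trades
off linearly against reference uptake rate:

    eps_int = eps0 + m_U * U_ref          (rate-yield tradeoff, m_U < 0)
    eps     = eps_int + m_T * (T - T_ref)

Maximizing G over U_ref gives a closed-form optimum.  The optimal
intrinsic CUE rises by -m_T/2 per degree of warming — adaptation offsets
exactly half of the temperature-forced CUE decline — and is independent
of the tradeoff slope m_U, while the maximal growth rate itself declines
as the tradeoff steepens.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import arrhenius_factor

__all__ = [
    "AnalyticalParams", "arrhenius_factor", "growth_rate", "optimal_uref",
    "optimal_eps_int", "adaptation_delta", "temperature_sweep",
    "growth_curve",
]


@dataclass(frozen=True)
class AnalyticalParams:
    """Parameters of the analytical rate-yield model.

    eps0 : CUE intercept at zero uptake investment (mg mg^-1), in (0, 1].
    m_t : CUE temperature slope (mg mg^-1 per deg C).
    m_u : CUE-uptake tradeoff slope (mg mg^-1 per unit reference uptake);
        must be negative for an interior growth optimum to exist.
    ea : activation energy for uptake (kJ mol^-1).
    t_ref : reference temperature (deg C).
    """

    eps0: float = 0.5
    m_t: float = -0.016
    m_u: float = -0.4
    ea: float = 35.0
    t_ref: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.eps0 <= 1.0:
            raise ValueError("eps0 must lie in (0, 1]")
        if not np.isfinite(self.m_u) or self.m_u > 0:
            raise ValueError("m_u must be finite and non-positive")


def growth_rate(u_ref, t, p: AnalyticalParams):
    """Growth rate G = U * eps at temperature ``t`` for reference uptake
    ``u_ref``.

    G = U_ref * f_A(T) * (eps0 + m_U*U_ref + m_T*(T - T_ref)); may be
    negative if the realized CUE is negative.  Concave (quadratic with
    negative leading coefficient) in ``u_ref`` when ``m_u < 0``.
    """
    u_ref = np.asarray(u_ref, dtype=float)
    if np.any(u_ref < 0):
        raise ValueError("u_ref must be non-negative")
    eps = p.eps0 + p.m_u * u_ref + p.m_t * (np.asarray(t, float) - p.t_ref)
    out = u_ref * arrhenius_factor(t, p.t_ref, p.ea) * eps
    return float(out) if out.ndim == 0 else out


def optimal_uref(t, p: AnalyticalParams):
    """Reference uptake rate maximizing ``growth_rate`` at temperature
    ``t``: U_ref* = -(eps0 + m_T*(T - T_ref)) / (2 m_U).

    Linear (and decreasing, for m_T < 0) in temperature.  Raises for
    ``m_u == 0``: with no tradeoff, growth is maximized at unbounded
    uptake investment.
    """
    if p.m_u == 0:
        raise ValueError("m_u = 0: no tradeoff, optimum is unbounded")
    out = -(p.eps0 + p.m_t * (np.asarray(t, float) - p.t_ref)) / (2.0 * p.m_u)
    return float(out) if out.ndim == 0 else out


def optimal_eps_int(t, p: AnalyticalParams):
    """Intrinsic CUE at the growth optimum:
    eps_int* = (eps0 - m_T*(T - T_ref)) / 2.

    Equals eps0 + m_U * optimal_uref(t) and is independent of m_U — the
    magnitude of CUE adaptation does not depend on how steep the tradeoff
    is.
    """
    if p.m_u == 0:
        raise ValueError("m_u = 0: no tradeoff, optimum is unbounded")
    out = (p.eps0 - p.m_t * (np.asarray(t, float) - p.t_ref)) / 2.0
    return float(out) if out.ndim == 0 else out


def adaptation_delta(t_warm: float, t_cool: float, p: AnalyticalParams) -> float:
    """Warming-driven change in optimal intrinsic CUE,
    optimal_eps_int(t_warm) - optimal_eps_int(t_cool) = -m_T*(dT)/2.

    Adaptation offsets exactly half of the temperature-forced CUE change
    m_T * dT.
    """
    return optimal_eps_int(t_warm, p) - optimal_eps_int(t_cool, p)


def temperature_sweep(p: AnalyticalParams, t_min: float = 10.0,
                      t_max: float = 30.0, step: float = 1.0) -> pd.DataFrame:
    """Optimal uptake, intrinsic CUE and maximal growth over a temperature
    range; one row per temperature."""
    temps = np.arange(t_min, t_max + 0.5 * step, step)
    uref = optimal_uref(temps, p)
    eps = optimal_eps_int(temps, p)
    growth = growth_rate(uref, temps, p)
    return pd.DataFrame({
        "temperature": temps,
        "optimal_uref": uref,
        "optimal_eps_int": eps,
        "max_growth": growth,
    })


def growth_curve(t: float, p: AnalyticalParams,
                 u_max: float = 5.0, n: int = 501) -> pd.DataFrame:
    """Growth rate as a function of intrinsic CUE at temperature ``t``
    (for plotting growth-vs-CUE curves): sweeps U_ref on [0, u_max] and
    reports the implied intrinsic CUE eps0 + m_U*U_ref alongside G."""
    uref = np.linspace(0.0, u_max, n)
    return pd.DataFrame({
        "u_ref": uref,
        "eps_int": p.eps0 + p.m_u * uref,
        "growth": growth_rate(uref, t, p),
    })
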