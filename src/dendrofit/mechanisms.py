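"""Ionic channel kinetics and intracellular Ca2+ dynamics.

Ten Hodgkin-Huxley style conductances known to shape layer-5b pyramidal
cell excitability are defined here: transient and persistent Na+ (Na_t,
Na_p), the hyperpolarization-activated cation current I_h, the muscarinic
K+ current I_m, slow- and fast-inactivating K+ currents (K_p, K_t), the
fast delayed rectifier Kv3.1, high- and low-voltage-activated Ca2+
currents (Ca_HVA, Ca_LVA), and the Ca2+-activated K+ current SK.  Each
current follows

    I = gbar * m^x * h^y * (V - E)

with gbar a maximal conductance density (pS/um^2), m/h activation and
inactivation gates, and E the reversal potential.

Kinetics are transcribed in their literature form.  Two corrections are
applied on top, never by mutating the coefficients:

* channels characterized at room temperature (21 C) have their time
  constants divided by q10^((T_sim - 21)/10) with q10 = 2.3 and a
  simulation temperature of 34 C;
* channels recorded without liquid-junction-potential correction carry a
  -10 mV shift (their literature curves are evaluated at V + 10 mV).

The submembrane Ca2+ pool obeys a first-order extrusion/buffering model:

    d[Ca]/dt = -gamma * I_Ca / (2 * F * depth) - ([Ca] - Ca_inf) / tau_decay

where gamma is the inverse of the Ca2+ buffer binding ratio, depth the
shell thickness (0.1 um) and tau_decay the effective clearance time
constant; Ca_inf = 1e-4 mM is the resting free concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from numba import njit

__all__ = [
    "ChannelKinetics",
    "CaDynamicsParams",
    "ReversalSet",
    "CHANNELS",
    "CHANNEL_NAMES",
    "steady_state",
    "time_constant",
    "channel_current",
    "ca_update",
    "ca_steady_state",
    "q10_factor",
    "nernst_eca",
    "FARADAY",
    "T_SIM_DEFAULT",
]

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.3145  # J/(mol K)
T_SIM_DEFAULT = 34.0  # degrees C
Q10_DEFAULT = 2.3

_NO_INACT_TAU = 1.0e9  # sentinel tau for absent inactivation gates


# --------------------------------------------------------------------------
# numerically safe building block
# --------------------------------------------------------------------------

@njit(cache=True)
def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the analytic limit y + x/2 near x = 0."""
    u = x / y
    if abs(u) < 1e-6:
        return y * (1.0 + 0.5 * u)
    return x / (1.0 - math.exp(-u))


# --------------------------------------------------------------------------
# per-channel rate functions (literature form; tau before temperature
# correction).  Every function maps V (mV) -> (m_inf, m_tau, h_inf, h_tau);
# channels without an inactivation gate return (1, large) for h.
# --------------------------------------------------------------------------

@njit(cache=True)
def rates_na_t(v):
    ma = 0.182 * _vtrap(v + 38.0, 6.0)
    mb = 0.124 * _vtrap(-(v + 38.0), 6.0)
    ha = 0.015 * _vtrap(-(v + 66.0), 6.0)
    hb = 0.015 * _vtrap(v + 66.0, 6.0)
    return ma / (ma + mb), 1.0 / (ma + mb), ha / (ha + hb), 1.0 / (ha + hb)


@njit(cache=True)
def rates_na_p(v):
    minf = 1.0 / (1.0 + math.exp(-(v + 52.6) / 4.6))
    ma = 0.182 * _vtrap(v + 38.0, 6.0)
    mb = 0.124 * _vtrap(-(v + 38.0), 6.0)
    mtau = 6.0 / (ma + mb)
    hinf = 1.0 / (1.0 + math.exp((v + 48.8) / 10.0))
    ha = 2.88e-6 * _vtrap(-(v + 17.0), 4.63)
    hb = 6.94e-6 * _vtrap(v + 64.4, 2.63)
    return minf, mtau, hinf, 1.0 / (ha + hb)


@njit(cache=True)
def rates_ih(v):
    ma = 0.00643 * _vtrap(-(v + 154.9), 11.9)
    mb = 0.193 * math.exp(v / 33.1)
    return ma / (ma + mb), 1.0 / (ma + mb), 1.0, _NO_INACT_TAU


@njit(cache=True)
def rates_im(v):
    ma = 3.3e-3 * math.exp(0.1 * (v + 35.0))
    mb = 3.3e-3 * math.exp(-0.1 * (v + 35.0))
    return ma / (ma + mb), 1.0 / (ma + mb), 1.0, _NO_INACT_TAU


@njit(cache=True)
def rates_k_p(v):
    minf = 1.0 / (1.0 + math.exp(-(v + 1.0) / 12.0))
    if v < -50.0:
        mtau = 1.25 + 175.03 * math.exp(0.026 * v)
    else:
        mtau = 1.25 + 13.0 * math.exp(-0.026 * v)
    hinf = 1.0 / (1.0 + math.exp((v + 54.0) / 11.0))
    htau = 360.0 + (1010.0 + 24.0 * (v + 55.0)) * math.exp(-(((v + 75.0) / 48.0) ** 2))
    return minf, mtau, hinf, htau


@njit(cache=True)
def rates_k_t(v):
    minf = 1.0 / (1.0 + math.exp(-v / 19.0))
    mtau = 0.34 + 0.92 * math.exp(-(((v + 71.0) / 59.0) ** 2))
    hinf = 1.0 / (1.0 + math.exp((v + 66.0) / 10.0))
    htau = 8.0 + 49.0 * math.exp(-(((v + 73.0) / 23.0) ** 2))
    return minf, mtau, hinf, htau


@njit(cache=True)
def rates_kv31(v):
    minf = 1.0 / (1.0 + math.exp(-(v - 18.7) / 9.7))
    mtau = 4.0 / (1.0 + math.exp((v + 46.56) / 44.14))
    return minf, mtau, 1.0, _NO_INACT_TAU


@njit(cache=True)
def rates_ca_hva(v):
    ma = 0.055 * _vtrap(v + 27.0, 3.8)
    mb = 0.94 * math.exp((-75.0 - v) / 17.0)
    ha = 0.000457 * math.exp((-13.0 - v) / 50.0)
    hb = 0.0065 / (math.exp((-v - 15.0) / 28.0) + 1.0)
    return ma / (ma + mb), 1.0 / (ma + mb), ha / (ha + hb), 1.0 / (ha + hb)


@njit(cache=True)
def rates_ca_lva(v):
    minf = 1.0 / (1.0 + math.exp(-(v + 30.0) / 6.0))
    mtau = 5.0 + 20.0 / (1.0 + math.exp((v + 25.0) / 5.0))
    hinf = 1.0 / (1.0 + math.exp((v + 80.0) / 6.4))
    htau = 20.0 + 50.0 / (1.0 + math.exp((v + 40.0) / 7.0))
    return minf, mtau, hinf, htau


@njit(cache=True)
def rates_sk(ca):
    # activation depends on submembrane [Ca2+] (mM), not on voltage
    if ca < 1e-7:
        ca = ca + 1e-7
    zinf = 1.0 / (1.0 + (0.00043 / ca) ** 4.8)
    return zinf, 1.0, 1.0, _NO_INACT_TAU


# --------------------------------------------------------------------------
# declarative channel table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReversalSet:
    """Fixed reversal potentials (mV), shared across an optimization run."""

    e_na: float = 50.0
    e_k: float = -85.0
    e_h: float = -45.0
    e_leak: float = -90.0
    e_ca: float = 132.0  # used when e_ca_mode == "fixed"
    e_ca_mode: str = "fixed"  # "fixed" | "nernst"
    ca_out: float = 2.0  # mM, for the Nernst option


def nernst_eca(ca_in_mM: float, ca_out_mM: float = 2.0, t_celsius: float = T_SIM_DEFAULT) -> float:
    """Ca2+ Nernst potential (mV) for a divalent ion."""
    rt_zf = 1e3 * GAS_CONSTANT * (273.15 + t_celsius) / (2.0 * FARADAY)
    return rt_zf * math.log(ca_out_mM / ca_in_mM)


@dataclass(frozen=True)
class ChannelKinetics:
    """One voltage- (or Ca2+-) gated conductance in HH form."""

    name: str
    ion: str  # "na" | "k" | "ca" | "nonspecific"
    x_exp: int  # activation-gate exponent
    y_exp: int  # inactivation-gate exponent (0 = no inactivation)
    rates: Callable  # literature-form rate function
    q10: float = 1.0
    t_exp: float = T_SIM_DEFAULT  # characterization temperature (C)
    shift_mV: float = 0.0  # junction-potential shift applied to the curves
    ca_gated: bool = False
    half_activation: float | None = None  # printed V1/2 of a sigmoid m_inf, literature frame
    tau_fixed: float | None = None  # fixed activation tau (ms), e.g. SK

    def reversal(self, rev: ReversalSet, ca_in: float | None = None) -> float:
        if self.ion == "na":
            return rev.e_na
        if self.ion == "k":
            return rev.e_k
        if self.ion == "ca":
            if rev.e_ca_mode == "nernst" and ca_in is not None:
                return nernst_eca(ca_in, rev.ca_out)
            return rev.e_ca
        return rev.e_h

    def _literature_v(self, v: float) -> float:
        # a -10 mV shift moves the curves leftward: evaluate at v - shift
        return v - self.shift_mV

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "ion": self.ion,
            "gates": {"activation_exponent": self.x_exp, "inactivation_exponent": self.y_exp},
            "q10": self.q10,
            "t_exp_celsius": self.t_exp,
            "junction_shift_mV": self.shift_mV,
            "ca_gated": self.ca_gated,
            "tau_fixed_ms": self.tau_fixed,
        }


CHANNELS: dict[str, ChannelKinetics] = {
    "Na_t": ChannelKinetics("Na_t", "na", 3, 1, rates_na_t, q10=Q10_DEFAULT, t_exp=21.0),
    "Na_p": ChannelKinetics("Na_p", "na", 3, 1, rates_na_p, q10=Q10_DEFAULT, t_exp=21.0,
                            half_activation=-52.6),
    "I_h": ChannelKinetics("I_h", "nonspecific", 1, 0, rates_ih),
    "I_m": ChannelKinetics("I_m", "k", 1, 0, rates_im, q10=Q10_DEFAULT, t_exp=21.0,
                           half_activation=-35.0),
    "K_p": ChannelKinetics("K_p", "k", 2, 1, rates_k_p, q10=Q10_DEFAULT, t_exp=21.0,
                           shift_mV=-10.0, half_activation=-1.0),
    "K_t": ChannelKinetics("K_t", "k", 4, 1, rates_k_t, q10=Q10_DEFAULT, t_exp=21.0,
                           shift_mV=-10.0, half_activation=0.0),
    "Kv3.1": ChannelKinetics("Kv3.1", "k", 1, 0, rates_kv31, half_activation=18.7),
    "Ca_HVA": ChannelKinetics("Ca_HVA", "ca", 2, 1, rates_ca_hva),
    "Ca_LVA": ChannelKinetics("Ca_LVA", "ca", 2, 1, rates_ca_lva, q10=Q10_DEFAULT,
                              t_exp=21.0, shift_mV=-10.0, half_activation=-30.0),
    "SK": ChannelKinetics("SK", "k", 1, 0, rates_sk, ca_gated=True, tau_fixed=1.0),
}

CHANNEL_NAMES = tuple(CHANNELS)


def q10_factor(k: ChannelKinetics, t_sim: float = T_SIM_DEFAULT) -> float:
    """Temperature adjustment factor q10^((T_sim - T_exp)/10)."""
    if k.q10 == 1.0:
        return 1.0
    return k.q10 ** ((t_sim - k.t_exp) / 10.0)


def steady_state(k: ChannelKinetics, v_or_ca: float):
    """Gate steady-state values at V (mV), or at [Ca2+] (mM) for SK.

    Returns ``(x_inf,)`` for channels without inactivation, else
    ``(x_inf, y_inf)``.
    """
    if k.ca_gated:
        if v_or_ca <= 0:
            raise ValueError("SK gating requires [Ca2+] > 0")
        minf, _, _, _ = k.rates(v_or_ca)
        return (minf,)
    minf, _, hinf, _ = k.rates(k._literature_v(v_or_ca))
    if k.y_exp == 0:
        return (minf,)
    return (minf, hinf)


def time_constant(k: ChannelKinetics, v_or_ca: float, t_sim: float = T_SIM_DEFAULT):
    """Gate time constants (ms) at the simulation temperature."""
    if k.tau_fixed is not None:
        return (k.tau_fixed,)
    qt = q10_factor(k, t_sim)
    _, mtau, _, htau = k.rates(k._literature_v(v_or_ca))
    if k.y_exp == 0:
        return (mtau / qt,)
    return (mtau / qt, htau / qt)


def channel_current(k: ChannelKinetics, gbar: float, gates, v: float,
                    rev: ReversalSet | None = None, e: float | None = None) -> float:
    """HH current density in pA/um^2 (gbar in pS/um^2, V and E in mV)."""
    if gbar < 0:
        raise ValueError("maximal conductance density must be >= 0")
    gates = np.atleast_1d(np.asarray(gates, dtype=float))
    if np.any((gates < 0) | (gates > 1)):
        raise ValueError("gate values must lie in [0, 1]")
    if e is None:
        e = k.reversal(rev if rev is not None else ReversalSet())
    open_frac = gates[0] ** k.x_exp
    if k.y_exp > 0:
        open_frac *= gates[1] ** k.y_exp
    return 1e-3 * gbar * open_frac * (v - e)  # pS*mV -> 1e-3 pA


# --------------------------------------------------------------------------
# intracellular Ca2+ dynamics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CaDynamicsParams:
    """First-order submembrane Ca2+ pool.

    gamma and tau_decay are free parameters of the model fit; depth and
    the resting concentration are fixed.
    """

    gamma: float = 0.0005  # unitless fraction of unbuffered Ca2+ influx
    tau_decay: float = 80.0  # ms
    depth: float = 0.1  # um, submembrane shell
    ca_inf: float = 1e-4  # mM, resting free [Ca2+]

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")

    def influx_rate(self, i_ca_pA_per_um2: float) -> float:
        """d[Ca]/dt contribution (mM/ms) of a Ca2+ current density.

        Inward (negative) Ca2+ current raises [Ca2+].  1 pA/um^2 equals
        0.1 mA/cm^2; the 1e4 factor converts A/m^2 over a um shell to
        mM/ms.
        """
        i_mA_cm2 = 0.1 * i_ca_pA_per_um2
        return -1e4 * self.gamma * i_mA_cm2 / (2.0 * FARADAY * self.depth)


def ca_update(c: CaDynamicsParams, ca: float, i_ca_pA_per_um2: float, dt: float) -> float:
    """Advance [Ca2+] one step with the exact exponential update.

    The pool ODE is linear in [Ca2+] for a frozen Ca2+ current, so the
    update is unconditionally stable.
    """
    if ca <= 0:
        raise ValueError("[Ca2+] must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = c.ca_inf + c.tau_decay * c.influx_rate(i_ca_pA_per_um2)
    return target + (ca - target) * math.exp(-dt / c.tau_decay)


def ca_steady_state(c: CaDynamicsParams, i_ca_pA_per_um2: float) -> float:
    """Closed-form fixed point of the pool for a constant Ca2+ current."""
    return c.ca_inf + c.tau_decay * c.influx_rate(i_ca_pA_per_um2)
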