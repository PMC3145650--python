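"""Cable simulation of the compartmental L5b cell model.

This module binds a discretized morphology to membrane mechanisms
(:class:`CellModel`), generates current-injection protocols, advances the
branched cable equation with the compiled core, and provides the passive
measurements used throughout (input resistance, transfer impedance,
I_h block).

Spatial channel distributions follow fixed rules: all channels are
uniform within a region except I_h, whose apical density grows
exponentially with path distance from a 1 pS/um^2 somatic base, and the
two Ca2+ channels, which are concentrated in a distal apical "hot" zone
(685-885 um path distance by default) at 10x (HVA) and 100x (LVA) their
density elsewhere on the apical tree.  To account for spine membrane,
dendritic capacitance and all dendritic conductance densities are doubled
internally; densities are always reported un-doubled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _core
from .mechanisms import (
    CHANNELS, CHANNEL_NAMES, CaDynamicsParams, ReversalSet, q10_factor,
    T_SIM_DEFAULT,
)
from .morphology import CompartmentalCell, Morphology, REGIONS

__all__ = [
    "PassiveProps",
    "DensityRule",
    "RmSigmoid",
    "CellModel",
    "StimulusProtocol",
    "Trace",
    "SimResult",
    "SimulationDiverged",
    "MeasurementInvalid",
    "Step",
    "BriefPulse",
    "EpspLike",
    "PulseTrain",
    "DCHold",
    "HOT_ZONE_DEFAULT",
    "IH_SHAPE_DEFAULT",
    "apply_density_rules",
    "default_rules",
    "build_cell_model",
    "simulate",
    "measure_input_resistance",
    "transfer_impedance",
    "set_ih_blocked",
    "main_bifurcation_distance",
    "resolve_site",
]

HOT_ZONE_DEFAULT = (685.0, 885.0)  # um path distance
HOT_ZONE_MULT = {"Ca_LVA": 100.0, "Ca_HVA": 10.0}
# apical I_h profile shape g(x) = base * (A + B*exp(C*x/x_end)) / (A + B)
IH_SHAPE_DEFAULT = (-0.8696, 2.0870, 3.6161)
IH_BASE_DEFAULT = 1.0  # pS/um^2 at the soma
V_INIT_DEFAULT = -80.0  # mV

Site = "tuple[str, float] | int"


class SimulationDiverged(RuntimeError):
    """The membrane potential left the physical range; the parameter set
    is treated as a failed model by the optimizer."""


class MeasurementInvalid(RuntimeError):
    """A passive measurement was contaminated (e.g., a spike was elicited)."""


@dataclass(frozen=True)
class PassiveProps:
    """Region-wise passive membrane properties.

    ``cm`` is 1 uF/cm^2 for soma and axon and 2 uF/cm^2 for dendrites
    (spine correction); leak conductance densities are free parameters in
    un-doubled pS/um^2.
    """

    cm_soma_axon: float = 1.0  # uF/cm^2
    cm_dendrite: float = 2.0  # uF/cm^2
    ra: float = 100.0  # Ohm*cm (used at compartmentalization time)
    e_leak: float = -90.0  # mV


@dataclass(frozen=True)
class RmSigmoid:
    """Optional non-uniform apical membrane resistance variant.

    R_m rises to fall sigmoidally from its somatic to its distal value
    with half-distance ``d_half`` and steepness ``steep``; ``factor``
    preserves the spatial integral of leak conductance.  The leak
    reversal follows the same profile from -90 to -80 mV.
    """

    rm_soma: float = 34963.0  # Ohm*cm^2
    rm_end: float = 5357.0
    d_half: float = 406.0  # um
    steep: float = 50.0  # um
    factor: float = 1.16
    e_leak_soma: float = -90.0
    e_leak_end: float = -80.0

    def profile(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = 1.0 / (1.0 + np.exp((self.d_half - x) / self.steep))
        rm = self.rm_soma + (self.rm_end - self.rm_soma) * s
        g = 1e4 * self.factor / rm  # S/cm^2 -> pS/um^2 is 1e4
        e = self.e_leak_soma + (self.e_leak_end - self.e_leak_soma) * s
        return g, e


@dataclass(frozen=True)
class DensityRule:
    """Spatial density rule for one channel in one region.

    ``kind`` is one of ``uniform`` (params: density), ``ih_exponential``
    (params: base, shape=(A, B, C), x_end), ``hot_zone_step`` (params:
    hot_density, zone=(lo, hi), multiplier).  Densities are un-doubled
    pS/um^2 and rule evaluation depends only on region and path distance.
    """

    channel: str
    region: str
    kind: str
    params: dict

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "uniform":
            return np.full_like(x, float(self.params["density"]))
        if self.kind == "ih_exponential":
            a, b, c = self.params.get("shape", IH_SHAPE_DEFAULT)
            x_end = float(self.params["x_end"])
            base = float(self.params["base"])
            return base * (a + b * np.exp(c * x / x_end)) / (a + b)
        if self.kind == "hot_zone_step":
            lo, hi = self.params["zone"]
            if not lo < hi:
                raise ValueError("hot zone bounds must be ordered")
            hot = float(self.params["hot_density"])
            mult = float(self.params["multiplier"])
            out = np.full_like(x, hot / mult)
            out[(x >= lo) & (x <= hi)] = hot
            return out
        raise ValueError(f"unknown density rule kind {self.kind!r}")


_SOMA_CHANNELS = ("Na_t", "Na_p", "K_p", "K_t", "Kv3.1", "Ca_HVA", "Ca_LVA", "SK")
_APICAL_UNIFORM = ("Na_t", "Kv3.1", "SK", "I_m")


def main_bifurcation_distance(m: Morphology) -> float:
    """Path distance (um) of the main apical bifurcation.

    The main bifurcation is the apical branch point that splits the tree
    most evenly: among branch points with two or more apical children,
    the one whose second-largest child subtree is longest (oblique side
    branches leave only a small secondary subtree, so trunk-oblique
    junctions score low); ties resolve to the most distal candidate.
    """
    lengths: dict[int, float] = {}
    for i in range(len(m.sections) - 1, -1, -1):
        s = m.sections[i]
        lengths[i] = s.length + sum(lengths[k] for k in m.children(i))
    best = None  # (score, distance)
    for i, s in enumerate(m.sections):
        if s.region != "apical":
            continue
        kids = [k for k in m.children(i) if m.sections[k].region == "apical"]
        if len(kids) < 2:
            continue
        score = sorted(lengths[k] for k in kids)[-2]
        d = m.section_start_distance(i) + s.length
        if best is None or score > best[0] + 1e-9 or \
                (abs(score - best[0]) <= 1e-9 and d > best[1]):
            best = (score, d)
    if best is None:
        raise LookupError("morphology has no apical bifurcation")
    return best[1]


def default_rules(params: dict, cell: CompartmentalCell,
                  hot_zone_mode: str = "distance",
                  hot_zone: tuple[float, float] = HOT_ZONE_DEFAULT,
                  ih_base: float = IH_BASE_DEFAULT,
                  ih_shape: tuple[float, float, float] = IH_SHAPE_DEFAULT,
                  ) -> list[DensityRule]:
    """The standard L5b distribution rules for a free-parameter dict.

    ``hot_zone_mode`` places the Ca2+ hot zone either by the fixed
    distance rule (default) or anchored 35 um proximal to the main
    apical bifurcation with a 200 um extent (``"bifurcation"``).
    """
    apical_mask = cell.region_mask("apical")
    x_end = float(cell.path_dist[apical_mask].max()) if apical_mask.any() else 1.0
    if hot_zone_mode == "bifurcation":
        bif = main_bifurcation_distance(cell.morphology)
        zone = (bif - 35.0, bif - 35.0 + 200.0)
    elif hot_zone_mode == "distance":
        zone = hot_zone
    else:
        raise ValueError("hot_zone_mode must be 'distance' or 'bifurcation'")
    if apical_mask.any() and zone[0] > cell.path_dist[apical_mask].max():
        raise ValueError(
            f"apical tree (max {cell.path_dist[apical_mask].max():.0f} um) does not "
            f"reach the Ca2+ hot zone starting at {zone[0]:.0f} um")

    rules = []
    for ch in _SOMA_CHANNELS:
        rules.append(DensityRule(ch, "soma", "uniform",
                                 {"density": params.get(f"s.gbar_{ch}", 0.0)}))
    rules.append(DensityRule("I_h", "soma", "uniform", {"density": ih_base}))
    rules.append(DensityRule("I_h", "basal", "uniform", {"density": ih_base}))
    rules.append(DensityRule("I_h", "apical", "ih_exponential",
                             {"base": ih_base, "shape": ih_shape, "x_end": x_end}))
    for ch in _APICAL_UNIFORM:
        rules.append(DensityRule(ch, "apical", "uniform",
                                 {"density": params.get(f"a.gbar_{ch}", 0.0)}))
    for ch, mult in HOT_ZONE_MULT.items():
        rules.append(DensityRule(ch, "apical", "hot_zone_step",
                                 {"hot_density": params.get(f"a.gbar_{ch}", 0.0),
                                  "zone": zone, "multiplier": mult}))
    return rules


def apply_density_rules(cell: CompartmentalCell, rules: list[DensityRule]) -> np.ndarray:
    """Evaluate density rules into an un-doubled (n_channels, n) matrix.

    Two rules addressing the same channel and region conflict.
    """
    seen = set()
    for r in rules:
        key = (r.channel, r.region)
        if key in seen:
            raise ValueError(f"conflicting density rules for {key}")
        if r.channel not in CHANNELS:
            raise ValueError(f"unknown channel {r.channel!r}")
        if r.region not in REGIONS:
            raise ValueError(f"unknown region {r.region!r}")
        seen.add(key)
    gbar = np.zeros((len(CHANNEL_NAMES), cell.n))
    for r in rules:
        mask = cell.region_mask(r.region)
        vals = r.evaluate(cell.path_dist[mask])
        if np.any(vals < 0):
            raise ValueError(f"negative density from rule {r.channel}/{r.region}")
        gbar[CHANNEL_NAMES.index(r.channel), mask] = vals
    return gbar


@dataclass
class CellModel:
    """A fully parameterized compartmental cell.

    ``gbar_report`` holds un-doubled densities (pS/um^2); the solver-side
    arrays have the dendritic doubling and area scaling applied.
    """

    cell: CompartmentalCell
    passive: PassiveProps
    rev: ReversalSet
    gbar_report: np.ndarray  # (n_channels, n) pS/um^2
    gbar_uS: np.ndarray  # (n_channels, n) uS, internal
    g_leak_report: np.ndarray  # (n,) pS/um^2
    g_leak_uS: np.ndarray  # (n,) uS, internal
    e_leak: np.ndarray  # (n,) mV
    cm_nF: np.ndarray  # (n,) nF
    gamma: np.ndarray  # (n,)
    tau_decay: np.ndarray  # (n,) ms
    ca_depth: float = 0.1
    ca_inf: float = 1e-4
    t_celsius: float = T_SIM_DEFAULT
    params: dict = field(default_factory=dict)
    ih_blocked: bool = False
    _ih_backup: tuple | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.cell.n

    def density(self, channel: str, site) -> float:
        """Reported (un-doubled) density (pS/um^2) at a site."""
        return float(self.gbar_report[CHANNEL_NAMES.index(channel),
                                      resolve_site(self.cell, site)])


def _dendrite_mask(cell: CompartmentalCell) -> np.ndarray:
    return cell.region_mask("basal") | cell.region_mask("apical")


def build_cell_model(cell: CompartmentalCell, params: dict, *,
                     passive: PassiveProps | None = None,
                     rev: ReversalSet | None = None,
                     rules: list[DensityRule] | None = None,
                     hot_zone_mode: str = "distance",
                     hot_zone: tuple[float, float] = HOT_ZONE_DEFAULT,
                     ih_base: float = IH_BASE_DEFAULT,
                     rm_sigmoid: RmSigmoid | None = None,
                     spine_correction: bool = True) -> CellModel:
    """Bind free parameters and density rules to a compartmental cell.

    ``params`` uses the canonical names (``s.gbar_Na_t`` ... ``a.gamma``);
    absent channel densities default to 0 and absent Ca2+-dynamics
    parameters to the mechanism defaults.  The spine correction (x2 on
    dendritic C_m and densities) is applied here, exactly once.
    """
    unknown = [k for k in params if not _valid_param_name(k)]
    if unknown:
        raise ValueError(f"unknown parameter names: {unknown}")
    passive = passive or PassiveProps()
    rev = rev or ReversalSet()
    if rules is None:
        rules = default_rules(params, cell, hot_zone_mode=hot_zone_mode,
                              hot_zone=hot_zone, ih_base=ih_base)
    gbar_report = apply_density_rules(cell, rules)

    n = cell.n
    g_leak_report = np.zeros(n)
    defaults = CaDynamicsParams()
    for short, region in (("s", "soma"), ("ax", "axon_initial"),
                          ("b", "basal"), ("a", "apical")):
        g_leak_report[cell.region_mask(region)] = params.get(f"{short}.g_leak", 0.3)
    e_leak = np.full(n, passive.e_leak)
    if rm_sigmoid is not None:
        mask = cell.region_mask("apical")
        g, e = rm_sigmoid.profile(cell.path_dist[mask])
        g_leak_report[mask] = g
        e_leak[mask] = e

    gamma = np.full(n, float(params.get("s.gamma", defaults.gamma)))
    tau = np.full(n, float(params.get("s.tau_decay", defaults.tau_decay)))
    amask = cell.region_mask("apical")
    gamma[amask] = float(params.get("a.gamma", defaults.gamma))
    tau[amask] = float(params.get("a.tau_decay", defaults.tau_decay))

    dend = _dendrite_mask(cell)
    if spine_correction:
        double = np.where(dend, 2.0, 1.0)
        cm = np.where(dend, passive.cm_dendrite, passive.cm_soma_axon)
    else:
        double = np.ones(n)
        cm = np.full(n, passive.cm_soma_axon)
    # uF/cm^2 * um^2 -> nF : 1e-5
    cm_nF = cm * cell.area * 1e-5
    # pS/um^2 * um^2 -> uS : 1e-6
    gbar_uS = gbar_report * double[None, :] * cell.area[None, :] * 1e-6
    g_leak_uS = g_leak_report * double * cell.area * 1e-6

    return CellModel(cell=cell, passive=passive, rev=rev,
                     gbar_report=gbar_report, gbar_uS=gbar_uS,
                     g_leak_report=g_leak_report, g_leak_uS=g_leak_uS,
                     e_leak=e_leak, cm_nF=cm_nF, gamma=gamma, tau_decay=tau,
                     ca_depth=CaDynamicsParams().depth,
                     params=dict(params))


_PARAM_SUFFIXES = {"g_leak", "gamma", "tau_decay"} | {f"gbar_{c}" for c in CHANNEL_NAMES}


def _valid_param_name(name: str) -> bool:
    if "." not in name:
        return False
    region, suffix = name.split(".", 1)
    return region in {"s", "ax", "b", "a"} and suffix in _PARAM_SUFFIXES


def set_ih_blocked(model: CellModel, blocked: bool = True) -> CellModel:
    """Return a model with I_h zeroed everywhere (or restored exactly)."""
    ih = CHANNEL_NAMES.index("I_h")
    m = replace(model)
    if blocked:
        if not m.ih_blocked:
            m._ih_backup = (model.gbar_report[ih].copy(), model.gbar_uS[ih].copy())
        m.gbar_report = model.gbar_report.copy()
        m.gbar_uS = model.gbar_uS.copy()
        m.gbar_report[ih] = 0.0
        m.gbar_uS[ih] = 0.0
        m.ih_blocked = True
    elif m.ih_blocked:
        m.gbar_report = model.gbar_report.copy()
        m.gbar_uS = model.gbar_uS.copy()
        m.gbar_report[ih], m.gbar_uS[ih] = m._ih_backup
        m.ih_blocked = False
        m._ih_backup = None
    return m


# --------------------------------------------------------------------------
# stimulus waveforms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Step:
    """Square current step (nA)."""

    amp: float
    onset: float = 0.0  # ms
    dur: float = 0.0  # ms

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return np.where((t >= self.onset) & (t < self.onset + self.dur), self.amp, 0.0)


@dataclass(frozen=True)
class BriefPulse:
    """Brief suprathreshold square pulse, 5 ms by default."""

    amp: float
    onset: float = 0.0
    dur: float = 5.0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return np.where((t >= self.onset) & (t < self.onset + self.dur), self.amp, 0.0)


@dataclass(frozen=True)
class EpspLike:
    """Double-exponential EPSP-shaped current; peak equals ``amp``."""

    amp: float
    onset: float = 0.0
    rise: float = 0.5  # ms
    decay: float = 5.0  # ms

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        tr, td = self.rise, self.decay
        tp = tr * td / (td - tr) * math.log(td / tr)
        norm = math.exp(-tp / td) - math.exp(-tp / tr)
        u = t - self.onset
        out = np.zeros_like(t)
        on = u >= 0
        out[on] = self.amp / norm * (np.exp(-u[on] / td) - np.exp(-u[on] / tr))
        return out


@dataclass(frozen=True)
class PulseTrain:
    """n brief pulses at a given frequency (Hz)."""

    n: int
    freq: float
    amp: float
    pulse_dur: float = 5.0
    onset: float = 0.0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        period = 1000.0 / self.freq
        out = np.zeros_like(t)
        for k in range(self.n):
            t0 = self.onset + k * period
            out += np.where((t >= t0) & (t < t0 + self.pulse_dur), self.amp, 0.0)
        return out


@dataclass(frozen=True)
class DCHold:
    """Sustained DC current (nA) emulating an Up-state depolarization."""

    amp: float
    onset: float = 0.0
    dur: float = 1e9

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return np.where((t >= self.onset) & (t < self.onset + self.dur), self.amp, 0.0)


@dataclass
class StimulusProtocol:
    """A set of current injections on a common time grid."""

    injections: list  # [(site, waveform), ...]
    duration: float  # ms
    dt: float = 0.025  # ms

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 0.1 + 1e-12:
            raise ValueError("dt must lie in (0, 0.1] ms")


def resolve_site(cell: CompartmentalCell, site) -> int:
    if isinstance(site, (int, np.integer)):
        if not (0 <= int(site) < cell.n):
            raise LookupError(f"compartment {site} off the cell")
        return int(site)
    region, dist = site
    return cell.index_at(region, float(dist))


def site_label(cell: CompartmentalCell, site) -> str:
    i = resolve_site(cell, site)
    region = REGIONS[cell.region[i]]
    if region == "soma":
        return "soma"
    return f"{region}_{cell.path_dist[i]:.0f}"


# --------------------------------------------------------------------------
# traces and simulation results
# --------------------------------------------------------------------------

@dataclass
class Trace:
    """Uniformly sampled time series at one recording site."""

    variable: str  # "V" (mV) | "Ca" (mM) | "I_Na_t" (pA/um^2)
    site_region: str
    site_distance: float  # um
    t: np.ndarray  # ms
    values: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"t_ms": self.t, self.variable: self.values}).to_csv(
            Path(path), index=False)

    def to_hdf5(self, group) -> None:
        group.create_dataset("time", data=self.t)
        group.create_dataset("value", data=self.values)
        group.attrs["variable"] = self.variable
        group.attrs["site_region"] = self.site_region
        group.attrs["site_distance_um"] = self.site_distance

    @classmethod
    def from_hdf5(cls, group) -> "Trace":
        return cls(variable=str(group.attrs["variable"]),
                   site_region=str(group.attrs["site_region"]),
                   site_distance=float(group.attrs["site_distance_um"]),
                   t=np.asarray(group["time"]), values=np.asarray(group["value"]))


@dataclass
class SimResult:
    traces: dict  # name -> Trace (voltage)
    ca_traces: dict  # name -> Trace
    inat_traces: dict  # name -> Trace
    diverged: bool
    state: tuple  # (V, m, h, ca) final solver state

    def __getitem__(self, name: str) -> Trace:
        return self.traces[name]


def _channel_constants(model: CellModel):
    e_chan = np.empty(len(CHANNEL_NAMES))
    shift = np.empty(len(CHANNEL_NAMES))
    qt = np.empty(len(CHANNEL_NAMES))
    for c, name in enumerate(CHANNEL_NAMES):
        k = CHANNELS[name]
        e_chan[c] = k.reversal(model.rev)
        shift[c] = k.shift_mV
        qt[c] = q10_factor(k, model.t_celsius)
    return e_chan, shift, qt


def _fresh_state(model: CellModel, v_init: float = V_INIT_DEFAULT):
    n = model.n
    V = np.full(n, v_init)
    m = np.zeros((len(CHANNEL_NAMES), n))
    h = np.ones((len(CHANNEL_NAMES), n))
    ca = np.full(n, model.ca_inf)
    _, shift, qt = _channel_constants(model)
    _core.init_gates(V, ca, shift, qt, m, h, n)
    return V, m, h, ca


def _advance(model: CellModel, state, stim_comp, stim_I, dt, n_steps, theta,
             rec_comp, rec_every):
    V, m, h, ca = state
    e_chan, shift, qt = _channel_constants(model)
    n_rec = max((n_steps // rec_every), 0) + 1
    out_v = np.empty((len(rec_comp), n_rec))
    out_ca = np.empty_like(out_v)
    out_inat = np.empty_like(out_v)
    out_v[:, 0] = V[rec_comp]
    out_ca[:, 0] = ca[rec_comp]
    out_inat[:, 0] = 0.0
    status = _core.run(
        model.cell.parent, model.cm_nF, model.cell.g_axial,
        model.g_leak_uS, model.e_leak,
        model.gbar_uS, e_chan, shift, qt, CHANNELS["SK"].tau_fixed,
        model.gamma, model.tau_decay, model.ca_depth, model.ca_inf,
        model.cell.area,
        1 if model.rev.e_ca_mode == "nernst" else 0, model.rev.ca_out,
        model.t_celsius,
        stim_comp, stim_I, dt, n_steps, theta,
        V, m, h, ca, rec_comp, rec_every, out_v, out_ca, out_inat)
    return status, (V, m, h, ca), out_v, out_ca, out_inat


def simulate(model: CellModel, protocol: StimulusProtocol, recordings=None, *,
             theta: float = 0.5, init_duration: float = 1000.0,
             init_dt: float = 0.1, state=None, record_every: int = 1,
             raise_on_divergence: bool = True) -> SimResult:
    """Run a stimulation protocol and return the requested traces.

    The model is first brought to rest by integrating ``init_duration`` ms
    with all stimuli off (backward Euler at a coarse step), so that
    I_h-dependent resting gradients are established before t = 0.  Pass
    ``state`` to chain simulations instead.
    """
    cell = model.cell
    if recordings is None:
        recordings = [("soma", 0.0)]
    rec_items = list(recordings.items()) if isinstance(recordings, dict) else \
        [(site_label(cell, s), s) for s in recordings]
    rec_comp = np.array([resolve_site(cell, s) for _, s in rec_items], dtype=np.int64)

    if state is None:
        state = _fresh_state(model)
        if init_duration > 0:
            n_init = int(round(init_duration / init_dt))
            status, state, *_ = _advance(
                model, state, np.zeros(0, dtype=np.int64),
                np.zeros((0, n_init)), init_dt, n_init, 1.0,
                rec_comp[:1], max(n_init, 1))
            if status != 0 and raise_on_divergence:
                raise SimulationDiverged("divergence during rest initialization")

    dt = protocol.dt
    n_steps = int(round(protocol.duration / dt))
    t_mid = (np.arange(n_steps) + theta) * dt
    by_comp: dict[int, np.ndarray] = {}
    for site, wf in protocol.injections:
        comp = resolve_site(cell, site)
        by_comp.setdefault(comp, np.zeros(n_steps))
        by_comp[comp] += wf.evaluate(t_mid)
    stim_comp = np.array(sorted(by_comp), dtype=np.int64)
    stim_I = np.array([by_comp[c] for c in stim_comp]) if len(by_comp) \
        else np.zeros((0, n_steps))

    status, state, out_v, out_ca, out_inat = _advance(
        model, state, stim_comp, stim_I, dt, n_steps, theta, rec_comp,
        record_every)
    if status != 0 and raise_on_divergence:
        raise SimulationDiverged("membrane potential diverged (|V| > 200 mV)")

    t = np.arange(out_v.shape[1]) * dt * record_every
    traces, ca_traces, inat_traces = {}, {}, {}
    for r, (name, site) in enumerate(rec_items):
        i = rec_comp[r]
        region = REGIONS[cell.region[i]]
        dist = float(cell.path_dist[i])
        traces[name] = Trace("V", region, dist, t, out_v[r].copy())
        ca_traces[name] = Trace("Ca", region, dist, t, out_ca[r].copy())
        inat_traces[name] = Trace("I_Na_t", region, dist, t, out_inat[r].copy())
    return SimResult(traces, ca_traces, inat_traces, status != 0, state)


# --------------------------------------------------------------------------
# passive measurements
# --------------------------------------------------------------------------

def measure_input_resistance(model: CellModel, site=("soma", 0.0), *,
                             amp: float = -0.05, dur: float = 200.0,
                             dt: float = 0.025) -> float:
    """Input resistance (MOhm) from a subthreshold square step.

    Default protocol: -50 pA for 200 ms, the I_h-sag protocol.
    """
    pre, post = 20.0, 20.0
    prot = StimulusProtocol([(site, Step(amp, onset=pre, dur=dur))],
                            duration=pre + dur + post, dt=dt)
    res = simulate(model, prot, recordings={"site": site})
    v = res["site"].values
    t = res["site"].t
    if np.any(v > -20.0):
        raise MeasurementInvalid("stimulus elicited a spike")
    v0 = v[t < pre][-1]
    steady = v[(t > pre + 0.9 * dur) & (t < pre + dur)].mean()
    return float((steady - v0) / amp)


def transfer_impedance(model: CellModel, site_a, site_b,
                       mode: str = "steady", *, amp: float = -0.05,
                       dt: float = 0.025) -> float:
    """Transfer impedance (MOhm) between two sites.

    ``steady``: sustained small step at ``site_a``, steady-state voltage
    deflection at ``site_b`` per injected current.  ``brief_5ms``: peak
    deflection at ``site_b`` for a 5 ms pulse (the duration of an AP) per
    injected current.
    """
    pre = 20.0
    if mode == "steady":
        dur, total = 400.0, 440.0
        wf = Step(amp, onset=pre, dur=dur)
    elif mode == "brief_5ms":
        dur, total = 5.0, 120.0
        wf = BriefPulse(amp, onset=pre, dur=5.0)
    else:
        raise ValueError("mode must be 'steady' or 'brief_5ms'")
    prot = StimulusProtocol([(site_a, wf)], duration=total, dt=dt)
    res = simulate(model, prot, recordings={"b": site_b, "a": site_a})
    for tr in (res["a"], res["b"]):
        if np.any(tr.values > -20.0):
            raise MeasurementInvalid("stimulus elicited a spike")
    v = res["b"].values
    t = res["b"].t
    v0 = v[t < pre][-1]
    if mode == "steady":
        deflect = v[(t > pre + 0.9 * dur) & (t < pre + dur)].mean() - v0
    else:
        dv = v - v0
        deflect = dv[np.argmax(np.abs(dv))]
    return float(deflect / amp)
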