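"""The in-silico experiment battery for L5b pyramidal cell models.

Protocols replicate the classical bench experiments the models are
judged by: BAC firing (coincident somatic pulse and distal EPSP-like
input), prolonged step-current firing with f-I normalization, the
critical frequency of somatic AP trains for dendritic Ca2+
electrogenesis, the Up/Down-state coincidence-detection window, I_h
contribution to dendritic voltage attenuation, and transfer of a fitted
parameter set onto a different morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cablesim import (
    BriefPulse, CellModel, DCHold, EpspLike, MeasurementInvalid, PulseTrain,
    SimulationDiverged, Step, StimulusProtocol, Trace, build_cell_model,
    measure_input_resistance, set_ih_blocked, simulate, site_label,
)
from .features import (
    FeatureReport, bac_features, detect_spikes, group_objectives,
    load_feature_stats, normalize_fi, step_features,
    STEP_AMPLITUDE_CLASSES,
)
from .morphology import (
    CompartmentalCell, Morphology, build_synthetic_l5b, compartmentalize,
)

__all__ = [
    "ProtocolResult",
    "reference_model",
    "bac_protocol",
    "step_protocol",
    "measure_fi",
    "find_reference_current",
    "normalized_step_amplitudes",
    "calibrate_pulse_amp",
    "critical_frequency",
    "coincidence_window",
    "ih_attenuation",
    "transfer_morphology",
    "evaluate_targets",
    "save_result",
    "load_result",
]

BAC_DEND_SITE = 620.0  # um, EPSP injection / distal trunk recording
BAC_HOT_SITE = 785.0  # um, center of the Ca2+ hot zone
CRITFREQ_SITE = 830.0  # um, distal recording for the critical-frequency scan
DT_DEFAULT = 0.025  # ms


@dataclass
class ProtocolResult:
    """Traces, derived scalars and provenance of one protocol run."""

    name: str
    config: dict
    traces: dict  # label -> Trace
    scalars: dict
    features: FeatureReport | None = None
    provenance: dict = field(default_factory=dict)


def reference_model(params: dict | None = None, morphology: Morphology | None = None,
                    seed: int = 0, max_len: float = 20.0, **build_kw) -> CellModel:
    """The working model: a parameter set bound to a morphology.

    Defaults to the published dually-constrained parameter set on the
    synthetic reduced L5b morphology.
    """
    from .moofit import TABLE3_PARAMS
    if params is None:
        params = TABLE3_PARAMS
    if morphology is None:
        morphology = build_synthetic_l5b(seed=seed)
    cell = compartmentalize(morphology, max_len=max_len)
    return build_cell_model(cell, params, **build_kw)


def _rested_state(model: CellModel, init_duration: float = 1000.0):
    """Settled resting state, cached on the model and copied per use."""
    cache = getattr(model, "_rest_cache", None)
    if cache is None or cache[0] != init_duration:
        res = simulate(model, StimulusProtocol([], duration=1.0, dt=0.025),
                       recordings=[("soma", 0.0)], init_duration=init_duration)
        cache = (init_duration, res.state)
        model._rest_cache = cache
    V, m, h, ca = cache[1]
    return V.copy(), m.copy(), h.copy(), ca.copy()


def _run(model, injections, duration, recordings, dt=DT_DEFAULT,
         raise_on_divergence=True):
    prot = StimulusProtocol(injections, duration=duration, dt=dt)
    return simulate(model, prot, recordings=recordings,
                    state=_rested_state(model),
                    raise_on_divergence=raise_on_divergence)


# --------------------------------------------------------------------------
# BAC firing
# --------------------------------------------------------------------------

def bac_protocol(model: CellModel, *, soma_amp: float = 1.9,
                 soma_dur: float = 5.0, epsp_amp: float = 0.5,
                 dend_site: float = BAC_DEND_SITE, interval: float = 5.0,
                 strong_amp: float = 2.5, hot_site: float = BAC_HOT_SITE,
                 onset: float = 20.0, duration: float = 200.0,
                 dt: float = DT_DEFAULT, stats=None,
                 raise_on_divergence: bool = True) -> ProtocolResult:
    """The four-phase BAC-firing protocol.

    Phases: EPSP-like current alone at the distal apical site; brief
    suprathreshold soma pulse alone; both coincident (EPSP lagging by
    ``interval`` ms); and an intense EPSP-like dendritic injection
    alone.  The ten BAC features are extracted from the soma-only and
    coincident phases.
    """
    soma = ("soma", 0.0)
    dend = ("apical", dend_site)
    recs = {"soma": soma, "d620": ("apical", 620.0), "d800": ("apical", 800.0),
            "hot": ("apical", hot_site)}
    phases = {
        "epsp": [(dend, EpspLike(epsp_amp, onset=onset))],
        "soma_only": [(soma, BriefPulse(soma_amp, onset=onset, dur=soma_dur))],
        "coincident": [(soma, BriefPulse(soma_amp, onset=onset, dur=soma_dur)),
                       (dend, EpspLike(epsp_amp, onset=onset + interval))],
        "strong_dend": [(dend, EpspLike(strong_amp, onset=onset))],
    }
    traces: dict[str, Trace] = {}
    diverged = False
    for phase, injections in phases.items():
        res = _run(model, injections, duration, recs, dt,
                   raise_on_divergence=raise_on_divergence)
        diverged = diverged or res.diverged
        for label, tr in res.traces.items():
            traces[f"{phase}/{label}"] = tr

    config = {"soma_amp": soma_amp, "soma_dur": soma_dur, "epsp_amp": epsp_amp,
              "dend_site": dend_site, "interval": interval,
              "strong_amp": strong_amp, "hot_site": hot_site, "onset": onset,
              "duration": duration, "dt": dt}
    scalars = _bac_scalars(traces, config)
    scalars["diverged"] = diverged
    report = None
    if stats is not None and not diverged:
        values = {("bac", k): v for k, v in scalars["features"].items()}
        report = FeatureReport.from_values(values, stats, "bac")
    return ProtocolResult("bac", config, traces, scalars, features=report)


def _bac_scalars(traces: dict, config: dict) -> dict:
    feats = bac_features(traces["coincident/soma"], traces["coincident/hot"],
                         traces["soma_only/soma"], traces["soma_only/d620"],
                         traces["soma_only/d800"])
    ep = traces["epsp/d620"]
    soma_ep = traces["epsp/soma"]
    return {
        "features": feats,
        "ap_count": {p: int(len(detect_spikes(traces[f"{p}/soma"])))
                     for p in ("epsp", "soma_only", "coincident", "strong_dend")},
        "epsp_local_mV": float(ep.values.max() - ep.values[0]),
        "epsp_somatic_mV": float(soma_ep.values.max() - soma_ep.values[0]),
    }


# --------------------------------------------------------------------------
# step-current firing and f-I normalization
# --------------------------------------------------------------------------

def step_protocol(model: CellModel, amplitudes, *, dur: float = 2000.0,
                  onset: float = 100.0, post: float = 100.0,
                  dt: float = DT_DEFAULT, stats=None,
                  raise_on_divergence: bool = True) -> ProtocolResult:
    """Somatic step-current firing at several amplitudes (nA).

    ``amplitudes`` maps class labels (``low``/``ref``/``high``) to step
    amplitudes, or is a plain sequence.  Extracts the ten step features
    per amplitude and assembles the f-I curve.
    """
    if not isinstance(amplitudes, dict):
        amplitudes = {f"amp{i}": a for i, a in enumerate(amplitudes)}
    soma = ("soma", 0.0)
    traces: dict[str, Trace] = {}
    per_amp: dict[str, dict] = {}
    fi = []
    diverged = False
    for label, amp in amplitudes.items():
        if amp < 0:
            raise ValueError("step amplitudes must be non-negative")
        res = _run(model, [(soma, Step(amp, onset=onset, dur=dur))],
                   onset + dur + post, {"soma": soma}, dt,
                   raise_on_divergence=raise_on_divergence)
        diverged = diverged or res.diverged
        traces[f"{label}/soma"] = res["soma"]
        feats = step_features(res["soma"], onset, dur)
        per_amp[label] = feats
        fi.append((amp, feats["spike_frequency"]))

    config = {"amplitudes": dict(amplitudes), "dur": dur, "onset": onset,
              "post": post, "dt": dt}
    scalars = {"features": per_amp, "fi_curve": fi, "diverged": diverged}
    report = None
    if stats is not None and not diverged and \
            set(amplitudes) >= set(STEP_AMPLITUDE_CLASSES):
        values = {(label, feat): val
                  for label in STEP_AMPLITUDE_CLASSES
                  for feat, val in per_amp[label].items()}
        report = FeatureReport.from_values(values, stats, "step")
    return ProtocolResult("step", config, traces, scalars, features=report)


def measure_fi(model: CellModel, amplitudes, *, dur: float = 2000.0,
               onset: float = 100.0, dt: float = DT_DEFAULT) -> list:
    """f-I points [(amp nA, rate Hz)] for a sequence of amplitudes."""
    result = step_protocol(model, list(amplitudes), dur=dur, onset=onset,
                           post=50.0, dt=dt, raise_on_divergence=False)
    return result.scalars["fi_curve"]


def find_reference_current(model: CellModel, reference_freq: float = 15.0, *,
                           lo: float = 0.1, hi: float = 4.0,
                           tol: float = 0.01, dur: float = 2000.0,
                           dt: float = DT_DEFAULT) -> tuple[float, list]:
    """Bisect the step amplitude whose firing rate brackets 15 Hz.

    Returns the interpolated reference current and the f-I points
    gathered along the way.
    """
    pts = {}

    def rate(amp):
        if amp not in pts:
            pts[amp] = measure_fi(model, [amp], dur=dur, dt=dt)[0][1]
        return pts[amp]

    if rate(lo) >= reference_freq:
        raise ValueError("lower amplitude bound already fires above reference")
    if rate(hi) < reference_freq:
        raise ValueError("upper amplitude bound fires below reference")
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if rate(mid) >= reference_freq:
            b = mid
        else:
            a = mid
    fi_points = sorted(pts.items())
    norm = normalize_fi(fi_points, reference_freq)
    return norm["i_ref"], fi_points


def normalized_step_amplitudes(model: CellModel, **kw) -> dict:
    """The three step amplitudes (78%, 100%, 190% of the 15 Hz current)."""
    i_ref, _ = find_reference_current(model, **kw)
    return {"low": 0.78 * i_ref, "ref": i_ref, "high": 1.90 * i_ref}


# --------------------------------------------------------------------------
# critical frequency of somatic AP trains
# --------------------------------------------------------------------------

def calibrate_pulse_amp(model: CellModel, *, pulse_dur: float = 5.0,
                        lo: float = 0.5, hi: float = 6.0,
                        step: float = 0.1) -> float:
    """Largest brief-pulse amplitude eliciting exactly one somatic AP.

    Trains of brief pulses must evoke an AP per pulse even when later
    pulses fall into the AHP of the preceding spike, so the calibration
    picks the top of the single-AP amplitude range: the strongest pulse
    that still evokes exactly one AP in isolation.
    """
    soma = ("soma", 0.0)
    best = None
    for amp in np.arange(lo, hi + step / 2, step):
        res = _run(model, [(soma, BriefPulse(amp, onset=10.0, dur=pulse_dur))],
                   80.0, {"soma": soma}, raise_on_divergence=False)
        n = len(detect_spikes(res["soma"]))
        if n == 1:
            best = float(amp)
        elif n > 1:
            break
    if best is None:
        raise MeasurementInvalid("no amplitude elicited exactly one AP per pulse")
    return best


def critical_frequency(model: CellModel, *, n_pulses: int = 5,
                       freqs=None, dend_site: float = CRITFREQ_SITE,
                       pulse_amp: float | None = None, pulse_dur: float = 5.0,
                       jump_mV: float = 15.0, dt: float = DT_DEFAULT) -> dict:
    """Scan somatic AP-train frequencies for dendritic Ca2+ electrogenesis.

    A train of ``n_pulses`` brief suprathreshold pulses is injected at
    the soma; the peak dendritic voltage at the distal hot-zone site is
    recorded per frequency.  The critical frequency is the lowest tested
    frequency at which the peak shows the all-or-none regenerative jump
    (> ``jump_mV`` over the previous frequency); ``None`` if no jump
    occurs in the scanned range.
    """
    if freqs is None:
        freqs = np.arange(40.0, 210.0, 10.0)
    freqs = np.asarray(sorted(freqs), float)
    if pulse_amp is None:
        pulse_amp = calibrate_pulse_amp(model, pulse_dur=pulse_dur)
    soma = ("soma", 0.0)
    dend = ("apical", dend_site)
    peaks = np.empty(len(freqs))
    traces = {}
    for k, f in enumerate(freqs):
        dur = 10.0 + (n_pulses - 1) * 1000.0 / f + 100.0
        res = _run(model, [(soma, PulseTrain(n_pulses, f, pulse_amp,
                                             pulse_dur=pulse_dur, onset=10.0))],
                   dur, {"soma": soma, "dend": dend}, dt,
                   raise_on_divergence=False)
        peaks[k] = res["dend"].values.max()
        traces[f"f{int(f):03d}/dend"] = res["dend"]
        traces[f"f{int(f):03d}/soma"] = res["soma"]
    jumps = np.diff(peaks)
    crit = None
    if len(jumps) and jumps.max() > jump_mV:
        crit = float(freqs[int(np.argmax(jumps > jump_mV)) + 1])
    return {
        "critical_frequency": crit,
        "freqs": freqs,
        "peak_dend_v": peaks,
        "pulse_amp": pulse_amp,
        "traces": traces,
    }


# --------------------------------------------------------------------------
# Up/Down state coincidence window
# --------------------------------------------------------------------------

def coincidence_window(model: CellModel, state: str = "down", *,
                       dt_grid=None, dc_amp: float = 0.42,
                       dc_site: float = 200.0, dc_dur: float = 200.0,
                       soma_amp: float | None = None, soma_dur: float = 5.0,
                       epsp_amp: float = 0.5, epsp_site: float = 700.0,
                       dt: float = DT_DEFAULT) -> dict:
    """Temporal window of BAP/EPSP coincidence producing a Ca2+ spike.

    The Up state is emulated by a DC current at the proximal apical
    dendrite (0.42 nA, 200 ms, 200 um from the soma); the Down state
    applies no DC.  For every stimulus time difference dt = t_epsp -
    t_soma the peak distal dendritic voltage is recorded; the window is
    the contiguous dt range whose peak rises above the midpoint between
    the smallest and largest peak across the grid (the all-or-none Ca2+
    spike criterion), reported as ``None`` when the spread never exceeds
    15 mV.

    The coincidence test needs the somatic pulse to trigger a BAP, so
    ``soma_amp=None`` uses 0.5 nA when that already evokes a resting-state
    AP and otherwise falls back to the model-specific calibrated
    single-AP amplitude.
    """
    if state not in ("up", "down"):
        raise ValueError("state must be 'up' or 'down'")
    if soma_amp is None:
        soma = ("soma", 0.0)
        res = _run(model, [(soma, BriefPulse(0.5, onset=10.0, dur=soma_dur))],
                   80.0, {"soma": soma}, raise_on_divergence=False)
        soma_amp = 0.5 if len(detect_spikes(res["soma"])) >= 1 else \
            calibrate_pulse_amp(model, pulse_dur=soma_dur)
    if dt_grid is None:
        dt_grid = np.arange(-40.0, 41.0, 5.0)
    dt_grid = np.asarray(sorted(dt_grid), float)
    if dt_grid[0] > -40.0 or dt_grid[-1] < 40.0:
        raise ValueError("dt grid must span at least [-40, 40] ms")
    soma = ("soma", 0.0)
    dend = ("apical", epsp_site)
    prox = ("apical", dc_site)
    t_soma = 100.0
    duration = 300.0
    peaks = np.empty(len(dt_grid))
    counts = np.empty(len(dt_grid), dtype=int)
    for k, d in enumerate(dt_grid):
        inj = [(soma, BriefPulse(soma_amp, onset=t_soma, dur=soma_dur)),
               (dend, EpspLike(epsp_amp, onset=t_soma + d))]
        if state == "up":
            inj.append((prox, DCHold(dc_amp, onset=t_soma - 90.0, dur=dc_dur)))
        res = _run(model, inj, duration, {"soma": soma, "dend": dend}, dt,
                   raise_on_divergence=False)
        peaks[k] = res["dend"].values.max()
        counts[k] = len(detect_spikes(res["soma"]))
    spread = peaks.max() - peaks.min()
    window = None
    mask = np.zeros(len(dt_grid), bool)
    if spread > 15.0:
        level = 0.5 * (peaks.max() + peaks.min())
        mask = peaks > level
        best = np.argmax(peaks)
        lo = hi = int(best)
        while lo > 0 and mask[lo - 1]:
            lo -= 1
        while hi < len(mask) - 1 and mask[hi + 1]:
            hi += 1
        window = (float(dt_grid[lo]), float(dt_grid[hi]))
    return {
        "state": state,
        "window": window,
        "dt_grid": dt_grid,
        "peak_dend_v": peaks,
        "ap_counts": counts,
        "ca_spike_mask": mask,
    }


# --------------------------------------------------------------------------
# I_h and dendritic voltage attenuation
# --------------------------------------------------------------------------

def ih_attenuation(model: CellModel, *, amp: float = -0.05, dur: float = 200.0,
                   n_sites: int = 8, dt: float = DT_DEFAULT) -> dict:
    """Steady-state voltage attenuation along the apical dendrites.

    A -50 pA, 200 ms square step at the soma; the steady voltage
    deflection is measured along the apical path, with I_h intact and
    blocked.  Also reports the somatic sag ratio (transient overshoot of
    the deflection relative to its steady value).
    """
    apical = model.cell.region_mask("apical")
    max_d = float(model.cell.path_dist[apical].max())
    distances = np.linspace(0.0, max_d * 0.95, n_sites)
    out = {"distance_um": distances}
    for label, mdl in (("control", model), ("blocked", set_ih_blocked(model))):
        recs = {"soma": ("soma", 0.0)}
        recs.update({f"d{i}": ("apical", d) for i, d in enumerate(distances[1:], 1)})
        pre, post = 20.0, 30.0
        res = _run(mdl, [(("soma", 0.0), Step(amp, onset=pre, dur=dur))],
                   pre + dur + post, recs, dt)
        deflect = np.empty(len(distances))
        sag = np.nan
        for i in range(len(distances)):
            tr = res["soma"] if i == 0 else res[f"d{i}"]
            t, v = tr.t, tr.values
            v0 = v[t < pre][-1]
            steady = v[(t > pre + 0.9 * dur) & (t < pre + dur)].mean() - v0
            if i == 0:
                trough = v[(t > pre) & (t < pre + dur)].min() - v0
                sag = float((trough - steady) / trough)
            deflect[i] = steady
        out[f"deflection_{label}"] = deflect
        out[f"attenuation_{label}"] = deflect / deflect[0]
        out[f"sag_ratio_{label}"] = sag
    return out


# --------------------------------------------------------------------------
# morphology transfer
# --------------------------------------------------------------------------

def transfer_morphology(params: dict, new_morphology: Morphology, *,
                        stats=None, reference_amplitudes: dict | None = None,
                        reference_rin: float | None = None,
                        hot_zone_mode: str = "distance",
                        run_bac: bool = True, run_step: bool = True,
                        **build_kw) -> dict:
    """Re-evaluate a fitted parameter set on a different morphology.

    The model is rebuilt on the new cell (hot zone placed by the
    configured rule); step amplitudes are rescaled by the ratio of input
    resistances so the stimuli are comparable across cells.  Returns the
    per-target feature reports and summary scalars.  Raises when the
    apical tree cannot host the Ca2+ hot zone.
    """
    if stats is None:
        stats = load_feature_stats()
    cell = compartmentalize(new_morphology)
    model = build_cell_model(cell, params, hot_zone_mode=hot_zone_mode, **build_kw)
    rin = measure_input_resistance(model)
    out = {"input_resistance_MOhm": rin, "reports": {}, "scalars": {}}
    if run_step:
        if reference_amplitudes is None:
            amplitudes = normalized_step_amplitudes(model)
        else:
            scale = 1.0 if reference_rin is None else reference_rin / rin
            amplitudes = {k: v * scale for k, v in reference_amplitudes.items()}
        out["step_amplitudes"] = amplitudes
        sp = step_protocol(model, amplitudes, stats=stats,
                           raise_on_divergence=False)
        out["reports"]["step"] = sp.features
        out["scalars"]["step"] = {"fi_curve": sp.scalars["fi_curve"],
                                  "diverged": sp.scalars["diverged"]}
    if run_bac:
        bp = bac_protocol(model, stats=stats, raise_on_divergence=False)
        out["reports"]["bac"] = bp.features
        out["scalars"]["bac"] = {"ap_count": bp.scalars["ap_count"],
                                 "diverged": bp.scalars["diverged"]}
    return out


# --------------------------------------------------------------------------
# target evaluation for the optimizer
# --------------------------------------------------------------------------

def evaluate_targets(params: dict, cell: CompartmentalCell, target: str, *,
                     stats=None, step_amplitudes: dict | None = None,
                     config: dict | None = None):
    """Score a parameter set on the step and/or BAC target.

    Returns ``(objective_vector, FeatureReport)``; diverging simulations
    yield sentinel objectives.  ``step_amplitudes`` must be provided for
    the step target (fixed per morphology, from
    :func:`normalized_step_amplitudes` of a reference model).
    """
    from .moofit import WORST_OBJECTIVE
    config = config or {}
    if stats is None:
        stats = load_feature_stats()
    model = build_cell_model(cell, params,
                             **{k: v for k, v in config.items()
                                if k in ("hot_zone_mode", "hot_zone", "ih_base",
                                         "passive", "rev", "spine_correction")})
    n_obj = {"step": 8, "bac": 5, "both": 13}[target]
    reports = []
    objectives = []
    try:
        if target in ("step", "both"):
            if step_amplitudes is None:
                raise ValueError("step target requires fixed step_amplitudes")
            sp = step_protocol(model, step_amplitudes, stats=stats,
                               raise_on_divergence=False,
                               dur=config.get("step_dur", 2000.0))
            if sp.scalars["diverged"] or sp.features is None:
                raise SimulationDiverged
            reports.append(sp.features)
            objectives.append(group_objectives(sp.features, "step"))
        if target in ("bac", "both"):
            bp = bac_protocol(model, stats=stats, raise_on_divergence=False,
                              **config.get("bac_kwargs", {}))
            if bp.scalars["diverged"] or bp.features is None:
                raise SimulationDiverged
            reports.append(bp.features)
            objectives.append(group_objectives(bp.features, "bac"))
    except SimulationDiverged:
        return np.full(n_obj, WORST_OBJECTIVE), None
    report = reports[0]
    for extra in reports[1:]:
        report = report.combined(extra)
    return np.concatenate(objectives), report


# --------------------------------------------------------------------------
# result serialization
# --------------------------------------------------------------------------

def save_result(result: ProtocolResult, path) -> None:
    """Write a protocol result (traces + scalars + config) to HDF5."""
    import h5py

    def sanitize(obj):
        if isinstance(obj, dict):
            return {k: sanitize(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        if isinstance(obj, Trace):
            return None
        return obj

    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = result.name
        f.attrs["config"] = json.dumps(sanitize(result.config))
        scalars = {k: sanitize(v) for k, v in result.scalars.items()
                   if k != "traces"}
        f.attrs["scalars"] = json.dumps(scalars)
        g = f.create_group("traces")
        for label, tr in result.traces.items():
            tr.to_hdf5(g.create_group(label))


def load_result(path) -> ProtocolResult:
    import h5py
    with h5py.File(path, "r") as f:
        traces = {}

        def visit(name, obj):
            if isinstance(obj, h5py.Group) and "time" in obj:
                traces[name] = Trace.from_hdf5(obj)

        f["traces"].visititems(visit)
        return ProtocolResult(str(f.attrs["protocol"]),
                              json.loads(f.attrs["config"]),
                              traces, json.loads(f.attrs["scalars"]))
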