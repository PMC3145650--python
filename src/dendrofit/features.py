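"""Spike detection and the 20-feature electrophysiology scoring scheme.

Two target firing behaviors are scored.  Perisomatic step-current firing
is summarized by ten features of the somatic response to a 2 s
depolarizing step (rate, regularity, latency, spike shape, AHP shape),
measured at three step amplitudes normalized per cell through the
current that elicits the 15 Hz reference frequency.  BAC firing is
summarized by ten features of the dendritic Ca2+ spike, the somatic
burst, and the back-propagating AP amplitudes at 620 and 800 um.

Each feature error is expressed in units of the experimental standard
deviation, |value - mean| / SD.  Features with zero experimental SD
(spike counts) act as hard constraints: their error is 0 on an exact
match and a large sentinel otherwise.  Features are combined into 8
(step) or 5 (BAC) objectives for the evolutionary search; the grouping
is configurable.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cablesim import Trace

__all__ = [
    "STEP_FEATURES",
    "BAC_FEATURES",
    "STEP_AMPLITUDE_CLASSES",
    "HARD_CONSTRAINT_SENTINEL",
    "STEP_GROUPS_DEFAULT",
    "BAC_GROUPS_DEFAULT",
    "FeatureStats",
    "FeatureReport",
    "load_feature_stats",
    "detect_spikes",
    "spike_shapes",
    "step_features",
    "bac_features",
    "feature_error",
    "normalize_fi",
    "group_objectives",
]

STEP_FEATURES = (
    "spike_frequency", "adaptation_index", "isi_cv", "initial_burst_isi",
    "first_spike_latency", "ap_peak", "fast_ahp_depth", "slow_ahp_depth",
    "slow_ahp_time", "ap_half_width",
)
BAC_FEATURES = (
    "ca_spike_peak", "ca_spike_width", "ap_count_coincident", "mean_ap_isi",
    "ahp_depth", "ap_peak", "ap_half_width", "ap_count_soma_only",
    "bap_amp_620", "bap_amp_800",
)
STEP_AMPLITUDE_CLASSES = ("low", "ref", "high")
HARD_CONSTRAINT_SENTINEL = 250.0  # SD units; dominates any soft error
SPIKE_THRESHOLD_DEFAULT = -20.0  # mV
CA_SPIKE_BASE = -55.0  # mV, width measured at the base of the Ca2+ spike
FAST_AHP_WINDOW = 5.0  # ms, fast/slow AHP split within an ISI

# default objective grouping: 30 step feature values (10 features x 3
# amplitudes, averaged across amplitudes) -> 8 objectives; 10 BAC
# features -> 5 objectives
STEP_GROUPS_DEFAULT = (
    ("spike_frequency",),
    ("adaptation_index",),
    ("isi_cv",),
    ("initial_burst_isi",),
    ("first_spike_latency",),
    ("ap_peak", "ap_half_width"),
    ("fast_ahp_depth",),
    ("slow_ahp_depth", "slow_ahp_time"),
)
BAC_GROUPS_DEFAULT = (
    ("ca_spike_peak", "ca_spike_width"),
    ("ap_count_coincident", "ap_count_soma_only"),
    ("mean_ap_isi",),
    ("ahp_depth", "ap_peak", "ap_half_width"),
    ("bap_amp_620", "bap_amp_800"),
)


# --------------------------------------------------------------------------
# experimental statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureStats:
    """Experimental mean and SD per feature and stimulus class."""

    table: pd.DataFrame  # columns: target, stimulus, feature, mean, sd, unit

    def get(self, feature: str, stimulus: str) -> tuple[float, float]:
        row = self.table[(self.table.feature == feature)
                         & (self.table.stimulus == stimulus)]
        if len(row) != 1:
            raise KeyError(f"no statistics for {feature!r} / {stimulus!r}")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    def features(self, target: str) -> list[tuple[str, str]]:
        sub = self.table[self.table.target == target]
        return list(zip(sub.stimulus, sub.feature))


def load_feature_stats(path: str | Path | None = None) -> FeatureStats:
    """Load the shipped experimental feature statistics (or a custom CSV)."""
    if path is None:
        ref = importlib.resources.files("dendrofit") / "data" / "feature_stats.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if (table.sd < 0).any():
        raise ValueError("feature SDs must be non-negative")
    return FeatureStats(table)


# --------------------------------------------------------------------------
# spike detection and shape measurements
# --------------------------------------------------------------------------

def detect_spikes(trace: Trace | np.ndarray, threshold: float = SPIKE_THRESHOLD_DEFAULT,
                  t: np.ndarray | None = None, refractory: float = 1.0) -> np.ndarray:
    """Times (ms) of positive-going threshold crossings.

    Crossing times are linearly interpolated between samples; crossings
    within ``refractory`` ms of the previous one are ignored.
    """
    if isinstance(trace, Trace):
        v, t = trace.values, trace.t
    else:
        v = np.asarray(trace, dtype=float)
        if t is None:
            raise ValueError("time grid required for array input")
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if not times or tc - times[-1] >= refractory:
            times.append(tc)
    return np.array(times)


ONSET_SLOPE = 20.0  # mV/ms, dV/dt criterion locating the AP onset voltage


def spike_shapes(trace: Trace, threshold: float = SPIKE_THRESHOLD_DEFAULT):
    """Per-spike peak voltage, peak time, and half-width.

    Half-width is measured at half height between the spike's
    threshold-crossing (onset) voltage and its peak.  The onset is where
    dV/dt first exceeds 20 mV/ms ahead of the detection crossing — the
    usual electrophysiology convention for the AP threshold voltage.
    """
    v, t = trace.values, trace.t
    dt = t[1] - t[0]
    crossings = detect_spikes(trace, threshold)
    peaks, peak_times, widths = [], [], []
    for tc in crossings:
        i0 = int(np.searchsorted(t, tc))
        # spike window: until V falls back below threshold (or trace end)
        below = np.flatnonzero(v[i0:] < threshold)
        i1 = i0 + (below[0] if len(below) else len(v) - i0)
        seg = slice(max(i0 - 1, 0), min(i1 + 1, len(v)))
        k = np.argmax(v[seg]) + seg.start
        peak = v[k]
        # walk back to the onset (dV/dt below the slope criterion)
        j = i0
        while j > 1 and (v[j] - v[j - 1]) / dt > ONSET_SLOPE:
            j -= 1
        onset_v = v[j]
        half = 0.5 * (onset_v + peak)
        lo = max(j - 1, 0)
        t_up = _cross_time(t, v, half, lo, k, rising=True)
        hi = min(i1 + int(round(5.0 / dt)), len(v) - 1)  # within 5 ms of repolarization
        t_down = _cross_time(t, v, half, k, hi, rising=False)
        peaks.append(peak)
        peak_times.append(t[k])
        widths.append(t_down - t_up if (t_up is not None and t_down is not None)
                      else np.nan)
    return np.array(peaks), np.array(peak_times), np.array(widths)


def _cross_time(t, v, level, lo, hi, rising: bool):
    for i in range(lo, hi) if rising else range(hi - 1, lo - 1, -1):
        a, b = v[i], v[i + 1]
        if (a < level <= b) if rising else (a >= level > b):
            frac = (level - a) / (b - a)
            return t[i] + frac * (t[i + 1] - t[i])
    return None


# --------------------------------------------------------------------------
# step-current features
# --------------------------------------------------------------------------

def step_features(trace: Trace, onset: float, dur: float,
                  threshold: float = SPIKE_THRESHOLD_DEFAULT) -> dict:
    """The ten features of the somatic response to a current step.

    Features that need spikes (or >= 2 spikes) are NaN when undefined;
    scoring maps NaN to the worst-case sentinel error.
    """
    spikes = detect_spikes(trace, threshold)
    spikes = spikes[(spikes >= onset) & (spikes <= onset + dur)]
    out = {name: np.nan for name in STEP_FEATURES}
    out["spike_frequency"] = len(spikes) / (dur / 1000.0)
    if len(spikes) >= 1:
        out["first_spike_latency"] = spikes[0] - onset
    peaks, peak_times, widths = spike_shapes(trace, threshold)
    in_step = (peak_times >= onset) & (peak_times <= onset + dur)
    if in_step.any():
        out["ap_peak"] = float(np.mean(peaks[in_step]))
        out["ap_half_width"] = float(np.nanmean(widths[in_step]))
    if len(spikes) >= 2:
        isis = np.diff(spikes)
        out["initial_burst_isi"] = float(isis[0])
        out["isi_cv"] = float(np.std(isis) / np.mean(isis))  # population SD
        fast, slow, slow_t = _ahp_features(trace, peak_times[in_step])
        out["fast_ahp_depth"] = fast
        out["slow_ahp_depth"] = slow
        out["slow_ahp_time"] = slow_t
    if len(spikes) >= 3:
        isis = np.diff(spikes)
        pair = (isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])
        out["adaptation_index"] = float(np.mean(pair))
    return out


def _ahp_features(trace: Trace, peak_times: np.ndarray):
    """Mean fast/slow AHP depth and slow-AHP time over all ISIs.

    The ISI window runs between consecutive AP peaks; the fast AHP is the
    minimum within the first 5 ms, the slow AHP the minimum afterwards,
    and the slow-AHP time is reported as a fraction of the ISI duration.
    """
    v, t = trace.values, trace.t
    fasts, slows, slow_ts = [], [], []
    for t0, t1 in zip(peak_times[:-1], peak_times[1:]):
        i0, i1 = np.searchsorted(t, t0), np.searchsorted(t, t1)
        isplit = np.searchsorted(t, min(t0 + FAST_AHP_WINDOW, t1))
        if isplit > i0:
            fasts.append(v[i0:isplit].min())
        if i1 > isplit:
            k = int(np.argmin(v[isplit:i1])) + isplit
            slows.append(v[k])
            slow_ts.append((t[k] - t0) / (t1 - t0))
    return (float(np.mean(fasts)) if fasts else np.nan,
            float(np.mean(slows)) if slows else np.nan,
            float(np.mean(slow_ts)) if slow_ts else np.nan)


# --------------------------------------------------------------------------
# BAC-firing features
# --------------------------------------------------------------------------

def bac_features(soma_coincident: Trace, hot_coincident: Trace,
                 soma_only: Trace, dend_620: Trace, dend_800: Trace,
                 threshold: float = SPIKE_THRESHOLD_DEFAULT) -> dict:
    """The ten features of BAC firing.

    ``soma_coincident``/``hot_coincident`` come from the coincident
    soma + dendrite phase; ``soma_only`` and the two dendritic traces
    from the phase with somatic injection alone.  BAP amplitudes are
    measured against the local resting potential (the first sample),
    which differs distally because of I_h.
    """
    out = {name: np.nan for name in BAC_FEATURES}
    spikes = detect_spikes(soma_coincident, threshold)
    out["ap_count_coincident"] = float(len(spikes))
    if len(spikes) >= 2:
        out["mean_ap_isi"] = float(np.mean(np.diff(spikes)))
    peaks, peak_times, widths = spike_shapes(soma_coincident, threshold)
    if len(peaks):
        out["ap_peak"] = float(np.mean(peaks))
        out["ap_half_width"] = float(np.nanmean(widths))
    if len(peak_times) >= 2:
        mins = []
        v, t = soma_coincident.values, soma_coincident.t
        for t0, t1 in zip(peak_times[:-1], peak_times[1:]):
            i0, i1 = np.searchsorted(t, t0), np.searchsorted(t, t1)
            if i1 > i0:
                mins.append(v[i0:i1].min())
        if mins:
            out["ahp_depth"] = float(np.mean(mins))
    out["ca_spike_peak"] = float(hot_coincident.values.max())
    out["ca_spike_width"] = ca_spike_width(hot_coincident)
    out["ap_count_soma_only"] = float(len(detect_spikes(soma_only, threshold)))
    for name, tr in (("bap_amp_620", dend_620), ("bap_amp_800", dend_800)):
        rest = tr.values[0]
        out[name] = float(tr.values.max() - rest)
    return out


def ca_spike_width(trace: Trace, base: float = CA_SPIKE_BASE) -> float:
    """Width (ms) of the dendritic Ca2+ spike at its base voltage.

    The longest contiguous excursion above the base level, with the
    crossing times linearly interpolated.
    """
    v, t = trace.values, trace.t
    above = v > base
    if not above.any():
        return np.nan
    best = 0.0
    i = 0
    n = len(v)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        t_start = t[i] if i == 0 else _interp_cross(t, v, base, i - 1)
        t_end = t[j - 1] if j == n else _interp_cross(t, v, base, j - 1)
        best = max(best, t_end - t_start)
        i = j
    return float(best)


def _interp_cross(t, v, level, i):
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return t[i] + frac * (t[i + 1] - t[i])


# --------------------------------------------------------------------------
# errors, f-I normalization, objectives
# --------------------------------------------------------------------------

def feature_error(value: float, mean: float, sd: float,
                  sentinel: float = HARD_CONSTRAINT_SENTINEL) -> float:
    """Error in SD units; hard constraint (indicator) when SD = 0."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return sentinel
    if sd == 0:
        return 0.0 if value == mean else sentinel
    return abs(value - mean) / sd


def normalize_fi(fi_points, reference_freq: float = 15.0,
                 ratios: tuple[float, float] = (0.78, 1.90)) -> dict:
    """Normalize an f-I curve via the current producing the reference
    frequency (15 Hz).

    ``fi_points`` is a sequence of (current nA, frequency Hz) pairs.
    Returns the reference current and the low/reference/high step
    amplitudes (78%, 100% and 190% of the reference current).
    """
    pts = sorted((float(i), float(f)) for i, f in fi_points)
    currents = np.array([p[0] for p in pts])
    freqs = np.array([p[1] for p in pts])
    above = freqs >= reference_freq
    if not above.any() or above.all() or freqs[0] >= reference_freq:
        raise ValueError(f"f-I points do not bracket {reference_freq} Hz")
    j = int(np.argmax(above))
    i0, i1 = currents[j - 1], currents[j]
    f0, f1 = freqs[j - 1], freqs[j]
    i_ref = i0 + (reference_freq - f0) * (i1 - i0) / (f1 - f0)
    return {
        "i_ref": float(i_ref),
        "amplitudes": {"low": ratios[0] * i_ref, "ref": float(i_ref),
                       "high": ratios[1] * i_ref},
    }


@dataclass
class FeatureReport:
    """Per-feature values and SD-unit errors for one model evaluation."""

    rows: pd.DataFrame  # columns: target, stimulus, feature, value, mean, sd, error
    complete: bool = True

    @classmethod
    def from_values(cls, values: dict, stats: FeatureStats, target: str,
                    complete: bool = True) -> "FeatureReport":
        """``values`` maps (stimulus, feature) -> measured value."""
        recs = []
        for stimulus, feature in stats.features(target):
            val = values.get((stimulus, feature), np.nan)
            mean, sd = stats.get(feature, stimulus)
            recs.append({"target": target, "stimulus": stimulus,
                         "feature": feature, "value": val, "mean": mean,
                         "sd": sd, "error": feature_error(val, mean, sd)})
        return cls(pd.DataFrame(recs), complete=complete)

    @property
    def errors(self) -> pd.Series:
        return self.rows.set_index(["stimulus", "feature"])["error"]

    @property
    def max_error(self) -> float:
        return float(self.rows.error.max())

    def acceptable(self, cutoff_sd: float = 3.0) -> bool:
        """All per-feature errors within the SD cutoff."""
        return bool(self.complete and (self.rows.error <= cutoff_sd).all())

    def combined(self, other: "FeatureReport") -> "FeatureReport":
        return FeatureReport(pd.concat([self.rows, other.rows],
                                       ignore_index=True),
                             complete=self.complete and other.complete)

    def to_csv(self, path) -> None:
        self.rows.to_csv(Path(path), index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.rows.to_dict("records"), indent=1))


def group_objectives(report: FeatureReport, target: str,
                     groups=None) -> np.ndarray:
    """Combine feature errors into the objective vector (8 step / 5 BAC).

    Each objective is the mean error over its member features, averaged
    across stimulus amplitudes for the step target.
    """
    if groups is None:
        groups = STEP_GROUPS_DEFAULT if target == "step" else BAC_GROUPS_DEFAULT
    sub = report.rows[report.rows.target == target]
    out = np.empty(len(groups))
    for g, members in enumerate(groups):
        sel = sub[sub.feature.isin(members)]
        if sel.empty:
            raise ValueError(f"objective group {members} matched no features")
        out[g] = float(sel.error.mean())
    return out
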