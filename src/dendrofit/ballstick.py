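"""Ball-and-stick parameter-recovery harness for the fitting engine.

A deliberately small ground-truth problem: a spherical soma with one
passive apical cable, five free somatic parameters (Na_t, K_t, Kv3.1 and
SK densities plus the leak density), and target features generated by
simulating the known ground-truth model itself.  Because the target is
produced by the same forward model, a correct optimizer must find
parameter sets whose features fall within the synthetic SDs — a direct
test of the evolutionary search, independent of experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cablesim import (DensityRule, Step, StimulusProtocol, build_cell_model,
                       simulate)
from .features import step_features
from .moofit import ParameterSpace, run_moo, select_acceptable
from .morphology import Morphology, Section, compartmentalize

__all__ = [
    "BALLSTICK_TRUTH",
    "BALLSTICK_BOUNDS",
    "ballstick_morphology",
    "build_ballstick_model",
    "ballstick_space",
    "ballstick_features",
    "make_ballstick_evaluator",
    "recovery_harness",
]

# ground-truth somatic densities (pS/um^2) and leak
BALLSTICK_TRUTH = {
    "s.gbar_Na_t": 25000.0,
    "s.gbar_K_t": 500.0,
    "s.gbar_Kv3.1": 9000.0,
    "s.gbar_SK": 300.0,
    "s.g_leak": 0.3,
}
BALLSTICK_BOUNDS = {
    "s.gbar_Na_t": (0.0, 40000.0),
    "s.gbar_K_t": (0.0, 1000.0),
    "s.gbar_Kv3.1": (0.0, 20000.0),
    "s.gbar_SK": (0.0, 1000.0),
    "s.g_leak": (0.2, 0.5),
}
# five spike-train/shape features scored against the ground truth, with
# synthetic SDs (a 5% relative scale with an absolute floor)
BALLSTICK_FEATURES = ("spike_frequency", "ap_peak", "ap_half_width",
                     "fast_ahp_depth", "first_spike_latency")
_SD_FLOOR = {"spike_frequency": 0.5, "ap_peak": 1.0, "ap_half_width": 0.05,
             "fast_ahp_depth": 1.0, "first_spike_latency": 1.0}
STEP_AMP = 0.12  # nA, drives the ground-truth model near 15 Hz
STEP_DUR = 600.0  # ms
STEP_ONSET = 20.0  # ms
DT = 0.05  # ms


def ballstick_morphology() -> Morphology:
    """Spherical soma (20 um) plus a single 300 um apical cable."""
    soma = Section("soma", [[0.0, 0.0, 0.0]], [20.0], None)
    pts = [[0.0, 10.0 + 20.0 * k, 0.0] for k in range(16)]
    stick = Section("apical", np.array(pts), np.full(16, 2.0), 0)
    return Morphology([soma, stick], identifier="ballstick")


def build_ballstick_model(params: dict):
    """Bind somatic densities to the ball-and-stick cell (passive stick)."""
    cell = compartmentalize(ballstick_morphology())
    rules = [DensityRule(ch, "soma", "uniform",
                         {"density": params.get(f"s.gbar_{ch}", 0.0)})
             for ch in ("Na_t", "K_t", "Kv3.1", "SK")]
    return build_cell_model(cell, params, rules=rules)


def ballstick_space() -> ParameterSpace:
    names = tuple(BALLSTICK_BOUNDS)
    lo = np.array([BALLSTICK_BOUNDS[n][0] for n in names])
    hi = np.array([BALLSTICK_BOUNDS[n][1] for n in names])
    return ParameterSpace(names, lo, hi)


def ballstick_features(params: dict) -> dict:
    """Forward-simulate a parameter set and extract the scored features."""
    model = build_ballstick_model(params)
    prot = StimulusProtocol([(("soma", 0.0),
                              Step(STEP_AMP, onset=STEP_ONSET, dur=STEP_DUR))],
                            duration=STEP_ONSET + STEP_DUR + 30.0, dt=DT)
    res = simulate(model, prot, recordings={"soma": ("soma", 0.0)},
                   init_duration=300.0, raise_on_divergence=False)
    if res.diverged:
        return {}
    return step_features(res["soma"], STEP_ONSET, STEP_DUR)


def make_ballstick_evaluator(targets: dict | None = None):
    """Evaluator mapping a parameter vector to per-feature SD errors.

    ``targets`` defaults to the features of the ground-truth model.
    Objectives equal the per-feature errors (5 objectives).
    """
    space = ballstick_space()
    if targets is None:
        targets = {k: v for k, v in ballstick_features(BALLSTICK_TRUTH).items()
                   if k in BALLSTICK_FEATURES}
    sds = {k: max(0.05 * abs(v), _SD_FLOOR[k]) for k, v in targets.items()}

    def evaluator(x):
        feats = ballstick_features(space.to_dict(x))
        if not feats:
            return None
        errs = np.array([
            abs(feats[k] - targets[k]) / sds[k]
            if np.isfinite(feats.get(k, np.nan)) else 250.0
            for k in BALLSTICK_FEATURES])
        return errs, errs

    return evaluator, targets, sds


def recovery_harness(seed: int = 1, pop_size: int = 64, n_gen: int = 50,
                     cutoff_sd: float = 2.0):
    """End-to-end ground-truth recovery run.

    Returns ``(result, acceptable_set, space)``; success means at least
    one model within ``cutoff_sd`` on every feature.
    """
    evaluator, _, _ = make_ballstick_evaluator()
    space = ballstick_space()
    result = run_moo(space, evaluator, pop_size, n_gen, seed)
    acc = select_acceptable(result.populations, space, cutoff_sd)
    return result, acc, space
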