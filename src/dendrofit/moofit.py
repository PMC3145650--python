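"""Multi-objective evolutionary fitting of channel densities.

The free parameters are the 22 maximal conductance densities, leak
densities and Ca2+-dynamics parameters of the L5b model (somatic,
axonal, basal and apical partitions), each bounded by biologically
plausible limits.  Candidate models are scored by the SD-unit feature
errors grouped into objectives, and the search is an elitist
non-dominated sorting genetic algorithm (NSGA-II style): binary
tournament on rank and crowding distance, simulated binary crossover,
bounded polynomial mutation, and environmental selection that merges
parents and offspring.

A model is *acceptable* when every individual feature error (not the
grouped objectives) is within the SD cutoff (2-3 SD; default 3).  Sets
of acceptable models delineate per-parameter ranges, reported normalized
by the upper bounds so that 1 corresponds to the upper limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_BOUNDS",
    "TABLE3_PARAMS",
    "APICAL_PARAMS",
    "DENDRITIC_PARAMS",
    "ParameterSpace",
    "Individual",
    "AcceptableSet",
    "MooResult",
    "table2_space",
    "evaluate",
    "nondominated_sort",
    "crowding_distance",
    "run_moo",
    "select_acceptable",
    "parameter_ranges",
    "compare_ranges",
    "two_stage_fit",
    "WORST_OBJECTIVE",
]

WORST_OBJECTIVE = 1e6  # sentinel objective for failed simulations

# free-parameter limits (densities pS/um^2, tau_decay ms, gamma unitless);
# apical Ca2+ densities refer to the hot zone
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "s.gbar_Na_t": (0.0, 40000.0),
    "s.gbar_Na_p": (0.0, 100.0),
    "s.gbar_K_p": (0.0, 10000.0),
    "s.gbar_K_t": (0.0, 1000.0),
    "s.gbar_Kv3.1": (0.0, 20000.0),
    "s.gbar_Ca_HVA": (0.0, 10.0),
    "s.gbar_Ca_LVA": (0.0, 100.0),
    "s.gbar_SK": (0.0, 1000.0),
    "s.tau_decay": (20.0, 1000.0),
    "s.gamma": (0.0005, 0.05),
    "s.g_leak": (0.2, 0.5),
    "ax.g_leak": (0.2, 0.5),
    "b.g_leak": (0.15, 0.5),
    "a.g_leak": (0.15, 0.5),
    "a.gbar_Na_t": (0.0, 200.0),
    "a.gbar_Kv3.1": (0.0, 200.0),
    "a.gbar_Ca_HVA": (0.0, 25.0),
    "a.gbar_Ca_LVA": (0.0, 1000.0),
    "a.gbar_SK": (0.0, 50.0),
    "a.gbar_I_m": (0.0, 5.0),
    "a.tau_decay": (20.0, 200.0),
    "a.gamma": (0.0005, 0.05),
}

# the published dually-constrained reference parameter set
TABLE3_PARAMS: dict[str, float] = {
    "s.gbar_Na_t": 20400.0,
    "s.gbar_Na_p": 17.2,
    "s.gbar_K_p": 22.3,
    "s.gbar_K_t": 812.0,
    "s.gbar_SK": 441.0,
    "s.gbar_Kv3.1": 6930.0,
    "s.gbar_Ca_HVA": 9.92,
    "s.gbar_Ca_LVA": 34.3,
    "s.gamma": 0.000501,
    "s.tau_decay": 460.0,
    "s.g_leak": 0.338,
    "ax.g_leak": 0.325,
    "b.g_leak": 0.234,
    "a.g_leak": 0.295,
    "a.gbar_Na_t": 107.0,
    "a.gbar_Kv3.1": 1.31,
    "a.gbar_Ca_HVA": 2.78,
    "a.gbar_Ca_LVA": 93.5,
    "a.gbar_SK": 6.0,
    "a.gbar_I_m": 0.338,
    "a.tau_decay": 122.0,
    "a.gamma": 0.000509,
}

APICAL_PARAMS = tuple(n for n in PARAM_BOUNDS if n.startswith("a."))
# the dendritic partition frozen in stage 2 of the two-stage fit
DENDRITIC_PARAMS = APICAL_PARAMS + ("b.g_leak",)


@dataclass(frozen=True)
class ParameterSpace:
    """Named, bounded free parameters with an optional frozen mask.

    Frozen entries keep their stored value during optimization (used to
    fix the dendritic parameters in stage 2 of the two-stage fit).
    """

    names: tuple
    lower: np.ndarray
    upper: np.ndarray
    frozen: np.ndarray = None  # bool mask
    frozen_values: np.ndarray = None

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, float))
        object.__setattr__(self, "upper", np.asarray(self.upper, float))
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds must not exceed upper bounds")
        if self.frozen is None:
            object.__setattr__(self, "frozen", np.zeros(len(self.names), bool))
            object.__setattr__(self, "frozen_values", np.zeros(len(self.names)))

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def n_free(self) -> int:
        return int((~self.frozen).sum())

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, float)
        return bool(np.all(x >= self.lower - 1e-12) and np.all(x <= self.upper + 1e-12))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def apply_mask(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.frozen, self.frozen_values, x)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Uniform-in-bounds initial sampling (seeded)."""
        x = rng.uniform(self.lower, self.upper, size=(size, self.n))
        return np.where(self.frozen[None, :], self.frozen_values[None, :], x)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """Normalized values: 1 corresponds to the upper limit."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.upper != 0, np.asarray(x) / self.upper, 0.0)

    def to_dict(self, x: np.ndarray) -> dict:
        return dict(zip(self.names, np.asarray(x, float)))

    def freeze(self, names, values: dict) -> "ParameterSpace":
        frozen = self.frozen.copy()
        fvals = self.frozen_values.copy()
        for nm in names:
            i = self.names.index(nm)
            frozen[i] = True
            fvals[i] = values[nm]
        return ParameterSpace(self.names, self.lower, self.upper, frozen, fvals)


def table2_space() -> ParameterSpace:
    """The canonical 22-parameter space."""
    names = tuple(PARAM_BOUNDS)
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])
    return ParameterSpace(names, lo, hi)


@dataclass
class Individual:
    """One candidate model with its evaluation results."""

    params: np.ndarray
    objectives: np.ndarray = None
    feature_errors: np.ndarray = None  # per-feature SD errors (acceptance basis)
    failed: bool = False
    generation: int = -1
    seed: int = 0


# --------------------------------------------------------------------------
# non-dominated sorting and crowding
# --------------------------------------------------------------------------

def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_sort(objectives) -> list[np.ndarray]:
    """Partition objective vectors into Pareto fronts (front 0 first).

    Accepts an (n, m) array or a population of Individuals.
    """
    if len(objectives) and isinstance(objectives[0], Individual):
        objs = np.array([ind.objectives for ind in objectives], float)
    else:
        objs = np.asarray(objectives, float)
    n = len(objs)
    dominated_by = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif _dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = np.flatnonzero(dom_count == 0)
    while len(current):
        fronts.append(np.array(sorted(current)))
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(nxt, dtype=int)
    return fronts


def crowding_distance(objs: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front."""
    objs = np.asarray(objs, float)
    n, m = objs.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(objs[:, k], kind="stable")
        span = objs[order[-1], k] - objs[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span == 0:
            continue
        dist[order[1:-1]] += (objs[order[2:], k] - objs[order[:-2], k]) / span
    return dist


def _rank_and_crowd(pop: list[Individual]):
    fronts = nondominated_sort(pop)
    rank = np.empty(len(pop), dtype=int)
    crowd = np.empty(len(pop))
    for r, front in enumerate(fronts):
        rank[front] = r
        crowd[front] = crowding_distance(
            np.array([pop[i].objectives for i in front]))
    return rank, crowd, fronts


# --------------------------------------------------------------------------
# variation operators (SBX crossover, polynomial mutation)
# --------------------------------------------------------------------------

def _sbx(rng, p1, p2, lo, hi, eta, p_cx):
    c1, c2 = p1.copy(), p2.copy()
    if rng.uniform() > p_cx:
        return c1, c2
    for k in range(len(p1)):
        if rng.uniform() > 0.5 or hi[k] == lo[k]:
            continue
        x1, x2 = min(p1[k], p2[k]), max(p1[k], p2[k])
        if x2 - x1 < 1e-14:
            continue
        u = rng.uniform()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else \
            (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[k] = 0.5 * ((1 + beta) * x1 + (1 - beta) * x2)
        c2[k] = 0.5 * ((1 - beta) * x1 + (1 + beta) * x2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutate(rng, x, lo, hi, eta, p_mut):
    y = x.copy()
    for k in range(len(x)):
        if rng.uniform() > p_mut or hi[k] == lo[k]:
            continue
        u = rng.uniform()
        delta = (2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5 else \
            1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[k] = x[k] + delta * (hi[k] - lo[k])
    return np.clip(y, lo, hi)


def _tournament(rng, pop, rank, crowd):
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    if rank[i] < rank[j] or (rank[i] == rank[j] and crowd[i] > crowd[j]):
        return i
    return j


# --------------------------------------------------------------------------
# the optimization loop
# --------------------------------------------------------------------------

@dataclass
class MooResult:
    """Archived populations of one optimization run."""

    populations: list  # list per generation of list[Individual]
    space: ParameterSpace
    seed: int

    @property
    def final(self) -> list[Individual]:
        return self.populations[-1]

    def all_individuals(self) -> list[Individual]:
        return [ind for pop in self.populations for ind in pop]


def _evaluate_individual(evaluator, space: ParameterSpace, ind: Individual,
                         n_obj_hint: list):
    x = space.apply_mask(ind.params)
    ind.params = x
    try:
        out = evaluator(x)
    except Exception:
        out = None
    if out is None:
        ind.failed = True
        n_obj = n_obj_hint[0] if n_obj_hint else 1
        ind.objectives = np.full(n_obj, WORST_OBJECTIVE)
        ind.feature_errors = np.array([WORST_OBJECTIVE])
        return
    if isinstance(out, tuple):
        objectives, ferrs = out
    else:
        objectives, ferrs = out, out
    ind.objectives = np.asarray(objectives, float)
    ind.feature_errors = np.asarray(ferrs, float)
    if not np.all(np.isfinite(ind.objectives)):
        ind.failed = True
        ind.objectives = np.full_like(ind.objectives, WORST_OBJECTIVE)
    if not n_obj_hint:
        n_obj_hint.append(len(ind.objectives))


def run_moo(space: ParameterSpace, evaluator, pop_size: int, n_gen: int,
            seed: int, *, eta_crossover: float = 15.0,
            eta_mutation: float = 20.0, p_crossover: float = 0.9,
            p_mutation: float | None = None) -> MooResult:
    """Elitist non-dominated sorting evolutionary optimization.

    ``evaluator(x)`` maps a parameter vector to an objective vector, or
    to ``(objectives, per_feature_errors)``; raising or returning None
    marks the individual as a failed simulation with sentinel
    objectives.  Every generation is archived; runs are bit-reproducible
    for a given seed (sequential evaluation).
    """
    if pop_size % 2:
        raise ValueError("pop_size must be even")
    rng = np.random.default_rng(seed)
    if p_mutation is None:
        p_mutation = 1.0 / space.n
    n_obj_hint: list = []
    pop = [Individual(x, generation=0, seed=seed) for x in space.sample(rng, pop_size)]
    for ind in pop:
        _evaluate_individual(evaluator, space, ind, n_obj_hint)
    archive = [list(pop)]
    rank, crowd, _ = _rank_and_crowd(pop)
    for gen in range(1, n_gen + 1):
        offspring = []
        while len(offspring) < pop_size:
            i = _tournament(rng, pop, rank, crowd)
            j = _tournament(rng, pop, rank, crowd)
            c1, c2 = _sbx(rng, pop[i].params, pop[j].params, space.lower,
                          space.upper, eta_crossover, p_crossover)
            for c in (c1, c2):
                c = _poly_mutate(rng, c, space.lower, space.upper,
                                 eta_mutation, p_mutation)
                offspring.append(Individual(c, generation=gen, seed=seed))
        offspring = offspring[:pop_size]
        for ind in offspring:
            _evaluate_individual(evaluator, space, ind, n_obj_hint)
        merged = pop + offspring
        rank_m, crowd_m, fronts = _rank_and_crowd(merged)
        chosen: list[int] = []
        for front in fronts:
            if len(chosen) + len(front) <= pop_size:
                chosen.extend(front.tolist())
            else:
                room = pop_size - len(chosen)
                order = sorted(front, key=lambda i: -crowd_m[i])
                chosen.extend(order[:room])
                break
        pop = [merged[i] for i in chosen]
        rank, crowd, _ = _rank_and_crowd(pop)
        archive.append(list(pop))
    return MooResult(archive, space, seed)


# --------------------------------------------------------------------------
# acceptable models and parameter ranges
# --------------------------------------------------------------------------

@dataclass
class AcceptableSet:
    """Models whose every feature error is within the SD cutoff."""

    individuals: list
    space: ParameterSpace
    cutoff_sd: float

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def params_array(self) -> np.ndarray:
        return np.array([ind.params for ind in self.individuals])


def select_acceptable(populations, space: ParameterSpace,
                      cutoff_sd: float = 3.0) -> AcceptableSet:
    """Filter archived populations on per-feature (not grouped) errors.

    Duplicated parameter vectors are dropped.
    """
    if cutoff_sd <= 0:
        raise ValueError("cutoff_sd must be positive")
    if populations and isinstance(populations[0], Individual):
        populations = [populations]
    seen = set()
    accepted = []
    for pop in populations:
        for ind in pop:
            if ind.failed or ind.feature_errors is None:
                continue
            if float(np.max(ind.feature_errors)) > cutoff_sd:
                continue
            key = ind.params.tobytes()
            if key in seen:
                continue
            seen.add(key)
            accepted.append(ind)
    return AcceptableSet(accepted, space, cutoff_sd)


def parameter_ranges(acceptable: AcceptableSet) -> pd.DataFrame:
    """Per-parameter [min, max], raw and normalized by the upper limits."""
    if len(acceptable) == 0:
        raise ValueError("empty acceptable set")
    arr = acceptable.params_array
    space = acceptable.space
    norm = space.normalize(arr)
    return pd.DataFrame({
        "parameter": list(space.names),
        "min": arr.min(axis=0),
        "max": arr.max(axis=0),
        "min_normalized": norm.min(axis=0),
        "max_normalized": norm.max(axis=0),
    })


def compare_ranges(set_a: AcceptableSet, set_b: AcceptableSet,
                   labels=("a", "b")) -> pd.DataFrame:
    """Range overlap/shift comparison between two acceptable sets."""
    ra = parameter_ranges(set_a).set_index("parameter")
    rb = parameter_ranges(set_b).set_index("parameter")
    lo = np.maximum(ra["min_normalized"], rb["min_normalized"])
    hi = np.minimum(ra["max_normalized"], rb["max_normalized"])
    out = pd.DataFrame({
        f"{labels[0]}_min": ra["min_normalized"],
        f"{labels[0]}_max": ra["max_normalized"],
        f"{labels[1]}_min": rb["min_normalized"],
        f"{labels[1]}_max": rb["max_normalized"],
        "overlap": np.maximum(hi - lo, 0.0),
        "shift": (rb["min_normalized"] + rb["max_normalized"]) / 2
        - (ra["min_normalized"] + ra["max_normalized"]) / 2,
    })
    return out.reset_index()


# --------------------------------------------------------------------------
# model evaluation against the experimental targets
# --------------------------------------------------------------------------

def evaluate(params, cell, target: str = "both", *, stats=None,
             step_amplitudes=None, config=None):
    """Score one parameter set on the step and/or BAC target.

    Builds the cell model, runs the target protocols, extracts features
    and returns ``(objective_vector, FeatureReport)``.  A diverging
    simulation yields sentinel objectives.
    """
    from . import experiments  # runtime import; experiments sits above moofit

    space = table2_space()
    if isinstance(params, np.ndarray):
        params = space.to_dict(params)
    for name, val in params.items():
        if name in PARAM_BOUNDS:
            lo, hi = PARAM_BOUNDS[name]
            if not (lo - 1e-12 <= val <= hi + 1e-12):
                raise ValueError(f"parameter {name}={val} outside bounds [{lo}, {hi}]")
    return experiments.evaluate_targets(params, cell, target, stats=stats,
                                        step_amplitudes=step_amplitudes,
                                        config=config)


def two_stage_fit(space: ParameterSpace, evaluator_bac, evaluator_other,
                  evaluator_both_factory, *, pop_size: int = 64,
                  n_gen: int = 25, seed: int = 1, cutoff_sd: float = 3.0,
                  stage1_result: MooResult | None = None,
                  max_rank_candidates: int | None = None,
                  frozen_names=DENDRITIC_PARAMS):
    """Two-stage dually-constrained fit.

    Stage 1 fits the BAC target.  Its acceptable models are re-scored on
    the other (step) target with ``evaluator_other``; the model with the
    smallest maximal per-feature SD error there donates its dendritic
    parameters (apical partition plus basal leak), which are frozen.
    Stage 2 then reoptimizes the perisomatic parameters against the
    union of both targets using the evaluator built by
    ``evaluator_both_factory(frozen_space)``.  Returns
    ``(dually_acceptable_set, stage1_result, stage2_result)``.
    """
    if stage1_result is None:
        stage1_result = run_moo(space, evaluator_bac, pop_size, n_gen, seed)
    acc1 = select_acceptable(stage1_result.populations, space, cutoff_sd)
    if len(acc1) == 0:
        best_err = min(
            (float(np.max(i.feature_errors)) for pop in stage1_result.populations
             for i in pop if i.feature_errors is not None and not i.failed),
            default=float("inf"))
        raise RuntimeError("stage 1 produced no acceptable BAC models; best "
                           f"max feature error = {best_err:.2f} SD")

    def rank(ind: Individual) -> float:
        try:
            out = evaluator_other(ind.params)
        except Exception:
            return WORST_OBJECTIVE
        ferr = out[1] if isinstance(out, tuple) else out
        return float(np.max(ferr))

    candidates = acc1.individuals
    if max_rank_candidates is not None and len(candidates) > max_rank_candidates:
        candidates = sorted(candidates,
                            key=lambda i: float(np.max(i.feature_errors)))
        candidates = candidates[:max_rank_candidates]
    best = min(candidates, key=rank)
    frozen_space = space.freeze(frozen_names, space.to_dict(best.params))
    stage2_result = run_moo(frozen_space, evaluator_both_factory(frozen_space),
                            pop_size, n_gen, seed + 1)
    acc2 = select_acceptable(stage2_result.populations, frozen_space, cutoff_sd)
    return acc2, stage1_result, stage2_result
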