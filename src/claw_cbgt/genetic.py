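"""Genetic search over the 13 searchable synaptic weights.

The fitness is feasibility-driven: a configuration must (1) keep every
population's mean firing rate inside its target range, (2) time out on
fewer than 1% of trials, and (3) show a positive trial-wise correlation
between cortical and striatal activity.  Among feasible candidates, those
whose rates sit closer to the centers of the target ranges score higher.
Operators: tournament selection, uniform crossover, Gaussian mutation
clipped to bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_RATE_TARGETS, SEARCHABLE_WEIGHTS, NetworkConfig
from .populations import ALL_POPULATIONS, POP_INDEX, base_type
from .simulate import (
    cortex_striatum_correlation,
    run_experiment,
    timeout_fraction,
)


@dataclass
class Evaluation:
    config: NetworkConfig
    mean_rates: dict
    timeout_frac: float
    cx_str_corr: float
    n_violations: int
    distance: float          # normalized distance to range midpoints
    feasible: bool

    @property
    def fitness(self) -> tuple:
        # lexicographic: fewer violations first, then closer to midpoints
        return (-self.n_violations, -self.distance)


def evaluate_config(config: NetworkConfig, targets: dict, n_trials: int,
                    seed: int) -> Evaluation:
    """Run trials and score a configuration against the feasibility
    predicates."""
    _, trials = run_experiment(config, n_trials, seed)
    ok = [t for t in trials if not t.timed_out]
    if ok:
        mean = np.mean([t.decision_rates().mean(axis=1) for t in ok], axis=0)
    else:
        mean = np.full(len(ALL_POPULATIONS), np.nan)
    rates = {p: float(mean[POP_INDEX[p]]) for p in ALL_POPULATIONS}
    to_frac = timeout_fraction(trials)
    corr = cortex_striatum_correlation(trials)

    violations = 0
    dist = 0.0
    for p, r in rates.items():
        lo, hi = targets[base_type(p)]
        if not np.isfinite(r) or not lo <= r <= hi:
            violations += 1
        if np.isfinite(hi) and np.isfinite(r):
            mid = (lo + hi) / 2
            span = max(hi - lo, 1e-9)
            dist += abs(r - mid) / span
    if to_frac >= 0.01:
        # allow a one-trial margin at small n
        if to_frac * n_trials > max(1.0, 0.01 * n_trials):
            violations += 1
    if not (np.isfinite(corr) and corr > 0):
        violations += 1
    return Evaluation(
        config=config, mean_rates=rates, timeout_frac=to_frac,
        cx_str_corr=corr, n_violations=violations,
        distance=dist / len(rates), feasible=violations == 0,
    )


@dataclass
class SearchReport:
    feasible: list = field(default_factory=list)
    best_infeasible: Evaluation | None = None
    n_evaluated: int = 0


def genetic_search(base_config: NetworkConfig, bounds: dict,
                   targets: dict | None = None, pop_size: int = 16,
                   generations: int = 6, n_keep: int = 8, seed: int = 0,
                   n_trials_eval: int = 10, mutation_sd: float = 0.15,
                   tournament: int = 3) -> tuple[list, SearchReport]:
    """Search the weight space for feasible network configurations.

    ``bounds`` maps searchable-weight pairs to (low, high) magnitude
    intervals and must cover exactly the 13 searchable weights; weights
    not listed... are not allowed.  Returns (configs sorted by fitness,
    report); the report carries the best infeasible candidate when the
    feasible list is empty.
    """
    bounds = {tuple(k): tuple(v) for k, v in bounds.items()}
    if set(bounds) != set(SEARCHABLE_WEIGHTS):
        raise ValueError("bounds must cover exactly the 13 searchable weights")
    if n_keep > pop_size * generations:
        raise ValueError("n_keep exceeds the number of evaluated candidates")
    targets = dict(DEFAULT_RATE_TARGETS if targets is None else targets)

    rng = np.random.default_rng(seed)
    keys = list(SEARCHABLE_WEIGHTS)
    lo = np.array([bounds[k][0] for k in keys])
    hi = np.array([bounds[k][1] for k in keys])
    span = hi - lo

    def to_config(x: np.ndarray) -> NetworkConfig:
        return base_config.with_searchable({k: v for k, v in zip(keys, x)})

    def evaluate(x: np.ndarray, s: int) -> Evaluation:
        return evaluate_config(to_config(x), targets, n_trials_eval, s)

    pop = lo + span * rng.random((pop_size, len(keys)))
    # seed the base config's own weights into the population when in bounds
    base_x = np.array([base_config.weights[k] for k in keys])
    if np.all((base_x >= lo) & (base_x <= hi)):
        pop[0] = base_x

    report = SearchReport()
    evaluated: list[Evaluation] = []
    for gen in range(generations):
        scores = []
        for i in range(pop_size):
            ev = evaluate(pop[i], int(rng.integers(2**31)))
            scores.append(ev)
            evaluated.append(ev)
            report.n_evaluated += 1
        if gen == generations - 1:
            break
        # tournament selection + uniform crossover + clipped Gaussian mutation
        new = np.empty_like(pop)
        for i in range(pop_size):
            picks = rng.integers(pop_size, size=tournament)
            p1 = max(picks, key=lambda j: scores[j].fitness)
            picks = rng.integers(pop_size, size=tournament)
            p2 = max(picks, key=lambda j: scores[j].fitness)
            mask = rng.random(len(keys)) < 0.5
            child = np.where(mask, pop[p1], pop[p2])
            child = child + rng.normal(0, mutation_sd, len(keys)) * span
            new[i] = np.clip(child, lo, hi)
        pop = new

    evaluated.sort(key=lambda e: e.fitness, reverse=True)
    feasible = [e for e in evaluated if e.feasible][:n_keep]
    report.feasible = feasible
    if not feasible and evaluated:
        report.best_infeasible = evaluated[0]
    return [e.config for e in feasible], report
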