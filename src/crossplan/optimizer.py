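"""Constrained mating-plan optimization: usefulness fitness + GA/SA search.

A mating plan is a multiset of parent pairs with per-family cross counts.
Its fitness is the average usefulness over families,

    Fit_m = (1/n_F) sum_F [ E(g_F) + i_F r sd(g_F) ],

where the within-family selection intensity i_F depends on the proportion
selected within the family and therefore on how many times the cross is
replicated (replication increases family size and i_F).  The optimization
maximizes Fit_m subject to PropSD < cutoff plus structural constraints (total
crosses, repeats, family count, per-parent bounds, allowed/forbidden pairs);
infeasible candidates receive a large negative penalty fitness, keeping the
search space connected.  The search blends a genetic algorithm (elite
retention, mutation, family-exchange crossover) with simulated annealing
(geometric cooling acceptance of inferior plans) and is deterministic under a
seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .diversity import GRM, prop_sd

__all__ = [
    "MatingPlan",
    "ConstraintSet",
    "OptimizerConfig",
    "FitnessReport",
    "selection_intensity",
    "plan_fitness",
    "check_feasibility",
    "optimize",
    "exhaustive_search",
    "prediction_table",
    "testcross_objective",
]


def selection_intensity(p_selected: float) -> float:
    """Standardized selection differential i = phi(z)/p with z = Phi^-1(1-p).

    Infinite-population normal approximation; i = 0 at p = 1 (no selection).
    """
    if not 0.0 < p_selected <= 1.0:
        raise ValueError("selected proportion must lie in (0, 1]")
    if p_selected == 1.0:
        return 0.0
    z = norm.ppf(1.0 - p_selected)
    return float(norm.pdf(z) / p_selected)


# ---------------------------------------------------------------------------
# Plans and constraints
# ---------------------------------------------------------------------------

def _norm_pair(k: int, l: int) -> tuple[int, int]:
    return (k, l) if k <= l else (l, k)


@dataclass(frozen=True)
class MatingPlan:
    """families: sorted tuple of (parent_k, parent_l, n_crosses), k <= l, no
    duplicate pairs (multiplicity lives in n_crosses)."""

    families: tuple[tuple[int, int, int], ...]

    @classmethod
    def from_crosses(cls, crosses: Sequence[tuple[int, int]]) -> "MatingPlan":
        counts: dict[tuple[int, int], int] = {}
        for k, l in crosses:
            counts[_norm_pair(k, l)] = counts.get(_norm_pair(k, l), 0) + 1
        fams = tuple(sorted((k, l, n) for (k, l), n in counts.items()))
        return cls(fams)

    def __post_init__(self) -> None:
        pairs = [(k, l) for k, l, _ in self.families]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate family pairs; use n_crosses for multiplicity")
        if any(n < 1 for _, _, n in self.families):
            raise ValueError("n_crosses must be >= 1")
        if any(k > l for k, l, _ in self.families):
            raise ValueError("pairs must be stored with k <= l")
        object.__setattr__(self, "families", tuple(sorted(self.families)))

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def total_crosses(self) -> int:
        return sum(n for _, _, n in self.families)

    def crosses(self) -> list[tuple[int, int]]:
        return [(k, l) for k, l, n in self.families for _ in range(n)]

    def selected_parents(self, unique: bool = False) -> list[int]:
        """Multiset of parents, one entry per mating each takes part in
        (``unique=True`` collapses to one entry per distinct parent)."""
        out: list[int] = []
        for k, l, n in self.families:
            out.extend([k] * n)
            out.extend([l] * n)
        return sorted(set(out)) if unique else sorted(out)

    def parent_cross_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for k, l, n in self.families:
            counts[k] = counts.get(k, 0) + n
            counts[l] = counts.get(l, 0) + n
        return counts


@dataclass
class ConstraintSet:
    total_crosses: int
    allow_repeats: bool = True
    allow_selfing: bool = False
    n_families: int | tuple[int, int] | None = None
    parent_min: int | None = None
    parent_max: int | None = None
    pair_mask: np.ndarray | None = None  # True = allowed
    testers: tuple[int, ...] = ()
    propsd_cutoff: float = 1.0
    selected_per_family: int = 10
    progeny_per_cross: int = 100
    contribution_weighted_propsd: bool = True

    def __post_init__(self) -> None:
        if self.total_crosses < 1:
            raise ValueError("total_crosses must be >= 1")
        if not 0.0 <= self.propsd_cutoff <= 1.0:
            raise ValueError("propsd_cutoff must lie in [0, 1]")
        if self.pair_mask is not None:
            m = np.asarray(self.pair_mask, dtype=bool)
            if not np.array_equal(m, m.T):
                raise ValueError("pair mask must be symmetric")
            self.pair_mask = m

    def family_range(self) -> tuple[int, int]:
        if self.n_families is None:
            return (1, self.total_crosses)
        if isinstance(self.n_families, int):
            return (self.n_families, self.n_families)
        return tuple(self.n_families)  # type: ignore[return-value]


@dataclass
class OptimizerConfig:
    population_size: int = 100
    n_elite: int = 10
    max_iterations: int = 300
    convergence_patience: int = 60
    mutation_rate: float = 0.2
    crossover_rate: float = 0.8
    initial_temperature: float = 1.0
    cooling: float = 0.98
    seed: int = 0
    penalty_fitness: float = -1e9

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")
        for name in ("population_size", "n_elite", "max_iterations", "convergence_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_elite > self.population_size:
            raise ValueError("n_elite cannot exceed population_size")


@dataclass
class FitnessReport:
    fitness: float
    family_usefulness: dict[tuple[int, int], float]
    propsd: float
    feasible: bool
    violations: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Fitness and feasibility
# ---------------------------------------------------------------------------

Predictions = Mapping[tuple[int, int], tuple[float, float]]  # pair -> (mean, sd)


def prediction_table(df) -> tuple[Predictions, dict]:
    """Index a prediction DataFrame (from predict_all_crosses with an
    index-keyed panel) into a {pair: (mean, sd)} mapping by parent name."""
    name_to_idx: dict = {}
    table: dict[tuple[int, int], tuple[float, float]] = {}
    for row in df.itertuples():
        for nm in (row.parent1, row.parent2):
            name_to_idx.setdefault(nm, len(name_to_idx))
        key = _norm_pair(name_to_idx[row.parent1], name_to_idx[row.parent2])
        table[key] = (row.mean, row.sd)
    return table, name_to_idx


def plan_fitness(
    plan: MatingPlan,
    predictions: Predictions,
    constraints: ConstraintSet,
    accuracy: float = 1.0,
) -> FitnessReport:
    """Average usefulness over the plan's families.

    Per family, the selected proportion is selected_per_family /
    (n_crosses x progeny_per_cross): replicating a cross enlarges the family
    and raises i_F, hence U_F.
    """
    per_family: dict[tuple[int, int], float] = {}
    for k, l, n in plan.families:
        if (k, l) not in predictions:
            raise KeyError(f"no prediction for family {(k, l)}")
        mean, sd = predictions[(k, l)]
        p = min(1.0, constraints.selected_per_family / (n * constraints.progeny_per_cross))
        per_family[(k, l)] = mean + selection_intensity(p) * accuracy * sd
    fit = float(np.mean(list(per_family.values())))
    return FitnessReport(fitness=fit, family_usefulness=per_family, propsd=np.nan, feasible=True)


def check_feasibility(
    plan: MatingPlan, constraints: ConstraintSet, G_pool: GRM | np.ndarray | None
) -> tuple[bool, tuple[str, ...], float]:
    """Evaluate every constraint; returns (feasible, violated names, PropSD)."""
    violations: list[str] = []
    if plan.total_crosses != constraints.total_crosses:
        violations.append("total_crosses")
    if not constraints.allow_repeats and any(n > 1 for _, _, n in plan.families):
        violations.append("repeats")
    if not constraints.allow_selfing and any(k == l for k, l, _ in plan.families):
        violations.append("selfing")
    lo, hi = constraints.family_range()
    if not lo <= plan.n_families <= hi:
        violations.append("n_families")
    counts = plan.parent_cross_counts()
    if constraints.parent_max is not None and any(
        v > constraints.parent_max for v in counts.values()
    ):
        violations.append("parent_max")
    if constraints.parent_min is not None and any(
        v < constraints.parent_min for v in counts.values()
    ):
        violations.append("parent_min")
    if constraints.pair_mask is not None and any(
        not constraints.pair_mask[k, l] for k, l, _ in plan.families
    ):
        violations.append("pair_mask")
    propsd = np.nan
    if G_pool is not None:
        sel = plan.selected_parents(unique=not constraints.contribution_weighted_propsd)
        propsd = prop_sd(G_pool, sel)
        if not propsd < constraints.propsd_cutoff:
            violations.append("propsd")
    return (not violations, tuple(violations), float(propsd))


def evaluate_plan(
    plan: MatingPlan,
    predictions: Predictions,
    constraints: ConstraintSet,
    G_pool,
    accuracy: float,
    penalty: float,
) -> FitnessReport:
    feasible, violations, propsd = check_feasibility(plan, constraints, G_pool)
    if not feasible:
        return FitnessReport(penalty, {}, propsd, False, violations)
    rep = plan_fitness(plan, predictions, constraints, accuracy)
    rep.propsd = propsd
    return rep


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _allowed_pairs(predictions: Predictions, constraints: ConstraintSet) -> list[tuple[int, int]]:
    pairs = []
    for k, l in predictions:
        if k == l and not constraints.allow_selfing:
            continue
        if constraints.pair_mask is not None and not constraints.pair_mask[k, l]:
            continue
        pairs.append((k, l))
    if not pairs:
        raise ValueError("no allowed pairs under the given constraints")
    return sorted(pairs)


def _random_plan(pairs, constraints, rng) -> MatingPlan:
    m = constraints.total_crosses
    if constraints.allow_repeats:
        idx = rng.integers(0, len(pairs), size=m)
    else:
        idx = rng.choice(len(pairs), size=min(m, len(pairs)), replace=False)
    return MatingPlan.from_crosses([pairs[i] for i in idx])


def _mutate(plan: MatingPlan, pairs, constraints, rng) -> MatingPlan:
    crosses = plan.crosses()
    op = rng.integers(0, 3)
    i = rng.integers(0, len(crosses))
    if op == 0:  # replace one cross's family entirely
        crosses[i] = pairs[rng.integers(0, len(pairs))]
    elif op == 1:  # swap one parent of one cross
        k, l = crosses[i]
        cand = [p for p in pairs if k in p or l in p]
        crosses[i] = cand[rng.integers(0, len(cand))]
    else:  # move a replication: duplicate one family at the cost of another
        j = rng.integers(0, len(crosses))
        crosses[i] = crosses[j]
    plan2 = MatingPlan.from_crosses(crosses)
    if not constraints.allow_repeats and any(n > 1 for _, _, n in plan2.families):
        return plan  # reject structurally invalid mutation
    return plan2


def _crossover(p1: MatingPlan, p2: MatingPlan, rng) -> MatingPlan:
    pool = p1.crosses() + p2.crosses()
    idx = rng.choice(len(pool), size=p1.total_crosses, replace=False)
    return MatingPlan.from_crosses([pool[i] for i in idx])


def optimize(
    predictions: Predictions,
    constraints: ConstraintSet,
    config: OptimizerConfig | None = None,
    G_pool: GRM | np.ndarray | None = None,
    accuracy: float = 1.0,
):
    """GA + simulated-annealing search for the best feasible mating plan.

    Returns (best MatingPlan, FitnessReport, elite fitness trace).  The trace
    is non-decreasing; the best plan returned is feasible whenever any
    feasible plan was encountered.
    """
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    pairs = _allowed_pairs(predictions, constraints)

    cache: dict = {}

    def ev(plan: MatingPlan) -> FitnessReport:
        rep = cache.get(plan.families)
        if rep is None:
            rep = evaluate_plan(
                plan, predictions, constraints, G_pool, accuracy, config.penalty_fitness
            )
            cache[plan.families] = rep
        return rep

    population = [_random_plan(pairs, constraints, rng) for _ in range(config.population_size)]
    fits = [ev(p).fitness for p in population]
    order = np.argsort(fits)[::-1]
    population = [population[i] for i in order]
    fits = [fits[i] for i in order]

    best, best_fit = population[0], fits[0]
    trace = [best_fit]
    temperature = config.initial_temperature * max(1.0, abs(best_fit))
    stagnant = 0

    for _ in range(config.max_iterations):
        offspring: list[MatingPlan] = []
        while len(offspring) < config.population_size - config.n_elite:
            i1, i2 = rng.integers(0, len(population), size=2)
            a = population[min(i1, i2)]  # tournament: population sorted by fitness
            if rng.random() < config.crossover_rate:
                j1, j2 = rng.integers(0, len(population), size=2)
                b = population[min(j1, j2)]
                child = _crossover(a, b, rng)
            else:
                child = a
            if rng.random() < config.mutation_rate or child is a:
                child = _mutate(child, pairs, constraints, rng)
            offspring.append(child)

        candidates = population[: config.n_elite] + offspring
        cand_fits = [ev(p).fitness for p in candidates]
        order = np.argsort(cand_fits)[::-1]
        keep = [candidates[i] for i in order[: config.population_size]]
        keep_fits = [cand_fits[i] for i in order[: config.population_size]]
        # annealed acceptance: inferior offspring may displace the tail
        tail = order[config.population_size :]
        for i in tail:
            delta = keep_fits[-1] - cand_fits[i]
            if delta > 0 and rng.random() < math.exp(-delta / max(temperature, 1e-12)):
                keep[-1] = candidates[i]
                keep_fits[-1] = cand_fits[i]
        population, fits = keep, keep_fits
        temperature *= config.cooling

        if fits[0] > best_fit:
            best, best_fit = population[0], fits[0]
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)
        if stagnant >= config.convergence_patience:
            break

    return best, ev(best), trace


def exhaustive_search(
    predictions: Predictions,
    constraints: ConstraintSet,
    G_pool: GRM | np.ndarray | None = None,
    accuracy: float = 1.0,
    max_space: int = 10**6,
):
    """Enumerate every plan (test oracle); ties broken by the lexicographically
    smallest canonical family tuple."""
    pairs = _allowed_pairs(predictions, constraints)
    m = constraints.total_crosses
    if constraints.allow_repeats:
        space = math.comb(len(pairs) + m - 1, m)
        it = itertools.combinations_with_replacement(pairs, m)
    else:
        space = math.comb(len(pairs), m)
        it = itertools.combinations(pairs, m)
    if space > max_space:
        raise ValueError(
            f"search space of {space} plans exceeds {max_space}; use optimize()"
        )
    best = None
    best_key = None
    for crosses in it:
        plan = MatingPlan.from_crosses(list(crosses))
        rep = evaluate_plan(plan, predictions, constraints, G_pool, accuracy, -np.inf)
        if not rep.feasible:
            continue
        key = (-rep.fitness, plan.families)
        if best_key is None or key < best_key:
            best, best_key = (plan, rep), key
    if best is None:
        raise ValueError("no feasible plan exists under the given constraints")
    return best


def testcross_objective(panel, scheme, effects, ld_model: str = "approx", pair_mask=None):
    """Per-pair predictions of testcross (hybrid) performance, averaged over
    the scheme's testers."""
    from .crosspredict import predict_all_crosses

    if not scheme.testers:
        raise ValueError("scheme carries no testers")
    for t in scheme.testers:
        if not 0 <= t < panel.n_parents:
            raise IndexError(f"tester index {t} out of range")
    return predict_all_crosses(panel, scheme, effects, ld_model=ld_model, pair_mask=pair_mask)
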