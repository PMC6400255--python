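"""Genetic-algorithm partitioning of sub-data sets into merging groups.

A candidate grouping is encoded as a *chromosome*: an integer array of length
n (the pool size) whose value at position i is the merging group of sub-data
set i.  The default is three groups — typically two potentially isomorphous
groups plus a sink for low-quality wedges.  Fitness is a signed, weighted
combination of merging statistics of the chromosome's best group:

    score(group) = - w_R * R_meas(inner)
                   + w_I * <I/sigma>(overall)
                   + w_anom * CC_anom(overall)
                   + w_half * CC1/2(overall)
                   + w_comp * completeness(overall)
                   + w_mult * multiplicity(overall)

with R_meas taken from the inner shell and every other term from the overall
column.  Default user weights are (1.0, 2.0, 0.0, 1.0, 0.2, 0.0); a one-cycle
automatic balancing step can rescale the non-R terms so no single statistic
dominates (see :func:`balance_weights`).

Every fitness evaluation is appended to an :class:`Archive` — intermediate
solutions are never deleted — so a single run yields thousands of
(grouping, statistics) pairs for post-hoc analysis.  A matched-budget random
control (:func:`random_control`) evaluates the same number of uniformly
random chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .merging import MergingStats
from .reflections import Pool, ShellAssignment

__all__ = [
    "Chromosome",
    "FitnessWeights",
    "GAConfig",
    "ArchiveRecord",
    "Archive",
    "GAResult",
    "initialize_population",
    "mutate",
    "crossover",
    "group_score",
    "chromosome_fitness",
    "balance_weights",
    "evolve",
    "random_control",
    "exhaustive_oracle",
]

TERMS = ("r_meas", "i_over_sigma", "cc_anom", "cc_half", "completeness", "multiplicity")

#: score contribution subtracted for each missing statistic with nonzero weight
DEFAULT_PENALTY = 1000.0


class Chromosome:
    """Integer group-label array of fixed length; values in [0, n_groups)."""

    __slots__ = ("labels",)

    def __init__(self, labels, n_groups: int | None = None):
        arr = np.asarray(labels, dtype=np.int64).copy()
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("chromosome must be a non-empty 1-d integer array")
        if arr.min() < 0 or (n_groups is not None and arr.max() >= n_groups):
            raise ValueError("group labels out of range")
        arr.setflags(write=False)
        self.labels = arr

    def __len__(self) -> int:
        return self.labels.size

    def __eq__(self, other) -> bool:
        return isinstance(other, Chromosome) and np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())

    def __repr__(self) -> str:
        return f"Chromosome({self.labels.tolist()})"


@dataclass
class FitnessWeights:
    """Per-term weights of the fitness function.

    ``w_*`` are the (automatic or default) weights; ``user_multipliers``
    multiply them term-wise, which is how a particular statistic — usually
    the anomalous correlation — is emphasised on top of automatic balancing.
    """

    w_r_meas: float = 1.0
    w_i_over_sigma: float = 2.0
    w_cc_anom: float = 0.0
    w_cc_half: float = 1.0
    w_completeness: float = 0.2
    w_multiplicity: float = 0.0
    r_user: float = 1.0
    user_multipliers: dict = field(default_factory=dict)
    balance_report: dict | None = None

    def __post_init__(self) -> None:
        vals = [getattr(self, f"w_{t}") for t in TERMS]
        if any(v < 0 for v in vals):
            raise ValueError("weights must be non-negative")
        if not any(v * self.user_multipliers.get(t, 1.0) > 0 for v, t in zip(vals, TERMS)):
            raise ValueError("at least one effective weight must be positive")
        if self.r_user <= 0:
            raise ValueError("r_user must be positive")

    def effective(self, term: str) -> float:
        return getattr(self, f"w_{term}") * self.user_multipliers.get(term, 1.0)


@dataclass
class GAConfig:
    """Run-size, operator and grouping parameters of a GA run."""

    population_size: int = 50
    generations: int = 150
    p_mutation: float = 0.6  # per-individual probability that mutation is applied
    p_crossover: float = 0.3
    n_groups: int = 3
    min_group_size: int = 3
    seed: int = 0
    selection: str = "fitness"  # "fitness" (tournament) or "random"
    mutation_rate: float | None = None  # per-position resampling rate; default 1/n
    n_shells: int = 10
    penalty: float = DEFAULT_PENALTY
    fitness_mode: str = "best_group"  # or "sum_groups"

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if not (0 <= self.p_mutation <= 1 and 0 <= self.p_crossover <= 1):
            raise ValueError("operator probabilities must lie in [0, 1]")
        if self.n_groups < 1 or self.min_group_size < 1:
            raise ValueError("n_groups and min_group_size must be positive")
        if self.selection not in ("fitness", "random"):
            raise ValueError("selection must be 'fitness' or 'random'")


@dataclass
class ArchiveRecord:
    """One fitness evaluation: the chromosome, its per-group statistics and
    scores, and the resulting fitness."""

    generation: int
    labels: np.ndarray
    group_stats: dict  # label -> MergingStats (groups meeting min_group_size)
    group_scores: dict  # label -> float
    fitness: float
    best_group: int | None


class Archive:
    """Append-only log of every evaluation in a run; never pruned."""

    def __init__(self) -> None:
        self.records: list[ArchiveRecord] = []

    def append(self, record: ArchiveRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def fitness_values(self) -> np.ndarray:
        return np.array([r.fitness for r in self.records])

    def best(self) -> ArchiveRecord:
        return max(self.records, key=lambda r: r.fitness)

    def to_frame(self):
        """Delimited-table view: one row per (evaluation, qualifying group);
        evaluations with no qualifying group get a single row with group -1."""
        import pandas as pd
        from .merging import _STAT_NAMES

        rows = []
        for ridx, rec in enumerate(self.records):
            labels = ",".join(str(int(x)) for x in rec.labels)
            base = {
                "record": ridx,
                "generation": rec.generation,
                "labels": labels,
                "fitness": rec.fitness,
            }
            if not rec.group_stats:
                rows.append({**base, "group": -1, "score": np.nan, "is_best": False})
                continue
            for label, stats in rec.group_stats.items():
                row = {
                    **base,
                    "group": label,
                    "score": rec.group_scores[label],
                    "is_best": label == rec.best_group,
                    "group_size": int((rec.labels == label).sum()),
                }
                for name in _STAT_NAMES:
                    t = getattr(stats, name)
                    row[f"{name}_inner"] = t.inner
                    row[f"{name}_outer"] = t.outer
                    row[f"{name}_overall"] = t.overall
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame) -> "Archive":
        """Rebuild an archive from :meth:`to_frame` output."""
        from .merging import _STAT_NAMES, MergingStats, ShellTriple

        def val(x):
            return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)

        archive = cls()
        for ridx, sub in frame.groupby("record", sort=True):
            first = sub.iloc[0]
            labels = np.array([int(x) for x in str(first["labels"]).split(",")])
            group_stats, group_scores, best_group = {}, {}, None
            for _, row in sub.iterrows():
                g = int(row["group"])
                if g < 0:
                    continue
                triples = {
                    name: ShellTriple(
                        val(row[f"{name}_inner"]),
                        val(row[f"{name}_outer"]),
                        val(row[f"{name}_overall"]),
                    )
                    for name in _STAT_NAMES
                }
                group_stats[g] = MergingStats(**triples)
                group_scores[g] = float(row["score"])
                if bool(row["is_best"]):
                    best_group = g
            archive.append(
                ArchiveRecord(
                    generation=int(first["generation"]),
                    labels=labels,
                    group_stats=group_stats,
                    group_scores=group_scores,
                    fitness=float(first["fitness"]),
                    best_group=best_group,
                )
            )
        return archive


@dataclass
class GAResult:
    """Outcome of a GA run: the best chromosome ever evaluated, the merging
    group it proposes, and the full evaluation archive."""

    best_chromosome: Chromosome
    best_group_label: int
    best_group_ids: list[str]
    best_stats: MergingStats | None
    best_fitness: float
    archive: Archive
    config: GAConfig
    weights: FitnessWeights
    generations_best: list[float]


# ---------------------------------------------------------------------------
# operators


def initialize_population(n: int, config: GAConfig, rng: np.random.Generator) -> list[Chromosome]:
    """Random initial population: labels i.i.d. uniform over [0, n_groups)."""
    if n < 1:
        raise ValueError("chromosome length must be >= 1")
    return [
        Chromosome(rng.integers(0, config.n_groups, size=n), config.n_groups)
        for _ in range(config.population_size)
    ]


def mutate(c: Chromosome, p: float, rng: np.random.Generator, n_groups: int | None = None) -> Chromosome:
    """Resample each position uniformly over all labels with probability p.

    The resampled label may equal the old one, so with g groups the expected
    fraction of *changed* positions is p(g-1)/g.  The input is not modified.
    """
    g = int(n_groups if n_groups is not None else c.labels.max() + 1)
    labels = c.labels.copy()
    hit = rng.random(labels.size) < p
    labels[hit] = rng.integers(0, g, size=int(hit.sum()))
    return Chromosome(labels, g)


def crossover(
    a: Chromosome, b: Chromosome, mode: str, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Single- or double-point crossover; returns two children."""
    if len(a) != len(b):
        raise ValueError("parents must have equal length")
    n = len(a)
    la, lb = a.labels.copy(), b.labels.copy()
    if n < 2:
        return Chromosome(la), Chromosome(lb)
    if mode == "single":
        cut = int(rng.integers(1, n))
        la[cut:], lb[cut:] = b.labels[cut:], a.labels[cut:]
    elif mode == "double":
        if n < 3:
            cut = 1
            la[cut:], lb[cut:] = b.labels[cut:], a.labels[cut:]
        else:
            c1, c2 = sorted(rng.choice(np.arange(1, n), size=2, replace=False).tolist())
            la[c1:c2], lb[c1:c2] = b.labels[c1:c2], a.labels[c1:c2]
    else:
        raise ValueError(f"unknown crossover mode {mode!r}")
    return Chromosome(la), Chromosome(lb)


# ---------------------------------------------------------------------------
# fitness


def _term_value(stats: MergingStats, term: str) -> float | None:
    # R_meas is judged on the inner shell; every other term on overall
    if term == "r_meas":
        return stats.r_meas.inner
    return getattr(stats, term).overall


def group_score(stats: MergingStats, weights: FitnessWeights, penalty: float = DEFAULT_PENALTY) -> float:
    """Signed weighted combination of one group's statistics.

    R_meas enters negatively (lower is better); all other terms positively.
    A missing statistic with nonzero effective weight contributes ``-penalty``.
    """
    score = 0.0
    for term in TERMS:
        w = weights.effective(term)
        if w == 0:
            continue
        value = _term_value(stats, term)
        if value is None:
            score -= penalty
        elif term == "r_meas":
            score -= w * value
        else:
            score += w * value
    return score


class _FitnessEvaluator:
    """Caches per-group statistics/scores by the frozenset of member positions.

    The GA revisits the same groups constantly (elitism, converged
    populations), so caching makes runs dramatically cheaper while leaving
    results bit-identical.
    """

    def __init__(self, pool: Pool, weights: FitnessWeights, config: GAConfig,
                 stat_seed: int, shells: ShellAssignment | None = None):
        from ._engine import StatsEngine

        self.pool = pool
        self.weights = weights
        self.config = config
        self.stat_seed = stat_seed
        self.engine = StatsEngine(
            pool,
            shells=shells if shells is not None else config.n_shells,
            seed=stat_seed,
        )
        self.ids = pool.ids
        self.cache: dict[frozenset, tuple[MergingStats, float]] = {}

    def group(self, members: tuple[int, ...]) -> tuple[MergingStats, float]:
        key = frozenset(members)
        hit = self.cache.get(key)
        if hit is None:
            stats = self.engine.stats(members)
            hit = (stats, group_score(stats, self.weights, self.config.penalty))
            self.cache[key] = hit
        return hit

    def __call__(self, c: Chromosome) -> tuple[float, int | None, dict, dict]:
        cfg = self.config
        group_stats: dict[int, MergingStats] = {}
        group_scores: dict[int, float] = {}
        for label in range(cfg.n_groups):
            members = tuple(np.nonzero(c.labels == label)[0].tolist())
            if len(members) < cfg.min_group_size:
                continue
            stats, score = self.group(members)
            group_stats[label] = stats
            group_scores[label] = score
        if not group_scores:
            return -cfg.penalty * len(TERMS), None, {}, {}
        if cfg.fitness_mode == "sum_groups":
            fitness = sum(group_scores.values())
            best = max(group_scores, key=group_scores.get)
        else:
            best = max(group_scores, key=group_scores.get)
            fitness = group_scores[best]
        return fitness, best, group_stats, group_scores


def chromosome_fitness(
    c: Chromosome | Sequence[int],
    pool: Pool,
    weights: FitnessWeights,
    config: GAConfig,
    seed: int | None = None,
):
    """Fitness of one chromosome: the score of its best qualifying group.

    Groups smaller than ``min_group_size`` are skipped; if no group
    qualifies the chromosome receives the maximal penalty.  Returns
    ``(fitness, best_group_label, {label: stats})``.
    """
    if not isinstance(c, Chromosome):
        c = Chromosome(c, config.n_groups)
    ev = _FitnessEvaluator(pool, weights, config, config.seed if seed is None else seed)
    fitness, best, group_stats, _ = ev(c)
    return fitness, best, group_stats


# ---------------------------------------------------------------------------
# weight balancing


def balance_weights(
    pool: Pool,
    config: GAConfig,
    r_user: float = 1.0,
    user_multipliers: dict | None = None,
    seed: int | None = None,
) -> FitnessWeights:
    """One-cycle automatic weight balancing.

    A single GA generation is evaluated with unit weights; the best value of
    each term over all qualifying groups is collected, and the automatic
    weight of each non-R term is set to ``r_user / best_value`` so that at
    calibration every balanced term tops out at exactly ``r_user``.  Terms
    whose calibration best is <= 0 get weight 0 (reported).  The R_meas
    weight stays at 1.  User multipliers are applied on top.
    """
    if r_user <= 0:
        raise ValueError("r_user must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    unit = FitnessWeights(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, r_user=r_user)
    ev = _FitnessEvaluator(pool, unit, config, config.seed)
    pop = initialize_population(pool.n_subdatasets, config, rng)
    best_terms: dict[str, float] = {}
    any_group = False
    for c in pop:
        _, _, group_stats, _ = ev(c)
        for stats in group_stats.values():
            any_group = True
            for term in TERMS:
                v = _term_value(stats, term)
                if v is None:
                    continue
                if term not in best_terms or v > best_terms[term]:
                    best_terms[term] = v
    if not any_group:
        raise ValueError(
            "weight balancing failed: no group met min_group_size in the calibration cycle"
        )
    auto: dict[str, float] = {"r_meas": 1.0}
    zeroed: list[str] = []
    for term in TERMS:
        if term == "r_meas":
            continue
        best = best_terms.get(term)
        if best is None or best <= 0:
            auto[term] = 0.0
            zeroed.append(term)
        else:
            auto[term] = r_user / best
    report = {"best_terms": best_terms, "zeroed": zeroed, "r_user": r_user}
    return FitnessWeights(
        w_r_meas=auto["r_meas"],
        w_i_over_sigma=auto["i_over_sigma"],
        w_cc_anom=auto["cc_anom"],
        w_cc_half=auto["cc_half"],
        w_completeness=auto["completeness"],
        w_multiplicity=auto["multiplicity"],
        r_user=r_user,
        user_multipliers=dict(user_multipliers or {}),
        balance_report=report,
    )


# ---------------------------------------------------------------------------
# evolution


def _tournament(fits: np.ndarray, rng: np.random.Generator) -> int:
    i, j = rng.integers(0, fits.size, size=2)
    return int(i if fits[i] >= fits[j] else j)


def evolve(
    pool: Pool,
    weights: FitnessWeights,
    config: GAConfig,
    callback: Callable | None = None,
) -> GAResult:
    """Run the genetic algorithm; fully deterministic given ``config.seed``.

    Each generation every individual is evaluated (and archived), the best
    individual is carried over unchanged (elitism), parents are chosen by
    size-2 tournament, and children undergo crossover with probability
    ``p_crossover`` (single- or double-point, equal odds) and mutation with
    probability ``p_mutation`` (per-position rate ``mutation_rate``,
    default 1/n).
    """
    n = pool.n_subdatasets
    if n < config.min_group_size:
        raise ValueError("pool smaller than min_group_size")
    rng = np.random.default_rng(config.seed)
    ev = _FitnessEvaluator(pool, weights, config, config.seed)
    indpb = config.mutation_rate if config.mutation_rate is not None else 1.0 / n

    pop = initialize_population(n, config, rng)
    archive = Archive()
    best_ever: tuple[float, Chromosome, int | None] | None = None
    generations_best: list[float] = []

    for gen in range(config.generations):
        fits = np.empty(len(pop))
        for i, c in enumerate(pop):
            fitness, best_label, gstats, gscores = ev(c)
            fits[i] = fitness
            archive.append(
                ArchiveRecord(gen, c.labels, gstats, gscores, fitness, best_label)
            )
            if best_ever is None or fitness > best_ever[0]:
                best_ever = (fitness, c, best_label)
        generations_best.append(float(fits.max()))
        if callback is not None:
            callback(gen, pop, fits)
        if gen == config.generations - 1:
            break

        # next generation: single elite + offspring of selected parents
        elite = pop[int(np.argmax(fits))]
        children: list[Chromosome] = [elite]
        while len(children) < config.population_size:
            if config.selection == "fitness":
                pa = pop[_tournament(fits, rng)]
                pb = pop[_tournament(fits, rng)]
            else:
                pa = pop[int(rng.integers(0, len(pop)))]
                pb = pop[int(rng.integers(0, len(pop)))]
            if rng.random() < config.p_crossover:
                mode = "single" if rng.random() < 0.5 else "double"
                ca, cb = crossover(pa, pb, mode, rng)
            else:
                ca, cb = pa, pb
            for child in (ca, cb):
                if rng.random() < config.p_mutation:
                    child = mutate(child, indpb, rng, config.n_groups)
                children.append(child)
                if len(children) >= config.population_size:
                    break
        pop = children

    assert best_ever is not None
    fitness, chrom, best_label = best_ever
    if best_label is not None:
        members = np.nonzero(chrom.labels == best_label)[0]
        ids = [pool.ids[i] for i in members]
        stats = ev.group(tuple(members.tolist()))[0]
    else:
        ids, stats = [], None
    return GAResult(
        best_chromosome=chrom,
        best_group_label=-1 if best_label is None else best_label,
        best_group_ids=ids,
        best_stats=stats,
        best_fitness=fitness,
        archive=archive,
        config=config,
        weights=weights,
        generations_best=generations_best,
    )


def random_control(pool: Pool, weights: FitnessWeights, config: GAConfig) -> Archive:
    """Matched-budget random control: population x generations uniformly
    random chromosomes with no variation operators or fitness-based
    selection, mirroring random merged-set sampling.  Returns the archive."""
    rng = np.random.default_rng(config.seed)
    ev = _FitnessEvaluator(pool, weights, config, config.seed)
    archive = Archive()
    for gen in range(config.generations):
        for c in initialize_population(pool.n_subdatasets, config, rng):
            fitness, best_label, gstats, gscores = ev(c)
            archive.append(ArchiveRecord(gen, c.labels, gstats, gscores, fitness, best_label))
    return archive


# ---------------------------------------------------------------------------
# exhaustive oracle


def _restricted_growth_strings(n: int, g: int):
    """All label arrays of length n with at most g groups, up to label
    permutation (restricted growth strings)."""

    def rec(prefix: list[int], used: int):
        if len(prefix) == n:
            yield np.array(prefix, dtype=np.int64)
            return
        for lab in range(min(used + 1, g)):
            yield from rec(prefix + [lab], max(used, lab + 1))

    yield from rec([], 0)


def exhaustive_oracle(
    pool: Pool,
    weights: FitnessWeights,
    config: GAConfig,
    limit: int = 10**6,
) -> tuple[Chromosome, float]:
    """Global optimum by enumeration of all group assignments (quotiented by
    label permutation).  Only feasible for small pools: with g groups and n
    sub-data sets the raw space has g**n assignments, so the call is refused
    when that exceeds ``limit``."""
    n, g = pool.n_subdatasets, config.n_groups
    count = g**n
    if count > limit:
        raise ValueError(
            f"exhaustive enumeration refused: {g}^{n} = {count} assignments exceeds {limit}"
        )
    ev = _FitnessEvaluator(pool, weights, config, config.seed)
    best: tuple[float, np.ndarray] | None = None
    for labels in _restricted_growth_strings(n, g):
        c = Chromosome(labels, g)
        fitness, _, _, _ = ev(c)
        if best is None or fitness > best[0]:
            best = (fitness, labels)
    assert best is not None
    return Chromosome(best[1], g), best[0]
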