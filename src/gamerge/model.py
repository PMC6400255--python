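"""High-level model/results interface.

:class:`GeneticGrouping` is the model object: a pool of sub-data sets plus
the fitness weights and run configuration.  Calling :meth:`fit` runs the
genetic algorithm and returns a :class:`GroupingResults` carrying the
selected merging group, its statistics, the full evaluation archive and a
printable summary.  Random-control simulation, archive analysis and plotting
hang off these two objects.

Example
-------
>>> from gamerge import GeneticGrouping, SyntheticConfig, make_pool
>>> pool, truth = make_pool(seed=7)
>>> model = GeneticGrouping(pool)                     # default weights/config
>>> res = model.fit()
>>> print(res.summary())                              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
import numpy as np

from .analysis import ArchiveAnalysis, ComparisonReport, archive_analysis, compare_ga_vs_all
from .cell import UnitCell
from .ga import (
    Archive,
    FitnessWeights,
    GAConfig,
    GAResult,
    balance_weights,
    evolve,
    random_control,
)
from .io import read_pool
from .reflections import Pool
from .simulate import SyntheticTruth

__all__ = ["GeneticGrouping", "GroupingResults"]


class GeneticGrouping:
    """Grouping of partial data sets into isomorphous merging groups by GA.

    Parameters
    ----------
    pool:
        The pool of sub-data sets (chromosome position i = ``pool.subdatasets[i]``).
    weights:
        Fitness weights; default is the standard set (R_meas 1.0,
        <I/sigma> 2.0, CC_anom 0.0, CC1/2 1.0, completeness 0.2,
        multiplicity 0.0).  Pass ``auto_balance=True`` to :meth:`fit` to
        recalibrate the non-R terms from a single unit-weight cycle.
    config:
        Run sizes and operator probabilities (defaults: population 50,
        150 generations, p_mutation 0.6, p_crossover 0.3, 3 groups).
    """

    def __init__(
        self,
        pool: Pool,
        weights: FitnessWeights | None = None,
        config: GAConfig | None = None,
    ):
        self.pool = pool
        self.weights = weights if weights is not None else FitnessWeights()
        self.config = config if config is not None else GAConfig()

    @classmethod
    def from_table(
        cls,
        path,
        cell: UnitCell,
        resolution_range: tuple[float, float],
        weights: FitnessWeights | None = None,
        config: GAConfig | None = None,
    ) -> "GeneticGrouping":
        pool, _ = read_pool(path, format="table", cell=cell, resolution_range=resolution_range)
        return cls(pool, weights, config)

    def balance(self, r_user: float = 1.0, user_multipliers: dict | None = None) -> FitnessWeights:
        """Run the one-cycle automatic weight balancing and adopt the result."""
        self.weights = balance_weights(
            self.pool, self.config, r_user=r_user, user_multipliers=user_multipliers
        )
        return self.weights

    def fit(self, seed: int | None = None, auto_balance: bool = False,
            r_user: float = 1.0, user_multipliers: dict | None = None) -> "GroupingResults":
        """Run the GA and return the results object."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        weights = self.weights
        if auto_balance:
            weights = balance_weights(
                self.pool, config, r_user=r_user, user_multipliers=user_multipliers
            )
        result = evolve(self.pool, weights, config)
        return GroupingResults(self, result)

    def fit_random_control(self, seed: int | None = None) -> Archive:
        """Matched-budget random sampling of chromosomes (no GA operators)."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        return random_control(self.pool, self.weights, config)


class GroupingResults:
    """Results of a GA grouping run."""

    def __init__(self, model: GeneticGrouping, result: GAResult):
        self.model = model
        self._result = result

    # pass-through conveniences -------------------------------------------
    @property
    def best_labels(self) -> np.ndarray:
        return self._result.best_chromosome.labels

    @property
    def best_group_ids(self) -> list[str]:
        return self._result.best_group_ids

    @property
    def best_stats(self):
        return self._result.best_stats

    @property
    def fitness(self) -> float:
        return self._result.best_fitness

    @property
    def archive(self) -> Archive:
        return self._result.archive

    @property
    def config(self) -> GAConfig:
        return self._result.config

    @property
    def weights(self) -> FitnessWeights:
        return self._result.weights

    def archive_frame(self):
        return self.archive.to_frame()

    def compare_with_all(self, truth: SyntheticTruth | None = None) -> ComparisonReport:
        return compare_ga_vs_all(self.model.pool, self._result, truth)

    def analyze_archive(self, truth: SyntheticTruth) -> ArchiveAnalysis:
        return archive_analysis(self.archive, self.model.pool, truth)

    def summary(self) -> str:
        """Printable run summary: configuration, best group and statistics."""
        r = self._result
        w = r.weights
        lines = [
            "Genetic-algorithm merging-group selection",
            "=" * 57,
            f"pool: {self.model.pool.n_subdatasets} sub-data sets, "
            f"{self.model.pool.n_observations} observations, "
            f"{self.model.pool.index.n_unique} unique reflections",
            f"config: population {r.config.population_size}, generations {r.config.generations}, "
            f"groups {r.config.n_groups}, p_mut {r.config.p_mutation}, p_cx {r.config.p_crossover}, "
            f"seed {r.config.seed}",
            "weights: "
            + ", ".join(
                f"{t}={w.effective(t):.4g}"
                for t in ("r_meas", "i_over_sigma", "cc_anom", "cc_half",
                          "completeness", "multiplicity")
            ),
            f"evaluations archived: {len(r.archive)}",
            f"best fitness: {r.best_fitness:.6g} (group {r.best_group_label}, "
            f"{len(r.best_group_ids)} sub-data sets)",
        ]
        if r.best_stats is not None:
            lines.append("best-group statistics (inner / outer / overall):")
            for row in r.best_stats.to_rows():
                vals = " / ".join(
                    "-" if row[c] is None else f"{row[c]:.4g}"
                    for c in ("inner", "outer", "overall")
                )
                lines.append(f"  {row['statistic']:14s} {vals}")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Best archived fitness per generation (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self._result.generations_best, lw=1.5)
        ax.set_xlabel("generation")
        ax.set_ylabel("best fitness in generation")
        return ax

    def plot_archive(self, statistic: str = "cc_anom", truth: SyntheticTruth | None = None, ax=None):
        """Scatter of an archived statistic against recovery (with truth) or
        fitness (without)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if truth is not None:
            analysis = self.analyze_archive(truth)
            ax.scatter(analysis.table[statistic], analysis.table["recovery"], s=4, alpha=0.4)
            ax.set_ylabel("anomalous recovery")
        else:
            frame = self.archive_frame()
            frame = frame[frame["group"] >= 0]
            ax.scatter(frame[f"{statistic}_overall"], frame["fitness"], s=4, alpha=0.4)
            ax.set_ylabel("fitness")
        ax.set_xlabel(statistic)
        return ax
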