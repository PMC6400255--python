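"""Archive post-analysis: merging statistics versus anomalous-signal recovery.

Because intermediate GA solutions are never deleted, one run produces
thousands of (grouping, merging statistics) pairs.  On synthetic pools each
archived group can additionally be scored by how well its merged Bijvoet
differences recover the planted ones, which makes it possible to ask the
central methodological question: *which merging statistic actually tracks
anomalous signal?*  Rank (Spearman) correlations are used because the
relationships are visibly nonlinear; decile binning summarises the trend.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sps

from .ga import Archive, GAResult
from .merging import MergingStats, UndefinedStatistic, compute_stats, merge_group
from .reflections import Pool
from .simulate import SyntheticTruth, anomalous_recovery

__all__ = ["ArchiveAnalysis", "archive_analysis", "compare_ga_vs_all", "ComparisonReport"]

ANALYSIS_STATS = ("cc_anom", "cc_half", "i_over_sigma", "r_meas")


@dataclass
class ArchiveAnalysis:
    """Long-format join of archived groups with recovery, plus summaries."""

    table: pd.DataFrame
    spearman: dict  # statistic -> rank correlation with recovery
    binned: dict  # statistic -> DataFrame(bin, mean statistic, mean recovery, n)

    def to_text(self) -> str:
        lines = ["archive analysis", f"  records analysed: {len(self.table)}"]
        for stat, rho in self.spearman.items():
            lines.append(f"  spearman({stat}, recovery) = {rho:+.3f}")
        return "\n".join(lines)


def _stat_value(stats: MergingStats, name: str) -> float | None:
    if name == "r_meas":
        return stats.r_meas.inner
    return getattr(stats, name).overall


def archive_analysis(
    archive: Archive,
    pool: Pool,
    truth: SyntheticTruth,
    n_bins: int = 10,
) -> ArchiveAnalysis:
    """Join each archived record's best group with its anomalous recovery.

    One row per qualifying record (records whose chromosome produced at
    least one scoreable group).  Recovery of a given group is computed once
    and cached by group membership.
    """
    if len(archive) == 0:
        raise ValueError("archive is empty")
    rec_cache: dict[frozenset, float] = {}
    ids = pool.ids
    rows = []
    for ridx, rec in enumerate(archive):
        if rec.best_group is None or rec.best_group not in rec.group_stats:
            continue
        stats = rec.group_stats[rec.best_group]
        members = frozenset(np.nonzero(rec.labels == rec.best_group)[0].tolist())
        recovery = rec_cache.get(members)
        if recovery is None:
            ms = merge_group(pool, [ids[i] for i in sorted(members)])
            try:
                recovery = anomalous_recovery(ms, truth)
            except UndefinedStatistic:
                recovery = np.nan
            rec_cache[members] = recovery
        row = {
            "record": ridx,
            "generation": rec.generation,
            "group": rec.best_group,
            "n_subdatasets": len(members),
            "fitness": rec.fitness,
            "recovery": recovery,
        }
        for name in ANALYSIS_STATS:
            row[name] = _stat_value(stats, name)
        rows.append(row)
    if not rows:
        raise ValueError("no qualifying archive records to analyse")
    table = pd.DataFrame(rows)

    usable = table.dropna(subset=["recovery"])
    spearman = {}
    binned = {}
    for name in ANALYSIS_STATS:
        sub = usable.dropna(subset=[name])
        if len(sub) >= 3 and sub[name].nunique() > 1 and sub["recovery"].nunique() > 1:
            rho = float(sps.spearmanr(sub[name], sub["recovery"]).statistic)
        else:
            rho = np.nan
        spearman[name] = rho
        if len(sub) >= n_bins:
            cats = pd.qcut(sub[name], n_bins, duplicates="drop")
            grouped = sub.groupby(cats, observed=True).agg(
                mean_stat=(name, "mean"), mean_recovery=("recovery", "mean"), n=(name, "size")
            )
            binned[name] = grouped.reset_index(names="bin")
    return ArchiveAnalysis(table=table, spearman=spearman, binned=binned)


@dataclass
class ComparisonReport:
    """Side-by-side merging statistics: all-merged pool vs the GA best group."""

    all_stats: MergingStats
    ga_stats: MergingStats
    n_all: int
    n_ga: int
    recovery_all: float | None
    recovery_ga: float | None
    improved: dict  # statistic -> bool (GA better than all-merged, overall)
    config_echo: dict

    def to_text(self) -> str:
        def fmt(t):
            return " / ".join("-" if v is None else f"{v:.4g}" for v in t)

        lines = [
            "all-merged vs GA-selected group  (inner / outer / overall)",
            f"  sub-data sets: {self.n_all} vs {self.n_ga}",
        ]
        for name in (
            "r_merge", "r_meas", "i_over_sigma", "cc_half", "cc_anom",
            "sig_ano", "completeness", "multiplicity",
        ):
            a = fmt(getattr(self.all_stats, name))
            g = fmt(getattr(self.ga_stats, name))
            mark = ""
            if name in self.improved:
                mark = "  [improved]" if self.improved[name] else ""
            lines.append(f"  {name:14s} all: {a:30s} GA: {g}{mark}")
        if self.recovery_all is not None or self.recovery_ga is not None:
            lines.append(
                f"  anomalous recovery: all {self.recovery_all} vs GA {self.recovery_ga}"
            )
        for k, v in self.config_echo.items():
            lines.append(f"  {k} = {v}")
        return "\n".join(lines)


_HIGHER_BETTER = {
    "r_merge": False, "r_meas": False, "i_over_sigma": True, "cc_half": True,
    "cc_anom": True, "sig_ano": True, "completeness": True, "multiplicity": True,
}


def compare_ga_vs_all(
    pool: Pool,
    result: GAResult,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> ComparisonReport:
    """Compare the GA's best merging group against merging everything."""
    stat_seed = result.config.seed if seed is None else seed
    all_ids = pool.ids
    ga_ids = result.best_group_ids or all_ids
    all_stats = compute_stats(pool, all_ids, shells=result.config.n_shells, seed=stat_seed)
    ga_stats = compute_stats(pool, ga_ids, shells=result.config.n_shells, seed=stat_seed)

    improved = {}
    for name, higher in _HIGHER_BETTER.items():
        a = getattr(all_stats, name).overall
        g = getattr(ga_stats, name).overall
        if a is None or g is None:
            continue
        improved[name] = (g > a) if higher else (g < a)

    recovery_all = recovery_ga = None
    if truth is not None:
        try:
            recovery_all = anomalous_recovery(merge_group(pool, all_ids), truth)
            recovery_ga = anomalous_recovery(merge_group(pool, ga_ids), truth)
        except UndefinedStatistic:
            pass
    return ComparisonReport(
        all_stats=all_stats,
        ga_stats=ga_stats,
        n_all=len(all_ids),
        n_ga=len(ga_ids),
        recovery_all=recovery_all,
        recovery_ga=recovery_ga,
        improved=improved,
        config_echo={
            "seed": result.config.seed,
            "population_size": result.config.population_size,
            "generations": result.config.generations,
            "n_groups": result.config.n_groups,
            "p_mutation": result.config.p_mutation,
            "p_crossover": result.config.p_crossover,
        },
    )
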