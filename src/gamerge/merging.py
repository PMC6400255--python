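"""Merging statistics for subsets of a multi-crystal pool.

Implements the eight standard data-quality statistics used to judge a merged
set of unmerged observations: R_merge, R_meas, <I/sigma(I)>, CC1/2, CC_anom,
SigAno, completeness and multiplicity, each reported for the inner resolution
shell, the outer shell, and overall.

Conventions
-----------
* R_merge = sum_h sum_i |I_hi - <I_h>| / sum_h sum_i I_hi, accumulated only
  over unique reflections measured at least twice; R_meas multiplies each
  reflection's deviation sum by sqrt(n_h / (n_h - 1)) (the multiplicity
  correction of Diederichs & Karplus).
* <I/sigma> is computed on merged reflections: the inverse-variance weighted
  mean intensity over its propagated sigma, averaged over unique reflections.
* CC1/2 splits each reflection's observations into two random half-sets
  (seeded, balanced) and correlates the half-set means.  No sigma-tau
  extrapolation is applied.
* CC_anom forms the Bijvoet difference <I+> - <I-> separately in each
  half-set, requiring at least two observations of each Friedel sign, and
  correlates the two half-set difference series.
* SigAno = mean over Friedel-paired reflections of
  |<I+> - <I->| / sqrt(sigma(<I+>)^2 + sigma(<I->)^2), with per-sign merged
  values; it is computed on intensities (no French-Wilson conversion to
  amplitudes is performed).

A statistic whose preconditions fail (e.g. R_merge with no multiply-measured
reflection) raises :class:`UndefinedStatistic`; :func:`compute_stats` records
such values as ``None``, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .reflections import Pool, ShellAssignment

__all__ = [
    "UndefinedStatistic",
    "MergedSet",
    "MergingStats",
    "ShellTriple",
    "merge_group",
    "r_merge",
    "r_meas",
    "mean_i_over_sigma",
    "cc_half",
    "cc_anom",
    "sig_ano",
    "completeness",
    "multiplicity",
    "compute_stats",
]


class UndefinedStatistic(ValueError):
    """The statistic's preconditions are not met; distinct from a zero value."""


class ShellTriple(NamedTuple):
    inner: float | None
    outer: float | None
    overall: float | None


class MergedSet:
    """Observations of a selected subset of sub-data sets, grouped by unique
    reflection.

    Internally array-backed: ``code`` maps each observation to a compact
    unique-reflection index (0..n_unique-1).  The dict view required by the
    grouped-observations contract is available through :meth:`reflections`.
    """

    def __init__(self, unique_hkl, code, intensity, sigma, sign, subdataset, provenance,
                 pool_codes=None):
        self.unique_hkl = np.asarray(unique_hkl)
        # optional map from local unique index to the owning pool's unique code
        self.pool_codes = None if pool_codes is None else np.asarray(pool_codes, dtype=np.int64)
        self.code = np.asarray(code, dtype=np.int64)
        self.intensity = np.asarray(intensity, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.sign = np.asarray(sign, dtype=np.int8)
        self.subdataset = list(subdataset)
        self.provenance = tuple(provenance)
        if self.code.size == 0:
            raise UndefinedStatistic("merged set is empty")
        self.n_unique = int(self.code.max()) + 1

    @property
    def n_obs(self) -> int:
        return self.code.size

    def reflections(self) -> dict:
        """Grouped view: {(h,k,l): [(intensity, sigma, sign, subdataset_id), ...]}."""
        out: dict[tuple[int, int, int], list] = {}
        for i in range(self.n_obs):
            key = tuple(int(x) for x in self.unique_hkl[self.code[i]])
            out.setdefault(key, []).append(
                (self.intensity[i], self.sigma[i], int(self.sign[i]), self.subdataset[i])
            )
        return out

    @classmethod
    def from_observations(cls, mapping: Mapping, provenance: Iterable[str] = ()) -> "MergedSet":
        """Build from {(h,k,l): [(I, sigma, sign, subdataset_id), ...]}."""
        hkl_rows, iv, sv, gv, dv = [], [], [], [], []
        for key, obs_list in mapping.items():
            for obs in obs_list:
                hkl_rows.append(key)
                iv.append(obs[0])
                sv.append(obs[1])
                gv.append(obs[2] if len(obs) > 2 else 1)
                dv.append(obs[3] if len(obs) > 3 else "?")
        if not hkl_rows:
            raise UndefinedStatistic("merged set is empty")
        hkl = np.asarray(hkl_rows, dtype=np.int64)
        uniq, code = np.unique(hkl, axis=0, return_inverse=True)
        return cls(uniq, code.astype(np.int64), iv, sv, gv, dv, provenance)

    def restrict(self, obs_mask: np.ndarray, label: str) -> "MergedSet":
        """Sub-set of observations (e.g. one resolution shell); codes re-compacted."""
        if not obs_mask.any():
            raise UndefinedStatistic(f"no observations in {label}")
        code = self.code[obs_mask]
        kept, new_code = np.unique(code, return_inverse=True)
        return MergedSet(
            self.unique_hkl[kept],
            new_code.astype(np.int64),
            self.intensity[obs_mask],
            self.sigma[obs_mask],
            self.sign[obs_mask],
            [self.subdataset[i] for i in np.nonzero(obs_mask)[0]],
            self.provenance,
            pool_codes=None if self.pool_codes is None else self.pool_codes[kept],
        )


def merge_group(pool: Pool, subset_ids: Sequence[str]) -> MergedSet:
    """Collect the observations of the selected sub-data sets, grouped by
    unique reflection.  No rescaling is applied."""
    if not subset_ids:
        raise ValueError("subset is empty")
    idx = pool.index
    positions = [pool.position_of(s) for s in subset_ids]
    obs = np.concatenate([idx.sub_ranges[p] for p in positions])
    obs.sort()
    kept, code = np.unique(idx.code[obs], return_inverse=True)
    sub_ids = np.array(pool.ids, dtype=object)[idx.sub[obs]]
    return MergedSet(
        idx.unique_hkl[kept],
        code.astype(np.int64),
        idx.intensity[obs],
        idx.sigma[obs],
        idx.sign[obs],
        list(sub_ids),
        provenance=tuple(subset_ids),
        pool_codes=kept,
    )


# ---------------------------------------------------------------------------
# statistic kernels


def _counts(ms: MergedSet) -> np.ndarray:
    return np.bincount(ms.code, minlength=ms.n_unique)


def _r_factors(ms: MergedSet) -> tuple[float, float]:
    counts = _counts(ms)
    sums = np.bincount(ms.code, weights=ms.intensity, minlength=ms.n_unique)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    dev = np.abs(ms.intensity - mean[ms.code])
    multi = counts >= 2
    if not multi.any():
        raise UndefinedStatistic("no unique reflection measured more than once")
    dev_sum = np.bincount(ms.code, weights=dev, minlength=ms.n_unique)
    obs_multi = multi[ms.code]
    denom = float(ms.intensity[obs_multi].sum())
    num_merge = float(dev_sum[multi].sum())
    factor = np.sqrt(counts[multi] / (counts[multi] - 1.0))
    num_meas = float((dev_sum[multi] * factor).sum())
    if denom == 0:
        raise UndefinedStatistic("zero intensity sum in R-factor denominator")
    return num_merge / denom, num_meas / denom


def r_merge(ms: MergedSet) -> float:
    """Linear merging residual over multiply-measured reflections."""
    return _r_factors(ms)[0]


def r_meas(ms: MergedSet) -> float:
    """Multiplicity-corrected merging residual (factor sqrt(n/(n-1)))."""
    return _r_factors(ms)[1]


def _merged_intensity(code, intensity, sigma, n_unique):
    """Inverse-variance merge: returns (I_hat, sigma_hat, observed mask)."""
    w = 1.0 / np.square(sigma)
    sw = np.bincount(code, weights=w, minlength=n_unique)
    swi = np.bincount(code, weights=w * intensity, minlength=n_unique)
    observed = sw > 0
    i_hat = np.full(n_unique, np.nan)
    s_hat = np.full(n_unique, np.nan)
    i_hat[observed] = swi[observed] / sw[observed]
    s_hat[observed] = 1.0 / np.sqrt(sw[observed])
    return i_hat, s_hat, observed


def mean_i_over_sigma(ms: MergedSet) -> float:
    """Mean over unique reflections of merged I over its propagated sigma."""
    if np.any(ms.sigma <= 0):
        raise ValueError("non-positive sigma in merged set")
    i_hat, s_hat, observed = _merged_intensity(ms.code, ms.intensity, ms.sigma, ms.n_unique)
    return float(np.mean(i_hat[observed] / s_hat[observed]))


def _half_split(code: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random balanced half-assignment (0/1) within each code group."""
    order = np.lexsort((rng.random(code.size), code))
    rank = np.empty(code.size, dtype=np.int64)
    # rank within group = position in sorted order minus group start
    sorted_code = code[order]
    starts = np.concatenate(([0], np.cumsum(np.bincount(sorted_code))))[:-1]
    rank[order] = np.arange(code.size) - starts[sorted_code]
    return (rank % 2).astype(np.int8)


def cc_half(ms: MergedSet, seed: int = 0) -> float:
    """Half-set correlation CC1/2: Pearson correlation between the mean
    intensities of two random halves of each reflection's observations."""
    rng = np.random.default_rng(seed)
    counts = _counts(ms)
    half = _half_split(ms.code, rng)
    usable = counts >= 2
    if usable.sum() < 3:
        raise UndefinedStatistic("CC1/2 needs >= 3 reflections with >= 2 observations")
    means = []
    for h in (0, 1):
        sel = half == h
        c = np.bincount(ms.code[sel], minlength=ms.n_unique)
        s = np.bincount(ms.code[sel], weights=ms.intensity[sel], minlength=ms.n_unique)
        with np.errstate(invalid="ignore", divide="ignore"):
            means.append(s / c)
    x, y = means[0][usable], means[1][usable]
    return _pearson(x, y, "CC1/2")


def _pearson(x: np.ndarray, y: np.ndarray, what: str) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        raise UndefinedStatistic(f"{what} undefined: zero variance in half-set series")
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


def _anom_half_diffs(ms: MergedSet, rng: np.random.Generator):
    """Per-reflection Bijvoet differences in each half-set.

    Returns (d0, d1, qualifying mask): reflections with >= 2 observations of
    each Friedel sign, so both halves of both signs are populated.
    """
    plus = ms.sign > 0
    group = ms.code * 2 + (~plus).astype(np.int64)  # (reflection, sign) groups
    half = _half_split(group, rng)
    n = ms.n_unique
    cnt = {}
    mean = {}
    for s_label, s_mask in (("+", plus), ("-", ~plus)):
        for h in (0, 1):
            sel = s_mask & (half == h)
            c = np.bincount(ms.code[sel], minlength=n)
            m = np.bincount(ms.code[sel], weights=ms.intensity[sel], minlength=n)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean[(s_label, h)] = m / c
            cnt[(s_label, h)] = c
    ok = (
        (cnt[("+", 0)] > 0)
        & (cnt[("+", 1)] > 0)
        & (cnt[("-", 0)] > 0)
        & (cnt[("-", 1)] > 0)
    )
    d0 = mean[("+", 0)] - mean[("-", 0)]
    d1 = mean[("+", 1)] - mean[("-", 1)]
    return d0, d1, ok


def cc_anom(ms: MergedSet, seed: int = 0) -> float:
    """Half-set correlation of Bijvoet (anomalous) differences."""
    rng = np.random.default_rng(seed)
    d0, d1, ok = _anom_half_diffs(ms, rng)
    if ok.sum() < 3:
        raise UndefinedStatistic(
            "CC_anom needs >= 3 reflections with both Friedel signs measured twice"
        )
    return _pearson(d0[ok], d1[ok], "CC_anom")


def sig_ano(ms: MergedSet) -> float:
    """Mean anomalous difference over its propagated uncertainty."""
    plus = ms.sign > 0
    n = ms.n_unique
    res = {}
    for label, mask in (("+", plus), ("-", ~plus)):
        if mask.any():
            res[label] = _merged_intensity(
                ms.code[mask], ms.intensity[mask], ms.sigma[mask], n
            )
        else:
            res[label] = (np.full(n, np.nan), np.full(n, np.nan), np.zeros(n, dtype=bool))
    ip, sp, op_ = res["+"]
    im, sm, om = res["-"]
    ok = op_ & om
    if not ok.any():
        raise UndefinedStatistic("SigAno needs at least one Friedel-paired reflection")
    z = np.abs(ip[ok] - im[ok]) / np.sqrt(sp[ok] ** 2 + sm[ok] ** 2)
    return float(z.mean())


def completeness(ms: MergedSet, pool: Pool, reference_codes: np.ndarray | None = None) -> float:
    """Fraction of reference unique reflections with >= 1 observation.

    The default reference is every unique reflection observed anywhere in the
    full pool; an explicit ``reference_unique_count`` on the pool overrides
    the denominator.
    """
    observed_keys = {tuple(int(x) for x in row) for row in ms.unique_hkl}
    if reference_codes is not None:
        ref_keys = {tuple(int(x) for x in row) for row in reference_codes}
    elif isinstance(pool.reference_unique_count, int):
        n_ref = pool.reference_unique_count
        if n_ref <= 0:
            raise ValueError("reference unique count must be positive")
        return min(1.0, len(observed_keys) / n_ref)
    else:
        ref_keys = {tuple(int(x) for x in row) for row in pool.index.unique_hkl}
    if not ref_keys:
        raise ValueError("empty completeness reference")
    return len(observed_keys & ref_keys) / len(ref_keys)


def multiplicity(ms: MergedSet) -> float:
    """Mean number of observations per observed unique reflection."""
    return ms.n_obs / len(np.unique(ms.code))


# ---------------------------------------------------------------------------
# shelled reporting


_STAT_NAMES = (
    "r_merge",
    "r_meas",
    "i_over_sigma",
    "cc_half",
    "cc_anom",
    "sig_ano",
    "completeness",
    "multiplicity",
)


@dataclass(frozen=True)
class MergingStats:
    """The eight merging statistics, each as (inner, outer, overall).

    ``None`` marks a statistic undefined for that shell (preconditions not
    met), which is distinct from a value of zero.  R factors and correlation
    coefficients are stored as fractions / values in [-1, 1]; reports convert
    to percent.
    """

    r_merge: ShellTriple
    r_meas: ShellTriple
    i_over_sigma: ShellTriple
    cc_half: ShellTriple
    cc_anom: ShellTriple
    sig_ano: ShellTriple
    completeness: ShellTriple
    multiplicity: ShellTriple
    n_subdatasets: int = 0
    n_observations: int = 0
    n_unique: int = 0

    def as_dict(self) -> dict:
        return {
            name: tuple(getattr(self, name)) for name in _STAT_NAMES
        }

    def to_rows(self) -> list[dict]:
        rows = []
        for name in _STAT_NAMES:
            t = getattr(self, name)
            rows.append(
                {"statistic": name, "inner": t.inner, "outer": t.outer, "overall": t.overall}
            )
        return rows


def compute_stats(
    pool: Pool,
    subset_ids: Sequence[str],
    shells: ShellAssignment | int | None = 10,
    seed: int = 0,
    engine=None,
) -> MergingStats:
    """All eight statistics for the merge of ``subset_ids``, as
    (inner, outer, overall) triples.

    The overall column is computed on the unshelled merged set (never as an
    average over shells).  Statistics whose preconditions fail in a shell are
    reported as ``None``.  A prebuilt :class:`~gamerge._engine.StatsEngine`
    may be passed to amortise the per-pool setup over many subsets.
    """
    if not subset_ids:
        raise ValueError("subset is empty")
    if engine is None:
        from ._engine import StatsEngine

        engine = StatsEngine(pool, shells=shells, seed=seed)
    positions = [pool.position_of(s) for s in subset_ids]
    return engine.stats(positions)
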