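"""Array engine for merging statistics over many subsets of one pool.

The GA evaluates thousands of sub-data-set groupings of the same pool.  This
engine presorts the pool's observations once (for the seeded half-set splits
of CC1/2 and CC_anom) so that every per-subset statistic reduces to linear
passes and ``bincount`` aggregations — no per-evaluation sorting.

The half-set split is defined by a per-run random priority per observation:
within each reflection (or each (reflection, Friedel-sign) group for
CC_anom), the selected observations are ranked by priority and alternate
halves by rank parity, which yields a balanced random split that is
deterministic given the seed and stable across subsets.
"""

from __future__ import annotations

import numpy as np

from .merging import MergingStats, ShellTriple, _STAT_NAMES
from .reflections import Pool, ShellAssignment, assign_shells

__all__ = ["StatsEngine"]


def _rank_parity(sorted_sel_groups: np.ndarray) -> np.ndarray:
    """Rank parity (0/1) within runs of equal, non-decreasing group labels."""
    n = sorted_sel_groups.size
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    np.not_equal(sorted_sel_groups[1:], sorted_sel_groups[:-1], out=new_group[1:])
    starts = np.maximum.accumulate(np.where(new_group, np.arange(n), 0))
    return ((np.arange(n) - starts) & 1).astype(np.int8)


class StatsEngine:
    """Merging statistics for arbitrary subsets of one pool's sub-data sets."""

    def __init__(self, pool: Pool, shells: ShellAssignment | int | None = 10, seed: int = 0):
        idx = pool.index
        self.pool = pool
        self.seed = seed
        if isinstance(shells, ShellAssignment):
            self.shells = shells
        else:
            self.shells = assign_shells(pool, 10 if shells is None else shells)
        self.code = idx.code
        self.sign = idx.sign
        self.intensity = idx.intensity
        self.sigma = idx.sigma
        self.weight = 1.0 / np.square(idx.sigma)
        self.n_unique = idx.n_unique
        self.n_obs = idx.n_obs
        self.shell_of_obs = self.shells.shell_of_unique[self.code]
        self.shell_ref = np.bincount(
            self.shells.shell_of_unique, minlength=self.shells.n_shells + 1
        )
        self.sub_ranges = idx.sub_ranges

        rng = np.random.default_rng(seed)
        r_half = rng.random(self.n_obs)
        r_anom = rng.random(self.n_obs)
        self.order_half = np.lexsort((r_half, self.code))
        key2 = self.code * 2 + (self.sign < 0)
        self.order_anom = np.lexsort((r_anom, key2))
        self.code_by_half_order = self.code[self.order_half]
        self.key2_by_anom_order = key2[self.order_anom]

    # ------------------------------------------------------------------
    def subset_mask(self, positions) -> np.ndarray:
        mask = np.zeros(self.n_obs, dtype=bool)
        for p in positions:
            mask[self.sub_ranges[p]] = True
        return mask

    def half_assignment(self, sel: np.ndarray, anom: bool = False):
        """(observation indices, half labels) of the seeded split for a
        selection mask — exposed so tests can recompute CC statistics
        independently from the same split."""
        order = self.order_anom if anom else self.order_half
        groups = self.key2_by_anom_order if anom else self.code_by_half_order
        sel_sorted = sel[order]
        pos = np.flatnonzero(sel_sorted)
        half = _rank_parity(groups[pos])
        return order[pos], half

    # ------------------------------------------------------------------
    def _column(self, sel: np.ndarray, n_ref: int) -> dict:
        out: dict[str, float | None] = {name: None for name in _STAT_NAMES}
        m = int(sel.sum())
        if m == 0:
            if n_ref:
                out["completeness"] = 0.0
            return out
        code = self.code[sel]
        ivals = self.intensity[sel]
        w = self.weight[sel]
        u = self.n_unique

        counts = np.bincount(code, minlength=u)
        observed = counts > 0
        n_observed = int(observed.sum())
        out["multiplicity"] = m / n_observed
        if n_ref:
            out["completeness"] = min(1.0, n_observed / n_ref)

        sums = np.bincount(code, weights=ivals, minlength=u)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = sums / counts
        multi = counts >= 2
        if multi.any():
            dev = np.abs(ivals - mean[code])
            dev_sum = np.bincount(code, weights=dev, minlength=u)
            denom = float(ivals[multi[code]].sum())
            if denom != 0:
                out["r_merge"] = float(dev_sum[multi].sum()) / denom
                factor = np.sqrt(counts[multi] / (counts[multi] - 1.0))
                out["r_meas"] = float((dev_sum[multi] * factor).sum()) / denom

        sw = np.bincount(code, weights=w, minlength=u)
        swi = np.bincount(code, weights=w * ivals, minlength=u)
        with np.errstate(invalid="ignore", divide="ignore"):
            i_over_sig = swi / np.sqrt(sw)
        out["i_over_sigma"] = float(np.mean(i_over_sig[observed]))

        out["cc_half"] = self._cc_half(sel, counts)
        out["cc_anom"] = self._cc_anom(sel)
        out["sig_ano"] = self._sig_ano(sel)
        return out

    def _pearson(self, x, y):
        x = x - x.mean()
        y = y - y.mean()
        denom = np.sqrt((x * x).sum() * (y * y).sum())
        if denom == 0:
            return None
        return float(np.clip((x * y).sum() / denom, -1.0, 1.0))

    def _cc_half(self, sel, counts):
        usable = counts >= 2
        if usable.sum() < 3:
            return None
        obs_idx, half = self.half_assignment(sel, anom=False)
        u = self.n_unique
        code = self.code[obs_idx]
        ivals = self.intensity[obs_idx]
        h0 = half == 0
        c0 = np.bincount(code[h0], minlength=u)
        s0 = np.bincount(code[h0], weights=ivals[h0], minlength=u)
        c1 = np.bincount(code[~h0], minlength=u)
        s1 = np.bincount(code[~h0], weights=ivals[~h0], minlength=u)
        with np.errstate(invalid="ignore", divide="ignore"):
            m0, m1 = s0 / c0, s1 / c1
        return self._pearson(m0[usable], m1[usable])

    def _cc_anom(self, sel):
        obs_idx, half = self.half_assignment(sel, anom=True)
        u = self.n_unique
        code = self.code[obs_idx]
        ivals = self.intensity[obs_idx]
        plus = self.sign[obs_idx] > 0
        cnt = {}
        mean = {}
        for s_flag, s_mask in ((1, plus), (0, ~plus)):
            for h in (0, 1):
                m = s_mask & (half == h)
                c = np.bincount(code[m], minlength=u)
                s = np.bincount(code[m], weights=ivals[m], minlength=u)
                with np.errstate(invalid="ignore", divide="ignore"):
                    mean[(s_flag, h)] = s / c
                cnt[(s_flag, h)] = c
        ok = (
            (cnt[(1, 0)] > 0) & (cnt[(1, 1)] > 0) & (cnt[(0, 0)] > 0) & (cnt[(0, 1)] > 0)
        )
        if ok.sum() < 3:
            return None
        d0 = mean[(1, 0)][ok] - mean[(0, 0)][ok]
        d1 = mean[(1, 1)][ok] - mean[(0, 1)][ok]
        return self._pearson(d0, d1)

    def _sig_ano(self, sel):
        u = self.n_unique
        plus = self.sign > 0
        res = {}
        for flag, s_mask in ((1, plus), (0, ~plus)):
            m = sel & s_mask
            code = self.code[m]
            w = self.weight[m]
            sw = np.bincount(code, weights=w, minlength=u)
            swi = np.bincount(code, weights=w * self.intensity[m], minlength=u)
            res[flag] = (sw, swi)
        swp, swip = res[1]
        swm, swim = res[0]
        ok = (swp > 0) & (swm > 0)
        if not ok.any():
            return None
        diff = np.abs(swip[ok] / swp[ok] - swim[ok] / swm[ok])
        sig = np.sqrt(1.0 / swp[ok] + 1.0 / swm[ok])
        return float(np.mean(diff / sig))

    # ------------------------------------------------------------------
    def stats(self, positions) -> MergingStats:
        """MergingStats triples for the union of the given sub-data-set
        positions."""
        sel = self.subset_mask(positions)
        n_shells = self.shells.n_shells
        ref_overall = self.n_unique
        if isinstance(self.pool.reference_unique_count, int):
            ref_overall = self.pool.reference_unique_count
        columns = {
            "inner": self._column(sel & (self.shell_of_obs == 1), int(self.shell_ref[1])),
            "outer": self._column(
                sel & (self.shell_of_obs == n_shells), int(self.shell_ref[n_shells])
            ),
            "overall": self._column(sel, ref_overall),
        }
        triples = {
            name: ShellTriple(
                columns["inner"][name], columns["outer"][name], columns["overall"][name]
            )
            for name in _STAT_NAMES
        }
        m = int(sel.sum())
        return MergingStats(
            **triples,
            n_subdatasets=len(list(positions)),
            n_observations=m,
            n_unique=int((np.bincount(self.code[sel], minlength=self.n_unique) > 0).sum()),
        )
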