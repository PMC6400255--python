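"""Domain types for unmerged multi-crystal reflection data.

A *sub-data set* is a small partial data set (typically a ~10-30 degree wedge
collected from one micro-crystal position).  A :class:`Pool` is an ordered
collection of sub-data sets sharing a unit cell and resolution range — the
object a grouping optimisation runs over.  Miller indices are stored already
reduced to a Friedel-unique representative, with ``friedel_sign`` recording
which mate of the pair was actually measured; the intensity difference between
the two mates carries the anomalous signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .cell import UnitCell, d_spacing

__all__ = [
    "ReflectionObservation",
    "SubDataSet",
    "Pool",
    "ShellAssignment",
    "reduce_friedel",
    "reduce_friedel_array",
    "assign_shells",
]


class ReflectionObservation(NamedTuple):
    """One unmerged intensity measurement.

    ``(h, k, l)`` is the Friedel-reduced representative index;
    ``friedel_sign`` is +1 if the representative itself was measured and -1
    for its mate (-h, -k, -l).
    """

    h: int
    k: int
    l: int
    friedel_sign: int
    intensity: float
    sigma: float
    subdataset_id: str


def reduce_friedel(h: int, k: int, l: int, symmetry_ops: Sequence | None = None):
    """Map a Miller index to its Friedel-unique representative.

    Returns ``((h, k, l), sign)``.  With the default P1 setting the
    representative is whichever of (h,k,l) and (-h,-k,-l) has its first
    nonzero component positive; ``sign`` is +1 if the input equals the
    representative and -1 if it is the mate.  An optional list of 3x3 integer
    rotation matrices extends the orbit for higher symmetry; the
    representative is then the lexicographically largest canonical-positive
    equivalent, which keeps the map deterministic and idempotent.
    """
    rep, sign = reduce_friedel_array(
        np.array([[h, k, l]], dtype=np.int64), symmetry_ops=symmetry_ops
    )
    return tuple(int(x) for x in rep[0]), int(sign[0])


def _first_nonzero_positive(hkl: np.ndarray) -> np.ndarray:
    """Boolean mask: first nonzero component of each row is positive."""
    n = hkl.shape[0]
    out = np.zeros(n, dtype=bool)
    decided = np.zeros(n, dtype=bool)
    for col in range(3):
        v = hkl[:, col]
        newly = ~decided & (v != 0)
        out[newly] = v[newly] > 0
        decided |= newly
    return out


def reduce_friedel_array(hkl: np.ndarray, symmetry_ops: Sequence | None = None):
    """Vectorised :func:`reduce_friedel` over an (n, 3) integer array."""
    hkl = np.asarray(hkl, dtype=np.int64)
    if symmetry_ops is None:
        ops = [np.eye(3, dtype=np.int64)]
    else:
        ops = [np.asarray(op, dtype=np.int64) for op in symmetry_ops]
        if not any(np.array_equal(op, np.eye(3, dtype=np.int64)) for op in ops):
            ops = [np.eye(3, dtype=np.int64)] + ops

    n = hkl.shape[0]
    if np.any(np.abs(hkl) >= 1 << 20):
        raise ValueError("Miller indices out of supported range")
    best_rep = np.zeros_like(hkl)
    best_sign = np.zeros(n, dtype=np.int8)
    best_key = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    for op in ops:
        for sign in (1, -1):
            cand = sign * (hkl @ op.T)
            ok = _first_nonzero_positive(cand)
            # exact integer lexicographic key; non-canonical rows never win
            key = (cand[:, 0] << 42) + (cand[:, 1] << 21) + cand[:, 2]
            key = np.where(ok, key, np.iinfo(np.int64).min)
            better = key > best_key
            best_key[better] = key[better]
            best_rep[better] = cand[better]
            best_sign[better] = sign
    zero = np.all(hkl == 0, axis=1)  # (0,0,0) is its own mate
    best_rep[zero] = 0
    best_sign[zero] = 1
    return best_rep, best_sign


@dataclass
class SubDataSet:
    """One partial data set: the unit the genetic algorithm assigns to groups."""

    id: str
    observations: list[ReflectionObservation]
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"sub-data set {self.id!r} has no observations")
        for obs in self.observations:
            if obs.subdataset_id != self.id:
                raise ValueError(
                    f"observation carries id {obs.subdataset_id!r}, expected {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.observations)


class PoolIndex:
    """Flat numpy view of a pool's observations, built once and cached.

    Columns: ``hkl`` (m, 3), ``sign``, ``intensity``, ``sigma``, ``sub`` (the
    position of the owning sub-data set in the pool), plus the factorisation
    of indices into compact unique-reflection codes.  Every merging statistic
    is computed from these arrays.
    """

    def __init__(self, pool: "Pool") -> None:
        hkl_parts, sign_parts, i_parts, s_parts, sub_parts = [], [], [], [], []
        for pos, sds in enumerate(pool.subdatasets):
            m = len(sds.observations)
            arr = np.array(
                [(o.h, o.k, o.l, o.friedel_sign) for o in sds.observations], dtype=np.int64
            )
            hkl_parts.append(arr[:, :3])
            sign_parts.append(arr[:, 3].astype(np.int8))
            i_parts.append(np.array([o.intensity for o in sds.observations]))
            s_parts.append(np.array([o.sigma for o in sds.observations]))
            sub_parts.append(np.full(m, pos, dtype=np.int64))
        self.hkl = np.concatenate(hkl_parts)
        self.sign = np.concatenate(sign_parts)
        self.intensity = np.concatenate(i_parts)
        self.sigma = np.concatenate(s_parts)
        self.sub = np.concatenate(sub_parts)
        self.unique_hkl, self.code = np.unique(self.hkl, axis=0, return_inverse=True)
        self.code = self.code.astype(np.int64)
        self.n_unique = self.unique_hkl.shape[0]
        self.unique_d = d_spacing(self.unique_hkl, pool.unit_cell)
        # contiguous observation index ranges per sub-data set
        bounds = np.cumsum([0] + [len(s) for s in pool.subdatasets])
        self.sub_ranges = [
            np.arange(bounds[i], bounds[i + 1]) for i in range(len(pool.subdatasets))
        ]

    @property
    def n_obs(self) -> int:
        return self.hkl.shape[0]


@dataclass
class Pool:
    """Ordered collection of sub-data sets; chromosome position i always
    refers to ``subdatasets[i]``."""

    subdatasets: list[SubDataSet]
    unit_cell: UnitCell
    resolution_range: tuple[float, float]  # (d_max, d_min), Angstrom
    reference_unique_count: int | str = "derived"
    _index: PoolIndex | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.subdatasets:
            raise ValueError("pool has no sub-data sets")
        ids = [s.id for s in self.subdatasets]
        if len(set(ids)) != len(ids):
            raise ValueError("sub-data-set ids are not unique")
        d_max, d_min = self.resolution_range
        if not d_max > d_min > 0:
            raise ValueError(f"resolution_range must be (d_max, d_min) with d_max > d_min > 0")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subdatasets]

    @property
    def n_subdatasets(self) -> int:
        return len(self.subdatasets)

    @property
    def n_observations(self) -> int:
        return sum(len(s) for s in self.subdatasets)

    @property
    def index(self) -> PoolIndex:
        if self._index is None:
            self._index = PoolIndex(self)
        return self._index

    def position_of(self, subdataset_id: str) -> int:
        for i, s in enumerate(self.subdatasets):
            if s.id == subdataset_id:
                return i
        raise KeyError(f"unknown sub-data set id {subdataset_id!r}")


@dataclass
class ShellAssignment:
    """Equal-count resolution shells over a pool's unique reflections.

    Shell 1 is the inner (lowest-resolution, largest d) shell; shell
    ``n_shells`` is the outer shell.  ``shell_of_unique[i]`` gives the shell
    ordinal of the pool's i-th unique reflection code.
    """

    n_shells: int
    boundaries: np.ndarray  # descending d cut points, length n_shells - 1
    shell_of_unique: np.ndarray  # int, 1..n_shells, indexed by unique code

    def __post_init__(self) -> None:
        if self.n_shells < 2:
            raise ValueError("need at least 2 shells")

    @property
    def shell_sizes(self) -> np.ndarray:
        return np.bincount(self.shell_of_unique, minlength=self.n_shells + 1)[1:]


def assign_shells(pool: Pool, n_shells: int = 10) -> ShellAssignment:
    """Partition the pool's unique reflections into equal-count resolution shells.

    Reflections are sorted by descending d and split into ``n_shells`` bins
    whose populations differ by at most one.  Degenerate pools (all unique
    reflections at the same d, or fewer uniques than shells) are rejected.
    """
    if n_shells < 2:
        raise ValueError("n_shells must be >= 2")
    idx = pool.index
    if idx.n_unique < n_shells:
        raise ValueError(
            f"cannot make {n_shells} shells from {idx.n_unique} unique reflections"
        )
    if np.unique(idx.unique_d).size < n_shells:
        raise ValueError("degenerate d-spacing distribution: too few distinct values")
    order = np.argsort(-idx.unique_d, kind="stable")
    shell_of = np.empty(idx.n_unique, dtype=np.int64)
    # equal-count split: sizes differ by at most 1
    splits = np.array_split(order, n_shells)
    for ordinal, members in enumerate(splits, start=1):
        shell_of[members] = ordinal
    boundaries = np.array([idx.unique_d[s[-1]] for s in splits[:-1]])
    return ShellAssignment(n_shells=n_shells, boundaries=boundaries, shell_of_unique=shell_of)
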