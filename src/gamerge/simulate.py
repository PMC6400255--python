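"""Synthetic multi-crystal reflection pools with known ground truth.

Emulates the situation the grouping optimiser is built for: a pool of many
partial sub-data sets (small wedges collected from different micro-crystal
positions), carrying a weak anomalous signal (Bijvoet ratio ~1-2%), split
into a few non-isomorphous classes plus some low-quality ("junk") wedges.

Model
-----
* True intensities follow a Wilson-like exponential distribution with a
  single overall B factor controlling the resolution falloff:
  I_true ~ Exp(mean = i0 * exp(-B / (2 d^2))).
* Anomalous signal is planted at the intensity level.  With F = sqrt(I),
  per-reflection amplitude differences dF ~ N(0, (ratio * RMS(F))^2) give
  dI = 2 F dF, and the two Friedel mates measure I +- dI/2.  The realised
  RMS(dF)/RMS(F) equals the configured Bijvoet ratio up to sampling error.
* Non-isomorphism: each class carries a fixed per-reflection intensity
  perturbation 2 * sigma_delta * I_true * z (z ~ N(0,1) drawn once per
  class), i.e. a linearised amplitude offset of sigma_delta * |F|.  The
  perturbation is shared by both Friedel mates, so it cancels in Bijvoet
  differences measured within one class but corrupts them when classes are
  mixed (through unbalanced sampling of the two signs across classes) —
  the mechanism that makes non-isomorphism poisonous to anomalous phasing.
* Each wedge observes a random subset of unique reflections (completeness
  drawn per wedge), each 1+Poisson times, with Gaussian noise of honestly
  reported sigma; junk wedges get a noise multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .cell import UnitCell, d_spacing
from .merging import MergedSet, UndefinedStatistic, _merged_intensity
from .reflections import (
    Pool,
    ReflectionObservation,
    SubDataSet,
    reduce_friedel_array,
)

__all__ = [
    "ClassSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_truth",
    "simulate_pool",
    "make_pool",
    "anomalous_recovery",
]


@dataclass(frozen=True)
class ClassSpec:
    """One isomorphism class of sub-data sets.

    ``scale`` is an overall intensity scale, ``b_offset`` an extra B factor
    (Angstrom^2), and ``sigma_delta`` the non-isomorphism magnitude as a
    fraction of |F|.
    """

    label: str
    count: int
    scale: float = 1.0
    b_offset: float = 0.0
    sigma_delta: float = 0.0


def _default_classes() -> list[ClassSpec]:
    return [
        ClassSpec("A", 25, scale=1.0, b_offset=0.0, sigma_delta=0.15),
        ClassSpec("B", 25, scale=0.9, b_offset=4.0, sigma_delta=0.15),
    ]


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults emulate a two-class + junk pool of 60
    wedges with ~45% per-wedge completeness and a 1.5% Bijvoet ratio."""

    n_unique: int = 600
    unit_cell: UnitCell = field(default_factory=lambda: UnitCell(50.0, 60.0, 70.0))
    resolution_range: tuple[float, float] = (20.0, 2.0)
    bijvoet_ratio: float = 0.015
    classes: list[ClassSpec] = field(default_factory=_default_classes)
    junk_count: int = 10
    junk_noise_multiplier: float = 5.0
    completeness_mean: float = 0.45
    completeness_sd: float = 0.046
    mean_obs_per_unique: float = 2.5  # per wedge, for uniques the wedge covers
    noise_scale: float = 0.35
    i0: float = 100.0
    wilson_b: float = 20.0
    seed: int = 0

    @property
    def n_subdatasets(self) -> int:
        return sum(c.count for c in self.classes) + self.junk_count

    def __post_init__(self) -> None:
        if self.n_unique < 10:
            raise ValueError("n_unique too small")
        if not 0 <= self.bijvoet_ratio < 1:
            raise ValueError("bijvoet_ratio must be a small fraction")
        if not (0 < self.completeness_mean <= 1):
            raise ValueError("completeness_mean must be in (0, 1]")
        if self.junk_count < 0 or any(c.count <= 0 for c in self.classes):
            raise ValueError("class counts must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated pool: noise-free intensities, planted
    anomalous differences and the class label of every sub-data set."""

    unique_hkl: np.ndarray  # (u, 3) Friedel-reduced representatives
    d: np.ndarray
    i_true: np.ndarray
    delta_i_true: np.ndarray  # I(+) - I(-), noise-free
    class_of_subdataset: dict  # id -> class label ("junk" for junk wedges)
    config: SyntheticConfig

    def code_of(self) -> dict:
        cached = self.__dict__.get("_code_cache")
        if cached is None:
            cached = {tuple(int(x) for x in row): i for i, row in enumerate(self.unique_hkl)}
            self.__dict__["_code_cache"] = cached
        return cached


def _candidate_indices(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """All Friedel-unique indices in the resolution range."""
    d_max, d_min = cfg.resolution_range
    cell = cfg.unit_cell
    hmax = int(np.ceil(cell.a / d_min))
    kmax = int(np.ceil(cell.b / d_min))
    lmax = int(np.ceil(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(0, hmax + 1), np.arange(-kmax, kmax + 1), np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[~np.all(hkl == 0, axis=1)]
    rep, _ = reduce_friedel_array(hkl)
    rep = np.unique(rep, axis=0)
    d = d_spacing(rep, cell)
    ok = (d > d_min) & (d <= d_max)
    return rep[ok], d[ok]


def simulate_truth(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw ground-truth intensities and anomalous differences.

    Unique indices are sampled inside the configured resolution shell; true
    intensities are exponential with Wilson falloff; anomalous differences
    are zero-mean with RMS amplitude ratio equal to ``bijvoet_ratio``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cand, cand_d = _candidate_indices(config)
    if cand.shape[0] < config.n_unique:
        raise ValueError(
            f"resolution shell holds only {cand.shape[0]} uniques, need {config.n_unique}"
        )
    pick = rng.choice(cand.shape[0], size=config.n_unique, replace=False)
    pick.sort()
    hkl, d = cand[pick], cand_d[pick]

    mean_i = config.i0 * np.exp(-config.wilson_b / (2.0 * d * d))
    i_true = rng.exponential(1.0, size=config.n_unique) * mean_i

    if config.bijvoet_ratio > 0:
        f = np.sqrt(i_true)
        rms_f = float(np.sqrt(np.mean(f * f)))
        delta_f = rng.normal(0.0, config.bijvoet_ratio * rms_f, size=config.n_unique)
        delta_i = 2.0 * f * delta_f
    else:
        delta_i = np.zeros(config.n_unique)

    class_labels: dict[str, str] = {}
    for spec in config.classes:
        for j in range(spec.count):
            class_labels[f"{spec.label}{j:03d}"] = spec.label
    for j in range(config.junk_count):
        class_labels[f"junk{j:03d}"] = "junk"

    return SyntheticTruth(
        unique_hkl=hkl, d=d, i_true=i_true, delta_i_true=delta_i,
        class_of_subdataset=class_labels, config=config,
    )


def _sigma_model(i_expected: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    # counting-statistics-like: background floor plus Poisson-ish term;
    # a tiny positive floor keeps sigmas valid in the noise-free limit
    return np.maximum(cfg.noise_scale * np.sqrt(np.abs(i_expected) + 0.05 * cfg.i0), 1e-8)


def simulate_pool(
    truth: SyntheticTruth, config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Pool:
    """Generate the observed pool for a ground truth.

    Each wedge draws its completeness from N(mean, sd) clipped to
    (0.01, 1], observes each covered unique 1+Poisson(mean_obs-1) times with
    a random Friedel sign per observation, and reports the true noise sigma.
    """
    cfg = truth.config if config is None else config
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    u = truth.i_true.size
    s2 = 1.0 / (4.0 * truth.d * truth.d)  # (sin theta / lambda)^2

    # per-class fixed perturbation, shared within the class
    class_z = {spec.label: rng.standard_normal(u) for spec in cfg.classes}
    class_by_label = {spec.label: spec for spec in cfg.classes}

    subdatasets: list[SubDataSet] = []
    for sid, class_label in truth.class_of_subdataset.items():
        is_junk = class_label == "junk"
        spec = None if is_junk else class_by_label[class_label]

        comp = float(np.clip(rng.normal(cfg.completeness_mean, cfg.completeness_sd), 0.011, 1.0))
        n_cov = max(5, int(round(comp * u)))
        covered = rng.choice(u, size=min(n_cov, u), replace=False)
        n_obs_each = 1 + rng.poisson(max(cfg.mean_obs_per_unique - 1.0, 0.0), size=covered.size)
        uniq_idx = np.repeat(covered, n_obs_each)
        sign = np.where(rng.random(uniq_idx.size) < 0.5, 1, -1).astype(np.int8)

        base = truth.i_true[uniq_idx] + 0.5 * sign * truth.delta_i_true[uniq_idx]
        if is_junk:
            i_exp = base
            noise_mult = cfg.junk_noise_multiplier
        else:
            assert spec is not None
            perturb = 2.0 * spec.sigma_delta * truth.i_true[uniq_idx] * class_z[class_label][uniq_idx]
            dw = spec.scale * np.exp(-spec.b_offset * s2[uniq_idx])
            i_exp = dw * (base + perturb)
            noise_mult = 1.0
        sigma = _sigma_model(i_exp, cfg) * noise_mult
        i_obs = i_exp + rng.normal(0.0, 1.0, size=sigma.size) * sigma

        hkl = truth.unique_hkl[uniq_idx]
        obs = [
            ReflectionObservation(
                int(hkl[j, 0]), int(hkl[j, 1]), int(hkl[j, 2]),
                int(sign[j]), float(i_obs[j]), float(sigma[j]), sid,
            )
            for j in range(uniq_idx.size)
        ]
        subdatasets.append(SubDataSet(id=sid, observations=obs, source="synthetic"))

    return Pool(
        subdatasets=subdatasets,
        unit_cell=cfg.unit_cell,
        resolution_range=cfg.resolution_range,
    )


def make_pool(config: SyntheticConfig | None = None, seed: int | None = None):
    """Convenience: truth + pool in one call, fully determined by the seed."""
    cfg = config if config is not None else SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_truth(cfg, rng)
    pool = simulate_pool(truth, cfg, rng)
    return pool, truth


def anomalous_recovery(ms: MergedSet, truth: SyntheticTruth) -> float:
    """Correlation between merged observed Bijvoet differences and the
    planted ones — the desk-scale stand-in for anomalous difference map
    peak heights.

    Uses reflections with both Friedel signs measured and nonzero planted
    difference; per-sign intensities are inverse-variance merged.
    """
    if not np.any(truth.delta_i_true != 0):
        raise UndefinedStatistic("truth carries no anomalous signal")
    n = ms.n_unique
    plus = ms.sign > 0
    res = {}
    for label, mask in (("+", plus), ("-", ~plus)):
        if mask.any():
            res[label] = _merged_intensity(ms.code[mask], ms.intensity[mask], ms.sigma[mask], n)
        else:
            raise UndefinedStatistic("no observations of one Friedel sign")
    ip, _, op_ = res["+"]
    im, _, om = res["-"]
    code_map = truth.code_of()
    truth_idx = np.array(
        [code_map.get(tuple(int(x) for x in row), -1) for row in ms.unique_hkl], dtype=np.int64
    )
    valid = truth_idx >= 0
    planted = np.zeros(truth_idx.size, dtype=bool)
    planted[valid] = truth.delta_i_true[truth_idx[valid]] != 0
    ok = op_ & om & planted
    if ok.sum() < 3:
        raise UndefinedStatistic("fewer than 3 Friedel-paired reflections with planted signal")
    d_obs = ip[ok] - im[ok]
    d_true = truth.delta_i_true[truth_idx[ok]]
    d_obs = d_obs - d_obs.mean()
    d_true = d_true - d_true.mean()
    denom = np.sqrt((d_obs**2).sum() * (d_true**2).sum())
    if denom == 0:
        raise UndefinedStatistic("zero variance in difference series")
    return float(np.clip((d_obs * d_true).sum() / denom, -1.0, 1.0))
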