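import numpy as np
import pytest

from gamerge import ClassSpec, GAConfig, SyntheticConfig, UnitCell, balance_weights, evolve, make_pool
from gamerge.reflections import Pool, ReflectionObservation, SubDataSet

#: the study fitness: the standard user weights (R_meas 1, <I/sigma> 2,
#: CC_anom 0, CC1/2 1, completeness 0.2, multiplicity 0) applied on top of
#: one-cycle automatic balancing with r_user = 0.1
STUDY_MULTIPLIERS = {
    "r_meas": 1.0,
    "i_over_sigma": 2.0,
    "cc_anom": 0.0,
    "cc_half": 1.0,
    "completeness": 0.2,
    "multiplicity": 0.0,
}
STUDY_R_USER = 0.1


def study_ga_run(seed, population=40, generations=80):
    """One full grouping run under the study conditions: default two-class +
    junk pool, balanced weights, run to convergence."""
    pool, truth = make_pool(seed=seed)
    config = GAConfig(
        population_size=population, generations=generations, n_groups=3, seed=seed
    )
    weights = balance_weights(
        pool, config, r_user=STUDY_R_USER, user_multipliers=STUDY_MULTIPLIERS
    )
    result = evolve(pool, weights, config)
    return {"pool": pool, "truth": truth, "config": config,
            "weights": weights, "result": result}


@pytest.fixture(scope="session")
def study_runs():
    """Ten independent study runs (seeds 1..10); shared by the archive
    analysis and acceptance tests."""
    return [study_ga_run(seed) for seed in range(1, 11)]


def small_synthetic_config(seed=0, n_per_class=5, junk=2, n_unique=200, **kw):
    """Small two-class pool configuration for fast unit tests."""
    defaults = dict(
        n_unique=n_unique,
        classes=[
            ClassSpec("A", n_per_class, 1.0, 0.0, 0.15),
            ClassSpec("B", n_per_class, 0.9, 4.0, 0.15),
        ],
        junk_count=junk,
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_pool():
    """Two classes of 5 + 2 junk wedges, 200 unique reflections."""
    return make_pool(small_synthetic_config(seed=11))


@pytest.fixture(scope="session")
def default_pool():
    """The standard study pool: 2 x 25 + 10 junk, 600 uniques."""
    return make_pool(seed=1)


def random_grouped_observations(rng, max_unique=40, max_obs=6):
    """Random {key: [(I, sigma, sign), ...]} mapping for oracle checks."""
    n_unique = int(rng.integers(4, max_unique + 1))
    groups = {}
    used = set()
    while len(groups) < n_unique:
        key = tuple(int(x) for x in rng.integers(-8, 9, size=3))
        if key in used or key == (0, 0, 0):
            continue
        used.add(key)
        n_obs = int(rng.integers(1, max_obs + 1))
        obs = [
            (
                float(rng.normal(100.0, 30.0)),
                float(rng.uniform(0.5, 5.0)),
                int(rng.choice([-1, 1])),
            )
            for _ in range(n_obs)
        ]
        groups[key] = obs
    return groups


def pool_from_grouped(groups, cell=None):
    """Single-sub-data-set pool holding the given grouped observations."""
    cell = cell or UnitCell(50.0, 60.0, 70.0)
    obs = []
    for key, olist in groups.items():
        for intensity, sigma, sign in olist:
            obs.append(
                ReflectionObservation(key[0], key[1], key[2], sign, intensity, sigma, "s0")
            )
    sds = SubDataSet(id="s0", observations=obs)
    return Pool([sds], cell, (1000.0, 0.1))
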