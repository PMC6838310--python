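"""Shared fixtures: small synthetic cohorts and their design matrices."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from deprisk import CohortSpec, generate_cohort
from deprisk.feature_prep import encode_dummies, standardize


def small_cohort_spec(seed: int = 7, **overrides) -> CohortSpec:
    """A reduced cohort: 12 peptides, 10 sociodemographic, 6 clinical."""
    kwargs = dict(
        n_reference=40,
        n_patients_train=40,
        n_patients_extrap=15,
        n_proteomic=12,
        n_sociodemographic=10,
        n_clinical=6,
        informative_features=[
            ("pep_001", "continuous", 1.2),
            ("bmi", "continuous", 1.0),
            ("sadness", "ordinal", 1.0),
        ],
        correlation_block_size=4,
        missing_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@pytest.fixture
def small_spec() -> CohortSpec:
    return small_cohort_spec()


@pytest.fixture
def small_table(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def small_design(small_table):
    raw, groups = encode_dummies(small_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = standardize(raw)
    return design, groups.subset(design.columns)


def random_grouped_problem(rng: np.random.Generator, n: int, group_sizes: list[int],
                           signal: float = 1.0):
    """A random logistic problem with the given penalty-group layout."""
    from deprisk.feature_prep import DesignMatrix, GroupStructure

    p = sum(group_sizes)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = rng.normal(0.0, signal, size=p)
    eta = X @ beta - (X @ beta).mean()
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < prob).astype(float)
    if y.min() == y.max():  # force both classes
        y[0] = 1.0 - y[0]
    columns = [f"x{j}" for j in range(p)]
    gids = np.concatenate([
        np.full(sz, g, dtype=np.int64) for g, sz in enumerate(group_sizes)
    ])
    design = DesignMatrix(X=X, y=y, columns=columns,
                          is_dummy=np.zeros(p, dtype=bool))
    groups = GroupStructure(columns=columns, group_ids=gids,
                            feature_of={c: f"g{g}" for c, g in zip(columns, gids)})
    return design, groups
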