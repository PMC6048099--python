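import numpy as np
import pandas as pd
import pytest

from longscn.synthetic import (
    ConfoundEffects,
    CovariateDistribution,
    GroupSpec,
    SyntheticScenario,
    generate_cohort,
)


@pytest.fixture
def triangle_weights():
    """The worked triangle: AB 0.8, AC 0.6, BC 0.2."""
    return np.array([[0.0, 0.8, 0.6], [0.8, 0.0, 0.2], [0.6, 0.2, 0.0]])


@pytest.fixture
def k4_half():
    """Complete graph on 4 nodes, all weights 0.5."""
    w = np.full((4, 4), 0.5)
    np.fill_diagonal(w, 0.0)
    return w


def two_visit_scenario(
    *,
    rho0: float = 0.4,
    rho12: float = 0.4,
    n_subjects: int = 30,
    n_regions: int = 20,
    seed: int = 0,
    label: str = "g",
    confounds: ConfoundEffects | None = None,
) -> SyntheticScenario:
    """One-group, two-visit scenario used across simulation tests."""
    return SyntheticScenario(
        groups=[
            GroupSpec(
                label,
                n_subjects,
                rho={0: rho0, 12: rho12},
                mean_thickness={0: 2.5, 12: 2.5},
            )
        ],
        n_regions=n_regions,
        timepoints=(0, 12),
        confounds=confounds or ConfoundEffects(),
        seed=seed,
    )


@pytest.fixture
def small_cohort():
    """Two small groups, four visits, 10 regions, with confound effects."""
    scenario = SyntheticScenario(
        groups=[
            GroupSpec(
                "HC",
                7,
                rho={0: 0.4, 3: 0.4, 6: 0.4, 12: 0.4},
                mean_thickness={m: 2.5 for m in (0, 3, 6, 12)},
                is_control=True,
            ),
            GroupSpec(
                "patient",
                9,
                rho={0: 0.55, 3: 0.5, 6: 0.45, 12: 0.35},
                mean_thickness={m: 2.5 for m in (0, 3, 6, 12)},
                covariates=CovariateDistribution(lesion_mean=4.0, lesion_sd=2.0),
            ),
        ],
        n_regions=10,
        confounds=ConfoundEffects(age_slope=-0.005, sex_offset=-0.03, lesion_slope=-0.004),
        seed=11,
    )
    return generate_cohort(scenario)


def random_weight_matrix(n: int, rng: np.random.Generator, density: float = 1.0):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        w = np.where(mask, w, 0.0)
    w = np.triu(w, 1)
    w = w + w.T
    return w


def long_format(x: np.ndarray, months, group="g", regions=None) -> pd.DataFrame:
    """Stack subjects x regions arrays (one per month) into the long dialect."""
    n, p = x[0].shape
    regions = regions or [f"r{i:02d}" for i in range(p)]
    rows = []
    for month, xm in zip(months, x):
        for i in range(n):
            for j in range(p):
                rows.append((f"s{i:03d}", group, month, regions[j], xm[i, j]))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "month", "region", "thickness_mm"]
    )
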