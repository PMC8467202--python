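import warnings

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from progscape import (OmicsMatrix, PathwayCollection, SimulationConfig,
                       SurvivalTable, generate_cohort,
                       generate_pathway_collection)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Filter routine solver warnings (zero-variance drops, non-converged
    path tails) so test output stays readable; error-level checks assert
    warnings explicitly where they matter."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*zero-variance.*")
        warnings.filterwarnings("ignore", message=".*non-converged.*")
        yield


@pytest.fixture(scope="session")
def tiny_pathways() -> PathwayCollection:
    return PathwayCollection(
        ["SETA", "SETB", "SETC"],
        {"SETA": ("G1", "G2", "G3"), "SETB": ("G4", "G5"),
         "SETC": ("G2", "G6", "G7")},
        {"SETA": "a", "SETB": "b", "SETC": "c"},
    )


@pytest.fixture
def small_matrix() -> OmicsMatrix:
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(1, 11)]
    samples = [f"S{i}" for i in range(1, 7)]
    return OmicsMatrix(pd.DataFrame(rng.standard_normal((10, 6)),
                                    index=genes, columns=samples))


@pytest.fixture
def small_survival() -> SurvivalTable:
    samples = [f"S{i}" for i in range(1, 7)]
    return SurvivalTable(pd.DataFrame(
        {"time": [5.0, 8.0, 3.0, 12.0, 7.0, 20.0],
         "event": [1, 0, 1, 1, 0, 1]},
        index=pd.Index(samples, name="sample")))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort with clear pathway-level signal, shared by
    the slower model-fitting tests."""
    config = SimulationConfig(n_samples=160, n_genes=80,
                              pathway_sizes=(8,) * 8,
                              n_prognostic_pathways=2, effect_size=1.2,
                              censoring_rate_target=0.3, seed=11)
    cohort = generate_cohort(config)
    return cohort, generate_pathway_collection(config)


def make_survival(time, event) -> SurvivalTable:
    idx = pd.Index([f"s{i}" for i in range(len(time))], name="sample")
    return SurvivalTable(pd.DataFrame(
        {"time": np.asarray(time, float), "event": np.asarray(event, int)},
        index=idx))
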