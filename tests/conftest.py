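import numpy as np
import pandas as pd
import pytest

from chemoscreen.datatypes import (
    DrugResponseTable,
    ExpressionMatrix,
    PredictionMatrix,
    RunConfig,
)
from chemoscreen.synthetic import (
    PlatformEffect,
    generate_cell_line_panel,
    generate_tumor_cohorts,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expr():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
        index=["TP53", "BRCA1", "EGFR"],
        columns=["S1", "S2", "S3"],
    )
    return ExpressionMatrix(data, platform="test")


@pytest.fixture
def quick_config():
    """Small-but-real run configuration for fast end-to-end tests."""
    return RunConfig(seed=0, cv_folds=5)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by the slower integration tests."""
    expr, response, truth = generate_cell_line_panel(
        n_lines=80, n_genes=200, n_drugs=16, n_candidates=3, seed=11
    )
    platforms = {
        "affymetrix": PlatformEffect(0.3, 1.2, 0.8, 1.0),
        "rnaseq": PlatformEffect(-0.4, 0.8, 0.75, 1.0),
    }
    cohorts, true_soc = generate_tumor_cohorts(
        truth, n_tumors=120, platforms=platforms, seed=12
    )
    return expr, response, truth, cohorts, true_soc


@pytest.fixture
def null_predictions(rng):
    """Predictions iid across samples: the no-signal regime for the screen."""
    samples = [f"S{i:03d}" for i in range(100)]
    drugs = ["cisplatin", "docetaxel"] + [f"d{i:03d}" for i in range(200)]
    data = pd.DataFrame(
        rng.standard_normal((100, len(drugs))), index=samples, columns=drugs
    )
    return PredictionMatrix(data, platform="null")
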