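import numpy as np
import pandas as pd
import pytest

from dgsyn.dataset import build_dataset, samples_to_frame
from dgsyn.omics import ExpressionMatrix, zscore_normalize
from dgsyn.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """The default synthetic universe (30 drugs, 12 cell lines, 600 triples)."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def normalized_expression(fixture_bundle):
    matrix, _ = zscore_normalize(ExpressionMatrix.from_frame(fixture_bundle["expression"]))
    return matrix


@pytest.fixture(scope="session")
def samples_frame(fixture_bundle, normalized_expression):
    samples, _ = build_dataset(
        fixture_bundle["synergy"],
        fixture_bundle["drugs"]["drug_id"],
        normalized_expression.cell_lines,
    )
    return samples_to_frame(samples)


@pytest.fixture(scope="session")
def small_model_kwargs(fixture_bundle, normalized_expression):
    """Fixture-scale architecture shared by training tests."""
    return dict(
        drug_smiles=fixture_bundle["drugs"],
        expression=normalized_expression.to_frame(),
        gin_hidden=(32, 32, 32),
        cell_hidden=(64, 48),
        coarse_dims=(96, 48, 48, 48),
        mlp_hidden=64,
        random_state=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_triples():
    return pd.DataFrame(
        {
            "drug1": ["D000", "D001", "D002"],
            "drug2": ["D001", "D002", "D000"],
            "cell_line": ["CL00", "CL01", "CL02"],
        }
    )
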