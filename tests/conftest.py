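import numpy as np
import pandas as pd
import pytest

from ibscluster import (GeneratorConfig, MixedDataMatrix, PipelineConfig,
                        VariableSchema, generate_cohort)

LIKERT = ("never or rarely", "sometimes", "often", "always")


@pytest.fixture
def small_schema():
    return [
        VariableSchema("AP", "Abdominal pain", "ordinal", levels=LIKERT),
        VariableSchema("COL", "Colour", "nominal", levels=("red", "green", "blue")),
        VariableSchema("ANX", "Anxiety", "continuous", range=(0, 21)),
    ]


@pytest.fixture
def small_matrix(small_schema):
    frame = pd.DataFrame(
        {
            "AP": ["never or rarely", "sometimes", "often", "always", "sometimes"],
            "COL": ["red", "green", "blue", "red", "green"],
            "ANX": [0.0, 7.0, 14.0, 21.0, 3.5],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"),
    )
    return MixedDataMatrix.from_labeled(frame, small_schema)


def toy_mixed(n: int, seed: int, p_ord: int = 3, p_cont: int = 2) -> MixedDataMatrix:
    """Small random mixed-type matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    schema = []
    cols = {}
    for j in range(p_ord):
        code = f"O{j}"
        schema.append(VariableSchema(code, code, "ordinal", levels=LIKERT))
        cols[code] = rng.integers(0, 4, size=n)
    for j in range(p_cont):
        code = f"C{j}"
        schema.append(VariableSchema(code, code, "continuous", range=(0, 10)))
        cols[code] = rng.uniform(0, 10, size=n)
    frame = pd.DataFrame(cols, index=pd.RangeIndex(n, name="sample_id"))
    return MixedDataMatrix(schema=schema, frame=frame)


@pytest.fixture
def toy_mixed_factory():
    return toy_mixed


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged default synthetic cohort (n=1000, nine planted profiles)."""
    return generate_cohort(GeneratorConfig(n_samples=1000, seed=988))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(master_seed=988)


@pytest.fixture(scope="session")
def fitted_default(default_cohort, default_config):
    """Full-cohort fit at the study's nine clusters, shared across tests."""
    from ibscluster import MixedSpectralClustering

    data, truth = default_cohort
    model = MixedSpectralClustering(data, default_config)
    return model.fit(k=9)
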