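import numpy as np
import pytest

from coexnet.datatypes import ExpressionMatrix, GeneSetCollection, SampleGroups
from coexnet.synthetic import SyntheticSpec, generate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 30 samples of independent noise."""
    values = rng.standard_normal((10, 30))
    return ExpressionMatrix([f"G{i}" for i in range(10)],
                            [f"S{j}" for j in range(30)], values)


@pytest.fixture
def modular_dataset():
    """Default planted-module dataset (4x12 modules, 40 background, 50+50)."""
    return generate_expression(SyntheticSpec(seed=7))


@pytest.fixture
def two_group_labels():
    def make(n_case, n_control):
        labels = {f"case_{i}": "case" for i in range(n_case)}
        labels.update({f"ctrl_{i}": "control" for i in range(n_control)})
        return SampleGroups(labels)
    return make


@pytest.fixture
def simple_gene_sets():
    return GeneSetCollection({
        "setA": ("first", ["G0", "G1", "G2"]),
        "setB": ("second", ["G3", "G4"]),
    })
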