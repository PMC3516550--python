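import numpy as np
import pandas as pd
import pytest

from tiescore.model import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneticMap,
    GenotypeMatrix,
    TraitVector,
)
from tiescore.simulate import CrossConfig, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One synthetic panel under the default study conditions."""
    return simulate_panel(CrossConfig(seed=7))


@pytest.fixture()
def tiny_map():
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3", "m4"],
                "chromosome": ["1", "1", "2", "2"],
                "cM": [0.0, 10.0, 0.0, 20.0],
                "bp": [1, 5_000_001, 1, 10_000_001],
            }
        )
    )


@pytest.fixture()
def tiny_genotypes(tiny_map):
    rng = np.random.default_rng(5)
    codes = rng.choice([0.0, 1.0, 2.0], size=(12, 4), p=[0.25, 0.5, 0.25])
    return GenotypeMatrix(
        mice=[f"M{i}" for i in range(12)], gmap=tiny_map, codes=codes
    )


def random_expression(n_genes=10, n_mice=12, seed=0, tissue="islet"):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        genes=[f"g{i}" for i in range(n_genes)],
        mice=[f"M{i}" for i in range(n_mice)],
        values=rng.standard_normal((n_genes, n_mice)),
        tissue=tissue,
    )


def random_trait(n_mice=12, seed=1, name="insulin"):
    rng = np.random.default_rng(seed)
    return TraitVector(
        mice=[f"M{i}" for i in range(n_mice)],
        values=rng.standard_normal(n_mice),
        name=name,
    )


def annotation_for(genes, chromosome="3", bp_start=1, step=1_000_000):
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene": list(genes),
                "chromosome": chromosome,
                "bp": [bp_start + i * step for i in range(len(genes))],
            }
        )
    )
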