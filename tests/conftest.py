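import numpy as np
import pandas as pd
import pytest

from stressprime.de import DETable
from stressprime.signature import Signature


def make_de_table(records, contrast="toy"):
    """Build a DETable from (gene_id, base_mean, lfc, p_value) tuples."""
    return DETable(
        contrast=contrast,
        data=pd.DataFrame(
            records, columns=["gene_id", "base_mean", "lfc", "p_value"]
        ),
    )


def random_de_table(rng, n=50, contrast="rand", genes=None):
    """Random but valid DE table for property-style checks."""
    if genes is None:
        genes = [f"g{i:03d}" for i in range(n)]
    return make_de_table(
        [
            (g, float(rng.uniform(0, 200)), float(rng.normal(0, 1)),
             float(rng.uniform(1e-6, 1.0)))
            for g in genes
        ],
        contrast=contrast,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_signature():
    return Signature(
        name="toy",
        up_genes=frozenset(f"u{i}" for i in range(30)),
        down_genes=frozenset(f"d{i}" for i in range(20)),
    )
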