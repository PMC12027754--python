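import numpy as np
import pandas as pd
import pytest

from cavpipe.io_formats import ExpressionMatrix
from cavpipe.synthetic_gtex import GeneratorConfig, generate_dataset


def make_expression(values: np.ndarray, genes=None, samples=None, tissue="t", unit="TPM"):
    """Wrap a raw array into an ExpressionMatrix with minimal annotations."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    if isinstance(tissue, str):
        tissue = [tissue] * len(samples)
    ann = pd.DataFrame({"tissue": tissue}, index=vals.columns)
    return ExpressionMatrix(vals, ann, unit=unit)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-tissue cohort with the default causal structure, modest size."""
    cfg = GeneratorConfig(n_tissues=3, samples_per_tissue=80, seed=11)
    return cfg, generate_dataset(cfg, cells_per_type=60)
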