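import numpy as np
import pandas as pd
import pytest

from cisfactor.preprocess import ExpressionMatrix


def make_design(n_replicates=3):
    rows = []
    for gen in ("Wt", "KO"):
        for trt in ("0", "LPS"):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "array_id": f"{gen}_{trt}_r{rep}",
                        "genotype": gen,
                        "treatment": trt,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("array_id")


def matrix_from_values(values, gene_ids=None, n_replicates=3, scale_state="raw"):
    design = make_design(n_replicates)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=design.index),
        design,
        scale_state=scale_state,
    )


@pytest.fixture
def design12():
    return make_design(3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
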