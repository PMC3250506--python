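import numpy as np
import pandas as pd
import pytest

from hetint.io import ExperimentDesign


@pytest.fixture
def small_design() -> ExperimentDesign:
    """Two replicates per role, the standard triplet layout."""
    return ExperimentDesign(
        {
            "monoA_r1": ("monoculture_A", 1),
            "monoA_r2": ("monoculture_A", 2),
            "monoB_r1": ("monoculture_B", 1),
            "monoB_r2": ("monoculture_B", 2),
            "co_r1": ("coculture", 1),
            "co_r2": ("coculture", 2),
        }
    )


@pytest.fixture
def spot_tsv(tmp_path):
    """Well-formed 3-spot table on disk."""
    path = tmp_path / "spots.tsv"
    path.write_text(
        "spot_id\tclone_id\tch1_fg\tch1_bg\tch2_fg\tch2_bg\tflag\n"
        "s1\tc1\t400\t100\t250\t100\t0\n"
        "s2\tc2\t900\t100\t300\t100\t0\n"
        "s3\tc3\t160\t100\t120\t100\t0\n"
    )
    return path


def make_matrix(values, genes=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=samples)
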