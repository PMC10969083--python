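import numpy as np
import pytest

from gfabric import AnalysisConfig, ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Four spots, three genes (B has two redundant spots), 4+4 replicates."""
    spot_ids = ["s1", "s2", "s3", "s4"]
    gene_of_spot = {"s1": "A", "s2": "B", "s3": "B", "s4": "C"}
    vals_n = np.array(
        [
            [2.0, 2.0, 2.0, 2.0],  # A: constant
            [10.0, 12.0, 9.0, 11.0],  # B spot 1
            [11.0, 13.0, 10.0, 12.0],  # B spot 2 (offset +1)
            [1.0, 2.0, 3.0, 4.0],  # C: monotone
        ]
    )
    vals_l = np.array(
        [
            [4.0, 4.2, 3.9, 4.1],
            [10.0, 12.0, 9.0, 11.0],
            [11.0, 13.0, 10.0, 12.0],
            [4.0, 3.0, 2.0, 1.0],  # C reversed
        ]
    )
    return ExpressionDataset(
        spot_ids=spot_ids,
        gene_of_spot=gene_of_spot,
        conditions=("N", "L"),
        values={"N": vals_n, "L": vals_l},
    )


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()
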