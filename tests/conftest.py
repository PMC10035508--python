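import logging

import numpy as np
import pytest

from splicescreen import JunctionCountMatrix

logging.getLogger("splicescreen").setLevel(logging.ERROR)


@pytest.fixture
def small_junctions() -> JunctionCountMatrix:
    """Two competing junctions (shared donor) plus one constitutive."""
    return JunctionCountMatrix(
        junction_ids=["chr3:100-200", "chr3:100-300", "chr3:400-500"],
        gene_of_junction={
            "chr3:100-200": "TP63",
            "chr3:100-300": "TP63",
            "chr3:400-500": "TP63",
        },
        sample_ids=["s1", "s2"],
        counts=np.array([[85, 10], [15, 30], [50, 60]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
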