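import numpy as np
import pandas as pd
import pytest

from otukit import SynthConfig, generate_community


@pytest.fixture(scope="session")
def default_community():
    """One default 18-sample synthetic data set (seed 42), shared read-only."""
    return generate_community(SynthConfig(seed=42))


@pytest.fixture()
def toy_table():
    """Tiny hand-written count table: 4 taxa x 4 samples."""
    return pd.DataFrame(
        {
            "s1": [10, 0, 5, 1],
            "s2": [2, 2, 0, 0],
            "s3": [0, 7, 7, 0],
            "s4": [1, 1, 1, 1],
        },
        index=pd.Index(["tA", "tB", "tC", "tD"], name="taxon_id"),
    )


@pytest.fixture()
def toy_info():
    return pd.DataFrame(
        {
            "habitat": ["water", "water", "sediment", "intestine"],
            "mode": ["MC", "RC", "MC", "RC"],
            "replicate": [1, 1, 1, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
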