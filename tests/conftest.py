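import numpy as np
import pandas as pd
import pytest

from glioproteo.containers import IntensityMatrix, SignatureSet
from glioproteo.synthetic import CohortConfig, generate_proteome_bundle


@pytest.fixture(scope="session")
def default_cohort():
    """Default two-batch synthetic cohort (39 samples, 26/13, seed 1)."""
    return generate_proteome_bundle(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def signature_100():
    return SignatureSet(
        gpc1_high=[f"A{i:03d}" for i in range(100)],
        gpc2_high=[f"B{i:03d}" for i in range(100)],
    )


@pytest.fixture()
def toy_matrix():
    """2x3 log2 matrix with a single GIS batch."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [3.0, 6.0, 5.0]],
        index=["f1", "f2"], columns=["s1", "s2", "s3"],
    )
    samples = pd.DataFrame(
        {"tmt_set": ["set1"] * 3, "gis_batch": ["GIS1"] * 3},
        index=["s1", "s2", "s3"],
    )
    return IntensityMatrix(values, log2=True, samples=samples)
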