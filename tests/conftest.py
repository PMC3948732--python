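import numpy as np
import pandas as pd
import pytest

from folliclepower import ModelSpec


@pytest.fixture
def toy_nested() -> pd.DataFrame:
    """Balanced two-fragment toy table with known variance components.

    Fragment A holds sections (1, 3), fragment B sections (5, 7): the
    expected-mean-squares solution is sigma2_section = 2 (MS_within) and
    sigma2_fragment = (MS_between - MS_within) / 2 = (16 - 2) / 2 = 7.
    """
    return pd.DataFrame(
        {
            "ewe_id": "e1",
            "ovary_id": "o1",
            "fragment_id": ["A", "A", "B", "B"],
            "section_index": [0, 1, 0, 1],
            "y": [1.0, 3.0, 5.0, 7.0],
        }
    )


@pytest.fixture
def intercept_only_spec() -> ModelSpec:
    return ModelSpec(fixed_factors=())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140310)
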