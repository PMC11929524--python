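import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lodpaternity import GenotypeMatrix

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def make_matrix(rows: dict[str, list], locus_ids: list[str],
                sex: dict[str, str] | None = None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from literal rows (None = missing)."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=locus_ids,
                                   dtype="object")
    frame = frame.astype("Int8")
    frame.index.name = "id"
    sex_series = None
    if sex is not None:
        sex_series = pd.Series({i: sex.get(i, "unknown") for i in frame.index})
    return GenotypeMatrix(genotypes=frame, sex=sex_series)


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """Offspring O1, mother M1, two candidates; 3 informative loci."""
    return make_matrix(
        {
            "M1": [0, 0, 1],
            "O1": [1, 0, 1],
            "F1": [2, 1, 1],
            "F2": [0, 2, 0],
        },
        ["L1", "L2", "L3"],
        sex={"M1": "female", "O1": "male", "F1": "male", "F2": "male"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)
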