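import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reductomir.core_io import CountMatrix, SampleDesign

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_design(sizes: dict[str, int], doses: dict[str, int] | None = None) -> SampleDesign:
    doses = doses or {"NTg": 0, "TgL": 1, "TgH": 2, "A": 0, "B": 1}
    rows = [
        {"sample_id": f"{g}_{i}", "group": g, "dose_code": doses[g]}
        for g, n in sizes.items()
        for i in range(1, n + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


def make_count_matrix(
    counts: np.ndarray, design: SampleDesign, feature_kind: str = "mRNA"
) -> CountMatrix:
    frame = pd.DataFrame(
        np.asarray(counts),
        index=[f"f{i}" for i in range(len(counts))],
        columns=design.sample_ids,
    )
    return CountMatrix(counts=frame, design=design, feature_kind=feature_kind)


@pytest.fixture
def two_group_design() -> SampleDesign:
    return make_design({"A": 2, "B": 2})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
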