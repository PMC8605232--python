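import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aviary_transect import BirdScoreRecord, HouseGeometry
from aviary_transect.reference import PUBLISHED_HOUSES

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def published_houses() -> dict[str, HouseGeometry]:
    return {h.house_id: h for h in PUBLISHED_HOUSES}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211013)


def make_graded_records(
    house: str, scheme: str, k_by_indicator: dict[tuple[str, int], int], n: int = 50
) -> list[BirdScoreRecord]:
    """n birds; the first k of them score `level` on `indicator` (disjointly
    assigned per indicator so each bird has one score per indicator)."""
    records = []
    for i in range(1, n + 1):
        scores: dict[str, int] = {}
        for (indicator, level), k in k_by_indicator.items():
            if i <= k:
                scores[indicator] = level
            else:
                scores.setdefault(indicator, 0)
        records.append(
            BirdScoreRecord(
                house_id=house,
                scheme_name=scheme,
                bird_ordinal=i,
                scores=scores,
                transect_index=1 + (i % 2),
                transect_kind="wall" if i % 2 else "central",
                vertical_level=1 + (i % 4),
            )
        )
    return records
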