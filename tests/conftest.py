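import numpy as np
import pytest

from crowdannot.annotation_core import AnswerKind, Rating
from crowdannot.rater_sim import SimConfig, generate_study


def binary_ratings(values, photo_id="p1", question_id="q1"):
    """Build one Rating per answer string for a single photo-question."""
    return [
        Rating(photo_id, f"rater{i:03d}", question_id, AnswerKind.BINARY, v)
        if v in ("present", "absent")
        else Rating(photo_id, f"rater{i:03d}", question_id, AnswerKind.CATEGORICAL, v)
        for i, v in enumerate(values)
    ]


def price_ratings(values, photo_id="p1", question_id="lowest_price"):
    return [
        Rating(photo_id, f"rater{i:03d}", question_id, AnswerKind.NUMERIC, v)
        for i, v in enumerate(values)
    ]


@pytest.fixture
def small_study():
    """8 photos x 20 raters, moderate-accuracy pool — fast default study."""
    return generate_study(SimConfig(n_photos=8, n_raters=20, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
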