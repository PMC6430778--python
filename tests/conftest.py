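import datetime as dt

import pytest

from dentalage import (
    DEFAULT_MODELS,
    ChildRecord,
    Stage,
    packaged_conversion_table,
    packaged_score_table,
)


@pytest.fixture(scope="session")
def score_table():
    return packaged_score_table()


@pytest.fixture(scope="session")
def conversion_table():
    return packaged_conversion_table()


@pytest.fixture(scope="session")
def male_model():
    return DEFAULT_MODELS["M"]


@pytest.fixture(scope="session")
def female_model():
    return DEFAULT_MODELS["F"]


@pytest.fixture
def make_record():
    """Factory for a child record with uniform stages on the seven left teeth."""

    def _make(stage=Stage.E, sex="M", child_id="c1", stages=None, **kwargs):
        if stages is None:
            stages = {t: stage for t in range(31, 38)}
        return ChildRecord(
            child_id=child_id,
            sex=sex,
            dob=kwargs.pop("dob", dt.date(2010, 1, 1)),
            dor=kwargs.pop("dor", dt.date(2017, 6, 1)),
            stages=stages,
            **kwargs,
        )

    return _make
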