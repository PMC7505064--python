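import datetime as dt

import numpy as np
import pytest

from bearcondition import BearRecord, Sex


@pytest.fixture
def rng():
    return np.random.default_rng(20160510)


@pytest.fixture
def small_records():
    """Three well-formed capture records."""
    return [
        BearRecord("A1", Sex.FEMALE, dt.date(2016, 5, 10), 98.0, 140.0,
                   age_years=6, torso_height=63.0),
        BearRecord("A2", Sex.MALE, dt.date(2016, 8, 31), 210.0, 175.0,
                   age_years=9),
        BearRecord("A3", Sex.FEMALE, dt.date(2016, 11, 1), 16.0, 70.0,
                   age_years=0),
    ]
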