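import numpy as np
import pytest

from sicolor import IndividualRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20190316)


@pytest.fixture
def small_records():
    """A handful of adult records spanning sexes, sites and seasons."""
    days = [75, 120, 160, 210, 250, 290, 75, 130, 170, 220, 260, 300]
    recs = []
    for i, day in enumerate(days):
        recs.append(IndividualRecord(
            id=f"L{i:03d}",
            population=["CA", "BG", "PA"][i % 3],
            sex="male" if i % 2 == 0 else "female",
            svl=55.0 + 2.5 * i,
            day=day,
            score=float(np.sin(i)),
        ))
    return recs
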