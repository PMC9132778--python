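import numpy as np
import pandas as pd
import pytest

from hhsaf.instrument import bundled_instrument
from hhsaf.synthetic import GenerationConfig, generate_dataset


@pytest.fixture(scope="session")
def instrument():
    return bundled_instrument()


@pytest.fixture(scope="session")
def max_answers(instrument):
    """Answer map choosing the maximum-point option everywhere."""
    return {ind.indicator_id: max(ind.answer_options, key=lambda o: o[1])[0]
            for ind in instrument.indicators}


@pytest.fixture(scope="session")
def min_answers(instrument):
    return {ind.indicator_id: min(ind.answer_options, key=lambda o: o[1])[0]
            for ind in instrument.indicators}


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic wave, shared across tests."""
    cfg = GenerationConfig(seed=20190116)
    return generate_dataset(cfg)


def make_response_row(response_id, answers, *, country="ALB", lat=41.3, lon=19.8,
                      name="Central Test Hospital", income="upper_middle",
                      region="europe", ftype="public", flevel="primary",
                      submitted="2019-06-01", wave="2019"):
    row = {
        "response_id": response_id,
        "facility_name": name,
        "country_code": country,
        "who_region": region,
        "income_level": income,
        "facility_type": ftype,
        "facility_level": flevel,
        "latitude": lat,
        "longitude": lon,
        "submitted_at": pd.Timestamp(submitted),
        "nationally_coordinated": False,
        "wave_label": wave,
    }
    row.update(answers)
    return row
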