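import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mycophen.io import Guild, SpeciesRecord, SurveyEvent


@pytest.fixture
def species_records():
    return [
        SpeciesRecord("ecm_a", "Russula", "Russulaceae", Guild.ECM),
        SpeciesRecord("ecm_b", "Amanita", "Amanitaceae", Guild.ECM),
        SpeciesRecord("lit_a", "Marasmius", "Marasmiaceae", Guild.LITTER),
        SpeciesRecord("wood_a", "Mycena", "Mycenaceae", Guild.WOOD),
        SpeciesRecord("hypo_a", "Tuber", "Tuberaceae", Guild.ECM,
                      hypogeous=True),
    ]


@pytest.fixture
def two_surveys():
    return [
        SurveyEvent(1, dt.date(1990, 5, 15), frozenset({"ecm_a", "ecm_b",
                                                        "lit_a"})),
        SurveyEvent(2, dt.date(1990, 6, 15), frozenset({"ecm_a"})),
    ]


@pytest.fixture
def constant_climate():
    """temp 10 degC and 1 mm rain every day through 1990."""
    dates = pd.date_range("1990-01-01", "1990-12-31", freq="D")
    return pd.DataFrame({"temp_mean_c": 10.0, "rain_mm": 1.0},
                        index=dates)
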