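import itertools

import numpy as np
import pandas as pd
import pytest

from ccsst.indicators import GALI, IndicatorProfile


@pytest.fixture
def profile_grid():
    """All 2^6 x 3 complete indicator profiles (the full rule domain)."""
    profiles = []
    for lt, nlt, dep, frail, imp, adl in itertools.product([False, True], repeat=6):
        for gali in GALI:
            profiles.append(
                IndicatorProfile(
                    frail=frail,
                    cognitively_impaired=imp,
                    depressed=dep,
                    gali=gali,
                    has_lt_chronic=lt,
                    has_nlt_chronic=nlt,
                    any_adl_difficulty=adl,
                    composite_cognition=0.0,
                )
            )
    return profiles


@pytest.fixture
def tiny_segmented_panel():
    """Hand-built segmented panel: 3 persons, 2 countries, with a death."""
    rows = [
        # person 1: low -> high, survives
        dict(person_id=1, country="X", wave=1, interview_time=0.0, age=60.0,
             gender="F", weight=2.0, gi_segment=1, any_cf=False,
             cf_assessable=True, health_state="low", death_time=np.nan),
        dict(person_id=1, country="X", wave=2, interview_time=2.0, age=62.0,
             gender="F", weight=2.0, gi_segment=4, any_cf=False,
             cf_assessable=True, health_state="high", death_time=np.nan),
        # person 2: high at baseline, dies at 3.0
        dict(person_id=2, country="X", wave=1, interview_time=0.0, age=75.0,
             gender="M", weight=1.0, gi_segment=5, any_cf=True,
             cf_assessable=True, health_state="high", death_time=3.0),
        # person 3: censored contact then low
        dict(person_id=3, country="Y", wave=1, interview_time=0.0, age=55.0,
             gender="F", weight=1.0, gi_segment=0, any_cf=False,
             cf_assessable=True, health_state="censored", death_time=np.nan),
        dict(person_id=3, country="Y", wave=2, interview_time=2.0, age=57.0,
             gender="F", weight=1.0, gi_segment=2, any_cf=False,
             cf_assessable=True, health_state="low", death_time=np.nan),
    ]
    return pd.DataFrame(rows)
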