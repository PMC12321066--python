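from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cmrselect.capture_io import Dataset, StudyDesign

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def design5() -> StudyDesign:
    """Five occasions: four yearly visits plus one extra late-season visit."""
    return StudyDesign(
        occasions=(
            ("may_y1", 2012.37),
            ("aug_y1", 2012.62),
            ("may_y2", 2013.37),
            ("may_y3", 2014.37),
            ("may_y4", 2015.37),
        ),
        species_codes=frozenset({"fence_lizard", "earless_lizard"}),
    )


@pytest.fixture
def toy_dataset(design5) -> Dataset:
    """Two individuals, three events, one trait with a gap."""
    frame = pd.DataFrame(
        {
            "individual_id": ["a", "a", "b"],
            "species": ["fence_lizard"] * 3,
            "occasion": [1, 3, 2],
            "svl": [50.0, 55.0, 48.0],
            "dorsal_L": [70.0, 72.0, np.nan],
        }
    )
    return Dataset.from_events(design5, frame)
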