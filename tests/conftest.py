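import numpy as np
import pandas as pd
import pytest

from ehrcausal.events import default_class_map


def ev(pid, day, system, code, value=np.nan):
    return (pid, int(day), system, code, value)


def events_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["patient_id", "day", "system", "code", "value"])


@pytest.fixture
def class_map():
    return default_class_map()


def basic_patient(pid, index_day=2000, birth_offset=21915, met_day=1500,
                  ingredient="glipizide", encounters=(1634, 2031, 2900),
                  extra=()):
    """One clean eligible patient; age ~60, sulfonylurea index by default."""
    rows = [
        ev(pid, index_day - birth_offset, "DEMOG", "BIRTH_DATE"),
        ev(pid, met_day, "MED", "metformin"),
        ev(pid, met_day + 60, "MED", "metformin"),
        ev(pid, index_day, "MED", ingredient),
        ev(pid, index_day + 60, "MED", ingredient),
    ]
    rows += [ev(pid, d, "ENCOUNTER", "ENC") for d in encounters]
    rows += list(extra)
    return rows
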