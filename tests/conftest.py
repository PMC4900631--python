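import datetime as dt

import numpy as np
import pandas as pd
import pytest

from fisofus.scan_io import ScanTable, SeasonCalendar


def make_scan_df(rows):
    """Rows of (date_iso, time_hm, subgroup_id, x, y, individual_id)."""
    recs = []
    for d, tm, sg, x, y, ind in rows:
        recs.append((dt.date.fromisoformat(d),
                     dt.time(*map(int, tm.split(":"))), sg, x, y, ind))
    return pd.DataFrame(recs, columns=["date", "time", "subgroup_id",
                                       "x", "y", "individual_id"])


def make_table(rows, roster=None, cal=None):
    t = ScanTable(make_scan_df(rows), roster=roster)
    return t.with_seasons(cal or SeasonCalendar())


@pytest.fixture(scope="session")
def calendar():
    return SeasonCalendar()


@pytest.fixture(scope="session")
def toy_table():
    """Two individuals together in 5 scans; A alone in 5 more, B alone in 3;
    one third individual C occasionally present."""
    rows = []
    for k in range(5):
        rows.append((f"2013-01-{k+1:02d}", "08:00", "S1", 10.0, 10.0, "A"))
        rows.append((f"2013-01-{k+1:02d}", "08:00", "S1", 10.0, 10.0, "B"))
    for k in range(5):
        rows.append((f"2013-01-{k+6:02d}", "09:00", "S2", 20.0, 20.0, "A"))
    for k in range(3):
        rows.append((f"2013-01-{k+11:02d}", "10:00", "S3", 30.0, 30.0, "B"))
    for k in range(2):
        rows.append((f"2013-01-{k+14:02d}", "11:00", "S4", 40.0, 40.0, "C"))
    return make_table(rows, roster={"A": "female", "B": "female", "C": "male"})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
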