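"""Published summary inputs from the La Jolla Giant Sea Bass tagging campaign.

Seven Giant Sea Bass (Stereolepis gigas) were acoustically tagged in the
La Jolla kelp forest between August 2018 and October 2019 and monitored
through 21 July 2022.  The raw detection logs are not public, but the
published per-fish summary — release date, total length, receivers
visited, days at liberty within the array, and count of days detected —
is sufficient input to recompute every days-at-liberty and residency
quantity, which is what :func:`kelptrack.coa.days_at_liberty` and
:func:`kelptrack.coa.residency_indices` consume.
"""

from __future__ import annotations

import datetime

import pandas as pd

GSB_STUDY_END = datetime.date(2022, 7, 21)
GSB_TIMEZONE = "America/Los_Angeles"

_ROWS = [
    # tag, release date (local), TL cm, stations, array days, days detected
    (1, "2018-08-15", 77, 14, 1426, 425),
    (2, "2018-11-09", 148, 25, 283, 179),
    (3, "2018-11-16", 117, 21, 864, 767),
    (4, "2019-07-22", 153, 14, 202, 202),
    (5, "2019-07-23", 163, 0, 0, 0),
    (6, "2019-07-24", 118, 1, 1, 1),
    (7, "2019-10-26", 107, 22, 271, 187),
]


def gsb_tagging_summary() -> pd.DataFrame:
    """Per-fish summary inputs for the seven tagged Giant Sea Bass."""
    df = pd.DataFrame(_ROWS, columns=[
        "tag", "release_date", "total_length_cm", "station_count",
        "array_days_at_liberty", "days_detected"])
    df["release_date"] = pd.to_datetime(df["release_date"]).dt.date
    return df
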