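import numpy as np
import pandas as pd
import pytest

from kelptrack.geo import unproject

ORIGIN = (-117.27, 32.85)


def stations_from_planar(xy, origin=ORIGIN, prefix="R"):
    """Build a receiver table from planar metre coordinates."""
    xy = np.asarray(xy, dtype=float)
    lon, lat = unproject(xy[:, 0], xy[:, 1], origin)
    return pd.DataFrame({
        "receiver_id": [f"{prefix}{i + 1:02d}" for i in range(len(xy))],
        "lat": lat, "lon": lon,
        "depth": 18.0, "in_kelp": True,
        "x": xy[:, 0], "y": xy[:, 1],
    })


def detections(rows):
    """Detections frame from (iso_utc_timestamp, receiver_id, tag_id) rows."""
    df = pd.DataFrame(rows, columns=["timestamp", "receiver_id", "tag_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


@pytest.fixture
def two_station_array():
    """Two receivers 400 m apart on the x axis (planar)."""
    return stations_from_planar([[0.0, 0.0], [400.0, 0.0]])


@pytest.fixture
def deployments_one_tag():
    return pd.DataFrame({
        "tag_id": ["A"],
        "release_time": pd.to_datetime(["2021-03-01T17:00:00+00:00"], utc=True),
        "release_lat": [32.85], "release_lon": [-117.27],
        "total_length": [120.0],
        "min_interval": [30.0], "max_interval": [120.0],
        "battery_days": [1400.0],
    })
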