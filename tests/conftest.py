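import datetime as dt

import pandas as pd
import pytest
from hypothesis import settings

from batphen import simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def make_events(rows):
    """Detection events from (timestamp, tag, entrance, reader) tuples."""
    df = pd.DataFrame(rows, columns=["timestamp", "tag_id", "entrance_id", "reader"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_passes(rows):
    """Pass table from (tag, timestamp, direction) tuples; bat_day/year derived."""
    from batphen.passes import bat_day_series, bat_year_series

    df = pd.DataFrame(rows, columns=["tag_id", "timestamp", "direction"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["entrance_id"] = 1
    df["bat_day"] = bat_day_series(df["timestamp"])
    df["bat_year"] = bat_year_series(df["bat_day"]).to_numpy()
    return df.sort_values(["tag_id", "timestamp"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_clean_sim():
    """Small perfect-detection simulation shared across tests."""
    cfg = sim.clean_config(
        seed=11,
        years=tuple(range(2016, 2020)),
        n_new_tags_per_year_per_species=12,
    )
    weather, truth, captures, detections = sim.simulate_dataset(cfg)
    return {
        "config": cfg,
        "weather": weather,
        "truth": truth,
        "captures": captures,
        "detections": detections,
    }


@pytest.fixture()
def one_capture():
    return {
        "tag_id": "D2012-0001",
        "species": "daubentonii",
        "sex": "F",
        "age_at_tagging": "juvenile",
        "tagging_date": dt.date(2012, 8, 20),
        "forearm_mm": 37.2,
        "mass_g": 8.5,
    }
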