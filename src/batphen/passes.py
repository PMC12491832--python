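"""Gate-pass reconstruction and the noon-to-noon / July-to-June calendar.

A *pass* is one crossing of the hibernaculum entrance by one tagged bat,
reconstructed from the raw antenna hits.  Where an entrance carries two
readers ~20 cm apart, the triggering order gives the direction of movement:
outer→inner is an entry, inner→outer an exit.  Hits that cannot be paired
(reader failure, or the single-reader era where the reader field is
``"only"``) become passes of unknown direction.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PASS_COLUMNS = ["tag_id", "timestamp", "entrance_id", "direction", "bat_day", "bat_year"]

#: default seconds within which an inner and an outer hit form one crossing
DEFAULT_PAIRING_WINDOW = 60.0
#: default seconds within which repeated same-reader hits are one trigger burst
DEFAULT_BURST_WINDOW = 5.0


def assign_bat_day(timestamp) -> dt.date:
    """Map a timestamp to its bat day (noon-to-noon, labelled by starting noon).

    Times at or after 12:00 belong to that calendar date's bat day; times
    before 12:00 belong to the previous date's.  The noon instant itself
    opens a new bat day (half-open convention [12:00, 12:00)).
    """
    ts = pd.Timestamp(timestamp)
    d = ts.date()
    if ts.hour < 12:
        d = d - dt.timedelta(days=1)
    return d


def bat_day_series(timestamps: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_bat_day` over a datetime series."""
    ts = pd.to_datetime(timestamps)
    shifted = ts - pd.Timedelta(hours=12)
    return shifted.dt.date


def assign_bat_year(date) -> int:
    """Bat year label of a date: 1 July of year Y through 30 June of Y+1 → Y."""
    d = pd.Timestamp(date)
    return d.year if d.month >= 7 else d.year - 1


def bat_year_series(dates: Iterable) -> pd.Series:
    d = pd.to_datetime(pd.Series(list(dates)))
    return d.dt.year.where(d.dt.month >= 7, d.dt.year - 1).astype(int)


def day_of_bat_year(date, bat_year: int) -> int:
    """Days since 1 July of ``bat_year`` (1 July itself is index 0)."""
    return (pd.Timestamp(date).date() - dt.date(int(bat_year), 7, 1)).days


def effective_age(capture: Mapping, bat_year: int) -> str:
    """Age class of a bat in a given bat year.

    Bats tagged as adults are adults forever; bats tagged as juveniles are
    juvenile only in the bat year of tagging and adult afterwards.
    """
    tagging_year = assign_bat_year(capture["tagging_date"])
    if bat_year < tagging_year:
        raise ValueError(
            f"bat year {bat_year} precedes tagging bat year {tagging_year} "
            f"for tag {capture.get('tag_id', '?')}"
        )
    if capture["age_at_tagging"] == "adult":
        return "adult"
    return "juvenile" if bat_year == tagging_year else "adult"


def build_passes(
    events: pd.DataFrame,
    pairing_window_seconds: float = DEFAULT_PAIRING_WINDOW,
    burst_window_seconds: float = DEFAULT_BURST_WINDOW,
) -> pd.DataFrame:
    """Convert antenna hits into directed gate passes.

    Within one tag and entrance, repeated same-reader hits closer than
    ``burst_window_seconds`` are first collapsed to the earliest hit
    (re-triggering during a slow crawl).  Remaining hits are paired greedily
    left-to-right in time: an inner and an outer hit within
    ``pairing_window_seconds`` form one pass (outer→inner = entry,
    inner→outer = exit), timestamped at the first hit of the pair.  Leftover
    hits, and all hits from single-reader entrances (``reader == "only"``),
    become passes of unknown direction.  Every hit is consumed by exactly
    one pass.

    Parameters
    ----------
    events : DataFrame with columns timestamp, tag_id, entrance_id, reader.
    """
    if pairing_window_seconds < 0 or burst_window_seconds < 0:
        raise ValueError("pairing/burst windows must be non-negative")
    if events.empty:
        return pd.DataFrame(columns=PASS_COLUMNS)

    ev = events.sort_values(["tag_id", "entrance_id", "timestamp"], kind="mergesort")
    rows: list[tuple] = []
    pair_dt = pd.Timedelta(seconds=pairing_window_seconds)
    burst_dt = pd.Timedelta(seconds=burst_window_seconds)

    for (tag, ent), grp in ev.groupby(["tag_id", "entrance_id"], sort=False):
        times = grp["timestamp"].tolist()
        readers = grp["reader"].tolist()

        # de-bounce: drop same-reader hits within the burst window of the
        # last kept hit on that reader
        kept_t: list[pd.Timestamp] = []
        kept_r: list[str] = []
        last_kept: dict[str, pd.Timestamp] = {}
        for t, r in zip(times, readers):
            prev = last_kept.get(r)
            if prev is not None and (t - prev) <= burst_dt:
                continue
            last_kept[r] = t
            kept_t.append(t)
            kept_r.append(r)

        pending: tuple[pd.Timestamp, str] | None = None
        for t, r in zip(kept_t, kept_r):
            if r == "only":
                if pending is not None:
                    rows.append((tag, pending[0], ent, "unknown"))
                    pending = None
                rows.append((tag, t, ent, "unknown"))
                continue
            if pending is None:
                pending = (t, r)
                continue
            pt, pr = pending
            if r != pr and (t - pt) <= pair_dt:
                direction = "entry" if (pr, r) == ("outer", "inner") else "exit"
                rows.append((tag, pt, ent, direction))
                pending = None
            else:
                rows.append((tag, pt, ent, "unknown"))
                pending = (t, r)
        if pending is not None:
            rows.append((tag, pending[0], ent, "unknown"))

    passes = pd.DataFrame(rows, columns=["tag_id", "timestamp", "entrance_id", "direction"])
    passes = passes.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    passes["bat_day"] = bat_day_series(passes["timestamp"])
    passes["bat_year"] = bat_year_series(passes["bat_day"]).to_numpy()
    return passes[PASS_COLUMNS]
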