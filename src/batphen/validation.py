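"""Validation of the longest-gap extraction.

Two checks mirror how the direction-filtered (dual-reader) data can vouch
for the plain longest-gap method: (1) re-analyse the dual-reader era as if
only one reader existed and measure how often end dates agree; (2) compare
each record's end date with the individual's *final departure* — the first
exit after the hibernation end not followed by an entry within 24 h.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from batphen.passes import assign_bat_day


@dataclass
class ConcordanceReport:
    species: str
    n_compared: int
    fraction_identical: float | None  # None when n_compared == 0


def single_reader_reanalysis(events: pd.DataFrame, keep_reader: str = "inner") -> pd.DataFrame:
    """Restrict dual-reader events to one reader position per entrance.

    Keeps only hits from ``keep_reader`` (plus hits already marked
    ``"only"``) and rewrites the reader field to ``"only"``, so downstream
    pass building yields direction-unknown passes exactly as in the
    single-reader era.  Idempotent.
    """
    if keep_reader not in {"inner", "outer"}:
        raise ValueError("keep_reader must be 'inner' or 'outer'")
    out = events[events["reader"].isin([keep_reader, "only"])].copy()
    out["reader"] = "only"
    return out.reset_index(drop=True)


def end_date_concordance(
    dual_records: pd.DataFrame, single_records: pd.DataFrame
) -> list[ConcordanceReport]:
    """Per-species fraction of (tag, bat year) keys with identical end dates.

    Only keys present in both tables are compared; a species with zero
    overlap is reported with ``n_compared=0`` and an undefined fraction.
    """
    key = ["tag_id", "bat_year"]
    merged = dual_records.merge(
        single_records[key + ["end_date"]], on=key, suffixes=("_dual", "_single")
    )
    reports = []
    species = sorted(set(dual_records["species"]).union(single_records.get("species", [])))
    for sp in species:
        sub = merged[merged["species"] == sp]
        n = len(sub)
        frac = (
            float((sub["end_date_dual"] == sub["end_date_single"]).mean()) if n else None
        )
        reports.append(ConcordanceReport(species=sp, n_compared=n, fraction_identical=frac))
    return reports


def final_departure(passes: pd.DataFrame, record: dict | pd.Series) -> dt.date | None:
    """First exit after the end date not followed by an entry within 24 h.

    Scans direction-confirmed exits of the record's tag with timestamps
    after the noon closing the end-date bat day; returns the bat day of the
    first exit with no entry by the same tag in the following 24 hours
    (exact timestamps, not calendar days), or ``None``.
    """
    end_date = record["end_date"]
    threshold = pd.Timestamp(dt.datetime.combine(end_date, dt.time(12)))
    tag = record["tag_id"]
    p = passes[(passes["tag_id"] == tag) & (passes["timestamp"] > threshold)]
    p = p.sort_values("timestamp", kind="mergesort")
    exits = p[p["direction"] == "exit"]
    entries = p.loc[p["direction"] == "entry", "timestamp"]
    for row in exits.itertuples(index=False):
        lookahead = row.timestamp + pd.Timedelta(hours=24)
        if not ((entries > row.timestamp) & (entries <= lookahead)).any():
            return assign_bat_day(row.timestamp)
    return None


def departure_within(
    records: pd.DataFrame, passes: pd.DataFrame, tolerance_days: int = 7
) -> dict[str, float | None]:
    """Per-species fraction of final departures < ``tolerance_days`` after the end date.

    Records without a final departure are excluded from the denominator.
    The comparison is strict (< 7 days ⇔ "less than 1 week") on bat days.
    """
    out: dict[str, float | None] = {}
    for sp, sub in records.groupby("species"):
        n_ok = 0
        n_tot = 0
        for rec in sub.itertuples(index=False):
            dep = final_departure(passes, rec._asdict())
            if dep is None:
                continue
            n_tot += 1
            if (dep - rec.end_date).days < tolerance_days:
                n_ok += 1
        out[sp] = (n_ok / n_tot) if n_tot else None
    return out
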