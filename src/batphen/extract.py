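"""Longest-gap hibernation extraction.

The hibernation bout of an individual in a bat year is operationalised as
the *longest interval without a recorded pass* whose start falls between
1 July and 1 February and whose end falls between 31 December and 30 April
(both windows inclusive) — "ecological hibernation".  In dual-reader mode
the interval must additionally open with a confirmed entry and close with a
confirmed exit; otherwise the record is discarded (no fallback to the
next-longest gap).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from batphen.passes import day_of_bat_year, effective_age

logger = logging.getLogger(__name__)

PHENOLOGY_COLUMNS = [
    "tag_id", "species", "sex", "age", "bat_year", "start_date", "end_date",
    "duration_days", "start_day_index", "end_day_index", "mode",
]


@dataclass(frozen=True)
class ExclusionRule:
    """Drop one variable for one species (or "both") in one bat year."""

    species: str  # "daubentonii", "nattereri" or "both"
    bat_year: int
    variable: str  # "start", "end" or "duration"

    def __post_init__(self):
        if self.variable not in {"start", "end", "duration"}:
            raise ValueError(f"unknown exclusion variable {self.variable!r}")


def read_exclusions(path) -> list[ExclusionRule]:
    df = pd.read_csv(path)
    return [
        ExclusionRule(str(r.species), int(r.bat_year), str(r.variable))
        for r in df.itertuples(index=False)
    ]


def eligibility_windows(bat_year: int):
    """((start_lo, start_hi), (end_lo, end_hi)) calendar bounds, inclusive."""
    y = int(bat_year)
    return (
        (dt.date(y, 7, 1), dt.date(y + 1, 2, 1)),
        (dt.date(y, 12, 31), dt.date(y + 1, 4, 30)),
    )


def _longest_gap_core(days: np.ndarray, directions: np.ndarray, bat_year: int, mode: str):
    """Index of the best eligible gap in one tag-year's sorted bat days.

    Returns the opening-pass index, or None (no eligible gap, or dual-mode
    discard of the selected gap).
    """
    if len(days) < 2:
        return None
    (s_lo, s_hi), (e_lo, e_hi) = eligibility_windows(bat_year)
    d = np.asarray(days, dtype="datetime64[D]")
    start_days = d[:-1]
    end_days = d[1:]
    durations = (end_days - start_days).astype(int)
    eligible = (
        (start_days >= np.datetime64(s_lo))
        & (start_days <= np.datetime64(s_hi))
        & (end_days >= np.datetime64(e_lo))
        & (end_days <= np.datetime64(e_hi))
    )
    if not eligible.any():
        return None
    idx_elig = np.flatnonzero(eligible)
    # maximal duration, ties to earliest start (argmax keeps first maximum)
    best = int(idx_elig[np.argmax(durations[idx_elig])])
    if mode == "dual" and (directions[best] != "entry" or directions[best + 1] != "exit"):
        return None
    return best


def extract_longest_gap(passes: pd.DataFrame, mode: str = "single") -> dict | None:
    """Longest eligible gap of one tag in one bat year, or ``None``.

    ``passes`` must be sorted by timestamp and belong to a single tag and
    bat year.  Candidate gaps are consecutive pass pairs; a gap is eligible
    iff its opening bat day lies in [1 Jul, 1 Feb] and its closing bat day
    in [31 Dec, 30 Apr].  Ties in duration break to the earliest start.  In
    ``mode="dual"`` the selected gap is discarded (``None``) unless it opens
    with a confirmed entry and closes with a confirmed exit.
    """
    if mode not in {"single", "dual"}:
        raise ValueError(f"mode must be 'single' or 'dual', got {mode!r}")
    if len(passes) < 2:
        return None
    ts = passes["timestamp"].to_numpy()
    if (ts[1:] < ts[:-1]).any():
        raise ValueError("passes must be sorted by timestamp")

    bat_year = int(passes["bat_year"].iloc[0])
    days = passes["bat_day"].to_numpy()
    best = _longest_gap_core(days, passes["direction"].to_numpy(), bat_year, mode)
    if best is None:
        return None

    start = days[best]
    end = days[best + 1]
    return {
        "tag_id": passes["tag_id"].iloc[0],
        "bat_year": bat_year,
        "start_date": start,
        "end_date": end,
        "duration_days": int((end - start).days),
        "start_day_index": day_of_bat_year(start, bat_year),
        "end_day_index": day_of_bat_year(end, bat_year),
        "mode": mode,
    }


def apply_exclusions(records: pd.DataFrame, rules) -> pd.DataFrame:
    """Mask excluded variables; duration is masked with either endpoint.

    Matching rows get the excluded variable (and its day-index encoding)
    set to missing.  Unmatched rows and unmasked fields pass through
    untouched; applying the same rules twice is a no-op.
    """
    out = records.copy()
    for rule in rules:
        m = out["bat_year"] == rule.bat_year
        if rule.species != "both":
            m &= out["species"] == rule.species
        if not m.any():
            continue
        out.loc[m, "duration_days"] = np.nan
        if rule.variable == "start":
            out.loc[m, "start_date"] = pd.NaT
            out.loc[m, "start_day_index"] = np.nan
        elif rule.variable == "end":
            out.loc[m, "end_date"] = pd.NaT
            out.loc[m, "end_day_index"] = np.nan
    return out


def compile_dataset(
    passes: pd.DataFrame,
    captures: pd.DataFrame,
    rules=(),
    mode: str = "single",
) -> pd.DataFrame:
    """One phenology row per (tag, bat year) with a non-null extraction.

    Joins hibernation records with species/sex and the age class effective
    in that bat year (juveniles promoted after their first year).  Tags
    absent from the capture table are dropped with a warning.  No outlier
    filtering is applied beyond the calendar eligibility windows.
    """
    if mode not in {"single", "dual"}:
        raise ValueError(f"mode must be 'single' or 'dual', got {mode!r}")
    cap = captures.set_index("tag_id")
    unknown = sorted(set(passes["tag_id"]) - set(cap.index))
    if unknown:
        logger.warning("dropping %d tags absent from captures: %s...", len(unknown), unknown[:5])
        passes = passes[~passes["tag_id"].isin(unknown)]

    p = passes.sort_values(["tag_id", "bat_year", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )
    days_arr = p["bat_day"].to_numpy()
    dirs_arr = p["direction"].to_numpy()
    groups = p.groupby(["tag_id", "bat_year"], sort=True).indices

    records = []
    for (tag, by), idx in groups.items():
        days = days_arr[idx]
        best = _longest_gap_core(days, dirs_arr[idx], int(by), mode)
        if best is None:
            continue
        start, end = days[best], days[best + 1]
        rec = {
            "tag_id": tag,
            "bat_year": int(by),
            "start_date": start,
            "end_date": end,
            "duration_days": int((end - start).days),
            "start_day_index": day_of_bat_year(start, int(by)),
            "end_day_index": day_of_bat_year(end, int(by)),
            "mode": mode,
        }
        info = cap.loc[tag]
        tagging_by = pd.Timestamp(info["tagging_date"])
        tagging_by = tagging_by.year if tagging_by.month >= 7 else tagging_by.year - 1
        if int(by) < tagging_by:
            logger.warning("tag %s has passes before its tagging bat year; skipped", tag)
            continue
        rec["species"] = info["species"]
        rec["sex"] = info["sex"]
        rec["age"] = effective_age(
            {"tag_id": tag, "age_at_tagging": info["age_at_tagging"],
             "tagging_date": info["tagging_date"]},
            int(by),
        )
        records.append(rec)

    if not records:
        return pd.DataFrame(columns=PHENOLOGY_COLUMNS)
    table = pd.DataFrame(records)[PHENOLOGY_COLUMNS]
    table = table.sort_values(["species", "tag_id", "bat_year"]).reset_index(drop=True)
    return apply_exclusions(table, rules)
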