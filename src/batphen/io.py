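"""Reading, validating and writing the pipeline's CSV interchange formats.

All files are comma-separated UTF-8 with a header row and ISO-8601
timestamps.  Timestamps are timezone-naive local time at second resolution;
phenology is resolved at daily scale, so no DST arithmetic is applied.

Schemas
-------
detections : timestamp, tag_id, entrance_id, reader ∈ {inner, outer, only}
captures   : tag_id, species ∈ {daubentonii, nattereri}, sex ∈ {F, M},
             age_at_tagging ∈ {juvenile, adult}, tagging_date, forearm_mm, mass_g
weather    : timestamp, temp_c
truth      : simulator ground truth (one row per individual-year)
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

READERS = {"inner", "outer", "only"}
SPECIES = {"daubentonii", "nattereri"}
SEXES = {"F", "M"}
AGES = {"juvenile", "adult"}

DETECTION_COLUMNS = ["timestamp", "tag_id", "entrance_id", "reader"]
CAPTURE_COLUMNS = [
    "tag_id", "species", "sex", "age_at_tagging", "tagging_date", "forearm_mm", "mass_g",
]
WEATHER_COLUMNS = ["timestamp", "temp_c"]

#: fraction of malformed rows above which a detections read aborts
MAX_BAD_ROW_FRACTION = 0.01


class FormatError(ValueError):
    """A file-level format violation (missing columns, too many bad rows)."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_detections(path) -> pd.DataFrame:
    """Read a detection log; returns rows sorted by (tag_id, timestamp).

    Malformed rows (unparseable timestamp, unknown reader, blank tag) are
    collected with their line numbers and logged; the run aborts with
    :class:`FormatError` if more than 1% of data rows are malformed.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, DETECTION_COLUMNS, path)
    if raw.empty:
        return pd.DataFrame(columns=DETECTION_COLUMNS)

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    ent = pd.to_numeric(raw["entrance_id"], errors="coerce")
    bad = (
        ts.isna()
        | ent.isna()
        | ~raw["reader"].isin(READERS)
        | (raw["tag_id"].str.len() == 0)
    )
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in raw.index[bad]]
        for ln, (_, row) in zip(lines, raw[bad].iterrows()):
            logger.error("%s line %d: malformed detection row %s", path, ln, row.to_dict())
        if bad.mean() > MAX_BAD_ROW_FRACTION:
            raise FormatError(
                f"{path}: {int(bad.sum())}/{len(raw)} malformed rows "
                f"(lines {lines[:20]}{'...' if len(lines) > 20 else ''})"
            )

    out = pd.DataFrame(
        {
            "timestamp": ts[~bad],
            "tag_id": raw.loc[~bad, "tag_id"],
            "entrance_id": ent[~bad].astype(int),
            "reader": raw.loc[~bad, "reader"],
        }
    )
    return out.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_captures(path) -> pd.DataFrame:
    """Read capture/tagging records; tag_id must be unique within the file."""
    df = pd.read_csv(path, dtype={"tag_id": str})
    _require_columns(df, CAPTURE_COLUMNS, path)
    if df.empty:
        df["tagging_date"] = pd.to_datetime(df["tagging_date"])
        return df[CAPTURE_COLUMNS]

    dupes = df.loc[df["tag_id"].duplicated(), "tag_id"].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicated tag_id(s) {dupes}")
    bad_species = set(df["species"]) - SPECIES
    if bad_species:
        raise FormatError(f"{path}: unknown species {sorted(bad_species)}")
    if not df["sex"].isin(SEXES).all() or not df["age_at_tagging"].isin(AGES).all():
        raise FormatError(f"{path}: sex must be F/M and age_at_tagging juvenile/adult")
    if (df["forearm_mm"] <= 0).any() or (df["mass_g"] <= 0).any():
        raise FormatError(f"{path}: forearm_mm and mass_g must be positive")
    df["tagging_date"] = pd.to_datetime(df["tagging_date"])
    return df[CAPTURE_COLUMNS].reset_index(drop=True)


def read_weather(path) -> pd.DataFrame:
    """Read an hourly temperature series.

    Duplicate timestamps keep the first sample (warned); gaps relative to
    the modal sampling interval are permitted but logged.
    """
    df = pd.read_csv(path)
    _require_columns(df, WEATHER_COLUMNS, path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["temp_c"] = pd.to_numeric(df["temp_c"])
    df = df.sort_values("timestamp", kind="mergesort")
    dup = df["timestamp"].duplicated()
    if dup.any():
        logger.warning("%s: %d duplicate timestamps, keeping first", path, int(dup.sum()))
        df = df[~dup]
    df = df.reset_index(drop=True)
    if len(df) > 2:
        steps = df["timestamp"].diff().dropna()
        modal = steps.mode().iloc[0]
        gaps = int((steps > modal).sum())
        if gaps:
            logger.info("%s: %d gaps larger than the modal step (%s)", path, gaps, modal)
    return df[WEATHER_COLUMNS]


def write_detections(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[DETECTION_COLUMNS].to_csv(path, index=False)


def write_captures(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["tagging_date"] = pd.to_datetime(out["tagging_date"]).dt.strftime("%Y-%m-%d")
    out[CAPTURE_COLUMNS].to_csv(path, index=False)


def write_weather(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[WEATHER_COLUMNS].to_csv(path, index=False)


def write_truth(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str})
    for col in ("true_entry_date", "true_exit_date", "winter_exit_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.date
    return df


def write_passes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_passes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["bat_day"] = pd.to_datetime(df["bat_day"]).dt.date
    return df


def write_phenology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenology(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str})
    for col in ("start_date", "end_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce").dt.date
    return df
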