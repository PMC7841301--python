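"""Readers and writers for cohort tables, event streams and run configuration.

File dialects are deliberately plain: comma-separated measure tables with a
header row, ISO 8601 timestamps in event streams, YAML for configuration and
schedules. All floats are written with ``%.10g`` so repeated runs with the
same seed produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ENVIRONMENT_LEVELS,
    GENOTYPE_LEVELS,
    BehaviorTable,
    EventStream,
    LightSchedule,
    Phase,
    PhaseSchedule,
    RDoCMap,
    ValidationError,
)

log = logging.getLogger("psycop")

FLOAT_FORMAT = "%.10g"
DEFAULT_MISSING_TOKEN = "NA"
FACTOR_COLUMNS = ("genotype", "environment")


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------

def read_behavior_table(
    path: str | Path,
    factor_columns: Sequence[str] = FACTOR_COLUMNS,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    id_column: str = "animal_id",
) -> BehaviorTable:
    """Read a comma-separated animals x variables table.

    Missing cells (``missing_token``) are recorded as NaN, never as zero.
    Unknown factor levels and duplicate animal ids are hard errors naming
    the offending row.
    """
    df = pd.read_csv(path, na_values=[missing_token], keep_default_na=False, dtype=str)
    if id_column not in df.columns:
        raise ValidationError(f"{path}: missing id column {id_column!r}")
    for col in factor_columns:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing factor column {col!r}")
    dup = df[id_column][df[id_column].duplicated()]
    if len(dup):
        raise ValidationError(
            f"{path}: duplicate animal_id {dup.iloc[0]!r} (row {dup.index[0] + 2})"
        )
    gcol, ecol = factor_columns
    for col, levels in ((gcol, GENOTYPE_LEVELS), (ecol, ENVIRONMENT_LEVELS)):
        bad = df[col][~df[col].isin(levels)]
        if len(bad):
            raise ValidationError(
                f"{path}: row {bad.index[0] + 2}: unknown {col} level "
                f"{bad.iloc[0]!r}; allowed levels: {list(levels)}"
            )
    df = df.set_index(id_column)
    factors = df[[gcol, ecol]].rename(columns={gcol: "genotype", ecol: "environment"})
    value_cols = [c for c in df.columns if c not in factor_columns]
    data = df[value_cols].apply(pd.to_numeric, errors="raise")
    return BehaviorTable(data=data, factors=factors)


def write_behavior_table(
    table: BehaviorTable,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> Path:
    """Write a table read-compatible with :func:`read_behavior_table`."""
    path = Path(path)
    frame = table.to_frame()
    frame.index.name = "animal_id"
    frame.to_csv(path, na_rep=missing_token, float_format=FLOAT_FORMAT)
    return path


# ---------------------------------------------------------------------------
# event streams
# ---------------------------------------------------------------------------

def read_event_stream(path: str | Path, dialect: Mapping | None = None) -> EventStream:
    """Read a delimited event stream with ISO 8601 timestamps.

    Nosepokes and licks that fall outside any visit interval of the same
    animal and corner are flagged as orphans in the log and retained.
    """
    dialect = dict(dialect or {})
    sep = dialect.get("sep", ",")
    df = pd.read_csv(path, sep=sep, dtype={"animal_id": str})
    required = ["animal_id", "timestamp", "corner", "side", "kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValidationError(
            f"{path}: line {row + 2}: unparseable timestamp {df['timestamp'].iloc[row]!r}"
        )
    df = df.assign(timestamp=ts, corner=df["corner"].astype(int))
    if "duration" in df.columns:
        df["duration"] = pd.to_numeric(df["duration"], errors="coerce")
    stream = EventStream(df)
    stream.n_orphans = _count_orphans(stream)
    if stream.n_orphans:
        log.warning("%s: %d orphan nosepoke/lick records retained", path, stream.n_orphans)
    return stream


def _count_orphans(stream: EventStream) -> int:
    """Nosepoke/lick records outside any same-animal same-corner visit."""
    n_orphans = 0
    visits = stream.visits()
    for (animal, corner), sub in stream.records.groupby(["animal_id", "corner"]):
        v = visits[(visits["animal_id"] == animal) & (visits["corner"] == corner)]
        starts = v["timestamp"].to_numpy()
        ends = (v["timestamp"] + pd.to_timedelta(v["duration"].fillna(0.0), unit="s")).to_numpy()
        events = sub[sub["kind"] != "visit"]
        for t in events["timestamp"].to_numpy():
            if not np.any((starts <= t) & (t <= ends)):
                n_orphans += 1
    return n_orphans


def write_event_stream(stream: EventStream, path: str | Path) -> Path:
    path = Path(path)
    df = stream.records.copy()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


# ---------------------------------------------------------------------------
# RDoC map / schedule / lights (YAML)
# ---------------------------------------------------------------------------

def read_rdoc_map(path: str | Path) -> RDoCMap:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: RDoC map must be a mapping variable -> domain")
    return RDoCMap(dict(raw))


def write_rdoc_map(rdoc: RDoCMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(rdoc.assignments), fh, sort_keys=True, allow_unicode=True)
    return path


def schedule_to_dict(schedule: PhaseSchedule) -> list[dict]:
    out = []
    for ph in schedule:
        d: dict = {
            "name": ph.name,
            "start": ph.start.isoformat(),
            "end": ph.end.isoformat(),
            "paradigm": ph.paradigm,
        }
        if ph.assignments is not None:
            d["assignments"] = {str(k): int(v) for k, v in ph.assignments.items()}
        if ph.door_open_prob is not None:
            d["door_open_prob"] = float(ph.door_open_prob)
        out.append(d)
    return out


def schedule_from_dict(raw: Sequence[Mapping]) -> PhaseSchedule:
    phases = [
        Phase(
            name=d["name"],
            start=pd.Timestamp(d["start"]),
            end=pd.Timestamp(d["end"]),
            paradigm=d["paradigm"],
            assignments=dict(d["assignments"]) if d.get("assignments") else None,
            door_open_prob=d.get("door_open_prob"),
        )
        for d in raw
    ]
    return PhaseSchedule(phases)


def read_schedule(path: str | Path) -> PhaseSchedule:
    with open(path) as fh:
        return schedule_from_dict(yaml.safe_load(fh))


def write_schedule(schedule: PhaseSchedule, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=False)
    return path


def lights_from_dict(raw: Mapping | None) -> LightSchedule:
    raw = dict(raw or {})
    return LightSchedule(
        lights_on=float(raw.get("lights_on", 7.0)),
        light_hours=float(raw.get("light_hours", 12.0)),
        dark_hours=float(raw.get("dark_hours", 12.0)),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValidationError(f"{path}: config must be a mapping")
    return dict(cfg)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
    return path
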