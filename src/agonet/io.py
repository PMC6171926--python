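"""Delimited-text readers and writers for rosters, event logs and lesion counts.

All files are comma-separated UTF-8 with a mandatory header row; lines
starting with ``#`` are comments (the writers record the generator seed
there).  Readers validate each record and report offending row numbers
(1-based, counting the header as row 1).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_roster",
    "read_events",
    "read_lesions",
    "write_roster",
    "write_events",
    "write_lesions",
    "read_config",
]

ROSTER_COLUMNS = ["pig_id", "pen_id", "litter_id", "sex", "breed", "weight", "batch_id"]
EVENT_COLUMNS = [
    "pen_id", "initiator", "receiver", "behaviour", "start_time", "duration", "bite_count",
]
LESION_COLUMNS = ["pig_id", "timepoint", "anterior", "central", "posterior"]

VALID_BEHAVIOURS = {"fight", "bully"}
VALID_TIMEPOINTS = {"pre", "24h", "3wk"}
SECONDS_PER_DAY = 86_400


class MalformedFileError(ValueError):
    pass


def _read_csv(path, required: list[str], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise MalformedFileError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: no data rows", UserWarning, stacklevel=3)
    # data rows start after the header (and any leading comment lines)
    with open(path) as fh:
        n_preamble = 0
        for line in fh:
            n_preamble += 1
            if not line.startswith("#"):
                break
    df.index = pd.RangeIndex(n_preamble + 1, n_preamble + 1 + len(df), name="row")
    return df


def _fail_rows(path, mask: pd.Series, message: str) -> None:
    if mask.any():
        rows = list(mask[mask].index[:5])
        raise MalformedFileError(f"{path}: {message} at row(s) {rows}")


def read_roster(path) -> pd.DataFrame:
    df = _read_csv(path, ROSTER_COLUMNS)
    _fail_rows(path, df["pig_id"].duplicated(), "duplicate pig_id")
    _fail_rows(path, ~(df["weight"] > 0), "non-positive weight")
    return df.reset_index(drop=True)


def read_events(path) -> pd.DataFrame:
    df = _read_csv(path, EVENT_COLUMNS, optional=("bite_count",))
    if "bite_count" not in df.columns:
        df["bite_count"] = float("nan")
    _fail_rows(path, ~df["behaviour"].isin(VALID_BEHAVIOURS), "unknown behaviour code")
    _fail_rows(path, df["initiator"] == df["receiver"], "initiator equals receiver (self-loop)")
    _fail_rows(path, ~(df["duration"] >= 1), "duration below 1 s")
    _fail_rows(
        path,
        (df["start_time"] < 0) | (df["start_time"] >= SECONDS_PER_DAY),
        "start_time outside the 24 h observation window",
    )
    return df.reset_index(drop=True)


def read_lesions(path) -> pd.DataFrame:
    df = _read_csv(path, LESION_COLUMNS)
    _fail_rows(path, ~df["timepoint"].isin(VALID_TIMEPOINTS), "unknown timepoint")
    for region in ("anterior", "central", "posterior"):
        _fail_rows(path, df[region] < 0, f"negative {region} lesion count")
    _fail_rows(
        path, df.duplicated(subset=["pig_id", "timepoint"]), "duplicate pig/timepoint record"
    )
    return df.reset_index(drop=True)


def _write(df: pd.DataFrame, path, seed: int | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def write_roster(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write(df[ROSTER_COLUMNS], path, seed)


def write_events(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write(df[EVENT_COLUMNS], path, seed)


def write_lesions(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write(df[LESION_COLUMNS], path, seed)


def read_config(path) -> dict:
    """Read a YAML (or flat ``key: value``) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise MalformedFileError(f"{path}: expected a mapping of configuration keys")
    return cfg
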