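"""Read/write raw instrumented-walkway exports and reduce them to peak-pressure points.

A raw export is a delimited text table with one row per sensor activation
sample: the activation time, the (x, y) grid indices of the sensor cell, the
pressure level, and optional device-assigned annotations (foot type, foot
count, footfall id, pass index).  The mat is 90 x 420 cm with a 1.27 cm
sensor pitch, so grid indices live in [0, 70] x [0, 330] by default.

Cells are sampled repeatedly while a foot is on them; downstream geometry
only needs one representative observation per cell per contact, so each
activation episode is reduced to the sample with maximum pressure (earliest
such sample on ties).  Device-assigned footfall/foot-type columns are carried
through for validation but are never used for segmentation — footfalls are
re-derived by clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, LinkageError, RowParseError

#: sensor pitch of the walkway grid, in cm
GRID_PITCH_CM = 1.27

#: canonical raw-export columns, in file order
RAW_COLUMNS = (
    "time",
    "x_index",
    "y_index",
    "pressure",
    "foot_type",
    "foot_count",
    "footfall",
    "pass_index",
)

_MANDATORY = ("time", "x_index", "y_index", "pressure")

_DEFAULT_ALIASES = {
    "time": "time",
    "t": "time",
    "time (sec.)": "time",
    "x": "x_index",
    "x_index": "x_index",
    "x-coordinate": "x_index",
    "x coordinate": "x_index",
    "y": "y_index",
    "y_index": "y_index",
    "y-coordinate": "y_index",
    "y coordinate": "y_index",
    "pressure": "pressure",
    "pressure level": "pressure",
    "foot type": "foot_type",
    "foot_type": "foot_type",
    "foot count": "foot_count",
    "foot_count": "foot_count",
    "footfall": "footfall",
    "pass index": "pass_index",
    "pass_index": "pass_index",
    "pass": "pass_index",
}


@dataclass
class WalkwayDialect:
    """Format options for a raw walkway export.

    Parameters
    ----------
    pitch_cm:
        Grid pitch used to convert integer cell indices to centimetres.
    n_cols, n_rows:
        Grid extent; indices must lie in ``[0, n_cols-1] x [0, n_rows-1]``.
        ``n_cols`` counts cells across the 90 cm mat width, ``n_rows`` along
        the 420 cm walking axis.
    episode_gap_s:
        A cell re-activated after this many seconds of silence starts a new
        activation episode (the same cell can be struck by two footfalls).
    aliases:
        Extra header-name -> canonical-column mappings, merged over the
        built-in ones (case-insensitive).
    """

    pitch_cm: float = GRID_PITCH_CM
    n_cols: int = 71
    n_rows: int = 331
    episode_gap_s: float = 0.2
    aliases: dict = field(default_factory=dict)

    def alias_map(self):
        m = dict(_DEFAULT_ALIASES)
        m.update({k.strip().lower(): v for k, v in self.aliases.items()})
        return m


def read_raw_export(path, dialect: WalkwayDialect | None = None, sep=None) -> pd.DataFrame:
    """Read a delimited raw export into a table of sensor activation events.

    The delimiter is auto-detected unless ``sep`` is given.  Header names are
    matched case-insensitively against the dialect's alias map.  Returns a
    DataFrame with the canonical :data:`RAW_COLUMNS`; optional columns absent
    from the file are filled with NA (``pass_index`` defaults to 0).

    Raises
    ------
    FormatError
        if a mandatory column (time/x/y/pressure) cannot be mapped, or an
        index falls outside the mat grid.
    RowParseError
        if a mandatory cell is non-numeric; carries the 1-based line number.
    """
    dialect = dialect or WalkwayDialect()
    df = pd.read_csv(path, sep=sep, engine="python", skipinitialspace=True)
    amap = dialect.alias_map()
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in amap:
            rename[col] = amap[key]
    df = df.rename(columns=rename)

    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"raw export is missing mandatory column {col!r}")

    out = pd.DataFrame(index=df.index)
    for col in ("time", "pressure"):
        out[col] = _numeric(df[col], col, float)
    for col in ("x_index", "y_index"):
        out[col] = _numeric(df[col], col, int)
    out["foot_type"] = df.get("foot_type", pd.Series(pd.NA, index=df.index))
    for col in ("foot_count", "footfall"):
        out[col] = pd.to_numeric(df.get(col, pd.Series(pd.NA, index=df.index)), errors="coerce")
    if "pass_index" in df.columns:
        out["pass_index"] = _numeric(df["pass_index"], "pass_index", int)
    else:
        out["pass_index"] = 0

    if (out["time"] < 0).any():
        raise FormatError("negative time stamps in raw export")
    if (out["pressure"] < 0).any():
        raise FormatError("negative pressure values in raw export")
    for col, n in (("x_index", dialect.n_cols), ("y_index", dialect.n_rows)):
        bad = (out[col] < 0) | (out[col] >= n)
        if bad.any():
            i = int(out.index[bad][0])
            raise FormatError(
                f"{col}={int(out[col].iloc[i])} at line {i + 2} outside the mat grid [0, {n - 1}]"
            )
    return out[list(RAW_COLUMNS)]


def _numeric(series, name, kind):
    coerced = pd.to_numeric(series, errors="coerce")
    bad = coerced.isna() & series.notna()
    if bad.any():
        line = int(series.index[bad][0]) + 2  # header occupies line 1
        raise RowParseError(f"non-numeric value {series[bad].iloc[0]!r} in column {name!r}", line=line)
    if coerced.isna().any():
        line = int(series.index[coerced.isna()][0]) + 2
        raise RowParseError(f"missing value in mandatory column {name!r}", line=line)
    if kind is int:
        rounded = np.rint(coerced.to_numpy(float))
        if np.max(np.abs(rounded - coerced.to_numpy(float))) > 1e-9:
            line = int(np.argmax(np.abs(rounded - coerced.to_numpy(float)))) + 2
            raise RowParseError(f"non-integer grid index in column {name!r}", line=line)
        return rounded.astype(int)
    return coerced.astype(float)


def write_raw_export(events: pd.DataFrame, path) -> None:
    """Write an event table in the canonical raw-export layout (CSV)."""
    events[list(RAW_COLUMNS)].to_csv(path, index=False)


def reduce_to_peak(events: pd.DataFrame, dialect: WalkwayDialect | None = None) -> pd.DataFrame:
    """Reduce per-sample events to one peak-pressure point per cell activation.

    Events are grouped by (pass, cell); within a group, samples separated by
    more than ``dialect.episode_gap_s`` belong to distinct activation
    episodes.  Each episode contributes one point whose ``t_peak`` is the
    time of the maximum observed pressure (earliest such time on ties) and
    whose coordinates are the cell centre in centimetres.

    Returns a DataFrame with columns ``pass_index, x_index, y_index, x_cm,
    y_cm, t_peak, peak_pressure, foot_type, footfall``.  Empty input yields
    an empty frame.  The operation is idempotent.
    """
    dialect = dialect or WalkwayDialect()
    cols = ["pass_index", "x_index", "y_index", "x_cm", "y_cm", "t_peak",
            "peak_pressure", "foot_type", "footfall"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)

    df = events.sort_values(["pass_index", "x_index", "y_index", "time"], kind="stable")
    keys = df[["pass_index", "x_index", "y_index"]].to_numpy()
    new_group = np.ones(len(df), dtype=bool)
    new_group[1:] = (keys[1:] != keys[:-1]).any(axis=1)
    dt = np.diff(df["time"].to_numpy(), prepend=df["time"].iloc[0])
    episode = np.cumsum(new_group | (dt > dialect.episode_gap_s))
    df = df.assign(_episode=episode)

    # idxmax returns the first maximal row, and rows are time-sorted within
    # an episode, so ties resolve to the earliest sample
    peak_rows = df.loc[df.groupby("_episode")["pressure"].idxmax()]
    out = pd.DataFrame({
        "pass_index": peak_rows["pass_index"].to_numpy(),
        "x_index": peak_rows["x_index"].to_numpy(),
        "y_index": peak_rows["y_index"].to_numpy(),
        "x_cm": peak_rows["x_index"].to_numpy() * dialect.pitch_cm,
        "y_cm": peak_rows["y_index"].to_numpy() * dialect.pitch_cm,
        "t_peak": peak_rows["time"].to_numpy(),
        "peak_pressure": peak_rows["pressure"].to_numpy(),
        "foot_type": peak_rows["foot_type"].to_numpy(),
        "footfall": peak_rows["footfall"].to_numpy(),
    })
    return out.sort_values(["pass_index", "t_peak"], kind="stable").reset_index(drop=True)


@dataclass
class PassRecording:
    """All peak-pressure points of one pass across the walkway."""

    pass_index: int
    points: pd.DataFrame  # sorted by t_peak
    subject_id: str
    visit_id: str
    class_label: str  # "patient" | "control"
    height_cm: float


def split_passes(points: pd.DataFrame, metadata: pd.DataFrame) -> list[PassRecording]:
    """Partition a point table into per-pass recordings with subject metadata.

    ``metadata`` must have one row per pass with columns ``pass_index,
    subject_id, visit_id, class_label, height_cm``.  Points are sorted by
    ``t_peak`` within each recording.

    Raises :class:`LinkageError` if a point references a pass absent from the
    metadata table.
    """
    if len(points) == 0:
        return []
    meta = metadata.set_index("pass_index")
    recordings = []
    for pass_index, grp in points.groupby("pass_index", sort=True):
        if pass_index not in meta.index:
            raise LinkageError(f"pass_index {pass_index} has no metadata row")
        row = meta.loc[pass_index]
        recordings.append(PassRecording(
            pass_index=int(pass_index),
            points=grp.sort_values("t_peak", kind="stable").reset_index(drop=True),
            subject_id=str(row["subject_id"]),
            visit_id=str(row["visit_id"]),
            class_label=str(row["class_label"]),
            height_cm=float(row["height_cm"]),
        ))
    return recordings
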