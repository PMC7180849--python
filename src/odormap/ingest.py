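"""Reading, validating, orienting and aligning per-minute campaign tables.

CSV schemas (RFC-4180, header row, ISO-8601 timestamps):

* e-nose file:    ``timestamp,S1,...,S10`` (raw instrument conventions)
* ancillary file: ``timestamp,tvoc_ppm,wind_speed_ms,wind_dir_deg,temp_c,rh_pct``

Policy for multi-month field data: malformed or out-of-range rows are
quarantined (dropped and counted in the log), not fatal; structural problems
(missing columns, duplicate timestamps) are hard errors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .frames import ANCILLARY_COLUMNS, AncillaryFrame, SensorFrame, SensorMeta

log = logging.getLogger(__name__)


def _read_csv(path, required_cols: list[str]) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in ["timestamp"] + required_cols if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    raw = raw[["timestamp"] + required_cols]
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    vals = raw[required_cols].apply(pd.to_numeric, errors="coerce")
    bad = ts.isna() | vals.isna().any(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("%s: quarantined %d malformed row(s)", path, n_bad)
    df = vals[~bad].copy()
    df.index = pd.DatetimeIndex(ts[~bad]).floor("min")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"{path}: duplicate timestamp {dup}")
    return df.sort_index()


def read_sensor_table(path, meta: SensorMeta | None = None) -> SensorFrame:
    """Read an e-nose CSV into an (unoriented) :class:`SensorFrame`.

    Rows with unparsable fields or nonpositive conductance ratios are
    quarantined with a log record; duplicate timestamps or a missing column
    are hard errors naming the offender.
    """
    meta = meta or SensorMeta.pen3()
    df = _read_csv(path, list(meta.sensor_ids))
    nonpos = (df.to_numpy() <= 0).any(axis=1)
    if nonpos.any():
        log.warning("%s: quarantined %d row(s) with nonpositive ratios", path, int(nonpos.sum()))
        df = df[~nonpos]
    return SensorFrame(data=df, meta=meta, oriented=False)


def read_ancillary_table(path) -> AncillaryFrame:
    """Read the TVOC/wind/weather CSV into an :class:`AncillaryFrame`."""
    df = _read_csv(path, list(ANCILLARY_COLUMNS))
    wd = df["wind_dir_deg"].to_numpy()
    bad = (wd < 0) | (wd >= 360) | (df["tvoc_ppm"].to_numpy() < 0) | (
        df["wind_speed_ms"].to_numpy() < 0
    )
    if bad.any():
        log.warning("%s: quarantined %d out-of-range row(s)", path, int(bad.sum()))
        df = df[~bad]
    return AncillaryFrame(data=df)


def write_sensor_table(frame: SensorFrame, path) -> None:
    df = frame.data.copy()
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.12g", date_format="%Y-%m-%dT%H:%M:%S")


def write_ancillary_table(frame: AncillaryFrame, path) -> None:
    df = frame.data.copy()
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.12g", date_format="%Y-%m-%dT%H:%M:%S")


def orient_signals(frame: SensorFrame) -> SensorFrame:
    """Invert G0/G channels (x -> 1/x) so every oriented channel reads
    "larger value = stronger response to detectable compounds".

    The transform is an involution per channel; :func:`unorient_signals`
    restores the raw conventions exactly.  Re-orienting an already oriented
    frame is an error (the guard against silent double inversion).
    """
    if frame.oriented:
        raise DataError("frame is already oriented; refusing to invert twice")
    df = frame.data.copy()
    for ch in frame.meta.inverted_channels:
        df[ch] = 1.0 / df[ch]
    return frame.with_data(df, oriented=True)


def unorient_signals(frame: SensorFrame) -> SensorFrame:
    """Analytic inverse of :func:`orient_signals` (back to raw conventions)."""
    if not frame.oriented:
        raise DataError("frame is not oriented")
    df = frame.data.copy()
    for ch in frame.meta.inverted_channels:
        df[ch] = 1.0 / df[ch]
    return frame.with_data(df, oriented=False)


def align_minutes(sensor: SensorFrame, ancillary: AncillaryFrame) -> pd.DataFrame:
    """Inner-join the two per-minute tables on timestamp.

    Returns one DataFrame with sensor columns followed by ancillary columns.
    Unmatched minutes on either side are reported as counts in the log; an
    empty join is allowed (warned), never an error.
    """
    common = sensor.timestamps.intersection(ancillary.timestamps)
    n_s_only = len(sensor) - len(common)
    n_a_only = len(ancillary) - len(common)
    if n_s_only or n_a_only:
        log.info(
            "align_minutes: %d joined, %d sensor-only, %d ancillary-only minutes",
            len(common), n_s_only, n_a_only,
        )
    if len(common) == 0:
        log.warning("align_minutes: empty join (no overlapping minutes)")
    return pd.concat(
        [sensor.data.loc[common], ancillary.data.loc[common]], axis=1
    )
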