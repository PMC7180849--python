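"""In-memory containers for e-nose campaigns.

A campaign is a per-minute multivariate time series from a ten-channel
metal-oxide-semiconductor (MOS) sensor array, plus ancillary per-minute
records (TVOC by photoionization detector, wind, temperature, humidity).
Each MOS channel reports a dimensionless conductance ratio; depending on the
instrument preset a channel logs either G/G0 (sample over baseline
conductance) or its reciprocal G0/G, so channels must be re-oriented before
any joint modeling (see :func:`odormap.ingest.orient_signals`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

#: Signal conventions: value logged as baseline-over-sample ("G0/G") or
#: sample-over-baseline ("G/G0").
G0_OVER_G = "G0/G"
G_OVER_G0 = "G/G0"

#: PEN3-style preset: channel id -> (descriptive name, signal convention).
PEN3_CHANNELS = {
    "S1": ("Aromatic-1", G0_OVER_G),
    "S2": ("Broad-range", G_OVER_G0),
    "S3": ("Aromatic-2", G0_OVER_G),
    "S4": ("Hydrogen", G_OVER_G0),
    "S5": ("Arom-aliph", G0_OVER_G),
    "S6": ("Broad-methane", G_OVER_G0),
    "S7": ("Sulphur-organic", G_OVER_G0),
    "S8": ("Broad-alcohol", G_OVER_G0),
    "S9": ("Sulph-chlor", G_OVER_G0),
    "S10": ("Methane-aliph", G_OVER_G0),
}

ANCILLARY_COLUMNS = ("tvoc_ppm", "wind_speed_ms", "wind_dir_deg", "temp_c", "rh_pct")


@dataclass(frozen=True)
class SensorMeta:
    """Ordered channel labels with per-channel signal convention."""

    sensor_ids: tuple[str, ...]
    conventions: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.sensor_ids:
            if sid not in self.conventions:
                raise ValidationError(f"no signal convention for channel {sid!r}")
            if self.conventions[sid] not in (G0_OVER_G, G_OVER_G0):
                raise ValidationError(
                    f"unknown convention {self.conventions[sid]!r} for {sid!r}"
                )

    @classmethod
    def pen3(cls) -> "SensorMeta":
        """Ten-channel MOS preset with the mixed G0/G / G/G0 conventions."""
        return cls(
            sensor_ids=tuple(PEN3_CHANNELS),
            conventions={k: v for k, (_, v) in PEN3_CHANNELS.items()},
            names={k: n for k, (n, _) in PEN3_CHANNELS.items()},
        )

    @property
    def inverted_channels(self) -> tuple[str, ...]:
        """Channels logged as G0/G, i.e. reciprocal of the modeling convention."""
        return tuple(s for s in self.sensor_ids if self.conventions[s] == G0_OVER_G)


def _check_minute_index(index: pd.Index, what: str) -> pd.DatetimeIndex:
    if not isinstance(index, pd.DatetimeIndex):
        raise DataError(f"{what}: index must be datetimes")
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise DataError(f"{what}: duplicate timestamp {dup}")
    if not index.is_monotonic_increasing:
        raise DataError(f"{what}: timestamps must be sorted increasing")
    return index


@dataclass
class SensorFrame:
    """Per-minute matrix of conductance-ratio responses.

    ``data`` is indexed by timestamp (strictly increasing, unique) with one
    column per channel, all values finite and > 0.  ``oriented`` records
    whether G0/G channels have been inverted to the common
    "larger = stronger response" convention.
    """

    data: pd.DataFrame
    meta: SensorMeta
    oriented: bool = False

    def __post_init__(self) -> None:
        _check_minute_index(self.data.index, "sensor frame")
        expected = list(self.meta.sensor_ids)
        if list(self.data.columns) != expected:
            raise DataError(
                f"sensor frame columns {list(self.data.columns)} != {expected}"
            )
        vals = self.data.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals <= 0).any()):
            raise DataError("sensor frame: all conductance ratios must be finite and > 0")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def with_data(self, data: pd.DataFrame, *, oriented: bool | None = None) -> "SensorFrame":
        return replace(self, data=data, oriented=self.oriented if oriented is None else oriented)


@dataclass
class AncillaryFrame:
    """Per-minute ancillary records: TVOC (ppm_v isobutylene-equivalent),
    wind speed (m/s), wind direction (degrees, [0, 360)), temperature (degC),
    relative humidity (%)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_minute_index(self.data.index, "ancillary frame")
        if list(self.data.columns) != list(ANCILLARY_COLUMNS):
            raise DataError(
                f"ancillary columns {list(self.data.columns)} != {list(ANCILLARY_COLUMNS)}"
            )
        d = self.data
        if len(d):
            wd = d["wind_dir_deg"].to_numpy()
            if ((wd < 0) | (wd >= 360)).any():
                raise DataError("wind_dir_deg outside [0, 360)")
            if (d["tvoc_ppm"].to_numpy() < 0).any():
                raise DataError("negative TVOC")
            if (d["wind_speed_ms"].to_numpy() < 0).any():
                raise DataError("negative wind speed")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)
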