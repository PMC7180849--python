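"""Synthetic e-nose campaign generator with ground truth.

The generator emulates the statistical structure a two-level SOM / k-means
odor analysis assumes in multi-month field data from a fixed site near an
industrial VOC source:

* a small number of recurrent *air types* (latent states) with distinct
  ten-channel response profiles, persisting for multi-hour episodes
  (first-order Markov chain with a sticky diagonal);
* a "plant-impact" air type whose minutes co-occur with elevated TVOC,
  low wind speed, and wind blowing from the source sector;
* multi-day power-failure gaps during which no instrument records;
* optionally a sudden sensor-freeze failure after which every channel is
  near-constant (loss of dynamic response), the anomaly the downstream
  detector must find.

Sensor values are generated directly in the oriented convention
("larger = stronger response"); :func:`write_campaign` converts G0/G
channels back to the raw instrument convention so the CSV files exercise
the full ingest path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .frames import ANCILLARY_COLUMNS, AncillaryFrame, SensorFrame, SensorMeta
from .ingest import unorient_signals, write_ancillary_table, write_sensor_table

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindStateModel:
    """Per-air-type wind model: von Mises direction (degrees, concentration
    kappa) and lognormal speed (parameters of log-speed, m/s)."""

    mean_dir_deg: float
    kappa: float
    speed_log_mu: float
    speed_log_sigma: float


@dataclass(frozen=True)
class TvocStateModel:
    """Per-air-type lognormal TVOC model (parameters of log-ppm)."""

    log_mu: float
    log_sigma: float

    @property
    def median_ppm(self) -> float:
        return math.exp(self.log_mu)


# Oriented mean response profiles for the four default air types (channel
# order S1..S10).  Each air type has its own channel signature — background
# near baseline, a sulphur-tinged episode (S7/S9), an aromatic episode
# (S1/S3/S5), and the broad plant-impact profile elevated on all channels —
# so the profiles are roughly equidistant rather than nested.
_BASE = np.array([1.0, 1.1, 0.9, 1.0, 1.05, 0.95, 1.0, 1.1, 0.9, 1.0])
DEFAULT_STATE_MEANS = np.vstack(
    [
        _BASE,
        _BASE + [0.2, 0.3, 0.2, 0.3, 0.2, 0.3, 1.8, 0.5, 1.7, 0.2],
        _BASE + [1.8, 0.7, 1.7, 0.6, 1.6, 0.6, 0.3, 0.7, 0.3, 0.2],
        _BASE + [1.2, 1.5, 1.1, 1.4, 1.3, 1.3, 1.2, 1.4, 1.2, 0.6],
    ]
)

#: Stationary shares of the four default air types (background, sulphur,
#: aromatic, plant).
DEFAULT_STATIONARY = np.array([0.15, 0.25, 0.40, 0.20])

DEFAULT_WIND_MODELS = (
    WindStateModel(270.0, 2.0, math.log(2.5), 0.5),   # background: westerly, brisk
    WindStateModel(225.0, 1.5, math.log(2.0), 0.5),
    WindStateModel(290.0, 1.5, math.log(1.8), 0.5),
    WindStateModel(67.5, 3.0, math.log(0.6), 0.4),    # plant: NE/E source sector, calm
)

DEFAULT_TVOC_MODELS = (
    TvocStateModel(math.log(0.03), 0.4),
    TvocStateModel(math.log(0.05), 0.4),
    TvocStateModel(math.log(0.06), 0.4),
    TvocStateModel(math.log(0.14), 0.5),              # plant: median 0.14 ppm
)


def sticky_transition(stationary: np.ndarray, self_weight: float = 0.995) -> np.ndarray:
    """Row-stochastic matrix ``self_weight * I + (1-self_weight) * 1 pi^T``.

    Jumps land in state j with probability pi_j independent of origin, so
    ``stationary`` is the exact stationary distribution by construction and
    episodes last ~1/(1-self_weight) minutes on average.
    """
    pi = np.asarray(stationary, dtype=float)
    if pi.ndim != 1 or not math.isclose(pi.sum(), 1.0, abs_tol=1e-9) or (pi < 0).any():
        raise ValidationError("stationary shares must be a probability vector")
    n = len(pi)
    return self_weight * np.eye(n) + (1.0 - self_weight) * np.tile(pi, (n, 1))


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1, normalized)."""
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class SimConfig:
    """Full parameterization of a synthetic campaign."""

    n_days: int
    minutes_per_day: int = 1440
    state_means: np.ndarray = field(default_factory=lambda: DEFAULT_STATE_MEANS.copy())
    state_noise_sd: np.ndarray = field(default_factory=lambda: np.full(10, 0.08))
    transition: np.ndarray = field(
        default_factory=lambda: sticky_transition(DEFAULT_STATIONARY)
    )
    diurnal_amplitude: float = 0.05
    wind_models: tuple[WindStateModel, ...] = DEFAULT_WIND_MODELS
    tvoc_models: tuple[TvocStateModel, ...] = DEFAULT_TVOC_MODELS
    gap_spec: tuple[tuple[int, int], ...] = ()
    failure_onset: int | None = None
    failure_noise_sd: float = 0.002
    start_time: str = "2017-04-07"
    seed: int = 0

    @property
    def n_minutes(self) -> int:
        return self.n_days * self.minutes_per_day

    @property
    def n_states(self) -> int:
        return self.state_means.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.state_means.shape[1]

    def validate(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (self.n_states, self.n_states):
            raise ValidationError(
                f"transition shape {t.shape} != ({self.n_states}, {self.n_states})"
            )
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("transition matrix rows must sum to 1 (±1e-12)")
        sd = np.asarray(self.state_noise_sd, dtype=float)
        if sd.shape != (self.n_sensors,) or (sd <= 0).any():
            raise ValidationError("state_noise_sd must be positive, one per sensor")
        if len(self.wind_models) != self.n_states or len(self.tvoc_models) != self.n_states:
            raise ValidationError("need one wind and one TVOC model per state")
        if self.failure_onset is not None and not (0 < self.failure_onset < self.n_minutes):
            raise ValidationError("failure_onset must lie inside the campaign")
        if self.failure_noise_sd <= 0:
            raise ValidationError("failure_noise_sd must be > 0")
        for start, length in self.gap_spec:
            if start < 0 or length <= 0 or start + length > self.n_minutes:
                raise ValidationError(f"gap ({start}, {length}) outside campaign")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated campaign: the latent per-minute air-type
    sequence, the gap mask, and the failure onset (minute index or None)."""

    timestamps: pd.DatetimeIndex
    state_sequence: np.ndarray
    gap_mask: np.ndarray
    failure_onset: int | None

    @property
    def failed_mask(self) -> np.ndarray:
        m = np.zeros(len(self.state_sequence), dtype=bool)
        if self.failure_onset is not None:
            m[self.failure_onset:] = True
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute_index": np.arange(len(self.state_sequence)),
                "timestamp": self.timestamps,
                "state": self.state_sequence,
                "gap": self.gap_mask.astype(int),
                "failed": self.failed_mask.astype(int),
            }
        )


def merge_gap_spec(gap_spec, n_minutes: int) -> list[tuple[int, int]]:
    """Normalize a gap list: sort, and merge overlapping/adjacent gaps
    (with a warning, matching the tolerant treatment of outage logs)."""
    gaps = sorted((int(s), int(l)) for s, l in gap_spec)
    merged: list[tuple[int, int]] = []
    for start, length in gaps:
        if start < 0 or length <= 0 or start + length > n_minutes:
            raise ValidationError(f"gap ({start}, {length}) outside range")
        if merged and start < merged[-1][0] + merged[-1][1]:
            log.warning("overlapping gaps merged: %s and (%d, %d)", merged[-1], start, length)
            ps, pl = merged[-1]
            merged[-1] = (ps, max(ps + pl, start + length) - ps)
        else:
            merged.append((start, length))
    return merged


def _gap_mask(gap_spec, n_minutes: int) -> np.ndarray:
    mask = np.zeros(n_minutes, dtype=bool)
    for start, length in merge_gap_spec(gap_spec, n_minutes):
        mask[start:start + length] = True
    return mask


def _markov_sequence(rng: np.random.Generator, transition: np.ndarray, n: int) -> np.ndarray:
    pi = stationary_distribution(transition)
    cum = np.cumsum(transition, axis=1)
    u = rng.random(n)
    states = np.empty(n, dtype=np.int64)
    s = int(rng.choice(len(pi), p=pi))
    for t in range(n):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, len(pi) - 1)
    return states


def simulate_campaign(
    config: SimConfig, meta: SensorMeta | None = None
) -> tuple[SensorFrame, AncillaryFrame, SyntheticTruth]:
    """Generate one campaign; deterministic given ``config.seed``.

    Returns an *oriented* sensor frame and an ancillary frame with gap rows
    absent, plus the full-length ground truth.
    """
    config.validate()
    meta = meta or SensorMeta.pen3()
    if len(meta.sensor_ids) != config.n_sensors:
        raise ValidationError("sensor meta does not match state_means width")
    rng = np.random.default_rng(config.seed)
    n = config.n_minutes

    states = _markov_sequence(rng, np.asarray(config.transition, float), n)

    minute_of_day = np.arange(n) % config.minutes_per_day
    phase = 2.0 * np.pi * minute_of_day / config.minutes_per_day
    diurnal = config.diurnal_amplitude * np.sin(phase)

    values = (
        config.state_means[states]
        + diurnal[:, None]
        + rng.standard_normal((n, config.n_sensors)) * np.asarray(config.state_noise_sd)
    )

    if config.failure_onset is not None:
        # Freeze at the last observed vector (the instantaneous sensor state
        # when responsivity is lost), not at a state mean: a real stuck
        # reading is an arbitrary point of the response cloud, and the state
        # mean is a degenerate choice sitting at the center of the trained
        # prototype arrangement.
        m = config.failure_onset
        frozen = values[m - 1].copy()
        values[m:] = frozen + rng.standard_normal((n - m, config.n_sensors)) * config.failure_noise_sd

    np.clip(values, 1e-6, None, out=values)

    # Ancillary streams follow the same latent state (vectorized draws with
    # per-minute parameters keep the output independent of state ordering).
    wm = config.wind_models
    mean_rad = np.deg2rad([wm[s].mean_dir_deg for s in range(config.n_states)])[states]
    kappa = np.array([wm[s].kappa for s in range(config.n_states)])[states]
    wind_dir = np.degrees(rng.vonmises(mean_rad, kappa)) % 360.0
    speed = rng.lognormal(
        np.array([w.speed_log_mu for w in wm])[states],
        np.array([w.speed_log_sigma for w in wm])[states],
    )
    tvoc = rng.lognormal(
        np.array([t.log_mu for t in config.tvoc_models])[states],
        np.array([t.log_sigma for t in config.tvoc_models])[states],
    )
    temp = 15.0 + 7.0 * np.sin(phase - np.pi / 2) + rng.standard_normal(n)
    rh = np.clip(70.0 - 15.0 * np.sin(phase - np.pi / 2) + 3.0 * rng.standard_normal(n), 5, 95)

    timestamps = pd.date_range(config.start_time, periods=n, freq="min")
    gap_mask = _gap_mask(config.gap_spec, n)
    keep = ~gap_mask

    sensor = SensorFrame(
        data=pd.DataFrame(values[keep], index=timestamps[keep], columns=list(meta.sensor_ids)),
        meta=meta,
        oriented=True,
    )
    ancillary = AncillaryFrame(
        data=pd.DataFrame(
            np.column_stack([tvoc, speed, wind_dir, temp, rh])[keep],
            index=timestamps[keep],
            columns=list(ANCILLARY_COLUMNS),
        )
    )
    truth = SyntheticTruth(
        timestamps=timestamps,
        state_sequence=states,
        gap_mask=gap_mask,
        failure_onset=config.failure_onset,
    )
    return sensor, ancillary, truth


def inject_gaps(frame: SensorFrame, gap_spec) -> SensorFrame:
    """Remove the rows falling in ``gap_spec`` (minute offsets from the
    frame's first timestamp); all surviving rows are untouched."""
    if not gap_spec or len(frame) == 0:
        return frame.with_data(frame.data.copy())
    offsets = ((frame.timestamps - frame.timestamps[0]).total_seconds() // 60).astype(int)
    span = int(offsets[-1]) + 1
    mask = _gap_mask(gap_spec, span)
    keep = ~mask[offsets]
    return frame.with_data(frame.data[keep])


#: Gap layout of the default 83-day campaign: one 10-day power failure
#: starting day 7, one whole lost day, and scattered multi-hour outages.
STUDY_GAPS = (
    (7 * 1440, 10 * 1440),
    (30 * 1440 + 600, 180),
    (44 * 1440 + 300, 240),
    (62 * 1440, 1440),
    (70 * 1440 + 900, 120),
)


def default_config(
    n_days: int = 83,
    seed: int = 0,
    failure_day: int | None = 47,
    gaps: tuple[tuple[int, int], ...] | None = STUDY_GAPS,
) -> SimConfig:
    """Default campaign: 83 days of four recurrent air types, the study-like
    gap layout, and a sensor freeze at the start of ``failure_day``."""
    gap_spec = tuple(g for g in (gaps or ()) if g[0] + g[1] <= n_days * 1440)
    onset = None if failure_day is None else failure_day * 1440
    if onset is not None and onset >= n_days * 1440:
        raise ValidationError("failure_day outside campaign")
    return SimConfig(n_days=n_days, gap_spec=gap_spec, failure_onset=onset, seed=seed)


def write_campaign(
    sensor: SensorFrame,
    ancillary: AncillaryFrame,
    truth: SyntheticTruth,
    outdir,
) -> dict[str, str]:
    """Write the ingest-schema CSVs plus the truth sidecar; sensor values are
    converted back to raw instrument conventions (G0/G channels inverted)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = unorient_signals(sensor) if sensor.oriented else sensor
    paths = {
        "sensors": str(outdir / "sensors.csv"),
        "ancillary": str(outdir / "ancillary.csv"),
        "truth": str(outdir / "truth.csv"),
    }
    write_sensor_table(raw, paths["sensors"])
    write_ancillary_table(ancillary, paths["ancillary"])
    truth.to_frame().to_csv(paths["truth"], index=False, float_format="%.12g")
    return paths
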