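"""Membership transfer, ancillary fusion, daily shares, anomaly detection.

The fusion key is the best matching unit: a minute whose e-nose vector maps
to prototype p inherits p's cluster label, and any ancillary datum recorded
at the same minute (TVOC, wind) inherits it too.  Temporal structure is then
summarized as the per-day percentage share of recorded minutes per cluster,
the statistic used to spot a loss of sensor dynamic response: a sudden,
persistent collapse onto a single cluster together with a collapse of
within-day signal variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import Partition
from .errors import DataError, ValidationError
from .frames import AncillaryFrame, SensorFrame
from .som import SomModel, bmu_batch, normalize_apply

log = logging.getLogger(__name__)

SECTORS_8 = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
SECTORS_16 = ("N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
              "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW")


@dataclass
class MembershipSeries:
    """Per-minute BMU index, BMU distance and transferred cluster label."""

    data: pd.DataFrame  # index: timestamps; columns: bmu, distance, cluster
    k: int

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DailyShareTable:
    """Per calendar day: recorded minutes, ND flag, and percent share of
    recorded minutes per cluster (NaN on ND days)."""

    data: pd.DataFrame  # index: date; columns: recorded_minutes, nd_flag, share_1..k
    k: int
    min_minutes_for_day: int

    @property
    def share_columns(self) -> list[str]:
        return [f"share_{c}" for c in range(1, self.k + 1)]

    @property
    def non_nd(self) -> pd.DataFrame:
        return self.data[~self.data["nd_flag"]]


@dataclass
class ClusterSummary:
    """Per-cluster fusion summary of the ancillary streams."""

    counts: pd.Series               # joined minutes per cluster
    percent: pd.Series              # percent of joined minutes per cluster
    tvoc_quartiles: pd.DataFrame    # cluster x [q25, median, q75] (ppm)
    wind_speed_quartiles: pd.DataFrame  # cluster x [q25, median, q75] (m/s)
    sector_freq: pd.DataFrame       # cluster x sector, rows sum to 100
    n_calm_excluded: int = 0


@dataclass
class AnomalyReport:
    flagged: bool
    reason: str
    onset_date: pd.Timestamp | None = None
    dominant_cluster: int | None = None
    consecutive_days: int = 0
    mean_daily_sensor_sd: pd.Series | None = None
    distinct_bmus_in_flagged_period: int | None = None
    thresholds: dict = field(default_factory=dict)


def assign_membership(model: SomModel, partition: Partition, frame: SensorFrame) -> MembershipSeries:
    """BMU and cluster label per minute of an oriented sensor frame."""
    if not frame.oriented:
        raise ValidationError("frame must be oriented before membership assignment")
    if frame.values.shape[1] != model.n_channels:
        raise DataError("frame width does not match model")
    x = normalize_apply(model.norm, frame.values)
    bmus, dist = bmu_batch(model, x)
    df = pd.DataFrame(
        {"bmu": bmus, "distance": dist, "cluster": partition.labels[bmus]},
        index=frame.timestamps,
    )
    return MembershipSeries(data=df, k=partition.k)


def daily_shares(membership: MembershipSeries, min_minutes_for_day: int = 60) -> DailyShareTable:
    """Percent of each day's recorded minutes per cluster, over the full
    calendar span; days with fewer than ``min_minutes_for_day`` recorded
    minutes are flagged ND (not recorded)."""
    m = membership.data
    k = membership.k
    if len(m) == 0:
        raise DataError("empty membership series")
    day = m.index.floor("D")
    counts = (
        pd.crosstab(day, m["cluster"])
        .reindex(columns=range(1, k + 1), fill_value=0)
    )
    full_days = pd.date_range(day.min(), day.max(), freq="D")
    counts = counts.reindex(full_days, fill_value=0)
    recorded = counts.sum(axis=1)
    nd = recorded < min_minutes_for_day
    shares = counts.div(recorded.where(recorded > 0), axis=0) * 100.0
    shares[nd] = np.nan
    out = pd.DataFrame(
        {"recorded_minutes": recorded.astype(int), "nd_flag": nd}
    )
    for c in range(1, k + 1):
        out[f"share_{c}"] = shares[c]
    out.index.name = "date"
    return DailyShareTable(data=out, k=k, min_minutes_for_day=min_minutes_for_day)


def wind_sector(direction_deg, n_sectors: int = 8):
    """Sector label(s) for wind direction(s) in [0, 360).

    Sectors are centered on the cardinal/intercardinal directions with
    half-open intervals: with 8 sectors, N = [337.5, 22.5), then clockwise.
    """
    if n_sectors == 8:
        names = SECTORS_8
    elif n_sectors == 16:
        names = SECTORS_16
    else:
        raise ValidationError("n_sectors must be 8 or 16")
    d = np.asarray(direction_deg, dtype=float)
    if ((d < 0) | (d >= 360)).any():
        raise DataError("wind direction outside [0, 360)")
    width = 360.0 / n_sectors
    idx = ((d + width / 2.0) // width).astype(int) % n_sectors
    labels = np.asarray(names)[idx]
    return labels.item() if np.isscalar(direction_deg) else labels


def summarize_ancillary(
    membership: MembershipSeries,
    ancillary: AncillaryFrame,
    n_sectors: int = 8,
    calm_threshold_ms: float = 0.5,
) -> ClusterSummary:
    """Per-cluster TVOC and wind-speed quartiles (linear interpolation) and
    wind-sector frequency tables, over the minutes present in both series.

    Calm minutes (speed below ``calm_threshold_ms``) contribute to the speed
    quartiles but are excluded from sector frequencies, where direction is
    ill-defined.
    """
    common = membership.timestamps.intersection(ancillary.timestamps)
    if len(common) == 0:
        raise DataError("membership and ancillary series share no minutes")
    k = membership.k
    cl = membership.data.loc[common, "cluster"]
    anc = ancillary.data.loc[common]
    sectors = (SECTORS_8 if n_sectors == 8 else SECTORS_16)

    counts = cl.value_counts().reindex(range(1, k + 1), fill_value=0)
    percent = counts / counts.sum() * 100.0
    qcols = ["q25", "median", "q75"]

    def quartiles(series: pd.Series) -> pd.DataFrame:
        rows = {}
        for c in range(1, k + 1):
            v = series[cl == c]
            if len(v) == 0:
                log.warning("cluster %d has no joined minutes", c)
                rows[c] = [np.nan] * 3
            else:
                rows[c] = np.percentile(v, [25, 50, 75]).tolist()
        return pd.DataFrame.from_dict(rows, orient="index", columns=qcols)

    windy = anc["wind_speed_ms"] >= calm_threshold_ms
    sec = pd.Series(
        wind_sector(anc.loc[windy, "wind_dir_deg"].to_numpy(), n_sectors),
        index=anc.index[windy],
    )
    freq = (
        pd.crosstab(cl[windy], sec)
        .reindex(index=range(1, k + 1), columns=list(sectors), fill_value=0)
        .astype(float)
    )
    row_sums = freq.sum(axis=1)
    freq = freq.div(row_sums.where(row_sums > 0), axis=0) * 100.0

    return ClusterSummary(
        counts=counts,
        percent=percent,
        tvoc_quartiles=quartiles(anc["tvoc_ppm"]),
        wind_speed_quartiles=quartiles(anc["wind_speed_ms"]),
        sector_freq=freq,
        n_calm_excluded=int((~windy).sum()),
    )


def _daily_sensor_sd(frame: SensorFrame) -> pd.Series:
    """Per-day mean (across channels) of the within-day standard deviation
    of each channel — the dispersion statistic behind the freeze test."""
    day = frame.data.index.floor("D")
    return frame.data.groupby(day).std(ddof=0).mean(axis=1)


def detect_anomaly(
    daily: DailyShareTable,
    frame: SensorFrame,
    membership: MembershipSeries | None = None,
    share_threshold: float = 95.0,
    min_consecutive_days: int = 3,
    sd_collapse_ratio: float = 0.1,
) -> AnomalyReport:
    """Flag a persistent loss of sensor dynamic response.

    The rule is a conjunction, so a single anomalous 100%-share day does not
    trigger it: the earliest run of >= ``min_consecutive_days`` non-ND days
    in which (a) one cluster holds >= ``share_threshold`` percent of every
    day's minutes and keeps doing so on every later non-ND day to the end of
    the campaign, and (b) the mean within-day per-channel standard deviation
    over the run is <= ``sd_collapse_ratio`` times the campaign median of
    that statistic.  If ``membership`` is supplied, the number of distinct
    BMUs visited in the flagged period is reported.
    """
    thresholds = {
        "share_threshold": share_threshold,
        "min_consecutive_days": min_consecutive_days,
        "sd_collapse_ratio": sd_collapse_ratio,
    }
    non_nd = daily.non_nd
    disp = _daily_sensor_sd(frame)
    disp_non_nd = disp.reindex(non_nd.index).dropna()
    report = AnomalyReport(flagged=False, reason="", mean_daily_sensor_sd=disp,
                           thresholds=thresholds)
    if len(non_nd) < min_consecutive_days:
        report.reason = (
            f"only {len(non_nd)} non-ND day(s); need {min_consecutive_days}"
        )
        return report

    shares = non_nd[daily.share_columns].to_numpy()
    days = non_nd.index
    # earliest start so that one fixed cluster dominates every later non-ND day
    onset_idx, dominant = None, None
    for c in range(daily.k):
        ok = shares[:, c] >= share_threshold
        # longest dominant suffix for this cluster
        if not ok[-1]:
            continue
        s = len(ok)
        while s > 0 and ok[s - 1]:
            s -= 1
        if len(ok) - s >= min_consecutive_days and (onset_idx is None or s < onset_idx):
            onset_idx, dominant = s, c + 1
    if onset_idx is None:
        report.reason = "no persistent single-cluster dominance to campaign end"
        return report

    # Scan run starts within the dominant suffix for the earliest run that
    # also satisfies the variability-collapse condition: natural full-day
    # single-state episodes in the same cluster can immediately precede the
    # freeze, and those healthy days must neither dilute the run mean past
    # the threshold nor be reported as the onset.
    campaign_median = float(disp_non_nd.median())
    cutoff = sd_collapse_ratio * campaign_median
    chosen = None
    run_mean = float("nan")
    for s in range(onset_idx, len(days) - min_consecutive_days + 1):
        cand = disp.reindex(days[s:]).dropna()
        run_mean = float(cand.mean()) if len(cand) else float("nan")
        if run_mean <= cutoff:
            chosen = s
            break
    if chosen is None:
        report.reason = (
            f"dominance found from {days[onset_idx].date()} but within-day "
            f"variability ({run_mean:.4g}) did not collapse below "
            f"{sd_collapse_ratio} x campaign median ({campaign_median:.4g})"
        )
        return report
    run_days = days[chosen:]
    run_disp = disp.reindex(run_days).dropna()

    # refine the reported onset to the first genuinely collapsed day
    onset = run_days[0]
    collapsed = run_disp[run_disp <= cutoff]
    if len(collapsed):
        onset = collapsed.index[0]
        run_days = run_days[run_days >= onset]
    run_mean = float(run_disp.mean())

    report.flagged = True
    report.onset_date = onset
    report.dominant_cluster = int(dominant)
    report.consecutive_days = len(run_days)
    report.reason = (
        f"cluster {dominant} held >= {share_threshold}% of minutes on "
        f"{len(run_days)} consecutive non-ND day(s) from {run_days[0].date()} "
        f"to campaign end, with within-day variability {run_mean:.4g} vs "
        f"campaign median {campaign_median:.4g}"
    )
    if membership is not None:
        in_run = membership.data.index.floor("D") >= run_days[0]
        report.distinct_bmus_in_flagged_period = int(
            membership.data.loc[in_run, "bmu"].nunique()
        )
    return report


def split_building_external(frame: SensorFrame, cutoff_date) -> tuple[SensorFrame, SensorFrame]:
    """Split at a calendar date: building = rows up to and including
    ``cutoff_date``; external = everything after.  Disjoint and exhaustive."""
    cutoff = pd.Timestamp(cutoff_date).floor("D")
    day = frame.data.index.floor("D")
    building = frame.with_data(frame.data[day <= cutoff])
    external = frame.with_data(frame.data[day > cutoff])
    return building, external


def project_external(
    model: SomModel, partition: Partition, frame: SensorFrame
) -> tuple[MembershipSeries, np.ndarray, int]:
    """Project new minutes onto a trained map (pure query: the model is not
    modified and its stored building-data normalization is reused).

    Returns the membership series, the per-unit hit histogram, and the
    number of distinct BMUs visited.
    """
    membership = assign_membership(model, partition, frame)
    hits = np.bincount(membership.data["bmu"].to_numpy(), minlength=model.n_units)
    return membership, hits, int((hits > 0).sum())
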