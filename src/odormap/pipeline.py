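"""Two-stage pipeline orchestration.

Stage 1 is exploratory: a heuristically sized small SOM on the whole
campaign, Davies-Bouldin k-selection over the prototypes, minute-level
membership, daily cluster shares, and the freeze-anomaly detector.  Stage 2
rebuilds the model on the pre-anomaly ("building") subset only — including
refitting the normalization — selects k again, fuses the ancillary streams,
and projects the post-cutoff ("external") minutes onto the refined map to
confirm the anomaly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import KSelection, cluster_variance, select_k
from .errors import DataError, ValidationError
from .frames import AncillaryFrame, SensorFrame
from .fusion import (
    AnomalyReport,
    ClusterSummary,
    DailyShareTable,
    MembershipSeries,
    assign_membership,
    daily_shares,
    detect_anomaly,
    project_external,
    split_building_external,
    summarize_ancillary,
)
from .ingest import orient_signals
from .som import (
    SomModel,
    TrainConfig,
    batch_train,
    eigen_ratio,
    fit_grid,
    heuristic_units,
    linear_init,
    normalize_apply,
    normalize_fit,
    save_model,
)

log = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "orient", "size_class", "lattice", "epochs", "neighborhood",
    "radius_initial", "radius_final", "phases", "k_min", "k_max", "restarts",
    "nd_min_minutes", "share_threshold", "min_consecutive_days",
    "sd_collapse_ratio", "n_sectors", "calm_threshold_ms", "seed",
}


@dataclass
class PipelineConfig:
    orient: bool = True
    size_class: str = "small"
    lattice: str = "hexagonal"
    epochs: int = 2
    neighborhood: str = "gaussian"
    radius_initial: float | None = None
    radius_final: float = 1.0
    phases: bool = False
    k_min: int = 2
    k_max: int = 8
    restarts: int = 10
    nd_min_minutes: int = 60
    share_threshold: float = 95.0
    min_consecutive_days: int = 3
    sd_collapse_ratio: float = 0.1
    n_sectors: int = 8
    calm_threshold_ms: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(doc) - _CONFIG_FIELDS
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**doc)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, neighborhood=self.neighborhood,
            radius_initial=self.radius_initial, radius_final=self.radius_final,
            phases=self.phases,
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StageResult:
    model: SomModel
    selection: KSelection
    membership: MembershipSeries
    daily: DailyShareTable
    n_input_rows: int


@dataclass
class Stage1Result(StageResult):
    anomaly: AnomalyReport = None


@dataclass
class Stage2Result(StageResult):
    summary: ClusterSummary = None
    variances: np.ndarray = None
    external_membership: MembershipSeries | None = None
    external_hits: np.ndarray | None = None
    external_distinct_bmus: int | None = None
    cutoff_date: pd.Timestamp | None = None
    notice: str = ""


def _train_som(frame: SensorFrame, config: PipelineConfig) -> SomModel:
    data = frame.values
    norm = normalize_fit(data)
    z = normalize_apply(norm, data)
    n_units = heuristic_units(len(z), config.size_class)
    grid = fit_grid(n_units, eigen_ratio(z), lattice=config.lattice)
    log.info("map geometry: %d x %d (%d units) for %d rows",
             grid.xdim, grid.ydim, grid.n_units, len(z))
    model = linear_init(z, grid, norm)
    return batch_train(model, z, config.train_config())


def _model_stage(frame: SensorFrame, config: PipelineConfig) -> StageResult:
    if len(frame) == 0:
        raise DataError("empty input frame")
    model = _train_som(frame, config)
    selection = select_k(model.codebook, config.k_min,
                         min(config.k_max, model.n_units), config.restarts,
                         seed=config.seed)
    membership = assign_membership(model, selection.best_partition, frame)
    daily = daily_shares(membership, config.nd_min_minutes)
    log.debug("per-k DB table: %s", dict(zip(selection.k_range, selection.db_index)))
    return StageResult(model=model, selection=selection, membership=membership,
                       daily=daily, n_input_rows=len(frame))


def run_stage1(
    sensor: SensorFrame, config: PipelineConfig | None = None
) -> Stage1Result:
    """Exploratory model on the whole campaign plus anomaly detection."""
    config = config or PipelineConfig()
    if config.orient and not sensor.oriented:
        sensor = orient_signals(sensor)
    base = _model_stage(sensor, config)
    anomaly = detect_anomaly(
        base.daily, sensor, base.membership,
        share_threshold=config.share_threshold,
        min_consecutive_days=config.min_consecutive_days,
        sd_collapse_ratio=config.sd_collapse_ratio,
    )
    log.info("stage 1: %d rows, best_k=%d, anomaly flagged=%s",
             base.n_input_rows, base.selection.best_k, anomaly.flagged)
    return Stage1Result(**base.__dict__, anomaly=anomaly)


def run_stage2(
    sensor: SensorFrame,
    ancillary: AncillaryFrame,
    anomaly: AnomalyReport,
    config: PipelineConfig | None = None,
) -> Stage2Result:
    """Refined model on the pre-anomaly building subset, ancillary fusion,
    and projection of the external subset.

    If no anomaly was flagged the full campaign is used (with a prominent
    notice) and the external projection is empty.
    """
    config = config or PipelineConfig()
    if config.orient and not sensor.oriented:
        sensor = orient_signals(sensor)
    notice = ""
    if anomaly.flagged:
        cutoff = anomaly.onset_date - pd.Timedelta(days=1)
    else:
        cutoff = sensor.timestamps[-1].floor("D")
        notice = ("NO ANOMALY FLAGGED: stage 2 built on the full campaign; "
                  "external projection is empty")
        log.warning(notice)
    building, external = split_building_external(sensor, cutoff)
    base = _model_stage(building, config)
    summary = summarize_ancillary(
        base.membership, ancillary, n_sectors=config.n_sectors,
        calm_threshold_ms=config.calm_threshold_ms,
    )
    variances = cluster_variance(base.model.codebook,
                                 base.selection.best_partition,
                                 norm=base.model.norm)
    if len(external):
        ext_m, hits, distinct = project_external(
            base.model, base.selection.best_partition, external
        )
    else:
        ext_m, hits, distinct = None, None, None
        if not notice:
            notice = "external subset empty (cutoff at campaign end)"
            log.info(notice)
    log.info("stage 2: building=%d external=%d best_k=%d",
             len(building), len(external), base.selection.best_k)
    return Stage2Result(
        **base.__dict__, summary=summary, variances=variances,
        external_membership=ext_m, external_hits=hits,
        external_distinct_bmus=distinct, cutoff_date=cutoff, notice=notice,
    )


# ---------------------------------------------------------------------------
# artifact writing and the run manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, rows_in: int, rows_out: int) -> None:
        self.stages.append({"name": name, "seconds": round(seconds, 3),
                            "rows_in": rows_in, "rows_out": rows_out})

    def add_file(self, path) -> None:
        p = Path(path)
        self.files[p.name] = _sha256(p)

    def write(self, path) -> None:
        doc = {"config_hash": self.config_hash, "seed": self.seed,
               "versions": self.versions, "stages": self.stages,
               "files": self.files}
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def new_manifest(config: PipelineConfig) -> RunManifest:
    return RunManifest(
        config_hash=config.hash(), seed=config.seed,
        versions={"odormap": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
    )


def write_membership_csv(membership: MembershipSeries, path) -> None:
    df = membership.data.copy()
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.9g", date_format="%Y-%m-%dT%H:%M:%S")


def write_daily_csv(daily: DailyShareTable, path) -> None:
    daily.data.to_csv(path, float_format="%.9g", date_format="%Y-%m-%d")


def write_selection_csv(selection: KSelection, path) -> None:
    pd.DataFrame({"k": selection.k_range, "db_index": selection.db_index}).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_anomaly_report(report: AnomalyReport, path) -> None:
    doc = {
        "flagged": report.flagged,
        "reason": report.reason,
        "onset_date": None if report.onset_date is None else str(report.onset_date.date()),
        "dominant_cluster": report.dominant_cluster,
        "consecutive_days": report.consecutive_days,
        "distinct_bmus_in_flagged_period": report.distinct_bmus_in_flagged_period,
        "thresholds": report.thresholds,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_summary_csv(summary: ClusterSummary, outdir) -> list[Path]:
    outdir = Path(outdir)
    paths = []
    table = pd.DataFrame({"minutes": summary.counts, "percent": summary.percent})
    for name, df in [
        ("cluster_counts", table),
        ("tvoc_quartiles", summary.tvoc_quartiles),
        ("wind_speed_quartiles", summary.wind_speed_quartiles),
        ("sector_freq", summary.sector_freq),
    ]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, float_format="%.9g", index_label="cluster")
        paths.append(p)
    return paths


def write_stage1_artifacts(result: Stage1Result, outdir, manifest: RunManifest) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_model(result.model, outdir / "stage1_model.som")
    write_selection_csv(result.selection, outdir / "stage1_db_table.csv")
    write_membership_csv(result.membership, outdir / "stage1_membership.csv")
    write_daily_csv(result.daily, outdir / "stage1_daily_shares.csv")
    write_anomaly_report(result.anomaly, outdir / "anomaly_report.json")
    for name in ["stage1_model.som", "stage1_db_table.csv", "stage1_membership.csv",
                 "stage1_daily_shares.csv", "anomaly_report.json"]:
        manifest.add_file(outdir / name)


def write_stage2_artifacts(result: Stage2Result, outdir, manifest: RunManifest) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_model(result.model, outdir / "stage2_model.som")
    write_selection_csv(result.selection, outdir / "stage2_db_table.csv")
    write_membership_csv(result.membership, outdir / "stage2_membership.csv")
    write_daily_csv(result.daily, outdir / "stage2_daily_shares.csv")
    names = ["stage2_model.som", "stage2_db_table.csv", "stage2_membership.csv",
             "stage2_daily_shares.csv"]
    for p in write_summary_csv(result.summary, outdir):
        names.append(p.name)
    np.savetxt(outdir / "stage2_cluster_variance.csv",
               np.column_stack([np.arange(1, len(result.variances) + 1),
                                result.variances]),
               delimiter=",", header="cluster,total_variance", comments="",
               fmt="%.9g")
    names.append("stage2_cluster_variance.csv")
    if result.external_membership is not None:
        write_membership_csv(result.external_membership, outdir / "external_membership.csv")
        np.savetxt(outdir / "external_hits.csv", result.external_hits,
                   delimiter=",", header="hits", comments="", fmt="%d")
        names += ["external_membership.csv", "external_hits.csv"]
    if result.notice:
        (outdir / "stage2_notice.txt").write_text(result.notice + "\n")
        names.append("stage2_notice.txt")
    for name in names:
        manifest.add_file(outdir / name)


def write_partition_csv(partition, path) -> None:
    pd.DataFrame({"unit": np.arange(len(partition.labels)),
                  "cluster": partition.labels}).to_csv(path, index=False)


def load_partition_csv(prototypes: np.ndarray, path):
    from .clustering import partition_from_labels

    df = pd.read_csv(path)
    if list(df.columns) != ["unit", "cluster"]:
        raise DataError(f"{path}: expected columns unit,cluster")
    return partition_from_labels(prototypes, df["cluster"].to_numpy())


def load_membership_csv(path) -> MembershipSeries:
    df = pd.read_csv(path, index_col="timestamp", parse_dates=["timestamp"])
    if list(df.columns) != ["bmu", "distance", "cluster"]:
        raise DataError(f"{path}: expected columns bmu,distance,cluster")
    return MembershipSeries(data=df, k=int(df["cluster"].max()))


def load_daily_csv(path, min_minutes_for_day: int = 60) -> DailyShareTable:
    df = pd.read_csv(path, index_col="date", parse_dates=["date"])
    share_cols = [c for c in df.columns if c.startswith("share_")]
    if "recorded_minutes" not in df.columns or not share_cols:
        raise DataError(f"{path}: not a daily share table")
    df["nd_flag"] = df["nd_flag"].astype(bool)
    return DailyShareTable(data=df, k=len(share_cols),
                           min_minutes_for_day=min_minutes_for_day)


class StageTimer:
    """Context manager recording a stage's wall time into a manifest."""

    def __init__(self, manifest: RunManifest, name: str, rows_in: int):
        self.manifest, self.name, self.rows_in = manifest, name, rows_in
        self.rows_out = rows_in

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.add_stage(self.name, time.perf_counter() - self.t0,
                                self.rows_in, self.rows_out)
        return False
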