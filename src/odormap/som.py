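"""Batch-trained self-organizing map with heuristic sizing.

The map is a 2-D lattice (hexagonal by default) of units, each holding a
prototype ("codebook") vector in sensor space.  Sizing follows the classic
heuristics: the unit count grows as 5*sqrt(n_samples) (quartered for a
"small" map, quadrupled for a "big" one) and the side-length ratio follows
the square root of the ratio of the two leading eigenvalues of the data
covariance.  Initialization is deterministic, spanning the plane of the two
leading principal components; training is the batch rule, in which each unit
moves to the neighborhood-kernel-weighted mean of the data whose best
matching unit (BMU) lies nearby, with the kernel radius shrinking across
epochs.  With a zero-radius kernel one batch pass degenerates to one Lloyd
k-means step with k equal to the number of units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .errors import DataError, ValidationError

log = logging.getLogger(__name__)

_EPS_SCALE = 1e-9


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class GridSpec:
    """Map geometry; ``xdim`` is the longer side by convention."""

    xdim: int
    ydim: int
    lattice: str = "hexagonal"

    def __post_init__(self) -> None:
        if self.ydim < 1 or self.xdim < self.ydim:
            raise ValidationError("require xdim >= ydim >= 1")
        if self.lattice not in ("hexagonal", "rectangular"):
            raise ValidationError(f"unknown lattice {self.lattice!r}")

    @property
    def n_units(self) -> int:
        return self.xdim * self.ydim

    def positions(self) -> np.ndarray:
        """(n_units, 2) lattice coordinates; unit u = row*xdim + col.
        Hexagonal rows are offset by half a unit and packed at sqrt(3)/2."""
        rows, cols = np.divmod(np.arange(self.n_units), self.xdim)
        if self.lattice == "hexagonal":
            x = cols + 0.5 * (rows % 2)
            y = rows * (math.sqrt(3.0) / 2.0)
        else:
            x, y = cols.astype(float), rows.astype(float)
        return np.column_stack([x, y])

    def grid_distances(self) -> np.ndarray:
        p = self.positions()
        return cdist(p, p)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel z-score parameters fitted on the building data."""

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if (np.asarray(self.scale) <= 0).any():
            raise ValidationError("normalization scale must be > 0")


@dataclass(frozen=True)
class TrainConfig:
    """Batch-training schedule.

    ``epochs`` counts full batch passes over the data.  The learning-rate
    schedule field is retained for config fidelity but the batch rule has no
    per-sample rate; it is ignored during batch training.
    """

    epochs: int = 2
    neighborhood: str = "gaussian"
    radius_initial: float | None = None
    radius_final: float = 1.0
    learning_schedule: str = "inverse-time"
    phases: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.neighborhood not in ("gaussian", "bubble"):
            raise ValidationError(f"unknown neighborhood {self.neighborhood!r}")
        if self.radius_initial is not None and self.radius_initial < self.radius_final:
            raise ValidationError("radius_initial must be >= radius_final")
        if self.radius_final < 0:
            raise ValidationError("radius_final must be >= 0")


@dataclass
class SomModel:
    grid: GridSpec
    codebook: np.ndarray
    norm: NormalizationParams
    history: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.grid.n_units

    @property
    def n_channels(self) -> int:
        return self.codebook.shape[1]


# ---------------------------------------------------------------------------
# sizing heuristics

def heuristic_units(n_samples: int, size_class: str = "small") -> int:
    """Target unit count: base = ceil(5*sqrt(n)); small = base/4 and big =
    4*base, rounded half away from zero."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    base = math.ceil(5.0 * math.sqrt(n_samples))
    if size_class == "normal":
        return base
    if size_class == "small":
        return _round_half_away(base / 4.0)
    if size_class == "big":
        return 4 * base
    raise ValidationError(f"unknown size_class {size_class!r}")


def eigen_ratio(data: np.ndarray) -> float:
    """Side-length ratio sqrt(lambda1/lambda2) of the two leading covariance
    eigenvalues of the (normalized) data."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DataError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    cov = np.cov(x, rowvar=False)
    w = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if w[0] <= 0 or w[1] <= max(w[0], 0.0) * 1e-12:
        raise DataError("degenerate covariance: fewer than two nonzero eigenvalues")
    return float(math.sqrt(w[0] / w[1]))


def fit_grid(n_units: int, ratio: float, lattice: str = "hexagonal") -> GridSpec:
    """Fit integer grid sides to a target unit count and side-length ratio:
    ydim = round(sqrt(n_units/ratio)), xdim = round(n_units/ydim), both
    rounded half away from zero."""
    if n_units < 1:
        raise ValidationError("n_units must be >= 1")
    if ratio < 1:
        raise ValidationError("ratio must be >= 1 (longer side over shorter)")
    ydim = _round_half_away(math.sqrt(n_units / ratio))
    ydim = max(1, min(ydim, n_units))
    xdim = max(1, _round_half_away(n_units / ydim))
    if xdim < ydim:
        xdim, ydim = ydim, xdim
    return GridSpec(xdim=xdim, ydim=ydim, lattice=lattice)


# ---------------------------------------------------------------------------
# normalization

def normalize_fit(data: np.ndarray, eps: float = _EPS_SCALE) -> NormalizationParams:
    """Per-channel z-score parameters; zero-variance channels get an epsilon
    scale with a warning rather than an error."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise DataError("need a nonempty 2-D matrix")
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    if (scale <= eps).any():
        log.warning(
            "zero-variance channel(s) %s: scale floored at %g",
            np.nonzero(scale <= eps)[0].tolist(), eps,
        )
        scale = np.where(scale <= eps, eps, scale)
    return NormalizationParams(center=center, scale=scale)


def normalize_apply(params: NormalizationParams, data: np.ndarray) -> np.ndarray:
    return (np.asarray(data, dtype=float) - params.center) / params.scale


def normalize_invert(params: NormalizationParams, data: np.ndarray) -> np.ndarray:
    return np.asarray(data, dtype=float) * params.scale + params.center


# ---------------------------------------------------------------------------
# initialization and training

def linear_init(data: np.ndarray, grid: GridSpec, norm: NormalizationParams) -> SomModel:
    """Deterministic initialization spanning the plane of the two leading
    principal components: unit (row, col) = mean + a*sd1*PC1 + b*sd2*PC2 with
    a (resp. b) linearly spaced over [-1, 1] along xdim (resp. ydim)."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise DataError("need a nonempty 2-D matrix")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False) if len(x) > 1 else np.zeros((x.shape[1], x.shape[1]))
    w, v = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    sd1 = math.sqrt(max(w[0], 0.0))
    if len(w) > 1 and w[1] > max(w[0], 0.0) * 1e-12:
        sd2, pc2 = math.sqrt(w[1]), v[:, 1]
    else:
        log.warning("rank-1 data: second initialization axis zeroed")
        sd2, pc2 = 0.0, np.zeros(x.shape[1])
    pc1 = v[:, 0]
    a = np.linspace(-1.0, 1.0, grid.xdim) if grid.xdim > 1 else np.array([0.0])
    b = np.linspace(-1.0, 1.0, grid.ydim) if grid.ydim > 1 else np.array([0.0])
    rows, cols = np.divmod(np.arange(grid.n_units), grid.xdim)
    if not isinstance(norm, NormalizationParams):
        raise ValidationError("linear_init requires fitted NormalizationParams")
    codebook = mean + np.outer(a[cols] * sd1, pc1) + np.outer(b[rows] * sd2, pc2)
    return SomModel(grid=grid, codebook=codebook, norm=norm)


def bmu_batch(model: SomModel, data: np.ndarray, chunk: int = 16384):
    """Best matching unit (argmin Euclidean distance, ties to the lowest unit
    index) and its distance, for every row of normalized ``data``."""
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[1] != model.n_channels:
        raise DataError(f"vector width {x.shape[1]} != codebook width {model.n_channels}")
    if not np.isfinite(x).all():
        raise DataError("non-finite input vector")
    idx = np.empty(len(x), dtype=np.int64)
    dist = np.empty(len(x), dtype=float)
    for lo in range(0, len(x), chunk):
        d = cdist(x[lo:lo + chunk], model.codebook)
        idx[lo:lo + chunk] = np.argmin(d, axis=1)
        dist[lo:lo + chunk] = d[np.arange(len(d)), idx[lo:lo + chunk]]
    return idx, dist


def bmu(model: SomModel, vector: np.ndarray) -> tuple[int, float]:
    idx, dist = bmu_batch(model, np.atleast_2d(vector))
    return int(idx[0]), float(dist[0])


def _kernel(grid_d: np.ndarray, sigma: float, neighborhood: str) -> np.ndarray:
    if neighborhood == "bubble":
        return (grid_d <= sigma).astype(float)
    if sigma <= 0:
        return (grid_d == 0).astype(float)
    return np.exp(-(grid_d ** 2) / (2.0 * sigma ** 2))


def default_radius_initial(grid: GridSpec) -> float:
    return max(1.0, max(grid.xdim, grid.ydim) / 4.0)


def _radius_schedule(r0: float, r1: float, passes: int) -> np.ndarray:
    if passes == 1:
        return np.array([r1])
    return np.linspace(r0, r1, passes)


def batch_train(model: SomModel, data: np.ndarray, config: TrainConfig | None = None) -> SomModel:
    """Batch SOM training: per pass, assign every row to its BMU, then move
    each unit to the kernel-weighted mean of the rows assigned near it.
    Units receiving zero kernel mass keep their previous prototype.  The
    returned model records quantization error after each pass.  The batch
    path uses no randomness: training is bit-reproducible.
    """
    config = config or TrainConfig()
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise DataError("empty training data")
    r0 = config.radius_initial if config.radius_initial is not None else default_radius_initial(model.grid)
    if config.phases:
        mid = max(config.radius_final, r0 / 4.0)
        sigmas = np.concatenate(
            [_radius_schedule(r0, mid, config.epochs),
             _radius_schedule(mid, config.radius_final, 2 * config.epochs)]
        )
    else:
        sigmas = _radius_schedule(r0, config.radius_final, config.epochs)

    grid_d = model.grid.grid_distances()
    codebook = model.codebook.copy()
    history = list(model.history)
    work = replace_codebook(model, codebook)
    for sigma in sigmas:
        bmus, _ = bmu_batch(work, x)
        counts = np.bincount(bmus, minlength=model.n_units).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmus, x)
        h = _kernel(grid_d, float(sigma), config.neighborhood)
        den = h @ counts
        num = h @ sums
        mask = den > 0
        codebook[mask] = num[mask] / den[mask, None]
        work = replace_codebook(work, codebook)
        _, dist = bmu_batch(work, x)
        history.append(float(dist.mean()))
        log.debug("batch pass sigma=%.3f QE=%.6f", sigma, history[-1])
    return SomModel(grid=model.grid, codebook=codebook, norm=model.norm, history=history)


def replace_codebook(model: SomModel, codebook: np.ndarray) -> SomModel:
    return SomModel(grid=model.grid, codebook=codebook, norm=model.norm,
                    history=list(model.history))


# ---------------------------------------------------------------------------
# quality metrics and planes

def quantization_error(model: SomModel, data: np.ndarray) -> float:
    """Mean Euclidean distance from each row to its BMU."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise DataError("empty data")
    _, dist = bmu_batch(model, x)
    return float(dist.mean())


def topographic_error(model: SomModel, data: np.ndarray, chunk: int = 16384) -> float:
    """Fraction of rows whose first and second BMUs are not lattice
    neighbors (grid distance > 1, to lattice tolerance)."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise DataError("empty data")
    if model.n_units < 2:
        return 0.0
    grid_d = model.grid.grid_distances()
    bad = 0
    for lo in range(0, len(x), chunk):
        d = cdist(x[lo:lo + chunk], model.codebook)
        part = np.argpartition(d, 1, axis=1)[:, :2]
        first = np.where(
            d[np.arange(len(part)), part[:, 0]] <= d[np.arange(len(part)), part[:, 1]],
            part[:, 0], part[:, 1],
        )
        second = np.where(first == part[:, 0], part[:, 1], part[:, 0])
        bad += int((grid_d[first, second] > 1.0 + 1e-9).sum())
    return bad / len(x)


def component_plane(model: SomModel, channel: int, denormalize: bool = True) -> np.ndarray:
    """One channel's prototype weights reshaped to (ydim, xdim); by default
    converted back to original ratio units via the stored normalization."""
    if not 0 <= channel < model.n_channels:
        raise ValidationError(f"channel {channel} out of range")
    col = model.codebook[:, channel]
    if denormalize:
        col = col * model.norm.scale[channel] + model.norm.center[channel]
    return col.reshape(model.grid.ydim, model.grid.xdim)


# ---------------------------------------------------------------------------
# serialization (single structured text file)

_FORMAT_VERSION = 1


def save_model(model: SomModel, path) -> None:
    doc = {
        "format": "odormap-som",
        "version": _FORMAT_VERSION,
        "grid": {"xdim": model.grid.xdim, "ydim": model.grid.ydim,
                 "lattice": model.grid.lattice},
        "norm": {"center": [float(c) for c in model.norm.center],
                 "scale": [float(s) for s in model.norm.scale]},
        "history": [float(h) for h in model.history],
        "codebook": [[float(v) for v in row] for row in model.codebook],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> SomModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != "odormap-som":
        raise DataError(f"{path}: not an odormap SOM model file")
    if doc.get("version") != _FORMAT_VERSION:
        raise DataError(f"{path}: unsupported model version {doc.get('version')}")
    grid = GridSpec(**doc["grid"])
    norm = NormalizationParams(
        center=np.array(doc["norm"]["center"], dtype=float),
        scale=np.array(doc["norm"]["scale"], dtype=float),
    )
    codebook = np.array(doc["codebook"], dtype=float)
    if codebook.shape[0] != grid.n_units:
        raise DataError(f"{path}: codebook rows != grid units")
    return SomModel(grid=grid, codebook=codebook, norm=norm,
                    history=list(doc.get("history", [])))
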