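import numpy as np
import pytest

from odormap import synthetic as sy
from odormap.pipeline import PipelineConfig, run_stage1


@pytest.fixture(scope="session")
def clean_campaign():
    """14-day clean campaign (no gaps, no failure), default air types."""
    cfg = sy.SimConfig(n_days=14, seed=0)
    sensor, ancillary, truth = sy.simulate_campaign(cfg)
    return cfg, sensor, ancillary, truth


@pytest.fixture(scope="session")
def stage1_clean(clean_campaign):
    """Exploratory stage-1 result on the clean 14-day campaign."""
    _, sensor, _, _ = clean_campaign
    return run_stage1(sensor, PipelineConfig(restarts=5))


def blobs(rng, centers, n_per, sd):
    """Gaussian blobs around the given centers, shuffled."""
    centers = np.asarray(centers, dtype=float)
    pts = np.concatenate(
        [c + rng.standard_normal((n_per, centers.shape[1])) * sd for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    order = rng.permutation(len(pts))
    return pts[order], labels[order]
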