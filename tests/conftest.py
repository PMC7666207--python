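"""Shared fixtures: the default synthetic scenario and cheap small datasets.

Expensive artefacts (the full default scenario and its processed
reference) are session-scoped so the clustering-recovery, benchmark and
acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import scdepth
from scdepth import benchmark as bm

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_scenario():
    """Default study conditions: 2000 genes x 3000 cells, 5 subtypes."""
    cfg = scdepth.GeneratorConfig(seed=DEFAULT_SEED)
    cm, reads, truth = scdepth.generate_dataset(cfg)
    return cfg, cm, reads, truth


@pytest.fixture(scope="session")
def pipeline_cfg():
    return scdepth.PipelineConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_reference(default_scenario, pipeline_cfg):
    """Processed full-depth reference of the default scenario."""
    _, cm, _, _ = default_scenario
    return scdepth.cluster_pipeline(cm, pipeline_cfg)


@pytest.fixture(scope="session")
def reference_model(default_reference, pipeline_cfg):
    return bm.train_reference_classifier(
        default_reference.norm,
        default_reference.hvgs,
        default_reference.labels,
        n_trees=pipeline_cfg.rf_n_trees,
        seed=DEFAULT_SEED,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap 600-gene x 400-cell sample for unit tests."""
    cfg = scdepth.GeneratorConfig(n_genes=600, n_cells=400, seed=1)
    cm, reads, truth = scdepth.generate_dataset(cfg)
    return cfg, cm, reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
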