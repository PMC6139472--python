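"""Shared fixtures: compact synthetic cohorts sized for fast, exact checks.

Real-protocol dimensions (360 volumes, 16 nodes, 120 features) are kept
wherever a count is the point of the test; grids are shrunk to a few
thousand voxels so rendering stays cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fcmvpa.classify import CohortFeatureMatrix
from fcmvpa.connectivity import (
    NodeSignalSet,
    canonical_hrf,
    connectivity_features,
    lower_triangle_pairs,
    make_psych_factor,
    ppi_node_series,
)
from fcmvpa.nodes import extract_block
from fcmvpa.simulate import SimCohortConfig, iter_cohort

#: compact rendering grid used throughout the suite (fits 16 disjoint cubes)
SMALL_GRID = (24, 24, 15)


@pytest.fixture(scope="session")
def hrf_tr2():
    return canonical_hrf(2.0)


def small_config(**kwargs) -> SimCohortConfig:
    """Study-protocol config on a compact grid; overrides via kwargs."""
    defaults = dict(grid_shape=SMALL_GRID, noise_sd=0.1, seed=11)
    defaults.update(kwargs)
    return SimCohortConfig(**defaults)


def pipeline_features(config: SimCohortConfig) -> CohortFeatureMatrix:
    """Run the full chain (render -> extract -> PPI -> r features) for a cohort."""
    nodes = config.node_specs()
    hrf = canonical_hrf(config.tr_seconds)
    rows, labels = [], []
    feats = None
    for sub in iter_cohort(config):
        psych = make_psych_factor(sub.events, config.n_volumes, config.tr_seconds)
        signals = np.vstack(
            [
                ppi_node_series(
                    extract_block(sub.bold_run, nd, tr=config.tr_seconds), psych, hrf
                )
                for nd in nodes
            ]
        )
        feats = connectivity_features(
            NodeSignalSet(sub.subject_id, signals, tuple(n.name for n in nodes))
        )
        rows.append(feats.values)
        labels.append(sub.group_label)
    return CohortFeatureMatrix(
        X=np.vstack(rows),
        labels=np.array(labels),
        edge_pairs=feats.edge_pairs,
        edge_names=feats.edge_names,
    )


def random_feature_cohort(
    n_per_group: int = 10, n_nodes: int = 16, seed: int = 0
) -> CohortFeatureMatrix:
    """A label-free null cohort: i.i.d. Gaussian features, balanced groups."""
    rng = np.random.default_rng(seed)
    pairs = tuple(lower_triangle_pairs(n_nodes))
    F = len(pairs)
    return CohortFeatureMatrix(
        X=rng.normal(size=(2 * n_per_group, F)),
        labels=np.array(["CTRL"] * n_per_group + ["PP"] * n_per_group),
        edge_pairs=pairs,
        edge_names=tuple(f"e{i}~e{j}" for i, j in pairs),
    )


@pytest.fixture()
def events_default():
    cfg = SimCohortConfig(grid_shape=SMALL_GRID, seed=3)
    from fcmvpa.simulate import generate_events

    return generate_events(cfg)
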