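"""Shared fixtures.

The expensive end-to-end pipeline (cohort → contrastive pre-training →
graphs → three training seeds) runs once per session; every test that needs
a trained model reuses it.
"""

from __future__ import annotations

import numpy as np
import pytest

import patchgraph as pg
from patchgraph.contrastive import PretrainConfig
from patchgraph.pipeline import cohort_to_graphs, pretrain_on_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 12-slide cohort for cheap structural tests."""
    return pg.generate_cohort(n_per_class=4, grid_range=(6, 8), patch_size=64, seed=3)


@pytest.fixture(scope="session")
def tiny_extractor(tiny_cohort):
    """Briefly pre-trained tiny backbone (enough for feature plumbing tests)."""
    ext, losses = pretrain_on_cohort(
        tiny_cohort, PretrainConfig(steps=8, batch_size=8, seed=5), n_patches=48
    )
    return ext


@pytest.fixture(scope="session")
def tiny_graphs(tiny_cohort, tiny_extractor):
    graphs, labels, masks = cohort_to_graphs(tiny_cohort, tiny_extractor)
    return graphs, labels, masks


@pytest.fixture(scope="session")
def trained_pipeline():
    """Full study-scale pipeline: 120 slides, shared extractor, 3 GTP seeds.

    Returns a dict with the graphs, labels, lesion masks, per-seed held-out
    splits, trained models and held-out accuracies.
    """
    from sklearn.model_selection import train_test_split

    cohort = pg.generate_cohort(n_per_class=40, grid_range=(8, 12), patch_size=64, seed=11)
    extractor, _ = pretrain_on_cohort(
        cohort, PretrainConfig(steps=150, batch_size=32, seed=100), n_patches=512
    )
    graphs, labels, masks = cohort_to_graphs(cohort, extractor)
    idx = np.arange(len(graphs))
    runs = []
    for seed in (0, 1, 2):
        tr, te = train_test_split(idx, test_size=0.25, stratify=labels, random_state=seed)
        cfg = pg.GTPConfig.desk_scale(
            n_features=extractor.feature_dim, n_classes=3, n_steps=300, seed=seed
        )
        result = pg.train([graphs[i] for i in tr], labels[tr], cfg)
        report = pg.evaluate_model(result.model, [graphs[i] for i in te], labels[te])
        runs.append({"seed": seed, "model": result.model, "test_idx": te,
                     "report": report, "accuracy": report.accuracy})
    return {
        "cohort": cohort,
        "extractor": extractor,
        "graphs": graphs,
        "labels": labels,
        "masks": masks,
        "runs": runs,
    }


def permute_graph(graph: pg.WSIGraph, perm: np.ndarray) -> pg.WSIGraph:
    """Jointly permute node order of F, A and coords (same graph, new order)."""
    return pg.build_graph(
        graph.F[perm],
        [graph.coords[i] for i in perm],
        connectivity=graph.connectivity,
        label=graph.label,
        slide_id=graph.slide_id,
        patch_size=graph.patch_size,
        slide_shape=graph.slide_shape,
        stride=graph.stride,
    )
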