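"""End-to-end orchestration: slides → patch grids → features → graphs → model.

Thin glue over the stage modules so the CLI, the tests and downstream scripts
share one code path for the full pipeline.
"""

from __future__ import annotations

import numpy as np

from .contrastive import FeatureExtractor, PretrainConfig, extract_features, pretrain
from .graph_builder import WSIGraph, build_graph
from .synthetic import Cohort, generate_slide
from .tiling import PatchGrid, tile_and_filter

__all__ = ["sample_patch_pool", "pretrain_on_cohort", "cohort_to_graphs",
           "slide_to_graph", "standardize_features"]


def standardize_features(graphs, mu: np.ndarray | None = None,
                         sd: np.ndarray | None = None):
    """Z-score node features in place across a set of graphs.

    The backbone's pooled features are non-negative with a large common mean;
    centring and scaling them conditions the model's input projection.  Fit
    statistics on the training graphs and reuse them for held-out ones.
    Returns ``(mu, sd)``.
    """
    if mu is None or sd is None:
        F = np.vstack([g.F for g in graphs])
        mu = F.mean(axis=0)
        sd = F.std(axis=0) + 1e-8
    for g in graphs:
        g.F = (g.F - mu) / sd
    return mu, sd


def sample_patch_pool(cohort: Cohort, n_patches: int, seed: int = 0,
                      background_max: float = 0.5) -> list[np.ndarray]:
    """Uniformly sample tissue patches across a cohort for pre-training."""
    rng = np.random.default_rng(seed)
    pool: list[np.ndarray] = []
    specs = list(cohort.specs)
    order = rng.permutation(len(specs))
    per_slide = max(1, int(np.ceil(n_patches / len(specs))))
    for i in order:
        slide, _, _ = generate_slide(specs[i])
        grid = tile_and_filter(slide, specs[i].patch_size, background_max=background_max)
        take = rng.choice(len(grid), size=min(per_slide, len(grid)), replace=False)
        pool.extend(grid.patches[j] for j in take)
        if len(pool) >= n_patches:
            break
    return pool[:n_patches]


def pretrain_on_cohort(cohort: Cohort, config: PretrainConfig,
                       n_patches: int = 512) -> tuple[FeatureExtractor, list[float]]:
    pool = sample_patch_pool(cohort, n_patches, seed=config.seed)
    return pretrain(pool, config)


def slide_to_graph(slide, extractor: FeatureExtractor, patch_size: int,
                   label: int | None = None, connectivity: int = 8,
                   overlap_fraction: float = 0.0,
                   background_max: float = 0.5) -> tuple[WSIGraph, PatchGrid]:
    """Tile, filter, embed and graph one slide."""
    grid = tile_and_filter(slide, patch_size, overlap_fraction, background_max)
    F = extract_features(extractor, grid)
    graph = build_graph(
        F, grid.coords, connectivity=connectivity, label=label,
        slide_id=grid.slide_id, patch_size=patch_size,
        slide_shape=grid.slide_shape, stride=grid.stride,
    )
    return graph, grid


def cohort_to_graphs(cohort: Cohort, extractor: FeatureExtractor,
                     connectivity: int = 8, standardize: bool = True
                     ) -> tuple[list[WSIGraph], np.ndarray, list[np.ndarray]]:
    """Graphs, labels and ground-truth lesion masks for a synthetic cohort."""
    graphs, labels, masks = [], [], []
    for spec in cohort.specs:
        slide, mask, label = generate_slide(spec)
        graph, _ = slide_to_graph(slide, extractor, spec.patch_size,
                                  label=label, connectivity=connectivity)
        graphs.append(graph)
        labels.append(label)
        masks.append(mask)
    if standardize:
        standardize_features(graphs)
    return graphs, np.asarray(labels), masks
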