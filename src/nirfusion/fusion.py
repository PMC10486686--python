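"""Low-level and mid-level multiblock data fusion.

Low level: column-wise concatenation of pretreated blocks, block scaling
(each block to unit summed column variance), then mean centering.

Mid level: per-block PCA, concatenation of retained score columns,
autoscaling.  The per-block models and scaling statistics are stored so
new samples are fused with training statistics, and the contribution of
the original variables to the fused components can be reconstructed as
O = P^T F, where F column-wise concatenates the per-block loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pca import PCAModel, fit_pca, project
from .preprocess import autoscale, block_scale, block_weights, column_stats, mean_center

__all__ = [
    "FusedBlock",
    "ContributionMatrix",
    "low_level_fuse",
    "mid_level_fuse",
    "reconstruct_contributions",
]


@dataclass
class FusedBlock:
    """Concatenated features plus the fitted state needed to fuse new data.

    ``block_map`` lists, per fused column, ``(block_index, source_index)``
    where the source index is a variable index (low level) or a component
    index (mid level).
    """

    X_fused: np.ndarray
    block_map: list[tuple[int, int]]
    level: str                                     # "low" | "mid"
    weights: list[float] | None = None             # low level: block weights
    center: np.ndarray | None = None               # low level: fused column means
    pca_models: list[PCAModel] | None = None       # mid level
    scale_stats: tuple | None = None               # mid level: (means, sds) or None

    def transform(self, blocks: list[np.ndarray]) -> np.ndarray:
        """Fuse new samples using the stored training statistics only."""
        blocks = [np.atleast_2d(np.asarray(b, float)) for b in blocks]
        if self.level == "low":
            scaled = block_scale(blocks, weights=self.weights)
            return np.hstack(scaled) - self.center
        scores = [project(m, b) for m, b in zip(self.pca_models, blocks)]
        fused = np.hstack(scores)
        if self.scale_stats is not None:
            fused = autoscale(fused, fitted_stats=self.scale_stats)
        return fused


def _check_rows(blocks: list[np.ndarray]) -> None:
    rows = {i: b.shape[0] for i, b in enumerate(blocks)}
    if len(set(rows.values())) > 1:
        raise ValueError(f"blocks have mismatched row counts: {rows}")


def low_level_fuse(blocks: list[np.ndarray]) -> FusedBlock:
    """Concatenate -> block-scale -> mean-center."""
    blocks = [np.asarray(b, float) for b in blocks]
    _check_rows(blocks)
    weights = block_weights(blocks)
    scaled = block_scale(blocks, weights=weights)
    fused = np.hstack(scaled)
    center = fused.mean(axis=0)
    block_map = [
        (k, j) for k, b in enumerate(blocks) for j in range(b.shape[1])
    ]
    return FusedBlock(
        X_fused=fused - center, block_map=block_map, level="low",
        weights=weights, center=center,
    )


def mid_level_fuse(
    blocks: list[np.ndarray],
    n_scores: tuple[int, ...] = (5, 5),
    scale: bool = True,
) -> FusedBlock:
    """Per-block PCA -> concatenate retained scores -> autoscale."""
    blocks = [np.asarray(b, float) for b in blocks]
    _check_rows(blocks)
    if len(n_scores) != len(blocks):
        raise ValueError("one score count per block required")
    models, parts, block_map = [], [], []
    for k, (b, a) in enumerate(zip(blocks, n_scores)):
        model = fit_pca(b, n_components=a, center=True, scale=False)
        models.append(model)
        parts.append(model.T)
        block_map.extend((k, j) for j in range(a))
    fused = np.hstack(parts)
    stats = None
    if scale:
        stats = column_stats(fused)
        fused = autoscale(fused, fitted_stats=stats)
    return FusedBlock(
        X_fused=fused, block_map=block_map, level="mid",
        pca_models=models, scale_stats=stats,
    )


@dataclass
class ContributionMatrix:
    """O = P^T F: fused components x original variables."""

    O: np.ndarray
    variable_blocks: list[int]     # source block index per original variable


def reconstruct_contributions(
    fused_model: PCAModel,
    block_loadings: list[np.ndarray],
    fused_scales: np.ndarray | None = None,
) -> ContributionMatrix:
    """Map fused-space loadings back onto the original variables.

    F is block-structured: fused feature i (score j of block k) maps to
    block k's loading vector j, zero elsewhere; when the fused columns
    were autoscaled, each row of F is divided by that column's sd so
    T_fused @ O back-projects the variables that actually entered the
    fused PCA.
    """
    block_loadings = [np.asarray(P, float) for P in block_loadings]
    n_feat = sum(P.shape[1] for P in block_loadings)
    if fused_model.P.shape[0] != n_feat:
        raise ValueError(
            f"fused model has {fused_model.P.shape[0]} features but block "
            f"loadings provide {n_feat}"
        )
    n_vars = sum(P.shape[0] for P in block_loadings)
    F = np.zeros((n_feat, n_vars))
    variable_blocks = []
    row = 0
    col = 0
    for k, P in enumerate(block_loadings):
        p_k, a_k = P.shape
        F[row:row + a_k, col:col + p_k] = P.T
        variable_blocks.extend([k] * p_k)
        row += a_k
        col += p_k
    if fused_scales is not None:
        F = F / np.asarray(fused_scales, float)[:, None]
    return ContributionMatrix(O=fused_model.P.T @ F, variable_blocks=variable_blocks)
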