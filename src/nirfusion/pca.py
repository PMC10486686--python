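"""Principal component analysis via singular value decomposition.

Used for exploration, feature extraction for mid-level fusion, and
per-group confidence-ellipse summaries of score plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "EllipseSummary", "fit_pca", "project", "ellipse_summary"]


@dataclass
class PCAModel:
    center: np.ndarray            # column means used for centering
    scale: np.ndarray | None      # column sds if scaled, else None
    P: np.ndarray                 # loadings, variables x components, orthonormal
    T: np.ndarray                 # training scores, observations x components
    eigenvalues: np.ndarray       # per-component variance (ddof=1 convention)
    explained: np.ndarray         # fraction of total variance per component

    @property
    def n_components(self) -> int:
        return self.P.shape[1]

    def reconstruct(self) -> np.ndarray:
        """T @ P.T on the preprocessed scale (residual E excluded)."""
        return self.T @ self.P.T


def fit_pca(
    X: np.ndarray, n_components: int, center: bool = True, scale: bool = False
) -> PCAModel:
    """Fit PCA by SVD of the (optionally centered/scaled) matrix.

    Components are ordered by decreasing eigenvalue; the sign convention
    (largest-magnitude loading element positive) makes repeated fits on
    identical data bit-identical.  Eigenvalues use the n-1 denominator.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")

    mu = X.mean(axis=0) if center else np.zeros(p)
    Xp = X - mu
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column: cannot scale")
        Xp = Xp / sd

    U, s, Vt = np.linalg.svd(Xp, full_matrices=False)
    eig_all = s**2 / (n - 1)
    total = eig_all.sum()

    P = Vt[:n_components].T.copy()
    T = Xp @ P
    # deterministic sign: largest-|loading| element positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(P[:, k]))
        if P[j, k] < 0:
            P[:, k] = -P[:, k]
            T[:, k] = -T[:, k]

    eig = eig_all[:n_components]
    return PCAModel(
        center=mu, scale=sd, P=P, T=T,
        eigenvalues=eig, explained=eig / total,
    )


def project(model: PCAModel, X_new: np.ndarray) -> np.ndarray:
    """Score new observations with the model's stored statistics."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.P.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.P.shape[0]}"
        )
    Xp = X_new - model.center
    if model.scale is not None:
        Xp = Xp / model.scale
    return Xp @ model.P


@dataclass
class EllipseSummary:
    """Per-group 1-sd axis-aligned ellipses on a pair of score axes."""

    axes: tuple[int, int]
    groups: list[str]
    centers: np.ndarray            # (n_groups, 2) mean scores
    radii: np.ndarray              # (n_groups, 2) sample sds


def ellipse_summary(
    scores: np.ndarray, labels: np.ndarray, axes: tuple[int, int] = (0, 1)
) -> EllipseSummary:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    i, j = axes
    groups = list(dict.fromkeys(labels.tolist()))
    centers, radii = [], []
    for g in groups:
        sel = scores[labels == g][:, [i, j]]
        if sel.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        centers.append(sel.mean(axis=0))
        radii.append(sel.std(axis=0, ddof=1))
    return EllipseSummary(
        axes=(i, j), groups=groups,
        centers=np.array(centers), radii=np.array(radii),
    )
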