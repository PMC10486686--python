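"""Spectral and tabular pretreatments.

Row-wise operators (SNV, MSC, Savitzky-Golay filtering, range trimming,
replicate averaging) act on :class:`~nirfusion.synth.SpectraBlock`;
column-wise operators (mean centering, autoscaling, block scaling) act on
plain matrices.  :class:`PreprocessPipeline` chains steps and retains
fitted statistics so test data are always treated with training-set
statistics.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.signal import savgol_filter

from .synth import SpectraBlock

__all__ = [
    "trim_range",
    "snv",
    "msc",
    "savgol",
    "average_replicates",
    "mean_center",
    "autoscale",
    "column_means",
    "column_stats",
    "block_weights",
    "block_scale",
    "PreprocessPipeline",
]


def trim_range(block: SpectraBlock, high: float, low: float) -> SpectraBlock:
    """Keep columns with low <= wavenumber <= high, order preserved."""
    if high <= low:
        raise ValueError(f"high ({high}) must exceed low ({low})")
    keep = (block.grid >= low) & (block.grid <= high)
    if not keep.any():
        raise ValueError(
            f"no grid points in [{low}, {high}]; grid spans "
            f"[{block.grid.min()}, {block.grid.max()}]"
        )
    return replace(block, grid=block.grid[keep], X=block.X[:, keep])


def snv(block: SpectraBlock) -> SpectraBlock:
    """Standard Normal Variate: each row to mean 0, sample sd 1 (ddof=1)."""
    mu = block.X.mean(axis=1, keepdims=True)
    sd = block.X.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd[:, 0] == 0)[0]
    if zero.size:
        raise ValueError(f"constant spectrum at row {zero[0]}: SNV undefined")
    return replace(block, X=(block.X - mu) / sd)


def msc(
    block: SpectraBlock, reference: np.ndarray | None = None
) -> tuple[SpectraBlock, np.ndarray]:
    """Multiplicative Scatter Correction against ``reference``.

    Each row x is replaced by (x - a) / b with (a, b) the least-squares
    intercept/slope of x on the reference.  The reference defaults to the
    column-wise mean of ``block`` and is returned so test data can be
    corrected with the training reference.
    """
    ref = block.X.mean(axis=0) if reference is None else np.asarray(reference, float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference is constant")
    Xc = block.X - block.X.mean(axis=1, keepdims=True)
    b = (Xc @ ref_c) / denom
    if np.any(b == 0):
        raise ValueError("degenerate spectrum: zero MSC slope")
    a = block.X.mean(axis=1) - b * ref.mean()
    out = (block.X - a[:, None]) / b[:, None]
    return replace(block, X=out), ref


def savgol(block: SpectraBlock, window: int, polyorder: int, deriv: int = 0) -> SpectraBlock:
    """Savitzky-Golay filtering/differentiation along the wavenumber axis.

    Derivatives are taken with respect to wavenumber (per cm-1), so a
    descending grid flips the sign of odd derivatives.  Edges are handled
    by polynomial extrapolation within the end windows.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")
    steps = np.diff(block.grid)
    step = steps[0]
    if np.max(np.abs(steps - step)) > 1e-6 * np.abs(step):
        raise ValueError("grid spacing must be uniform for Savitzky-Golay filtering")
    out = savgol_filter(
        block.X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=abs(step), axis=1, mode="interp",
    )
    if step < 0 and deriv % 2 == 1:
        out = -out
    return replace(block, X=out)


def average_replicates(block: SpectraBlock) -> SpectraBlock:
    """Collapse the 1-2 replicate rows of each fruit to their mean.

    Fruit order follows first appearance in the block.
    """
    ids, first = np.unique(block.sample_id, return_index=True)
    order = np.argsort(first)
    ids = ids[order]
    rows, cults = [], []
    for sid in ids:
        idx = np.where(block.sample_id == sid)[0]
        if idx.size > 2:
            raise ValueError(f"fruit {sid!r} has {idx.size} replicates (max 2)")
        rows.append(block.X[idx].mean(axis=0))
        cults.append(block.cultivar[idx[0]])
    return SpectraBlock(
        grid=block.grid.copy(),
        X=np.vstack(rows),
        sample_id=ids,
        cultivar=np.array(cults),
        replicate=np.ones(len(ids), int),
    )


def column_means(X: np.ndarray) -> np.ndarray:
    return np.asarray(X, float).mean(axis=0)


def column_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(means, sample sds) per column; raises on zero-variance columns."""
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance column {zero[0]}: autoscaling undefined")
    return mu, sd


def mean_center(X: np.ndarray, fitted_means: np.ndarray | None = None) -> np.ndarray:
    X = np.asarray(X, float)
    mu = column_means(X) if fitted_means is None else np.asarray(fitted_means, float)
    return X - mu


def autoscale(
    X: np.ndarray, fitted_stats: tuple[np.ndarray, np.ndarray] | None = None
) -> np.ndarray:
    X = np.asarray(X, float)
    mu, sd = column_stats(X) if fitted_stats is None else fitted_stats
    return (X - mu) / sd


def block_weights(blocks: list[np.ndarray]) -> list[float]:
    """1/sqrt(sum of column sample variances) per block."""
    w = []
    for i, b in enumerate(blocks):
        tv = np.asarray(b, float).var(axis=0, ddof=1).sum()
        if tv == 0:
            raise ValueError(f"block {i} has zero total variance")
        w.append(1.0 / np.sqrt(tv))
    return w


def block_scale(
    blocks: list[np.ndarray], weights: list[float] | None = None
) -> list[np.ndarray]:
    """Scale each block so its summed column variance is 1; within-block
    variance ratios are preserved (scalar multiplication)."""
    if weights is None:
        weights = block_weights(blocks)
    return [np.asarray(b, float) * w for b, w in zip(blocks, weights)]


class PreprocessPipeline:
    """An ordered chain of pretreatments with train-fitted statistics.

    Supported steps: ``("trim", {"high", "low"})``, ``("snv", {})``,
    ``("msc", {})``, ``("savgol", {"window", "polyorder", "deriv"})``,
    ``("mean_center", {})``, ``("autoscale", {})``.

    ``fit_transform`` fits statistics (MSC reference, column means/sds) on
    the training block; ``transform`` reuses them, never recomputing from
    the new data.
    """

    _ROW_WISE = {"trim", "snv", "savgol"}

    def __init__(self, steps: list[tuple[str, dict]]):
        self.steps = [(name, dict(params)) for name, params in steps]
        self.fitted_: dict[int, object] = {}
        self._is_fitted = False

    @classmethod
    def default_nir(cls, window: int = 9) -> "PreprocessPipeline":
        """Trim to 4000-9000 cm-1, first derivative (2nd-order polynomial),
        mean centering — the default chain for spectra."""
        return cls([
            ("trim", {"high": 9000.0, "low": 4000.0}),
            ("savgol", {"window": window, "polyorder": 2, "deriv": 1}),
            ("mean_center", {}),
        ])

    def _apply(self, block: SpectraBlock, fit: bool) -> SpectraBlock:
        for i, (name, params) in enumerate(self.steps):
            if name == "trim":
                block = trim_range(block, **params)
            elif name == "snv":
                block = snv(block)
            elif name == "savgol":
                block = savgol(block, **params)
            elif name == "msc":
                if fit:
                    block, ref = msc(block)
                    self.fitted_[i] = ref
                else:
                    block, _ = msc(block, reference=self.fitted_[i])
            elif name == "mean_center":
                if fit:
                    self.fitted_[i] = column_means(block.X)
                block = replace(block, X=mean_center(block.X, self.fitted_[i]))
            elif name == "autoscale":
                if fit:
                    self.fitted_[i] = column_stats(block.X)
                block = replace(block, X=autoscale(block.X, self.fitted_[i]))
            else:
                raise ValueError(f"unknown preprocessing step {name!r}")
        return block

    def fit_transform(self, block: SpectraBlock) -> SpectraBlock:
        self.fitted_ = {}
        out = self._apply(block, fit=True)
        self._is_fitted = True
        return out

    def transform(self, block: SpectraBlock) -> SpectraBlock:
        if not self._is_fitted and any(
            name not in self._ROW_WISE for name, _ in self.steps
        ):
            raise RuntimeError("pipeline has fitted steps; call fit_transform first")
        return self._apply(block, fit=False)

    def to_dict(self) -> dict:
        return {"steps": [[name, params] for name, params in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessPipeline":
        return cls([(name, params) for name, params in d["steps"]])
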