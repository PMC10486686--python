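"""Duplex train/test partitioning, venetian-blinds folds and latent-variable selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplitAssignment", "FoldPlan", "duplex_split", "venetian_blinds", "select_lvs"]


@dataclass
class SplitAssignment:
    train_ids: np.ndarray     # row indices
    test_ids: np.ndarray

    def __post_init__(self):
        self.train_ids = np.asarray(self.train_ids, int)
        self.test_ids = np.asarray(self.test_ids, int)
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValueError("train and test sets overlap")


def duplex_split(X: np.ndarray, n_test: int, scale: bool = True) -> SplitAssignment:
    """Classic duplex partition on Euclidean distance.

    The two most mutually distant points seed the training set, the next
    most distant remaining pair seeds the test set, and pairs keep
    alternating (train, test, train, ...) until the test set holds
    ``n_test`` points; everything left goes to training.  Distances are
    computed on autoscaled variables by default (constant columns are
    left unscaled).  Deterministic; distance ties break toward the lowest
    row-index pair.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if not 0 <= n_test <= n - 2:
        raise ValueError(f"n_test must be in [0, {n - 2}], got {n_test}")
    if n_test == 0:
        return SplitAssignment(np.arange(n), np.array([], int))

    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
    else:
        Xs = X

    sq = (Xs**2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2 * Xs @ Xs.T
    np.fill_diagonal(D, -np.inf)
    D[np.tril_indices(n)] = -np.inf    # i < j only; argmax ties -> lowest (i, j)

    remaining = np.ones(n, bool)
    train: list[int] = []
    test: list[int] = []
    n_train_target = n - n_test
    to_train = True
    while len(test) < n_test and remaining.any():
        sub = np.where(remaining)[0]
        if sub.size == 1:
            test.append(int(sub[0]))
            remaining[sub[0]] = False
            break
        Dsub = D[np.ix_(sub, sub)]
        i, j = np.unravel_index(np.argmax(Dsub), Dsub.shape)
        a, b = int(sub[i]), int(sub[j])
        if to_train and len(train) < n_train_target:
            # a side one short of its target takes the lower-index point only
            if n_train_target - len(train) == 1:
                train.append(a)
                remaining[a] = False
            else:
                train.extend([a, b])
                remaining[[a, b]] = False
        else:
            if n_test - len(test) == 1:
                test.append(a)
                remaining[a] = False
            else:
                test.extend([a, b])
                remaining[[a, b]] = False
        to_train = not to_train
    train.extend(np.where(remaining)[0].tolist())
    return SplitAssignment(np.array(sorted(train)), np.array(sorted(test)))


@dataclass
class FoldPlan:
    n_segments: int
    fold: np.ndarray          # fold index per sample, dataset order

    def indices(self, k: int) -> np.ndarray:
        return np.where(self.fold == k)[0]


def venetian_blinds(n: int, segments: int) -> FoldPlan:
    """Sample at position i (0-based) goes to fold ``i mod segments``."""
    if not 2 <= segments <= n:
        raise ValueError(f"segments must be in [2, {n}], got {segments}")
    return FoldPlan(n_segments=segments, fold=np.arange(n) % segments)


def select_lvs(
    cv_errors: np.ndarray,
    cv_se: np.ndarray | None = None,
    lv_counts: np.ndarray | None = None,
) -> int:
    """1-SE parsimony rule: the smallest latent-variable count whose CV
    error is within one standard error of the minimum."""
    cv_errors = np.asarray(cv_errors, float)
    if cv_errors.size == 0:
        raise ValueError("cv_errors must be non-empty")
    if lv_counts is None:
        lv_counts = np.arange(1, cv_errors.size + 1)
    se = np.zeros_like(cv_errors) if cv_se is None else np.asarray(cv_se, float)
    best = int(np.argmin(cv_errors))
    threshold = cv_errors[best] + se[best]
    chosen = int(np.argmax(cv_errors <= threshold))
    return int(lv_counts[chosen])
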