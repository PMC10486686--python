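"""PLS-DA classification.

PLS1 on a 1/0 dummy response for the binary cultivar-group models, a
PLS2 multiclass variant, ROC analysis, CV-based threshold choice, and
the end-to-end ``run_mode`` pipeline (replicate averaging, complete-case
join, train-fitted preprocessing, optional mid-level fusion, duplex
split, venetian-blinds cross-validation, latent-variable selection).

The PLS core is an iterative-deflation (NIPALS-style) implementation;
at full rank its predictions coincide with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .fusion import mid_level_fuse
from .model_selection import duplex_split, select_lvs, venetian_blinds
from .preprocess import (
    PreprocessPipeline,
    autoscale,
    average_replicates,
    column_stats,
)
from .synth import LabPanel, SpectraBlock

__all__ = [
    "ModeSpec",
    "MODES",
    "PLSDAModel",
    "MulticlassPLSDAModel",
    "Metrics",
    "ClassificationReport",
    "ModeRunConfig",
    "fit_plsda",
    "predict_scores",
    "roc_curve",
    "choose_threshold",
    "evaluate",
    "run_mode",
    "fit_multiclass",
]


# ---------------------------------------------------------------------------
# mode definitions

@dataclass(frozen=True)
class ModeSpec:
    """A binary cultivar grouping; the positive class is coded 1."""

    name: str
    positive: frozenset
    negative: frozenset

    def __post_init__(self):
        if not self.positive or not self.negative:
            raise ValueError("both class sets must be non-empty")
        if self.positive & self.negative:
            raise ValueError("class sets must be disjoint")

    def code(self, cultivars: np.ndarray) -> np.ndarray:
        """1/0 coding; raises on cultivars in neither set."""
        cultivars = np.asarray(cultivars)
        y = np.full(len(cultivars), -1, int)
        for i, c in enumerate(cultivars):
            if c in self.positive:
                y[i] = 1
            elif c in self.negative:
                y[i] = 0
        if (y < 0).any():
            bad = cultivars[y < 0][0]
            raise ValueError(f"cultivar {bad!r} belongs to neither class of {self.name}")
        return y


#: The three binary groupings; the positive class is the larger cultivar
#: group for mode2/mode3 (one-vs-rest with "rest" positive).
MODES = {
    "mode1": ModeSpec("MODE1", frozenset({"Romina", "Sibilla"}),
                      frozenset({"Silvia", "Cristina"})),
    "mode2": ModeSpec("MODE2", frozenset({"Romina", "Sibilla", "Cristina"}),
                      frozenset({"Silvia"})),
    "mode3": ModeSpec("MODE3", frozenset({"Romina", "Sibilla", "Silvia"}),
                      frozenset({"Cristina"})),
}


# ---------------------------------------------------------------------------
# PLS core

def _pls1_decompose(X: np.ndarray, y: np.ndarray, n_lv: int):
    """NIPALS-style PLS1 with X-deflation.

    Returns (W, P, q) with one column/entry per latent variable, computed
    on already-centered X and y.
    """
    Xc = X.copy()
    yc = y.copy()
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise ValueError(f"X carries no covariance with y at LV {a + 1}")
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < 1e-14:
            raise ValueError(f"degenerate score vector at LV {a + 1}")
        p_a = Xc.T @ t / tt
        q_a = yc @ t / tt
        Xc -= np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
    return W, P, q


def _pls1_coef(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector using the first k latent variables."""
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


@dataclass
class PLSDAModel:
    mode: ModeSpec
    n_lv: int
    weights: np.ndarray            # x-weights W, variables x LVs
    x_loadings: np.ndarray         # P
    y_loadings: np.ndarray         # q per LV
    coef: np.ndarray               # regression vector for n_lv LVs
    x_mean: np.ndarray
    y_mean: float
    threshold: float = 0.5

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict_scores(self, X_new)

    def predict_class(self, X_new: np.ndarray) -> np.ndarray:
        return (self.predict(X_new) >= self.threshold).astype(int)


def fit_plsda(
    X: np.ndarray, labels: np.ndarray, mode: ModeSpec, n_lv: int
) -> PLSDAModel:
    """Fit a 1/0-dummy PLS1 model on mean-centered X."""
    X = np.asarray(X, float)
    y = mode.code(labels).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training labels")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds rank {rank} of the centered matrix")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    W, P, q = _pls1_decompose(X - x_mean, y - y_mean, n_lv)
    return PLSDAModel(
        mode=mode, n_lv=n_lv, weights=W, x_loadings=P, y_loadings=q,
        coef=_pls1_coef(W, P, q, n_lv), x_mean=x_mean, y_mean=y_mean,
    )


def predict_scores(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous dummy-response predictions from stored statistics."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.coef.shape[0]}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


# ---------------------------------------------------------------------------
# evaluation

def roc_curve(y_true: np.ndarray, y_score: np.ndarray):
    """ROC points at every distinct threshold plus trapezoidal AUC.

    Ties are grouped (equal scores move TPR/FPR together).  Returns
    ``(fpr, tpr, thresholds, auc)`` with rates on the 0-1 scale.
    """
    y_true = np.asarray(y_true, int)
    y_score = np.asarray(y_score, float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in y_true")
    order = np.argsort(-y_score, kind="stable")
    ys, ss = y_true[order], y_score[order]
    distinct = np.where(np.diff(ss))[0]          # last index of each tie group
    idx = np.r_[distinct, len(ss) - 1]
    tp = np.cumsum(ys == 1)[idx]
    fp = np.cumsum(ys == 0)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, ss[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def choose_threshold(cv_y_true: np.ndarray, cv_y_score: np.ndarray) -> float:
    """Threshold minimizing CV misclassification error.

    Candidates are midpoints between consecutive distinct scores plus
    sentinels outside the score range; among tied minima the midpoint of
    the first contiguous tied interval is returned.
    """
    y = np.asarray(cv_y_true, int)
    s = np.asarray(cv_y_score, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to choose a threshold")
    u = np.unique(s)
    candidates = np.r_[u[0] - 1.0, (u[:-1] + u[1:]) / 2.0, u[-1] + 1.0]
    errors = np.array([np.mean((s >= t).astype(int) != y) for t in candidates])
    best = errors.min()
    tied = np.where(errors == best)[0]
    start = tied[0]
    end = start
    while end + 1 in tied:
        end += 1
    return float((candidates[start] + candidates[end]) / 2.0)


@dataclass
class Metrics:
    """Binary classification metrics, rates in percent."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    @property
    def tpr(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def tnr(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return 100.0 - self.tnr

    @property
    def error(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.fp + self.fn) / n

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": self.tpr, "tnr": self.tnr, "fpr": self.fpr,
            "error": self.error, "auc": self.auc,
        }


def evaluate(y_true: np.ndarray, y_pred_class: np.ndarray) -> Metrics:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred_class, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred_class must have equal length")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class ModeRunConfig:
    n_test: int = 60
    cv_segments: int = 5
    lv_grid: tuple[int, ...] = tuple(range(1, 11))
    preprocess: PreprocessPipeline | None = None    # default: trim+savgol+center
    n_scores: tuple[int, int] = (5, 5)              # mid-level: (lab, nir)
    threshold: str | float = "roc"                  # "roc", or a fixed number
    shuffle_seed: int | None = None


@dataclass
class ClassificationReport:
    mode: str
    feature_set: str
    n_lv: int
    threshold: float
    positive_class: tuple
    cv: Metrics
    test: Metrics
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "feature_set": self.feature_set,
            "n_lv": self.n_lv, "threshold": self.threshold,
            "positive_class": list(self.positive_class),
            "n_train": self.n_train, "n_test": self.n_test,
            "cv": self.cv.to_dict(), "test": self.test.to_dict(),
        }


class _FeatureBuilder:
    """Train-fitted feature construction for one split.

    The row-wise spectral steps (trim, derivative, SNV) are stateless and
    already applied upstream; only fitted statistics (centering, lab
    autoscale, per-block PCA, fused autoscale) are computed here, on the
    training rows alone.
    """

    def __init__(self, feature_set: str, n_scores: tuple[int, int]):
        if feature_set not in ("nir_only", "fused"):
            raise ValueError(f"unknown feature_set {feature_set!r}")
        self.feature_set = feature_set
        self.n_scores = n_scores

    def fit(self, D_train: np.ndarray, lab_train: np.ndarray):
        self.nir_mean_ = D_train.mean(axis=0)
        if self.feature_set == "fused":
            self.lab_stats_ = column_stats(lab_train)
            lab_s = autoscale(lab_train, fitted_stats=self.lab_stats_)
            nir_c = D_train - self.nir_mean_
            self.fused_ = mid_level_fuse(
                [lab_s, nir_c], n_scores=self.n_scores, scale=True
            )
        return self

    def train_matrix(self) -> np.ndarray:
        if self.feature_set == "fused":
            return self.fused_.X_fused
        return None  # nir handled via transform for symmetry

    def transform(self, D: np.ndarray, lab: np.ndarray) -> np.ndarray:
        nir_c = D - self.nir_mean_
        if self.feature_set == "nir_only":
            return nir_c
        lab_s = autoscale(lab, fitted_stats=self.lab_stats_)
        return self.fused_.transform([lab_s, nir_c])


def _cv_predictions(
    D: np.ndarray, lab: np.ndarray, y: np.ndarray, config: ModeRunConfig
):
    """Venetian-blinds CV over the LV grid.

    Returns (cv_scores[lv_index][sample], fold_errors[lv_index][fold]).
    """
    n = len(y)
    plan = venetian_blinds(n, config.cv_segments)
    order = np.arange(n)
    if config.shuffle_seed is not None:
        order = np.random.default_rng(config.shuffle_seed).permutation(n)
    max_lv = max(config.lv_grid)
    n_lv_grid = len(config.lv_grid)
    scores = np.full((n_lv_grid, n), np.nan)
    fold_errors = np.zeros((n_lv_grid, plan.n_segments))
    for k in range(plan.n_segments):
        val = order[plan.indices(k)]
        trn = np.setdiff1d(order, val)
        if len(np.unique(y[trn])) < 2:
            raise ValueError(f"fold {k} training data contains a single class")
        fb = _FeatureBuilder(config._feature_set, config.n_scores)
        fb.fit(D[trn], lab[trn])
        Xtr = fb.transform(D[trn], lab[trn])
        Xva = fb.transform(D[val], lab[val])
        rank = min(Xtr.shape) - 1
        lv_cap = min(max_lv, rank)
        x_mean = Xtr.mean(axis=0)
        y_mean = y[trn].mean()
        W, P, q = _pls1_decompose(Xtr - x_mean, y[trn] - y_mean, lv_cap)
        for li, lv in enumerate(config.lv_grid):
            k_lv = min(lv, lv_cap)
            coef = _pls1_coef(W, P, q, k_lv)
            pred = (Xva - x_mean) @ coef + y_mean
            scores[li, val] = pred
            fold_errors[li, k] = np.mean((pred >= 0.5).astype(int) != y[val])
    return scores, fold_errors


def _classify_split(
    D_train, lab_train, y_train, D_test, lab_test, y_test,
    mode: ModeSpec, feature_set: str, config: ModeRunConfig,
) -> ClassificationReport:
    """CV-select LVs and threshold on training data, refit, evaluate."""
    config._feature_set = feature_set
    cv_scores, fold_errors = _cv_predictions(D_train, lab_train, y_train, config)
    cv_err = fold_errors.mean(axis=1)
    cv_se = fold_errors.std(axis=1, ddof=1) / np.sqrt(fold_errors.shape[1])
    n_lv = select_lvs(cv_err, cv_se=cv_se, lv_counts=np.asarray(config.lv_grid))
    li = list(config.lv_grid).index(n_lv)
    cv_s = cv_scores[li]

    if config.threshold == "roc":
        thr = choose_threshold(y_train, cv_s)
    else:
        thr = float(config.threshold)

    fb = _FeatureBuilder(feature_set, config.n_scores).fit(D_train, lab_train)
    Xtr = fb.transform(D_train, lab_train)
    Xte = fb.transform(D_test, lab_test)
    n_lv_fit = min(n_lv, min(Xtr.shape) - 1)
    x_mean = Xtr.mean(axis=0)
    y_mean = y_train.mean()
    W, P, q = _pls1_decompose(Xtr - x_mean, y_train - y_mean, n_lv_fit)
    coef = _pls1_coef(W, P, q, n_lv_fit)
    test_s = (Xte - x_mean) @ coef + y_mean

    cv_metrics = evaluate(y_train, (cv_s >= thr).astype(int))
    *_, cv_auc = roc_curve(y_train, cv_s)
    cv_metrics.auc = cv_auc
    test_metrics = evaluate(y_test, (test_s >= thr).astype(int))
    if len(np.unique(y_test)) == 2:
        *_, test_auc = roc_curve(y_test, test_s)
        test_metrics.auc = test_auc
    return ClassificationReport(
        mode=mode.name, feature_set=feature_set, n_lv=n_lv_fit, threshold=thr,
        positive_class=tuple(sorted(mode.positive)),
        cv=cv_metrics, test=test_metrics,
        n_train=len(y_train), n_test=len(y_test),
    )


def run_mode(
    spectra: SpectraBlock,
    panel: LabPanel,
    mode: ModeSpec,
    feature_set: str = "nir_only",
    config: ModeRunConfig | None = None,
) -> ClassificationReport:
    """End-to-end binary classification for one cultivar grouping.

    Stages: average NIR replicates -> complete-case join with the lab
    panel -> stateless spectral pretreatment (trim + derivative) ->
    duplex split on the pretreated spectra -> venetian-blinds CV over the
    LV grid (all fitted statistics recomputed per fold) -> 1-SE LV choice
    -> threshold from CV predictions -> refit on the training set ->
    external-test evaluation.
    """
    from .io import join_blocks  # local import to avoid a cycle

    config = config or ModeRunConfig()
    try:
        averaged = average_replicates(spectra)
        joined_spectra, joined_panel = join_blocks(averaged, panel, complete_case=True)
    except Exception as e:
        raise RuntimeError(f"run_mode [join stage]: {e}") from e
    if joined_panel.n_fruits < 20:
        raise ValueError(
            f"only {joined_panel.n_fruits} complete-case samples; need >= 20"
        )

    pipe = config.preprocess or PreprocessPipeline.default_nir()
    stateless = PreprocessPipeline(
        [s for s in pipe.steps if s[0] in PreprocessPipeline._ROW_WISE]
    )
    try:
        D = stateless.transform(joined_spectra).X
    except Exception as e:
        raise RuntimeError(f"run_mode [preprocess stage]: {e}") from e
    lab = joined_panel.values
    y = mode.code(joined_panel.cultivar)
    if len(np.unique(y)) < 2:
        raise ValueError(f"both classes of {mode.name} must be present")

    try:
        split = duplex_split(D, n_test=min(config.n_test, len(y) - 2))
    except Exception as e:
        raise RuntimeError(f"run_mode [split stage]: {e}") from e
    tr, te = split.train_ids, split.test_ids
    try:
        return _classify_split(
            D[tr], lab[tr], y[tr], D[te], lab[te], y[te],
            mode, feature_set, config,
        )
    except Exception as e:
        raise RuntimeError(f"run_mode [classification stage]: {e}") from e


# ---------------------------------------------------------------------------
# multiclass

@dataclass
class MulticlassPLSDAModel:
    classes: np.ndarray
    n_lv: int
    coef: np.ndarray               # variables x classes
    x_mean: np.ndarray
    y_mean: np.ndarray

    def predict_dummy(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, float))
        return (X_new - self.x_mean) @ self.coef + self.y_mean

    def predict_class(self, X_new: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_dummy(X_new), axis=1)]


def _pls2_decompose(X: np.ndarray, Y: np.ndarray, n_lv: int, max_iter=500, tol=1e-12):
    """NIPALS PLS2 with X- and Y-deflation on centered matrices."""
    Xc, Yc = X.copy(), Y.copy()
    p, m = X.shape[1], Y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    for a in range(n_lv):
        u = Yc[:, np.argmax(Yc.var(axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xc.T @ u
            w /= np.linalg.norm(w)
            t = Xc @ w
            q = Yc.T @ t / (t @ t)
            u = Yc @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        p_a = Xc.T @ t / tt
        Xc -= np.outer(t, p_a)
        Yc -= np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p_a, q
    return W, P, Q


def fit_multiclass(
    X: np.ndarray, labels: np.ndarray, n_lv: int | None = None
) -> MulticlassPLSDAModel:
    """PLS2 on a one-column-per-class dummy matrix; predicted class is the
    argmax of the predicted dummy columns."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("at least two classes required")
    Y = (labels[:, None] == classes[None, :]).astype(float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_lv is None:
        n_lv = min(10, rank)
    if not 1 <= n_lv <= rank:
        raise ValueError(f"n_lv must be in [1, {rank}], got {n_lv}")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, P, Q = _pls2_decompose(X - x_mean, Y - y_mean, n_lv)
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return MulticlassPLSDAModel(
        classes=classes, n_lv=n_lv, coef=coef, x_mean=x_mean, y_mean=y_mean
    )
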