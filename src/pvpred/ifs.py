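"""Incremental feature selection (IFS) with a cross-validated RBF-SVM.

Given features in ranked column order, IFS evaluates the nested prefixes
of sizes k = 1, 2, ..., each with a soft-margin SVM (RBF kernel) under
stratified k-fold cross-validation, and reports the accuracy curve plus
the smallest prefix size attaining the maximum. All prefixes up to the
requested maximum are evaluated rather than stopping at the first
accuracy decrease, which would halt at local plateaus.

Cross-validation metrics are *pooled*: out-of-fold predictions from all
folds form one confusion matrix and one ROC, matching the single
Sn/Sp/Acc/Mcc set reported per model. Fold assignment is a deterministic
function of (labels, n_folds, seed), so identical inputs and seeds give
bit-identical curves.

(C, gamma) are tuned by exhaustive grid search; defaults follow the libsvm
practice of log2-spaced grids C in 2^-5..2^15, gamma in 2^-15..2^3. Grid
ties resolve toward smaller C, then smaller gamma (the least complex
model). Tuning can be re-run at every prefix size (honest but costly) or
done once at the first evaluated prefix and reused ("once" mode) for
desk-scale sweeps. Features are g-gap frequencies already in [0, 1], so no
rescaling is applied before the SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .ggap import FeatureMatrix
from .metrics import MetricsReport, evaluate_predictions

DEFAULT_GRID_C = [2.0**e for e in range(-5, 16, 2)]
DEFAULT_GRID_GAMMA = [2.0**e for e in range(-15, 4, 2)]


@dataclass
class ModelConfig:
    """SVM and cross-validation settings.

    C and gamma are the values used when calling :func:`cv_accuracy`
    directly; grid_c / grid_gamma are the candidate values searched by
    :func:`grid_search`.
    """

    C: float = 1.0
    gamma: float = 1.0
    n_folds: int = 5
    seed: int = 0
    grid_c: Sequence[float] = field(default_factory=lambda: list(DEFAULT_GRID_C))
    grid_gamma: Sequence[float] = field(default_factory=lambda: list(DEFAULT_GRID_GAMMA))

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class IFSCurve:
    """Accuracy as a function of prefix size, with the peak located."""

    sizes: list[int]
    accuracies: list[float]
    peak_k: int
    peak_metrics: MetricsReport
    peak_params: tuple[float, float]  # (C, gamma) at the peak
    params: list[tuple[float, float]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"k": self.sizes, "acc": self.accuracies}).to_csv(
            path, sep="\t", index=False
        )


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Within each class, samples are shuffled by a seeded generator and dealt
    to folds round-robin, so per-class counts across folds differ by at
    most one. Returns the fold index (0..k-1) of every sample.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than k = {k} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


def cv_accuracy(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[int],
    config: ModelConfig,
    C: float | None = None,
    gamma: float | None = None,
) -> MetricsReport:
    """Pooled cross-validated evaluation of an RBF-SVM at fixed (C, gamma).

    Out-of-fold predictions and decision scores from every fold are pooled
    into a single confusion matrix, metric set and ROC curve.
    """
    values = _as_array(X)
    y = np.asarray(y).astype(int)
    if values.shape[1] == 0:
        raise ValueError("feature matrix has no columns")
    C = config.C if C is None else C
    gamma = config.gamma if gamma is None else gamma

    folds = stratified_folds(y, config.n_folds, config.seed)
    pred = np.empty(len(y), dtype=int)
    score = np.empty(len(y), dtype=float)
    for f in range(config.n_folds):
        test = folds == f
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(values[~test], y[~test])
        s = clf.decision_function(values[test])
        score[test] = s
        pred[test] = (s > 0).astype(int)
    return evaluate_predictions(y, pred, scores=score)


def grid_search(
    X: FeatureMatrix | np.ndarray, y: Sequence[int], config: ModelConfig
) -> tuple[float, float, float]:
    """Exhaustive (C, gamma) search maximizing pooled CV accuracy.

    Returns (best_C, best_gamma, best_accuracy). Accuracy ties resolve to
    the smaller C, then the smaller gamma.
    """
    if not config.grid_c or not config.grid_gamma:
        raise ValueError("empty parameter grid")
    best: tuple[float, float, float] | None = None
    for C in sorted(config.grid_c):
        for gamma in sorted(config.grid_gamma):
            acc = cv_accuracy(X, y, config, C=C, gamma=gamma).acc
            if best is None or acc > best[2]:
                best = (C, gamma, acc)
    assert best is not None
    return best


def ifs_sweep(
    X_ranked: FeatureMatrix | np.ndarray,
    y: Sequence[int],
    config: ModelConfig,
    max_k: int | None = None,
    k_values: Sequence[int] | None = None,
    tune: str = "per_k",
) -> IFSCurve:
    """Sweep nested prefixes of a ranked feature matrix.

    Parameters
    ----------
    X_ranked : FeatureMatrix or ndarray
        Columns already in ranked order (best first).
    max_k : int, optional
        Largest prefix to evaluate (default: all columns). Ignored when
        ``k_values`` is given.
    k_values : sequence of int, optional
        Explicit, strictly increasing prefix sizes to evaluate (a
        subsampled sweep for large feature counts).
    tune : {"per_k", "once"}
        Re-run the (C, gamma) grid search at every prefix, or tune at the
        first evaluated prefix and reuse.

    Returns
    -------
    IFSCurve
        With ``peak_k`` the smallest evaluated size achieving the maximum
        accuracy and ``peak_metrics`` the full pooled-CV report there.
    """
    values = _as_array(X_ranked)
    n_feat = values.shape[1]
    if k_values is None:
        if max_k is None:
            max_k = n_feat
        if not 1 <= max_k <= n_feat:
            raise ValueError(f"max_k = {max_k} outside [1, {n_feat}]")
        k_values = list(range(1, max_k + 1))
    else:
        k_values = list(k_values)
        if not k_values or any(b <= a for a, b in zip(k_values, k_values[1:])):
            raise ValueError("k_values must be non-empty and strictly increasing")
        if k_values[0] < 1 or k_values[-1] > n_feat:
            raise ValueError("k_values outside [1, n_features]")
    if tune not in ("per_k", "once"):
        raise ValueError("tune must be 'per_k' or 'once'")

    sizes: list[int] = []
    accs: list[float] = []
    params: list[tuple[float, float]] = []
    fixed: tuple[float, float] | None = None
    for k in k_values:
        Xk = values[:, :k]
        if tune == "per_k" or fixed is None:
            C, gamma, acc = grid_search(Xk, y, config)
            if tune == "once":
                fixed = (C, gamma)
        else:
            C, gamma = fixed
            acc = cv_accuracy(Xk, y, config, C=C, gamma=gamma).acc
        sizes.append(k)
        accs.append(acc)
        params.append((C, gamma))

    peak_i = int(np.argmax(accs))  # first occurrence = smallest k at the max
    peak_k = sizes[peak_i]
    peak_C, peak_gamma = params[peak_i]
    peak_metrics = cv_accuracy(values[:, :peak_k], y, config, C=peak_C, gamma=peak_gamma)
    return IFSCurve(
        sizes=sizes,
        accuracies=accs,
        peak_k=peak_k,
        peak_metrics=peak_metrics,
        peak_params=(peak_C, peak_gamma),
        params=params,
    )


def fit_final_svm(
    X: FeatureMatrix | np.ndarray, y: Sequence[int], C: float, gamma: float
) -> SVC:
    """Train the deployment SVM on all data at fixed hyperparameters."""
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(_as_array(X), np.asarray(y).astype(int))
    return clf
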