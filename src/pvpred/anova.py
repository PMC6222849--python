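"""One-way ANOVA F-score feature ranking.

Each feature is scored by the ratio of between-class to within-class
variance,

    F(i) = (SS_B(i) / df_B) / (SS_W(i) / df_W),

with df_B = K - 1 groups and df_W = M - K residual degrees of freedom.
A large F marks a feature whose class-conditional means are well separated
relative to its within-class spread. The score is used purely as a
univariate relevance filter — features are ranked from high to low F — so
no p-value conversion is performed.

Degenerate features the textbook formula leaves undefined are resolved as:
zero within-class variance with non-zero between-class variance scores
+inf (a perfectly separating feature must rank first); a feature constant
across all samples (0/0) scores 0 (no discriminative signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ggap import FeatureMatrix, GGapDescriptor

# SS terms below this fraction of the total scale are treated as exact zeros
# (the frequencies are small rationals; float round-off leaves dust).
_SS_TOL = 1e-12


@dataclass
class AnovaResult:
    """Per-feature F statistics and their sum-of-squares decomposition."""

    f_scores: np.ndarray
    ss_between: np.ndarray
    ss_within: np.ndarray
    df_between: int
    df_within: int
    n_groups: int
    n_samples: int
    group_sizes: np.ndarray


@dataclass
class RankedFeatures:
    """A descending-score ordering of feature indices.

    ``order[r]`` is the original index of the rank-r feature and
    ``scores[r]`` its score; ties are broken by ascending original index
    (stable sort), so rankings are reproducible.
    """

    order: np.ndarray
    scores: np.ndarray
    descriptors: list[GGapDescriptor] | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.order.shape != self.scores.shape:
            raise ValueError("order and scores must align")

    def top(self, k: int) -> np.ndarray:
        """Original indices of the k best-ranked features."""
        return self.order[:k]

    def to_tsv(self, path: str | Path, score_name: str = "score",
               extra: dict[str, np.ndarray] | None = None) -> None:
        rows = {
            "rank": np.arange(1, len(self.order) + 1),
            "feature": (
                [self.descriptors[i].name for i in self.order]
                if self.descriptors
                else self.order
            ),
            score_name: self.scores,
        }
        if extra:
            rows.update(extra)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def anova_f_scores(X: FeatureMatrix | np.ndarray, y: Sequence[int]) -> AnovaResult:
    """One-way ANOVA F statistic for every feature column.

    Works for any number of groups K >= 2 (the pipeline uses K = 2).

    Raises
    ------
    ValueError
        If fewer than two classes are present, or M <= K (df_W = 0).
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    K = len(classes)
    M = values.shape[0]
    if K < 2:
        raise ValueError("ANOVA needs at least two classes")
    if M <= K:
        raise ValueError(f"M = {M} samples with K = {K} groups leaves df_W = 0")
    if len(y) != M:
        raise ValueError("label length mismatch")

    sizes = np.bincount(y_codes, minlength=K).astype(float)
    grand = values.mean(axis=0)
    group_means = np.stack([values[y_codes == j].mean(axis=0) for j in range(K)])

    ss_between = (sizes[:, None] * (group_means - grand) ** 2).sum(axis=0)
    ss_within = np.zeros(values.shape[1])
    for j in range(K):
        ss_within += ((values[y_codes == j] - group_means[j]) ** 2).sum(axis=0)

    df_between = K - 1
    df_within = M - K
    scale = np.maximum(ss_between + ss_within, 1.0)
    zero_w = ss_within <= _SS_TOL * scale
    zero_b = ss_between <= _SS_TOL * scale

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    f = np.where(zero_w & zero_b, 0.0, f)       # constant feature: no signal
    f = np.where(zero_w & ~zero_b, np.inf, f)   # perfect separator

    return AnovaResult(
        f_scores=f,
        ss_between=ss_between,
        ss_within=ss_within,
        df_between=df_between,
        df_within=df_within,
        n_groups=K,
        n_samples=M,
        group_sizes=sizes.astype(int),
    )


def rank_by_score(
    scores: np.ndarray, descriptors: list[GGapDescriptor] | None = None
) -> RankedFeatures:
    """Rank features by descending score, ties broken by ascending index."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    order = np.argsort(-scores, kind="stable")
    return RankedFeatures(order=order, scores=scores[order], descriptors=descriptors)
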