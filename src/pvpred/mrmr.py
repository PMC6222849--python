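"""Minimal-redundancy-maximal-relevance (mRMR) feature ordering.

Features are first discretized (mutual information on continuous
frequencies would need density estimation; the mRMR literature works on
binned data), then ordered greedily: the first pick maximizes relevance
I(x; c) with the class label, and each subsequent pick maximizes the
incremental criterion

    MID (difference):  I(x; c) - (1/|S|) sum_{x_j in S} I(x; x_j)
    MIQ (quotient):    I(x; c) / ((1/|S|) sum_{x_j in S} I(x; x_j))

where S is the already-selected set. Mutual information is the empirical
plug-in estimate in bits (base 2; the base uniformly rescales all scores
and cannot change the greedy order). The set-level mRMR objective is
NP-hard; this incremental greedy form is its standard operationalization.

Default discretization is the three-bin mean +/- sigma rule: per feature,
code 0 below mu - a*sigma, 1 inside [mu - a*sigma, mu + a*sigma], 2 above,
with multiplier a = 1 and population sigma. It is parameter-light and
deterministic; an equal-frequency quantile scheme is available for other
bin counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anova import RankedFeatures
from .ggap import FeatureMatrix, GGapDescriptor

_EPS = 1e-12


@dataclass
class DiscreteMatrix:
    """Binned feature codes: samples x features small non-negative integers."""

    codes: np.ndarray
    n_bins: int
    boundaries: list[np.ndarray]
    descriptors: list[GGapDescriptor] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) >= self.n_bins:
            raise ValueError("codes outside [0, n_bins)")


@dataclass
class ZScores:
    """Standardized scores: z_i = (x_i - mu) / sigma with population sigma."""

    z: np.ndarray
    mu: float
    sigma: float


def discretize(
    X: FeatureMatrix | np.ndarray,
    n_bins: int = 3,
    scheme: str = "mean_sd",
    multiplier: float = 1.0,
) -> DiscreteMatrix:
    """Bin each feature column into integer codes.

    ``scheme="mean_sd"`` (default, requires ``n_bins=3``): edges at
    mu - multiplier*sigma and mu + multiplier*sigma per feature, population
    sigma. A constant feature yields a single repeated code (and thus zero
    mutual information with everything). ``scheme="quantile"``:
    equal-frequency bins for any ``n_bins >= 2``.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    descs = X.descriptors if isinstance(X, FeatureMatrix) else None
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    if scheme == "mean_sd":
        if n_bins != 3:
            raise ValueError("mean_sd scheme defines exactly 3 bins")
        mu = values.mean(axis=0)
        sigma = values.std(axis=0)  # population
        lo = mu - multiplier * sigma
        hi = mu + multiplier * sigma
        codes = np.ones_like(values, dtype=np.int64)
        codes[values < lo] = 0
        codes[values > hi] = 2
        boundaries = [np.array([lo[j], hi[j]]) for j in range(values.shape[1])]
    elif scheme == "quantile":
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        boundaries = []
        codes = np.empty_like(values, dtype=np.int64)
        for j in range(values.shape[1]):
            edges = np.unique(np.quantile(values[:, j], qs))
            boundaries.append(edges)
            codes[:, j] = np.searchsorted(edges, values[:, j], side="right")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    return DiscreteMatrix(codes=codes, n_bins=n_bins, boundaries=boundaries,
                          descriptors=descs)


def mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Empirical mutual information between two discrete vectors, in bits.

    I = sum_{x,y} p(x,y) log2( p(x,y) / (p(x) p(y)) ) over the empirical
    joint distribution; zero-probability cells contribute 0. Symmetric and
    non-negative, and invariant under relabeling of the category codes.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if a.size == 0:
        raise ValueError("empty vectors")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb) / a.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def _mi_against_all(codes: np.ndarray, col: np.ndarray) -> np.ndarray:
    """MI of one discrete vector against every column of ``codes``."""
    return np.array([mutual_info(codes[:, j], col) for j in range(codes.shape[1])])


def mrmr_order(
    Xd: DiscreteMatrix,
    y: np.ndarray,
    m: int | None = None,
    criterion: str = "mid",
) -> RankedFeatures:
    """Greedy mRMR ordering of the first ``m`` features.

    The returned scores are the per-step criterion values (the first entry
    is plain relevance). Ties break toward the lower feature index. With
    MIQ, if the mean redundancy of a candidate is below 1e-12 the quotient
    is undefined and the candidate is scored by its relevance alone.
    """
    codes = Xd.codes
    n_feat = codes.shape[1]
    if m is None:
        m = n_feat
    if not 1 <= m <= n_feat:
        raise ValueError(f"m = {m} outside [1, {n_feat}]")
    if criterion not in ("mid", "miq"):
        raise ValueError(f"criterion must be 'mid' or 'miq', got {criterion!r}")
    y = np.asarray(y)

    relevance = _mi_against_all(codes, y)
    redundancy_sum = np.zeros(n_feat)
    selected: list[int] = []
    step_scores: list[float] = []
    remaining = np.ones(n_feat, dtype=bool)

    for _ in range(m):
        if not selected:
            crit = relevance.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            if criterion == "mid":
                crit = relevance - mean_red
            else:
                crit = np.where(mean_red < _EPS, relevance, relevance / mean_red)
        crit = np.where(remaining, crit, -np.inf)
        best = int(np.argmax(crit))  # argmax takes the first (lowest) index on ties
        selected.append(best)
        step_scores.append(float(crit[best]))
        remaining[best] = False
        if len(selected) < m:
            redundancy_sum += _mi_against_all(codes, codes[:, best])

    descs = None
    if Xd.descriptors is not None:
        descs = list(Xd.descriptors)
    return RankedFeatures(
        order=np.array(selected), scores=np.array(step_scores), descriptors=descs
    )


def zscore(scores: np.ndarray) -> ZScores:
    """Standardize scores to mean 0, population standard deviation 1."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two values to standardize")
    mu = float(scores.mean())
    sigma = float(scores.std())  # population
    if sigma == 0:
        raise ValueError("zero standard deviation: standardization undefined")
    return ZScores(z=(scores - mu) / sigma, mu=mu, sigma=sigma)
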