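"""Discretization, mutual information, greedy mRMR ordering (vs brute
force) and Z-score standardization."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from pvpred.mrmr import discretize, mrmr_order, mutual_info, zscore


def mi_brute(a, b) -> float:
    """Independent plug-in MI oracle using plain-Python counting."""
    n = len(a)
    ja = Counter(a)
    jb = Counter(b)
    jab = Counter(zip(a, b))
    total = 0.0
    for (x, y), c in jab.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((ja[x] / n) * (jb[y] / n)))
    return total


def mrmr_brute(codes, y, m, criterion):
    """Independent greedy re-implementation of the incremental criterion."""
    n_feat = codes.shape[1]
    selected: list[int] = []
    for _ in range(m):
        best, best_val = None, None
        for i in range(n_feat):
            if i in selected:
                continue
            rel = mi_brute(list(codes[:, i]), list(y))
            if not selected:
                val = rel
            else:
                red = sum(
                    mi_brute(list(codes[:, i]), list(codes[:, j])) for j in selected
                ) / len(selected)
                if criterion == "mid":
                    val = rel - red
                else:
                    val = rel if red < 1e-12 else rel / red
            if best_val is None or val > best_val + 1e-12:
                best, best_val = i, val
        selected.append(best)
    return selected


# --- discretization ---------------------------------------------------------


def test_mean_sd_binning_outlier_example():
    """[0,0,0,0,10]: mu=2, population sigma=4, edges at -2 and 6, so the
    outlier lands in the top bin and the rest in the middle."""
    X = np.array([[0.0], [0.0], [0.0], [0.0], [10.0]])
    d = discretize(X, n_bins=3, scheme="mean_sd")
    assert list(d.codes[:, 0]) == [1, 1, 1, 1, 2]
    assert d.boundaries[0] == pytest.approx([-2.0, 6.0])


def test_constant_feature_single_code():
    d = discretize(np.full((8, 1), 0.4))
    assert len(set(d.codes[:, 0])) == 1


def test_binary_feature_mi_with_labels_unchanged_by_binning():
    """A 0/1 feature binned to 3 levels keeps exactly two distinct codes,
    so its MI with the labels equals MI of the raw categories."""
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, size=40).astype(float)
    y = rng.integers(0, 2, size=40)
    d = discretize(x[:, None])
    assert len(np.unique(d.codes[:, 0])) == 2
    assert mutual_info(d.codes[:, 0], y) == pytest.approx(
        mutual_info(x.astype(int), y)
    )


def test_quantile_scheme_supports_other_bin_counts():
    rng = np.random.default_rng(1)
    d = discretize(rng.normal(size=(100, 2)), n_bins=4, scheme="quantile")
    assert d.codes.max() == 3 and d.codes.min() == 0


def test_invalid_binning_arguments():
    with pytest.raises(ValueError):
        discretize(np.zeros((3, 1)), n_bins=1)
    with pytest.raises(ValueError):
        discretize(np.zeros((3, 1)), n_bins=5, scheme="mean_sd")


# --- mutual information -----------------------------------------------------


def test_self_information_of_balanced_binary():
    a = np.array([0] * 50 + [1] * 50)
    assert mutual_info(a, a) == pytest.approx(1.0)


def test_constant_vector_carries_no_information():
    b = np.array([0, 1, 0, 1, 1, 0])
    assert mutual_info(np.zeros(6, dtype=int), b) == pytest.approx(0.0)


def test_printed_joint_table_example():
    """Joint counts (0,0)x2 (0,1)x1 (1,0)x1 (1,1)x2 over 6 samples give
    (2/3)log2(4/3) + (1/3)log2(2/3) ~ 0.0817 bits."""
    a = np.array([0, 0, 0, 1, 1, 1])
    b = np.array([0, 0, 1, 0, 1, 1])
    expected = (2 / 3) * math.log2(4 / 3) + (1 / 3) * math.log2(2 / 3)
    assert mutual_info(a, b) == pytest.approx(expected)
    assert mutual_info(a, b) == pytest.approx(0.0817, abs=5e-5)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        mutual_info(np.zeros(3, dtype=int), np.zeros(4, dtype=int))


def test_mi_properties_on_random_vectors():
    """Symmetry, non-negativity, I(a,a) = H(a), relabeling invariance."""
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.integers(0, 4, size=60)
        b = rng.integers(0, 3, size=60)
        iab = mutual_info(a, b)
        assert iab >= -1e-12
        assert iab == pytest.approx(mutual_info(b, a))
        assert iab == pytest.approx(mi_brute(list(a), list(b)))
        p = np.bincount(a, minlength=4) / a.size
        entropy = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert mutual_info(a, a) == pytest.approx(entropy)
        relabel = rng.permutation(4)
        assert mutual_info(relabel[a], b) == pytest.approx(iab)


# --- greedy mRMR ------------------------------------------------------------


def _random_discrete(seed, n=50, n_feat=5, levels=3):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, levels, size=(n, n_feat))
    y = (codes[:, 0] + rng.integers(0, 2, size=n) > 1).astype(int)
    from pvpred.mrmr import DiscreteMatrix

    return DiscreteMatrix(codes=codes, n_bins=levels, boundaries=[]), y


def test_first_pick_maximizes_relevance():
    Xd, y = _random_discrete(3)
    ranked = mrmr_order(Xd, y, m=1)
    rels = [mutual_info(Xd.codes[:, j], y) for j in range(Xd.codes.shape[1])]
    assert ranked.order[0] == int(np.argmax(rels))
    assert ranked.scores[0] == pytest.approx(max(rels))


def test_duplicated_column_is_penalized():
    """After one copy of a relevant feature is chosen, its duplicate's mean
    redundancy equals its self-information, so with the difference
    criterion its incremental score is non-positive and a weakly relevant
    independent feature is taken first."""
    rng = np.random.default_rng(4)
    strong = rng.integers(0, 2, size=80)
    y = strong.copy()
    y[:8] = 1 - y[:8]
    weak = y.copy()
    weak[: 40] = rng.integers(0, 2, size=40)
    codes = np.column_stack([strong, strong, weak])
    from pvpred.mrmr import DiscreteMatrix

    Xd = DiscreteMatrix(codes=codes, n_bins=2, boundaries=[])
    ranked = mrmr_order(Xd, y, m=3, criterion="mid")
    assert ranked.order[0] == 0          # first copy: max relevance
    assert ranked.order[1] == 2          # duplicate pushed below the weak one
    dup_step = list(ranked.order).index(1)
    assert ranked.scores[dup_step] <= 1e-12


@pytest.mark.parametrize("criterion", ["mid", "miq"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_greedy_order_matches_brute_force(criterion, seed):
    Xd, y = _random_discrete(seed, n=50, n_feat=6)
    m = 6
    ours = list(mrmr_order(Xd, y, m=m, criterion=criterion).order)
    assert ours == mrmr_brute(Xd.codes, y, m, criterion)


def test_prefix_consistency_and_full_permutation():
    Xd, y = _random_discrete(9, n_feat=8)
    full = list(mrmr_order(Xd, y, m=8).order)
    assert sorted(full) == list(range(8))
    assert list(mrmr_order(Xd, y, m=4).order) == full[:4]


def test_m_out_of_range_rejected():
    Xd, y = _random_discrete(5)
    with pytest.raises(ValueError):
        mrmr_order(Xd, y, m=99)


# --- z-scores ---------------------------------------------------------------


def test_zscore_hand_example():
    z = zscore(np.array([1.0, 2.0, 3.0]))
    assert z.z == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)
    assert z.mu == pytest.approx(2.0)
    assert z.sigma == pytest.approx(math.sqrt(2 / 3))


def test_zscore_is_idempotent_and_standardizes():
    rng = np.random.default_rng(6)
    x = rng.normal(3, 2, size=40)
    z1 = zscore(x).z
    assert z1.mean() == pytest.approx(0.0, abs=1e-12)
    assert z1.std() == pytest.approx(1.0)
    assert zscore(z1).z == pytest.approx(z1)


def test_zscore_constant_input_rejected():
    with pytest.raises(ValueError):
        zscore(np.full(5, 2.0))
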