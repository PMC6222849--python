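"""g-gap dipeptide encoding: worked examples, conservation laws, fusion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvpred.ggap import (
    DegenerateSequenceError,
    FeatureMatrix,
    GGapDescriptor,
    N_DIPEPTIDES,
    build_matrix,
    descriptors_for_g,
    dipeptide_index,
    fuse,
    ggap_vector,
)
from pvpred.sequence_io import ALPHABET, ProteinSequence

residue_text = st.text(alphabet=ALPHABET, min_size=2, max_size=80)


def naive_pair_counts(residues: str, g: int) -> dict[tuple[str, str], int]:
    """Independent oracle: enumerate every (p, p+g+1) pair by hand."""
    counts: dict[tuple[str, str], int] = {}
    for p in range(len(residues) - g - 1):
        key = (residues[p], residues[p + g + 1])
        counts[key] = counts.get(key, 0) + 1
    return counts


@pytest.mark.parametrize(
    "pair,expected",
    [(("A", "A"), 0), (("A", "C"), 1), (("Y", "Y"), 399), (("C", "A"), 20)],
)
def test_dipeptide_index_examples(pair, expected):
    assert dipeptide_index(*pair) == expected


def test_dipeptide_index_is_a_bijection():
    seen = {dipeptide_index(a, b) for a in ALPHABET for b in ALPHABET}
    assert seen == set(range(N_DIPEPTIDES))


def test_dipeptide_index_rejects_nonstandard():
    with pytest.raises(ValueError):
        dipeptide_index("X", "A")


def test_adjacent_dipeptides_of_acde():
    """'ACDE' at g=0 has pairs AC, CD, DE, each with frequency 1/3."""
    v = ggap_vector("ACDE", 0)
    expect = {dipeptide_index(*p): 1 / 3 for p in [("A", "C"), ("C", "D"), ("D", "E")]}
    for i in range(N_DIPEPTIDES):
        assert v[i] == pytest.approx(expect.get(i, 0.0))


def test_homopolymer_single_pair():
    v = ggap_vector("AAAA", 1)
    assert v[dipeptide_index("A", "A")] == 1.0
    assert v.sum() == pytest.approx(1.0)


def test_too_short_sequence_raises():
    with pytest.raises(DegenerateSequenceError):
        ggap_vector("AC", 1)  # L - g - 1 = 0


@given(residue_text, st.integers(min_value=0, max_value=9))
def test_vector_matches_pair_enumeration_oracle(residues, g):
    """Entries equal n_i / (L - g - 1) from a naive pair enumeration, are
    non-negative, and sum to 1 (count conservation)."""
    if len(residues) < g + 2:
        with pytest.raises(DegenerateSequenceError):
            ggap_vector(residues, g)
        return
    v = ggap_vector(residues, g)
    denom = len(residues) - g - 1
    oracle = naive_pair_counts(residues, g)
    assert sum(oracle.values()) == denom  # sum n_i = L - g - 1
    for (a, b), n in oracle.items():
        assert v[dipeptide_index(a, b)] == pytest.approx(n / denom)
    assert (v >= 0).all()
    assert abs(v.sum() - 1.0) < 1e-12


def test_vector_depends_only_on_residues_and_g():
    s1 = ProteinSequence(id="x", residues="ACDEFGHIK")
    s2 = ProteinSequence(id="y", residues="ACDEFGHIK", label=1)
    assert np.array_equal(ggap_vector(s1, 2), ggap_vector(s2, 2))


def test_build_matrix_shape_and_row_sums():
    seqs = [
        ProteinSequence(id=f"s{i}", residues="ACDEFGHIKLMNPQRSTVWY" * 2, label=i % 2)
        for i in range(10)
    ]
    for g in (0, 3):
        X = build_matrix(seqs, g)
        assert X.values.shape == (10, 400)
        assert np.allclose(X.values.sum(axis=1), 1.0, atol=1e-12)
    assert not np.array_equal(build_matrix(seqs, 0).values, build_matrix(seqs, 1).values)


def test_build_matrix_reports_all_short_sequences():
    seqs = [
        ProteinSequence(id="ok", residues="ACDEFGHIK"),
        ProteinSequence(id="short1", residues="AC"),
        ProteinSequence(id="short2", residues="DE"),
    ]
    with pytest.raises(DegenerateSequenceError) as exc:
        build_matrix(seqs, 2)
    assert "short1" in str(exc.value) and "short2" in str(exc.value)


def _matrices_for_fusion(n_g=10):
    seqs = [
        ProteinSequence(id=f"s{i}", residues="ACDEFGHIKLMNPQRSTVWY", label=i % 2)
        for i in range(4)
    ]
    return [build_matrix(seqs, g) for g in range(n_g)]


def test_fusion_width_matches_per_gap_subset_sizes():
    """Subsets sized 107..94 across the ten gaps fuse to width 1266."""
    sizes = [107, 213, 135, 87, 42, 89, 70, 174, 255, 94]
    mats = _matrices_for_fusion()
    fused = fuse(mats, [list(range(n)) for n in sizes])
    assert fused.n_features == sum(sizes) == 1266
    gs = [d.g for d in fused.descriptors]
    assert gs == sorted(gs)  # ascending g blocks


def test_fusion_identity_case_single_gap():
    mats = _matrices_for_fusion(2)
    fused = fuse(mats, [[5, 2, 9], []])
    assert fused.n_features == 3
    assert np.array_equal(fused.values, mats[0].values[:, [5, 2, 9]])
    assert [d.name for d in fused.descriptors] == [
        mats[0].descriptors[i].name for i in [5, 2, 9]
    ]


def test_fusion_rejects_duplicate_selection():
    mats = _matrices_for_fusion(1)
    with pytest.raises(ValueError):
        fuse(mats, [[3, 3]])


def test_fusion_rejects_mismatched_samples():
    mats = _matrices_for_fusion(1)
    other = build_matrix(
        [ProteinSequence(id="zz", residues="ACDEFGHIKLMNPQRSTVWY")], 1
    )
    with pytest.raises(ValueError):
        fuse([mats[0], other], [[1], [2]])


def test_matrix_tsv_round_trip(tmp_path):
    X = _matrices_for_fusion(1)[0]
    p = tmp_path / "m.tsv"
    X.to_tsv(p)
    back = FeatureMatrix.from_tsv(p)
    assert back.sample_ids == X.sample_ids
    assert [d.name for d in back.descriptors] == [d.name for d in X.descriptors]
    assert np.allclose(back.values, X.values)
    assert np.array_equal(back.labels, X.labels)


def test_descriptor_name_round_trip():
    d = GGapDescriptor(g=7, first="W", second="A")
    assert GGapDescriptor.from_name(d.name) == d
    assert descriptors_for_g(3)[d.index].first == "W"
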