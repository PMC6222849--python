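"""g-gap dipeptide composition features.

A g-gap dipeptide is an ordered pair of residues separated by exactly ``g``
intervening positions; ``g = 0`` recovers the classical adjacent dipeptide
composition. A protein of length ``L`` contains ``L - g - 1`` such pairs,
and its g-gap composition vector holds the 400 pair frequencies

    v_i = n_i / (L - g - 1),

which are non-negative and sum to exactly 1. The 400 ordered pairs are
indexed row-major by alphabetical residue rank (AA=0, AC=1, ..., YY=399);
the ordering is a free choice and is fixed here so that ranked-index
outputs are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, ProteinSequence

#: Number of ordered residue pairs.
N_DIPEPTIDES = 400

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(ALPHABET):
    _CODE[ord(_aa)] = _i


class DegenerateSequenceError(ValueError):
    """Sequence too short for the requested gap (needs L >= g + 2)."""


@dataclass(frozen=True)
class GGapDescriptor:
    """Identity of one feature column: gap value plus ordered residue pair."""

    g: int
    first: str
    second: str

    @property
    def index(self) -> int:
        """Position 0..399 within this descriptor's g-block."""
        return dipeptide_index(self.first, self.second)

    @property
    def name(self) -> str:
        return f"g{self.g}_{self.first}{self.second}"

    @classmethod
    def from_name(cls, name: str) -> "GGapDescriptor":
        gpart, pair = name.split("_")
        return cls(g=int(gpart[1:]), first=pair[0], second=pair[1])


def dipeptide_index(first: str, second: str) -> int:
    """Map an ordered residue pair to its column index 0..399.

    ``index = 20 * rank(first) + rank(second)`` with alphabetical ranks,
    a bijection between ordered pairs and 0..399.
    """
    try:
        a, b = _CODE[ord(first)], _CODE[ord(second)]
    except (TypeError, IndexError):
        raise ValueError(f"invalid residue pair ({first!r}, {second!r})")
    if a < 0 or b < 0:
        raise ValueError(f"residue outside standard alphabet: ({first!r}, {second!r})")
    return int(20 * a + b)


def descriptors_for_g(g: int) -> list[GGapDescriptor]:
    """All 400 descriptors for one gap value, in index order."""
    return [GGapDescriptor(g, a, b) for a in ALPHABET for b in ALPHABET]


def encode_residues(residues: str) -> np.ndarray:
    """Residue string -> integer codes 0..19."""
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in residues if _CODE[ord(c)] < 0})
        raise ValueError(f"non-standard residue(s): {bad}")
    return codes


def ggap_vector(seq: ProteinSequence | str, g: int) -> np.ndarray:
    """g-gap dipeptide frequency vector of length 400.

    Counts ordered pairs (position p, position p + g + 1) for
    p = 0 .. L - g - 2 and divides by the pair count L - g - 1.

    Raises
    ------
    DegenerateSequenceError
        If ``L < g + 2`` (the denominator would be zero or negative).
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    sid = seq.id if isinstance(seq, ProteinSequence) else "<str>"
    if g < 0:
        raise ValueError(f"gap must be non-negative, got {g}")
    L = len(residues)
    if L < g + 2:
        raise DegenerateSequenceError(
            f"sequence {sid!r} has length {L} < g + 2 = {g + 2}; "
            f"no {g}-gap pairs exist"
        )
    codes = encode_residues(residues)
    idx = 20 * codes[: L - g - 1] + codes[g + 1 :]
    counts = np.bincount(idx, minlength=N_DIPEPTIDES)
    return counts / float(L - g - 1)


@dataclass
class FeatureMatrix:
    """Samples x features matrix of g-gap dipeptide frequencies.

    Rows align with the input sequence order; each column carries a
    :class:`GGapDescriptor` naming its gap value and residue pair.
    """

    values: np.ndarray
    descriptors: list[GGapDescriptor]
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.descriptors) != m:
            raise ValueError("descriptors length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        """Column subset in the given order (duplicates rejected)."""
        idx = list(indices)
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate column indices in selection")
        return FeatureMatrix(
            values=self.values[:, idx],
            descriptors=[self.descriptors[i] for i in idx],
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=[d.name for d in self.descriptors]
        )
        df.index.name = "sample_id"
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(
            values=df.to_numpy(dtype=float),
            descriptors=[GGapDescriptor.from_name(c) for c in df.columns],
            sample_ids=[str(i) for i in df.index],
            labels=labels,
        )


def build_matrix(seqs: Sequence[ProteinSequence], g: int) -> FeatureMatrix:
    """Encode every sequence at gap ``g`` into one FeatureMatrix.

    All sequences must satisfy ``L >= g + 2``; offenders are reported by id
    in a single error rather than silently dropped, which would
    desynchronize rows and labels.
    """
    too_short = [s.id for s in seqs if len(s) < g + 2]
    if too_short:
        raise DegenerateSequenceError(
            f"{len(too_short)} sequence(s) shorter than g + 2 = {g + 2} "
            f"for g = {g}: {', '.join(too_short[:10])}"
            + ("..." if len(too_short) > 10 else "")
        )
    values = np.stack([ggap_vector(s, g) for s in seqs]) if seqs else np.empty((0, N_DIPEPTIDES))
    labels = None
    if seqs and all(s.label is not None for s in seqs):
        labels = np.array([s.label for s in seqs], dtype=int)
    return FeatureMatrix(
        values=values,
        descriptors=descriptors_for_g(g),
        sample_ids=[s.id for s in seqs],
        labels=labels,
    )


def fuse(
    matrices: Sequence[FeatureMatrix], selections: Sequence[Sequence[int]]
) -> FeatureMatrix:
    """Concatenate selected columns from per-g matrices into one matrix.

    ``matrices[k]`` must be a single-g matrix and ``selections[k]`` the
    column indices chosen for it (e.g. the prefix of its relevance ranking).
    Output columns run in ascending g order, preserving each selection's
    internal order; descriptors retain (g, pair) provenance. Fused width is
    the sum of the selection sizes.
    """
    if len(matrices) != len(selections):
        raise ValueError("matrices and selections must align")
    if not matrices:
        raise ValueError("nothing to fuse")

    ref_ids = matrices[0].sample_ids
    order = []
    for mat, sel in zip(matrices, selections):
        gs = {d.g for d in mat.descriptors}
        if len(gs) != 1:
            raise ValueError("each matrix to fuse must hold a single g")
        if mat.sample_ids != ref_ids:
            raise ValueError("mismatched sample sets across per-g matrices")
        sel = list(sel)
        if len(set(sel)) != len(sel):
            raise ValueError(f"duplicate column selected within g={gs.pop()}")
        order.append((min(gs), mat, sel))
    order.sort(key=lambda t: t[0])

    blocks = [mat.values[:, sel] for _, mat, sel in order if sel]
    descs: list[GGapDescriptor] = []
    for _, mat, sel in order:
        descs.extend(mat.descriptors[i] for i in sel)
    values = (
        np.concatenate(blocks, axis=1) if blocks else np.empty((len(ref_ids), 0))
    )
    return FeatureMatrix(
        values=values,
        descriptors=descs,
        sample_ids=list(ref_ids),
        labels=matrices[0].labels,
    )
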