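"""Synthetic labeled protein sequences with planted g-gap dipeptide signal.

The generator emulates the shape of a two-class virion / non-virion
benchmark without any download: negatives are drawn i.i.d. from a
background residue distribution; positives are drawn from the same
background but with *planted* g-gap dipeptide biases. Signal is planted by
biased sequential sampling — when emitting the residue at position t, the
probability of residue ``b`` is multiplied by the enrichment factor for
every planted pair (g, a, b) whose conditioning position t - g - 1 holds
``a`` — rather than by post-hoc editing, which keeps the sequences
compositionally natural and the enrichment factor interpretable as an
approximate conditional-odds multiplier.

What this emulates: class-conditional differences in pair frequencies at
specific gaps, class imbalance, and length variation. What it does not:
domain architecture, homology structure, or phylogenetic redundancy — so a
pipeline that recovers planted signal here is shown to work mechanically,
not to generalize to real proteomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import ALPHABET, ProteinSequence

#: Approximate Swiss-Prot residue frequencies, A..Y alphabetical order.
SWISSPROT_FREQS = np.array([
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0593, 0.0581,
    0.0966, 0.0241, 0.0406, 0.0474, 0.0394, 0.0553, 0.0660, 0.0535, 0.0687,
    0.0110, 0.0292,
])
SWISSPROT_FREQS = SWISSPROT_FREQS / SWISSPROT_FREQS.sum()

_RANK = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class PlantedPair:
    """One enriched g-gap dipeptide: (gap, first residue, second residue)."""

    g: int
    first: str
    second: str
    enrichment: float = 8.0

    def __post_init__(self) -> None:
        if self.first not in _RANK or self.second not in _RANK:
            raise ValueError(f"residues must be standard: {self.first}{self.second}")
        if self.g < 0:
            raise ValueError("gap must be non-negative")
        if self.enrichment <= 0:
            raise ValueError("enrichment must be positive")


@dataclass
class SynthSpec:
    """Generation recipe for one two-class dataset.

    Defaults mirror the shape of the curated virion benchmark this
    generator stands in for: 99 positives vs 208 negatives, lengths 80-200
    so every gap up to 9 is encodable, uniform background.
    """

    n_pos: int = 99
    n_neg: int = 208
    length_range: tuple[int, int] = (80, 200)
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    planted: list[PlantedPair] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or (self.background <= 0).any():
            raise ValueError("background must be 20 positive frequencies")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        lo, hi = self.length_range
        max_g = max((p.g for p in self.planted), default=0)
        if lo < max_g + 2:
            raise ValueError(
                f"min length {lo} < largest planted g + 2 = {max_g + 2}"
            )
        if lo > hi or lo < 2:
            raise ValueError("invalid length range")
        for p in self.planted:
            if p.enrichment * self.background[_RANK[p.second]] > 1.0:
                raise ValueError(
                    f"infeasible enrichment for {p.first}{p.second} at g={p.g}: "
                    f"expected conditional frequency exceeds 1"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_pos": self.n_pos,
                "n_neg": self.n_neg,
                "length_range": list(self.length_range),
                "background": [round(float(x), 6) for x in self.background],
                "planted": [
                    {"g": p.g, "pair": p.first + p.second, "enrichment": p.enrichment}
                    for p in self.planted
                ],
                "seed": self.seed,
            },
            indent=2,
        )


def benchmark_shape_spec(
    planted: Sequence[PlantedPair] = (), seed: int = 0
) -> SynthSpec:
    """A spec mimicking the curated benchmark's class sizes (99 vs 208).

    The total of 307 samples reproduces the benchmark's sample count; the
    sequence content is synthetic.
    """
    return SynthSpec(n_pos=99, n_neg=208, planted=list(planted), seed=seed)


def _sample_background(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    codes = rng.choice(20, size=length, p=bg)
    return "".join(ALPHABET[c] for c in codes)


def _sample_planted(
    rng: np.random.Generator, length: int, bg: np.ndarray, planted: Sequence[PlantedPair]
) -> str:
    # planted pairs grouped by gap for O(#planted) work per position
    by_gap: dict[int, list[tuple[int, int, float]]] = {}
    for p in planted:
        by_gap.setdefault(p.g, []).append(
            (_RANK[p.first], _RANK[p.second], p.enrichment)
        )
    codes = np.empty(length, dtype=int)
    for t in range(length):
        probs = bg
        boosted = False
        for g, pairs in by_gap.items():
            src = t - g - 1
            if src < 0:
                continue
            for a, b, enr in pairs:
                if codes[src] == a:
                    if not boosted:
                        probs = bg.copy()
                        boosted = True
                    probs[b] *= enr
        if boosted:
            probs = probs / probs.sum()
        codes[t] = rng.choice(20, p=probs)
    return "".join(ALPHABET[c] for c in codes)


def generate(spec: SynthSpec) -> tuple[list[ProteinSequence], list[ProteinSequence]]:
    """Generate (positives, negatives) deterministically from the spec seed.

    Negatives are i.i.d. background; positives carry the planted biases.
    With every enrichment equal to 1 the two classes are exchangeable.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    positives = []
    for i in range(spec.n_pos):
        L = int(rng.integers(lo, hi + 1))
        positives.append(
            ProteinSequence(
                id=f"pos_{i + 1:04d}",
                residues=_sample_planted(rng, L, spec.background, spec.planted),
                label=1,
            )
        )
    negatives = []
    for i in range(spec.n_neg):
        L = int(rng.integers(lo, hi + 1))
        negatives.append(
            ProteinSequence(
                id=f"neg_{i + 1:04d}",
                residues=_sample_background(rng, L, spec.background),
                label=0,
            )
        )
    return positives, negatives


def write_dataset(spec: SynthSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate and write positive.fasta / negative.fasta plus a provenance
    sidecar (spec + seed as JSON)."""
    from .sequence_io import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos, neg = generate(spec)
    pos_path = out_dir / "positive.fasta"
    neg_path = out_dir / "negative.fasta"
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    (out_dir / "provenance.json").write_text(spec.to_json() + "\n")
    return pos_path, neg_path
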