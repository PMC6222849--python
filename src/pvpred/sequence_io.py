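"""FASTA input/output with strict amino-acid validation.

Sequences are restricted to the 20 standard residues. Records containing
ambiguous or nonstandard letters (``B``, ``U``, ``X``, ``Z``, stop ``*``,
gaps, ...) are rejected outright rather than masked, so every downstream
feature vector is computed on a fully specified sequence. Lowercase
residues are uppercased — a common FASTA dialect variance — but any other
out-of-alphabet character is a hard error naming the record.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetically ordered (A=0 ... Y=19).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

logger = logging.getLogger(__name__)


class SequenceValidationError(ValueError):
    """A record contains residues outside the 20-letter standard alphabet."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Parameters
    ----------
    id : str
        Record identifier (FASTA description up to the first whitespace).
    residues : str
        Uppercase residue string over the 20-letter standard alphabet.
    label : int, optional
        Binary class tag: 1 = virion (positive), 0 = non-virion (negative).
        ``None`` for unlabeled sequences.
    """

    id: str
    residues: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.residues) - _ALPHABET_SET)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard residue(s) "
                f"{', '.join(repr(c) for c in bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, label: int | None = None) -> list[ProteinSequence]:
    """Read a FASTA file into validated :class:`ProteinSequence` records.

    Wrapped (multi-line) records are concatenated; lowercase residues are
    uppercased. If any record fails validation the whole read fails with a
    :class:`SequenceValidationError` listing every offending record — no
    silent dropping, which would desynchronize sample/label bookkeeping.

    Parameters
    ----------
    path : path-like
        FASTA file to read.
    label : int, optional
        Class label to attach to every record (1 = virion, 0 = non-virion).

    Returns
    -------
    list of ProteinSequence
        One entry per record, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")

    seqs: list[ProteinSequence] = []
    failures: list[str] = []
    for rec in records:
        try:
            seqs.append(
                ProteinSequence(id=rec.id, residues=str(rec.seq).upper(), label=label)
            )
        except SequenceValidationError as exc:
            failures.append(str(exc))
    if failures:
        raise SequenceValidationError(
            f"{path}: {len(failures)} invalid record(s):\n" + "\n".join(failures)
        )

    dupes = [rid for rid, n in Counter(s.id for s in seqs).items() if n > 1]
    if dupes:
        logger.warning("%s: duplicate record ids: %s", path, ", ".join(dupes))
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences to ``path`` in FASTA format.

    Round-trip safe: ``read_fasta`` on the written file reproduces ids and
    residues exactly (an empty input list yields an empty file, which
    ``read_fasta`` rejects as containing no records).
    """
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def labels_of(seqs: Sequence[ProteinSequence]) -> list[int]:
    """Extract labels from a sequence list; error if any is unlabeled."""
    out = []
    for s in seqs:
        if s.label is None:
            raise ValueError(f"sequence {s.id!r} has no class label")
        out.append(s.label)
    return out
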