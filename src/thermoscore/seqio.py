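"""Reading and writing sequences, pair tables, and pre-aligned pairs.

FASTA parsing is delegated to Biopython; this module adds the validation
contracts the rest of the package relies on: a restricted residue alphabet,
first-token identifiers, duplicate-id detection, and alignment-shape checks
for gapped pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import AMBIGUOUS_AA, STANDARD_AA

GAP = "-"
_ACCEPTED = set(STANDARD_AA) | set(AMBIGUOUS_AA)


class SequenceError(ValueError):
    """Malformed sequence input (illegal residue, bad record shape)."""


class PairTableError(ValueError):
    """Malformed or unresolvable pair-table entry."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: identifier plus upper-case residue string.

    Residues are restricted to the 20 standard one-letter codes; the
    ambiguity codes B, J, X, Z, U, O are tolerated (they are skipped by
    compositional feature denominators downstream).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _ACCEPTED:
                raise SequenceError(
                    f"illegal residue {ch!r} in record {self.id!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_AA for c in self.residues)


@dataclass(frozen=True)
class LabeledPair:
    """An oriented training pair: ``stable`` is the putatively more
    thermostable side (HP), ``other`` the less stable side (MP)."""

    stable: ProteinSequence
    other: ProteinSequence

    def __post_init__(self) -> None:
        if self.stable.id == self.other.id:
            raise PairTableError(f"pair members share id {self.stable.id!r}")


@dataclass(frozen=True)
class AlignedPair:
    """Two gapped rows of equal aligned length; no all-gap columns."""

    top: str
    bottom: str

    def __post_init__(self) -> None:
        if len(self.top) != len(self.bottom):
            raise SequenceError(
                f"aligned rows differ in length ({len(self.top)} vs {len(self.bottom)})"
            )
        if len(self.top) == 0:
            raise SequenceError("alignment is empty")
        for col, (a, b) in enumerate(zip(self.top, self.bottom), start=1):
            if a == GAP and b == GAP:
                raise SequenceError(f"column {col} is gapped in both rows")
            for ch in (a, b):
                if ch != GAP and ch not in _ACCEPTED:
                    raise SequenceError(f"illegal residue {ch!r} at column {col}")


def read_fasta(path: str | os.PathLike) -> list[ProteinSequence]:
    """Read a FASTA file into validated :class:`ProteinSequence` records.

    Ids are the first whitespace-delimited header token; residues are
    upper-cased.  Duplicate ids are an error (pair tables need unambiguous
    lookup).
    """
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    return records


def write_fasta(path: str | os.PathLike, seqs: Iterable[ProteinSequence]) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, os.fspath(path), "fasta")


def index_sequences(seqs: Iterable[ProteinSequence]) -> dict[str, ProteinSequence]:
    out: dict[str, ProteinSequence] = {}
    for s in seqs:
        if s.id in out:
            raise SequenceError(f"duplicate sequence id {s.id!r}")
        out[s.id] = s
    return out


def read_pair_table(
    path: str | os.PathLike, seqs: dict[str, ProteinSequence]
) -> list[LabeledPair]:
    """Read a two-column TSV of (stable_id, other_id) into LabeledPairs.

    Lines starting with ``#`` are comments; blank lines are skipped.  Every
    id must resolve in ``seqs``.
    """
    pairs: list[LabeledPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise PairTableError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            stable_id, other_id = (f.strip() for f in fields)
            for sid in (stable_id, other_id):
                if sid not in seqs:
                    raise PairTableError(f"line {lineno}: unknown sequence id {sid!r}")
            pairs.append(LabeledPair(stable=seqs[stable_id], other=seqs[other_id]))
    return pairs


def write_pair_table(path: str | os.PathLike, pairs: Iterable[LabeledPair]) -> None:
    with open(path, "w") as fh:
        fh.write("#stable_id\tother_id\n")
        for p in pairs:
            fh.write(f"{p.stable.id}\t{p.other.id}\n")


def read_aligned_pair(path: str | os.PathLike) -> AlignedPair:
    """Read a gapped FASTA with exactly two records of equal aligned length.

    The first record is the top row; for substitution counting the caller's
    contract is top = MP, bottom = HP.
    """
    rows = list(SeqIO.parse(os.fspath(path), "fasta"))
    if len(rows) != 2:
        raise SequenceError(f"expected exactly 2 aligned records, got {len(rows)}")
    return AlignedPair(top=str(rows[0].seq).upper(), bottom=str(rows[1].seq).upper())
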