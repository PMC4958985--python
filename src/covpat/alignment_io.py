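"""Reading, validating and writing aligned sequence data.

The central container is :class:`Alignment`: an ordered set of equal-length
sequence records over an amino-acid or nucleotide alphabet, with a single
gap character (``'-'`` by default).  All site coordinates used anywhere in
this package are 1-based indices into the aligned columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"


class AlignmentError(ValueError):
    """Raised when input records do not form a valid alignment."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length sequence records with unique ids.

    Parameters
    ----------
    ids :
        Record identifiers, unique, in input order.
    seqs :
        Upper-case residue strings, all of the same length ``L``.
    alphabet :
        ``"protein"`` or ``"nucleotide"`` (informational tag).
    gap_char :
        The single gap character, ``'-'`` by default.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    alphabet: str = PROTEIN
    gap_char: str = "-"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if not self.seqs:
            raise AlignmentError("alignment has no records")
        L = len(self.seqs[0])
        for rid, seq in zip(self.ids, self.seqs):
            if len(seq) != L:
                raise AlignmentError(
                    f"not an alignment: record {rid!r} has length "
                    f"{len(seq)}, expected {L}"
                )
        if len(set(self.ids)) != len(self.ids):
            dup = next(r for r, c in Counter(self.ids).items() if c > 1)
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        if len(self.gap_char) != 1:
            raise AlignmentError("gap_char must be a single character")

    @property
    def length(self) -> int:
        """Number of aligned columns L."""
        return len(self.seqs[0])

    @property
    def n_records(self) -> int:
        return len(self.seqs)

    def records(self) -> Iterator[tuple[str, str]]:
        return zip(self.ids, self.seqs)

    def column(self, site: int) -> str:
        """Residues of 1-based column ``site`` in record order."""
        if not 1 <= site <= self.length:
            raise IndexError(f"site {site} outside 1..{self.length}")
        i = site - 1
        return "".join(seq[i] for seq in self.seqs)

    def subset(self, indices: Iterable[int]) -> "Alignment":
        """New alignment with the records at the given 0-based positions."""
        idx = list(indices)
        return Alignment(
            ids=tuple(self.ids[i] for i in idx),
            seqs=tuple(self.seqs[i] for i in idx),
            alphabet=self.alphabet,
            gap_char=self.gap_char,
        )


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-column plurality residues of an alignment.

    ``residues`` has one character per aligned column: the most frequent
    non-gap residue, ties broken by the lexicographically smallest residue,
    and the gap character for all-gap columns.  ``counts`` records the
    winning residue and its count per column.
    """

    residues: str
    counts: tuple[tuple[str, int], ...] = field(repr=False)

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta_alignment(path, alphabet: str = PROTEIN, gap_char: str = "-") -> Alignment:
    """Read an aligned FASTA file.

    All records must have identical length; characters are upper-cased and
    otherwise preserved verbatim.  Raises :class:`AlignmentError` on an
    empty file, duplicate ids or unequal record lengths (naming the first
    offending record).
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(tuple(ids), tuple(seqs), alphabet=alphabet, gap_char=gap_char)


def write_fasta_alignment(aln: Alignment, path) -> None:
    """Write the alignment as multi-record FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for rid, seq in aln.records():
            fh.write(f">{rid}\n{seq}\n")


def consensus(aln: Alignment) -> ConsensusSequence:
    """Plurality consensus of an alignment.

    Per column the most frequent non-gap residue wins; ties go to the
    lexicographically smallest residue; a column consisting only of gaps
    yields the gap character.  Invariant under record order.
    """
    chars: list[str] = []
    counts: list[tuple[str, int]] = []
    for site in range(1, aln.length + 1):
        col = aln.column(site)
        tally = Counter(c for c in col if c != aln.gap_char)
        if not tally:
            chars.append(aln.gap_char)
            counts.append((aln.gap_char, 0))
            continue
        # max count first, then lexicographically smallest residue
        best = min(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        chars.append(best[0])
        counts.append(best)
    return ConsensusSequence("".join(chars), tuple(counts))


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV of ``sequence_id<TAB>label``.

    Blank lines and lines starting with ``#`` are ignored.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sid, label = parts
            if sid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {sid!r}")
            labels[sid] = label
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, label in labels.items():
            fh.write(f"{sid}\t{label}\n")
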