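"""Data-initialization filters.

Two screens run before any covariance statistics are computed:

* sequence quality — a record is kept only when the number of its positions
  matching the consensus sequence is strictly greater than a configurable
  fraction of the alignment length (one third by default), discarding
  unrelated or heavily corrupted sequences;
* site informativeness — a column enters the element model only when at
  least two distinct non-gap residue types are each carried by a minimum
  number of sequences (five by default), so that a substitution at the site
  is actually observable in the sample.
"""

from __future__ import annotations

from collections import Counter

from .alignment_io import Alignment, ConsensusSequence


def filter_sequences(
    aln: Alignment,
    cons: ConsensusSequence,
    min_fraction: float = 1.0 / 3.0,
) -> tuple[Alignment, list[str]]:
    """Discard records insufficiently similar to the consensus.

    A record is kept iff its count of positions equal to the consensus
    character (gap-vs-gap counts as a match) is strictly greater than
    ``min_fraction * L``.  The consensus is *not* recomputed afterwards:
    this is a single pass.

    Returns the surviving alignment and the list of discarded ids, in
    input order.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if cons.length != aln.length:
        raise ValueError("consensus length does not match alignment length")
    cutoff = min_fraction * aln.length
    kept: list[int] = []
    discarded: list[str] = []
    for i, (rid, seq) in enumerate(aln.records()):
        matches = sum(1 for a, b in zip(seq, cons.residues) if a == b)
        if matches > cutoff:
            kept.append(i)
        else:
            discarded.append(rid)
    if not kept:
        raise ValueError("all sequences discarded by the consensus filter")
    return aln.subset(kept), discarded


def informative_sites(
    aln: Alignment,
    min_types: int = 2,
    min_count: int = 5,
) -> list[int]:
    """1-based columns where covariance is observable.

    A site qualifies when at least ``min_types`` distinct non-gap residue
    types each occur in at least ``min_count`` sequences.  Gaps never count
    as a residue type.  Returns a sorted list of site indices.
    """
    if min_types < 2:
        raise ValueError(f"min_types must be >= 2, got {min_types}")
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    sites: list[int] = []
    for site in range(1, aln.length + 1):
        tally = Counter(c for c in aln.column(site) if c != aln.gap_char)
        frequent = sum(1 for n in tally.values() if n >= min_count)
        if frequent >= min_types:
            sites.append(site)
    return sites
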