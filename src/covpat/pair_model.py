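"""Independent covariant pair detection.

The atomic unit of the model is the *site-residue element*: one residue at
one aligned column, e.g. ``139-Q`` is glutamine at column 139.  Two elements
at different sites form a covariant pair when their occurrence sets across
the alignment overlap strongly.  The strength of the coupling is the
*purity*

    P(a, b) = 2 * n_ab / (n_a + n_b)

where ``n_a`` and ``n_b`` are the numbers of sequences carrying each
element and ``n_ab`` the number carrying both — the Sørensen–Dice
coefficient of the two occurrence sets.  P is 0 when the elements never
co-occur, 1 when their occurrence sets are identical, and 2/3 when all of
``a`` is coupled with half of ``b``; hence an actual correlation requires
P above 2/3 and the default detection threshold is 0.7.

A covariance between two *sites* is confirmed only when at least two
distinct element pairs connect them at or above the threshold: a single
qualifying pair cannot represent a substitution of one residue pair into
another and is treated as noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .alignment_io import Alignment

RATIONAL_PURITY_FLOOR = 2.0 / 3.0


class SiteResidueElement(NamedTuple):
    """One residue at one 1-based aligned column, e.g. ``Element(7, 'D')``."""

    site: int
    residue: str

    def __str__(self) -> str:  # "7-D" display form
        return f"{self.site}-{self.residue}"


# short alias used throughout the package
Element = SiteResidueElement


@dataclass(frozen=True)
class ElementIndex:
    """Occurrence sets of every site-residue element.

    ``occurrences`` maps an element to the frozen set of 0-based record
    positions carrying it; within one site these sets are pairwise
    disjoint (a sequence has exactly one character per column).
    """

    occurrences: dict[Element, frozenset[int]]

    def count(self, e: Element) -> int:
        return len(self.occurrences[e])

    def elements_at(self, site: int) -> list[Element]:
        return sorted(e for e in self.occurrences if e.site == site)

    @property
    def sites(self) -> list[int]:
        return sorted({e.site for e in self.occurrences})


@dataclass(frozen=True, order=True)
class CovariantPair:
    """Two elements at distinct sites with their purity and counts.

    Canonical orientation: ``a.site < b.site``.
    """

    a: Element
    b: Element
    purity: float
    n_a: int
    n_b: int
    n_ab: int

    def __post_init__(self) -> None:
        if self.a.site >= self.b.site:
            raise ValueError("pair must be canonically ordered: a.site < b.site")

    @property
    def sites(self) -> tuple[int, int]:
        return (self.a.site, self.b.site)

    def __str__(self) -> str:
        return f"({self.a} {self.b})"


def build_element_index(aln: Alignment, sites: Iterable[int]) -> ElementIndex:
    """Index every (site, non-gap residue) occurrence at the given sites.

    Gap positions contribute no element; a fully gapped column yields no
    elements at all.
    """
    occ: dict[Element, set[int]] = {}
    for site in sorted(set(sites)):
        col = aln.column(site)
        for i, c in enumerate(col):
            if c == aln.gap_char:
                continue
            occ.setdefault(Element(site, c), set()).add(i)
    return ElementIndex({e: frozenset(s) for e, s in occ.items()})


def purity(idx: ElementIndex, a: Element, b: Element) -> float:
    """Sørensen–Dice purity of two elements at distinct sites.

    Symmetric; in [0, 1]; 0 iff the elements never co-occur; 1 iff their
    occurrence sets are identical.  Raises ``KeyError`` for an element not
    in the index and ``ValueError`` for two elements at the same site.
    """
    if a.site == b.site:
        raise ValueError("purity is defined for elements at distinct sites")
    sa = idx.occurrences[a]
    sb = idx.occurrences[b]
    if not sa or not sb:
        raise ValueError("purity requires non-empty occurrence sets")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def detect_pairs(
    aln: Alignment,
    sites: Iterable[int],
    purity_threshold: float = 0.7,
    min_count: int = 5,
    index: Optional[ElementIndex] = None,
) -> list[CovariantPair]:
    """All element pairs across distinct sites with purity >= threshold.

    Both elements must occur in at least ``min_count`` sequences.  The
    threshold comparison is inclusive.  Thresholds outside the rational
    correlation range (2/3, 1] are allowed but provoke a warning — they
    admit couplings weaker than the all-with-half configuration.

    Output is canonically oriented (``a.site < b.site``) and sorted by
    (site_a, site_b, residue_a, residue_b), so the result is invariant
    under permutation of the input records.
    """
    if not 0.0 < purity_threshold <= 1.0:
        raise ValueError(f"purity_threshold must be in (0, 1], got {purity_threshold}")
    if purity_threshold <= RATIONAL_PURITY_FLOOR:
        warnings.warn(
            f"purity threshold {purity_threshold:g} is at or below the rational "
            f"floor 2/3; couplings weaker than all-with-half will be reported",
            stacklevel=2,
        )
    site_list = sorted(set(sites))
    if len(site_list) < 2:
        return []
    idx = index if index is not None else build_element_index(aln, site_list)
    per_site: dict[int, list[Element]] = {
        s: [e for e in idx.elements_at(s) if idx.count(e) >= min_count]
        for s in site_list
    }
    pairs: list[CovariantPair] = []
    for i, s1 in enumerate(site_list):
        for s2 in site_list[i + 1 :]:
            for a in per_site[s1]:
                sa = idx.occurrences[a]
                for b in per_site[s2]:
                    sb = idx.occurrences[b]
                    n_ab = len(sa & sb)
                    p = 2.0 * n_ab / (len(sa) + len(sb))
                    if p >= purity_threshold:
                        pairs.append(
                            CovariantPair(a, b, p, len(sa), len(sb), n_ab)
                        )
    pairs.sort(key=lambda p: (p.a.site, p.b.site, p.a.residue, p.b.residue))
    return pairs


def confirm_site_covariance(pairs: Iterable[CovariantPair], x: int, y: int) -> bool:
    """True iff sites x and y are connected by >= 2 distinct qualifying pairs.

    A covariance event transforms one residue pair into another, so at
    least two element pairs must reach the threshold simultaneously; a
    site pair carried by a single qualifying pair is noise.
    """
    lo, hi = min(x, y), max(x, y)
    n = sum(1 for p in pairs if p.sites == (lo, hi))
    return n >= 2


def confirmed_pairs(pairs: Iterable[CovariantPair]) -> list[CovariantPair]:
    """Restrict a detect_pairs result to pairs at confirmed site pairs."""
    pairs = list(pairs)
    tally: dict[tuple[int, int], int] = {}
    for p in pairs:
        tally[p.sites] = tally.get(p.sites, 0) + 1
    return [p for p in pairs if tally[p.sites] >= 2]


def pairs_to_frame(pairs: Iterable[CovariantPair]) -> pd.DataFrame:
    """Tabulate pairs for TSV output, flagging confirmed site pairs."""
    pairs = list(pairs)
    keep = {p.sites for p in confirmed_pairs(pairs)}
    rows = [
        {
            "site_a": p.a.site,
            "residue_a": p.a.residue,
            "site_b": p.b.site,
            "residue_b": p.b.residue,
            "n_a": p.n_a,
            "n_b": p.n_b,
            "n_ab": p.n_ab,
            "purity": round(p.purity, 6),
            "confirmed": p.sites in keep,
        }
        for p in pairs
    ]
    cols = [
        "site_a", "residue_a", "site_b", "residue_b",
        "n_a", "n_b", "n_ab", "purity", "confirmed",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_pairs_tsv(pairs: Iterable[CovariantPair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
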