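"""Correlated tandem model: from confirmed pairs to multi-site patterns.

Confirmed covariant pairs sharing a common site-residue element are joined
into groups (connected components of the element graph).  Each group is
transformed into a symmetric matrix of pairwise purities over its elements;
the *association degree* of an element is the mean of its off-diagonal row,
i.e. its average purity to the other elements of the group.  While the
smallest degree ``d_m`` falls below a threshold (0.7 by default, matching
the pair threshold), the corresponding element is removed and the degrees
are recomputed; the elements that survive — at least three of them, at most
one per site — constitute a covariant pattern, reported in the
``(1-A 6-T 7-V)`` format.  Patterns whose element set is contained in
another reported pattern are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .pair_model import CovariantPair, Element, ElementIndex, purity

#: divisor convention for the association degree: the mean runs over the
#: n-1 off-diagonal entries of an element's row (self-purity excluded).
DEGREE_DIVISOR_EXCLUDES_SELF = True


@dataclass(frozen=True)
class PairGroup:
    """A connected component of the element graph built from confirmed pairs."""

    group_id: int
    elements: tuple[Element, ...]
    member_pairs: tuple[CovariantPair, ...]


@dataclass(frozen=True)
class PurityMatrix:
    """Symmetric pairwise purities over an ordered element list.

    Entries for two elements at the same site are 0 by construction (their
    occurrence sets are disjoint).  The diagonal is never used.
    """

    elements: tuple[Element, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.elements)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match element count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("purity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.elements)

    def submatrix(self, keep: Sequence[int]) -> "PurityMatrix":
        keep = list(keep)
        return PurityMatrix(
            tuple(self.elements[i] for i in keep),
            self.values[np.ix_(keep, keep)],
        )


@dataclass(frozen=True)
class CovariantPattern:
    """A set of >=3 elements, one per site, surviving degree pruning.

    ``min_purity`` (the smallest pairwise purity among the elements) and
    ``degrees`` (each element's terminal association degree) are reporting
    metadata and do not participate in pattern identity.
    """

    elements: tuple[Element, ...]
    group_id: int = 0
    min_purity: float = field(default=float("nan"), compare=False)
    degrees: tuple[float, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        sites = [e.site for e in self.elements]
        if sites != sorted(sites):
            object.__setattr__(
                self, "elements", tuple(sorted(self.elements, key=lambda e: e.site))
            )
            sites = [e.site for e in self.elements]
        if len(set(sites)) != len(sites):
            raise ValueError("pattern has two elements at one site")

    @property
    def size(self) -> int:
        return len(self.elements)

    @property
    def element_set(self) -> frozenset[Element]:
        return frozenset(self.elements)

    def __str__(self) -> str:
        return format_pattern(self)


def format_pattern(p: CovariantPattern) -> str:
    """Render a pattern as ``(s1-R1 s2-R2 ...)``, sites ascending, 1-based."""
    return "(" + " ".join(str(e) for e in p.elements) + ")"


def parse_pattern(text: str, group_id: int = 0) -> CovariantPattern:
    """Inverse of :func:`format_pattern`, e.g. ``"(1-A 6-T 7-V)"``."""
    body = text.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    elements = []
    for token in body.split():
        site, _, residue = token.partition("-")
        if not residue:
            raise ValueError(f"malformed pattern token {token!r}")
        elements.append(Element(int(site), residue))
    return CovariantPattern(tuple(elements), group_id=group_id)


def build_groups(pairs: Iterable[CovariantPair]) -> list[PairGroup]:
    """Connected components of the graph (nodes=elements, edges=pairs).

    Every confirmed pair belongs to exactly one group.  Groups are numbered
    from 1 in order of their smallest (site, residue) member, so the output
    is deterministic.
    """
    pairs = list(pairs)
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.a, p.b)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: c[0],
    )
    groups: list[PairGroup] = []
    for gid, comp in enumerate(comps, start=1):
        comp_set = set(comp)
        members = tuple(p for p in pairs if p.a in comp_set)
        groups.append(PairGroup(gid, tuple(comp), members))
    return groups


def purity_matrix(group_elements: Sequence[Element], idx: ElementIndex) -> PurityMatrix:
    """Full pairwise purity matrix over a group's elements.

    Every off-diagonal entry is the actual purity computed from the
    alignment — including for element pairs that were never detected as
    covariant pairs.  Same-site entries come out 0 because per-site
    occurrence sets are disjoint.
    """
    elements = tuple(group_elements)
    n = len(elements)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if elements[i].site == elements[j].site:
                p = 0.0
            else:
                p = purity(idx, elements[i], elements[j])
            m[i, j] = m[j, i] = p
    return PurityMatrix(elements, m)


def association_degrees(m: PurityMatrix) -> tuple[np.ndarray, float]:
    """Per-element association degrees and their minimum ``d_m``.

    The degree of an element is the mean of the n-1 off-diagonal purities
    in its row: its average association with the other elements of the
    current matrix.  Requires n >= 2.
    """
    if m.n < 2:
        raise ValueError("association degrees need at least 2 elements")
    off_sum = m.values.sum(axis=1) - np.diag(m.values)
    degrees = off_sum / (m.n - 1)
    return degrees, float(degrees.min())


def _removal_choice(m: PurityMatrix, candidates: Sequence[int]) -> int:
    # among tied minimum-degree elements: largest site, then
    # lexicographically largest residue
    return max(candidates, key=lambda i: (m.elements[i].site, m.elements[i].residue))


def prune_group(
    m: PurityMatrix,
    degree_threshold: float = 0.7,
    min_size: int = 3,
    group_id: int = 0,
) -> Optional[CovariantPattern]:
    """Iteratively remove the weakest element until all degrees pass.

    Each round recomputes the degrees and removes the single element
    achieving the minimum degree ``d_m`` while ``d_m < degree_threshold``
    (ties: largest site, then lexicographically largest residue).  Once all
    degrees are at or above the threshold, per-site uniqueness is enforced
    by removing the lower-degree of any two same-site survivors and
    continuing.  Returns the surviving elements as a pattern if at least
    ``min_size`` remain, else ``None``.
    """
    cur = m
    while True:
        if cur.n < min_size:
            return None
        degrees, d_m = association_degrees(cur)
        if d_m < degree_threshold:
            tied = [i for i in range(cur.n) if degrees[i] == d_m]
            drop = _removal_choice(cur, tied)
            cur = cur.submatrix([i for i in range(cur.n) if i != drop])
            continue
        dup = _duplicate_site_victim(cur, degrees)
        if dup is not None:
            cur = cur.submatrix([i for i in range(cur.n) if i != dup])
            continue
        break
    degrees, _ = association_degrees(cur)
    by_element = dict(zip(cur.elements, degrees))
    ordered = tuple(sorted(cur.elements, key=lambda e: e.site))
    return CovariantPattern(
        ordered,
        group_id=group_id,
        min_purity=_min_off_diagonal(cur),
        degrees=tuple(float(by_element[e]) for e in ordered),
    )


def _duplicate_site_victim(m: PurityMatrix, degrees: np.ndarray) -> Optional[int]:
    by_site: dict[int, list[int]] = {}
    for i, e in enumerate(m.elements):
        by_site.setdefault(e.site, []).append(i)
    for site in sorted(by_site):
        idxs = by_site[site]
        if len(idxs) > 1:
            # remove the lowest-degree duplicate; ties resolved like pruning
            worst = min(degrees[i] for i in idxs)
            tied = [i for i in idxs if degrees[i] == worst]
            return _removal_choice(m, tied)
    return None


def _min_off_diagonal(m: PurityMatrix) -> float:
    if m.n < 2:
        return float("nan")
    vals = m.values[~np.eye(m.n, dtype=bool)]
    return float(vals.min())


def harvest_patterns(
    pairs: Iterable[CovariantPair],
    idx: ElementIndex,
    degree_threshold: float = 0.7,
    min_size: int = 3,
) -> list[CovariantPattern]:
    """Full tandem pass: group, prune, split, and deduplicate.

    ``pairs`` must already be confirmed (>=2 element pairs per site pair).
    After pruning, survivors that are no longer connected in the
    confirmed-pair graph are split into components, each re-pruned on its
    own matrix.  Subset patterns are removed at the end.
    """
    groups = build_groups(pairs)
    edge_set = {frozenset((p.a, p.b)) for p in pairs}
    patterns: list[CovariantPattern] = []
    for group in groups:
        patterns.extend(
            _harvest_component(
                group.elements, idx, edge_set, degree_threshold, min_size, group.group_id
            )
        )
    return remove_subset_patterns(patterns)


def _harvest_component(
    elements: Sequence[Element],
    idx: ElementIndex,
    edge_set: set[frozenset[Element]],
    degree_threshold: float,
    min_size: int,
    group_id: int,
) -> list[CovariantPattern]:
    if len(elements) < min_size:
        return []
    m = purity_matrix(elements, idx)
    pat = prune_group(m, degree_threshold, min_size, group_id)
    if pat is None:
        return []
    surv = set(pat.elements)
    g = nx.Graph()
    g.add_nodes_from(surv)
    for e in edge_set:
        a, b = tuple(e)
        if a in surv and b in surv:
            g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    if len(comps) == 1:
        return [pat]
    out: list[CovariantPattern] = []
    for comp in sorted(comps, key=lambda c: c[0]):
        out.extend(
            _harvest_component(comp, idx, edge_set, degree_threshold, min_size, group_id)
        )
    return out


def remove_subset_patterns(patterns: Iterable[CovariantPattern]) -> list[CovariantPattern]:
    """Drop duplicates and proper subsets; sort by (size desc, first site asc)."""
    unique: dict[frozenset[Element], CovariantPattern] = {}
    for p in patterns:
        unique.setdefault(p.element_set, p)
    kept = [
        p
        for key, p in unique.items()
        if not any(key < other for other in unique if other != key)
    ]
    kept.sort(key=lambda p: (-p.size, p.elements[0].site, str(p)))
    return kept


def patterns_to_frame(patterns: Iterable[CovariantPattern]) -> pd.DataFrame:
    rows = [
        {
            "pattern_id": i,
            "group_id": p.group_id,
            "size": p.size,
            "pattern": format_pattern(p),
            "min_purity": round(p.min_purity, 6),
            "degrees": ",".join(f"{d:.6g}" for d in p.degrees),
        }
        for i, p in enumerate(patterns, start=1)
    ]
    cols = ["pattern_id", "group_id", "size", "pattern", "min_purity", "degrees"]
    return pd.DataFrame(rows, columns=cols)


def write_patterns_tsv(patterns: Iterable[CovariantPattern], path) -> None:
    patterns_to_frame(patterns).to_csv(path, sep="\t", index=False)


def read_patterns_tsv(path) -> list[CovariantPattern]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        p = parse_pattern(row["pattern"], group_id=int(row.get("group_id", 0)))
        out.append(p)
    return out
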