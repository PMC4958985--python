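"""Synthetic alignments with planted covariant structure.

The generator emulates the situation the detector is built for: a common
consensus background with independent per-site substitution noise, and two
or more subpopulations ("classes", think viral genotypes) each carrying a
planted tuple of site-residue elements.  Within a class only a configurable
fraction of members — the *carriers* — receive the full planted tuple;
the rest keep pure background at the pattern sites.  Optional gaps are
inserted independently per position.

Two deliberate simplifications keep ground truth exact:

* substitutions are iid uniform over alternative residues — there is no
  phylogeny, so no background correlation between columns;
* at a planted site, noise never draws a planted residue (of any class),
  so the occurrence count of every planted element equals its configured
  carrier count exactly (at gap rate 0) and pairwise purities have a
  closed form (:func:`expected_pattern_purity`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment_io import Alignment, NUCLEOTIDE, PROTEIN
from .pair_model import Element
from .tandem_model import CovariantPattern, format_pattern

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


def _letters(alphabet: str) -> str:
    if alphabet == PROTEIN:
        return AMINO_ACIDS
    if alphabet == NUCLEOTIDE:
        return NUCLEOTIDES
    raise ValueError(f"unknown alphabet {alphabet!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic alignment.

    ``class_patterns`` maps a class label to its planted element tuple;
    ``carrier_purity`` is the fraction of class members carrying the full
    tuple.  ``consensus`` may be supplied or left ``None`` to be drawn
    uniformly from the alphabet.
    """

    class_sizes: dict[str, int]
    class_patterns: dict[str, tuple[Element, ...]]
    length: int = 60
    alphabet: str = PROTEIN
    consensus: Optional[str] = None
    substitution_rate: float = 0.05
    carrier_purity: float = 0.9
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_patterns) - set(self.class_sizes):
            raise ValueError("pattern classes must be a subset of sized classes")
        if not 0.0 < self.carrier_purity <= 1.0:
            raise ValueError("carrier_purity must be in (0, 1]")
        for rate, name in ((self.substitution_rate, "substitution_rate"), (self.gap_rate, "gap_rate")):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for cls, pattern in self.class_patterns.items():
            sites = [e.site for e in pattern]
            if len(set(sites)) != len(sites):
                raise ValueError(f"class {cls!r}: planted pattern repeats a site")
            if any(not 1 <= s <= self.length for s in sites):
                raise ValueError(f"class {cls!r}: pattern site outside 1..{self.length}")
        if self.consensus is not None and len(self.consensus) != self.length:
            raise ValueError("consensus length differs from alignment length")

    def n_carriers(self, cls: str) -> int:
        """Carrier count: carrier_purity x class size, half rounded up."""
        return int(math.floor(self.carrier_purity * self.class_sizes[cls] + 0.5))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated alignment."""

    labels: dict[str, str]
    patterns: dict[str, CovariantPattern]
    carriers: dict[str, tuple[str, ...]] = field(repr=False)
    consensus: str = ""

    def to_json(self) -> str:
        payload = {
            "labels": self.labels,
            "patterns": {cls: format_pattern(p) for cls, p in self.patterns.items()},
            "carriers": {cls: list(ids) for cls, ids in self.carriers.items()},
            "consensus": self.consensus,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _planted_by_site(cfg: SimulationConfig) -> dict[int, set[str]]:
    planted: dict[int, set[str]] = {}
    for pattern in cfg.class_patterns.values():
        for e in pattern:
            planted.setdefault(e.site, set()).add(e.residue)
    return planted


def generate(cfg: SimulationConfig) -> tuple[Alignment, SyntheticTruth]:
    """Draw one alignment + ground truth, reproducibly from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    letters = _letters(cfg.alphabet)
    L = cfg.length
    if cfg.consensus is None:
        cons = "".join(rng.choice(list(letters), size=L))
    else:
        cons = cfg.consensus.upper()
    planted = _planted_by_site(cfg)
    for site, residues in planted.items():
        if cons[site - 1] in residues:
            raise ValueError(
                f"planted residue {cons[site - 1]!r} at site {site} equals the consensus"
            )
    # per-column substitution alternatives: everything but the consensus
    # residue and any planted residue at that column
    alternatives: list[list[str]] = []
    for j in range(L):
        banned = {cons[j]} | planted.get(j + 1, set())
        alts = [c for c in letters if c not in banned]
        if not alts:
            raise ValueError(f"no substitution alternatives left at site {j + 1}")
        alternatives.append(alts)

    classes = sorted(cfg.class_sizes)
    ids: list[str] = []
    labels: dict[str, str] = {}
    rows: list[tuple[str, int]] = []  # (class, within-class index)
    for cls in classes:
        for i in range(cfg.class_sizes[cls]):
            sid = f"{cls}_{i:04d}"
            ids.append(sid)
            labels[sid] = cls
            rows.append((cls, i))
    n = len(ids)

    mat = np.full((n, L), "?", dtype="<U1")
    for j in range(L):
        mat[:, j] = cons[j]
    noise = rng.random((n, L)) < cfg.substitution_rate
    for j in range(L):
        hit = np.flatnonzero(noise[:, j])
        if hit.size:
            mat[hit, j] = rng.choice(alternatives[j], size=hit.size)

    carriers: dict[str, tuple[str, ...]] = {}
    offset = 0
    for cls in classes:
        size = cfg.class_sizes[cls]
        pattern = cfg.class_patterns.get(cls, ())
        if pattern:
            n_c = cfg.n_carriers(cls)
            chosen = np.sort(rng.choice(size, size=n_c, replace=False))
            for e in pattern:
                mat[offset + chosen, e.site - 1] = e.residue
            carriers[cls] = tuple(ids[offset + i] for i in chosen)
        offset += size

    if cfg.gap_rate > 0.0:
        gaps = rng.random((n, L)) < cfg.gap_rate
        mat[gaps] = "-"

    seqs = tuple("".join(row) for row in mat)
    aln = Alignment(tuple(ids), seqs, alphabet=cfg.alphabet)
    truth = SyntheticTruth(
        labels=labels,
        patterns={
            cls: CovariantPattern(tuple(sorted(p, key=lambda e: e.site)))
            for cls, p in cfg.class_patterns.items()
            if p
        },
        carriers=carriers,
        consensus=cons,
    )
    return aln, truth


def expected_pattern_purity(
    cfg: SimulationConfig,
) -> dict[str, dict[tuple[Element, Element], float]]:
    """Closed-form expected Dice purity between planted elements, per class.

    Because background noise never draws a planted residue, a planted
    element occurs exactly in the carriers of every class whose pattern
    contains it.  For elements a, b of one class's pattern,

        P = 2 * n_ab / (n_a + n_b)

    with n_e the summed carrier counts over classes planting e, and n_ab
    the summed carrier counts over classes planting both.  Holds exactly
    at gap rate 0.
    """
    carrier_counts = {cls: cfg.n_carriers(cls) for cls in cfg.class_patterns}
    containing: dict[Element, set[str]] = {}
    for cls, pattern in cfg.class_patterns.items():
        for e in pattern:
            containing.setdefault(e, set()).add(cls)
    out: dict[str, dict[tuple[Element, Element], float]] = {}
    for cls, pattern in cfg.class_patterns.items():
        per_pair: dict[tuple[Element, Element], float] = {}
        ordered = sorted(pattern, key=lambda e: e.site)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                n_a = sum(carrier_counts[c] for c in containing[a])
                n_b = sum(carrier_counts[c] for c in containing[b])
                n_ab = sum(carrier_counts[c] for c in containing[a] & containing[b])
                per_pair[(a, b)] = 2.0 * n_ab / (n_a + n_b)
        out[cls] = per_pair
    return out


def make_demo_config(
    seed: int = 0,
    class_sizes: Sequence[int] = (167, 167, 166),
    pattern_sizes: Sequence[int] = (3, 4, 5),
    length: int = 60,
    substitution_rate: float = 0.05,
    carrier_purity: float = 0.9,
    gap_rate: float = 0.0,
    alphabet: str = PROTEIN,
) -> SimulationConfig:
    """Default study conditions: 500 sequences of length 60 in three
    classes planting disjoint 3-, 4- and 5-site patterns at carrier purity
    0.9 over 5% background noise.

    Pattern sites, the consensus and planted residues are drawn from a
    dedicated RNG stream so that ``generate`` (seeded with ``seed``)
    remains independent of the construction order here.
    """
    if len(class_sizes) != len(pattern_sizes):
        raise ValueError("need one pattern size per class")
    rng = np.random.default_rng([seed, 9173])
    letters = _letters(alphabet)
    cons = "".join(rng.choice(list(letters), size=length))
    total_sites = sum(pattern_sizes)
    if total_sites > length:
        raise ValueError("more pattern sites than columns")
    all_sites = 1 + np.sort(rng.choice(length, size=total_sites, replace=False))
    class_labels = [chr(ord("A") + i) for i in range(len(class_sizes))]
    patterns: dict[str, tuple[Element, ...]] = {}
    cursor = 0
    for cls, k in zip(class_labels, pattern_sizes):
        elements = []
        for site in all_sites[cursor : cursor + k]:
            site = int(site)
            choices = [c for c in letters if c != cons[site - 1]]
            elements.append(Element(site, str(rng.choice(choices))))
        patterns[cls] = tuple(elements)
        cursor += k
    return SimulationConfig(
        class_sizes=dict(zip(class_labels, class_sizes)),
        class_patterns=patterns,
        length=length,
        alphabet=alphabet,
        consensus=cons,
        substitution_rate=substitution_rate,
        carrier_purity=carrier_purity,
        gap_rate=gap_rate,
        seed=seed,
    )
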