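"""End-to-end detection pipeline: preprocessing -> pairs -> patterns."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .alignment_io import Alignment, ConsensusSequence, consensus
from .pair_model import (
    CovariantPair,
    ElementIndex,
    build_element_index,
    confirmed_pairs,
    detect_pairs,
)
from .preprocess import filter_sequences, informative_sites
from .tandem_model import CovariantPattern, harvest_patterns


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the detection pipeline with their defaults."""

    min_consensus_fraction: float = 1.0 / 3.0
    min_residue_count: int = 5
    purity_threshold: float = 0.7
    degree_threshold: float = 0.7
    min_pattern_size: int = 3


@dataclass(frozen=True)
class DetectionResult:
    alignment: Alignment  # records surviving the consensus filter
    consensus: ConsensusSequence
    discarded_ids: tuple[str, ...]
    sites: tuple[int, ...]
    index: ElementIndex = field(repr=False)
    pairs: tuple[CovariantPair, ...]  # all pairs >= purity threshold
    confirmed: tuple[CovariantPair, ...]  # pairs at confirmed site pairs
    patterns: tuple[CovariantPattern, ...]


def run_detection(
    aln: Alignment, params: Optional[DetectionParams] = None
) -> DetectionResult:
    """Run the full covariance analysis on an alignment.

    Sequence filtering uses the consensus of the *input* alignment; site
    screening and all statistics run on the surviving records.
    """
    params = params or DetectionParams()
    cons = consensus(aln)
    kept, discarded = filter_sequences(aln, cons, params.min_consensus_fraction)
    sites = informative_sites(kept, min_count=params.min_residue_count)
    idx = build_element_index(kept, sites)
    pairs = detect_pairs(
        kept,
        sites,
        purity_threshold=params.purity_threshold,
        min_count=params.min_residue_count,
        index=idx,
    )
    confirmed = confirmed_pairs(pairs)
    patterns = harvest_patterns(
        confirmed,
        idx,
        degree_threshold=params.degree_threshold,
        min_size=params.min_pattern_size,
    )
    return DetectionResult(
        alignment=kept,
        consensus=cons,
        discarded_ids=tuple(discarded),
        sites=tuple(sites),
        index=idx,
        pairs=tuple(pairs),
        confirmed=tuple(confirmed),
        patterns=tuple(patterns),
    )
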