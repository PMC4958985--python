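"""Pattern-based sequence classification and its evaluation.

Every covariant pattern characterises one subpopulation, so a *loose* fit
suffices for classification: a sequence joins a pattern's cluster when at
least 45% of the pattern's sites carry the pattern's residues (gaps never
match).  A sequence may join several clusters, clusters may overlap, and
sequences matching nothing are reported as unassigned.

Against known labels (e.g. genotypes) the clusters are scored with the
standard confusion-matrix indexes

    Sen = TP / (TP + FN),  Spe = TN / (TN + FP),
    Acc = (TP + TN) / (TP + TN + FP + FN)

per class, macro-averaged over classes.  A stratified k-fold
cross-validation harness (k=10 by default) re-detects patterns on each
training split, maps each pattern to the majority class of its training
cluster, picks each class's best pattern by training accuracy, and scores
the held-out split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .alignment_io import Alignment
from .pipeline import DetectionParams, run_detection
from .tandem_model import CovariantPattern, format_pattern


def match_fraction(seq: str, pattern: CovariantPattern, gap_char: str = "-") -> float:
    """Fraction of a pattern's elements present in an aligned sequence.

    An element matches when the sequence carries exactly its residue at its
    site; a gap never matches.  Raises ``IndexError`` when a pattern site
    lies beyond the sequence length.
    """
    last = pattern.elements[-1].site
    if last > len(seq):
        raise IndexError(
            f"pattern site {last} beyond sequence length {len(seq)}"
        )
    hits = sum(
        1 for e in pattern.elements if seq[e.site - 1] == e.residue and e.residue != gap_char
    )
    return hits / pattern.size


@dataclass(frozen=True)
class ClusterAssignment:
    """Multi-label cluster membership of sequences under a pattern set.

    ``memberships`` maps 1-based pattern ids (positions in the pattern
    list) to ``(sequence_id, match_fraction)`` members; ``by_sequence``
    is the inverse view; ``unassigned`` lists sequences matching no
    pattern at the threshold.
    """

    memberships: dict[int, tuple[tuple[str, float], ...]]
    by_sequence: dict[str, tuple[int, ...]]
    unassigned: tuple[str, ...]
    min_match: float


def assign_clusters(
    aln: Alignment,
    patterns: Sequence[CovariantPattern],
    min_match: float = 0.45,
    best_only: bool = False,
) -> ClusterAssignment:
    """Assign each sequence to every pattern it matches at ``min_match``.

    The threshold comparison is inclusive (45% *or more* by default).
    With ``best_only`` a sequence joins only its best-matching cluster
    (ties: the lower pattern id).
    """
    if not patterns:
        raise ValueError("assign_clusters requires a non-empty pattern list")
    memberships: dict[int, list[tuple[str, float]]] = {
        pid: [] for pid in range(1, len(patterns) + 1)
    }
    by_sequence: dict[str, tuple[int, ...]] = {}
    unassigned: list[str] = []
    for sid, seq in aln.records():
        fracs = [
            (pid, match_fraction(seq, pat, aln.gap_char))
            for pid, pat in enumerate(patterns, start=1)
        ]
        hits = [(pid, f) for pid, f in fracs if f >= min_match]
        if best_only and hits:
            hits = [max(hits, key=lambda h: (h[1], -h[0]))]
        for pid, f in hits:
            memberships[pid].append((sid, f))
        by_sequence[sid] = tuple(pid for pid, _ in hits)
        if not hits:
            unassigned.append(sid)
    return ClusterAssignment(
        memberships={pid: tuple(m) for pid, m in memberships.items()},
        by_sequence=by_sequence,
        unassigned=tuple(unassigned),
        min_match=min_match,
    )


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class confusion counts with macro-averaged indexes."""

    per_class: dict[str, ClassMetrics]

    @property
    def macro_sensitivity(self) -> float:
        return mean(m.sensitivity for m in self.per_class.values())

    @property
    def macro_specificity(self) -> float:
        return mean(m.specificity for m in self.per_class.values())

    @property
    def macro_accuracy(self) -> float:
        return mean(m.accuracy for m in self.per_class.values())


def evaluate(
    assign: ClusterAssignment,
    labels: dict[str, str],
    pattern_to_class: dict[int, str],
) -> EvaluationReport:
    """Score cluster membership against known labels.

    For each class, membership in any cluster whose pattern maps to the
    class counts as a positive call.  Every sequence in the assignment
    must be labeled; a pattern mapped to a class absent from the labels,
    or a class without any labeled member, is an error (its sensitivity
    would be undefined).
    """
    classes = sorted(set(labels.values()))
    for pid, cls in pattern_to_class.items():
        if cls not in classes:
            raise ValueError(f"pattern {pid} mapped to unknown class {cls!r}")
    missing = [sid for sid in assign.by_sequence if sid not in labels]
    if missing:
        raise ValueError(f"unlabeled sequences, e.g. {missing[0]!r}")
    per_class: dict[str, ClassMetrics] = {}
    for cls in classes:
        pos_pids = {pid for pid, c in pattern_to_class.items() if c == cls}
        tp = fp = fn = tn = 0
        for sid, pids in assign.by_sequence.items():
            called = any(pid in pos_pids for pid in pids)
            truth = labels[sid] == cls
            if truth and called:
                tp += 1
            elif truth:
                fn += 1
            elif called:
                fp += 1
            else:
                tn += 1
        if tp + fn == 0:
            raise ValueError(f"class {cls!r} has no labeled members")
        per_class[cls] = ClassMetrics(tp, fp, fn, tn)
    return EvaluationReport(per_class)


@dataclass(frozen=True)
class CrossValidationReport:
    """Mean +/- sd of the macro indexes across folds."""

    folds: tuple[EvaluationReport, ...]

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = [getattr(f, attr) for f in self.folds]
        sd = stdev(vals) if len(vals) > 1 else 0.0
        return mean(vals), sd

    @property
    def macro_sensitivity(self) -> tuple[float, float]:
        return self._agg("macro_sensitivity")

    @property
    def macro_specificity(self) -> tuple[float, float]:
        return self._agg("macro_specificity")

    @property
    def macro_accuracy(self) -> tuple[float, float]:
        return self._agg("macro_accuracy")


def majority_class(
    members: Iterable[tuple[str, float]], labels: dict[str, str]
) -> Optional[str]:
    """Dominant label among cluster members; ties by smallest label."""
    tally: dict[str, int] = {}
    for sid, _ in members:
        cls = labels[sid]
        tally[cls] = tally.get(cls, 0) + 1
    if not tally:
        return None
    return min(tally, key=lambda c: (-tally[c], c))


def select_class_patterns(
    train: Alignment,
    patterns: Sequence[CovariantPattern],
    labels: dict[str, str],
    min_match: float = 0.45,
) -> dict[str, CovariantPattern]:
    """Pick each class's best pattern on a training alignment.

    A pattern is attributed to the majority class of its training cluster;
    among a class's patterns the one whose cluster maximises the class's
    accuracy wins (ties: larger pattern, then smaller first site).
    """
    if not patterns:
        return {}
    assign = assign_clusters(train, patterns, min_match=min_match)
    best: dict[str, tuple[float, int, int, CovariantPattern]] = {}
    for pid, pat in enumerate(patterns, start=1):
        cls = majority_class(assign.memberships[pid], labels)
        if cls is None:
            continue
        report = evaluate(assign, labels, {pid: cls})
        acc = report.per_class[cls].accuracy
        key = (acc, pat.size, -pat.elements[0].site)
        if cls not in best or key > best[cls][:3]:
            best[cls] = (acc, pat.size, -pat.elements[0].site, pat)
    return {cls: entry[3] for cls, entry in best.items()}


def cross_validate(
    aln: Alignment,
    labels: dict[str, str],
    k: int = 10,
    seed: int = 0,
    params: Optional[DetectionParams] = None,
    min_match: float = 0.45,
) -> CrossValidationReport:
    """Stratified k-fold cross-validation of pattern-based genotyping.

    Each class is split into k equal parts; fold i tests on part i of
    every class and trains on the rest.  Per fold, patterns are detected
    on the training records only, each class's best pattern is chosen by
    training accuracy, and the held-out records are classified and scored.
    Fully deterministic for a fixed seed.
    """
    missing = [sid for sid in aln.ids if sid not in labels]
    if missing:
        raise ValueError(f"unlabeled sequences, e.g. {missing[0]!r}")
    y = np.array([labels[sid] for sid in aln.ids])
    counts = pd.Series(y).value_counts()
    small = counts[counts < k]
    if not small.empty:
        raise ValueError(
            f"class {small.index[0]!r} has {int(small.iloc[0])} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[EvaluationReport] = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = aln.subset(train_idx)
        test = aln.subset(test_idx)
        result = run_detection(train, params)
        chosen = select_class_patterns(
            result.alignment, result.patterns, labels, min_match=min_match
        )
        test_labels = {sid: labels[sid] for sid in test.ids}
        if chosen:
            classes = sorted(chosen)
            pats = [chosen[c] for c in classes]
            assign = assign_clusters(test, pats, min_match=min_match)
            mapping = {pid: cls for pid, cls in enumerate(classes, start=1)}
        else:  # no pattern survived on this training split: all-negative calls
            assign = ClusterAssignment({}, {sid: () for sid in test.ids}, tuple(test.ids), min_match)
            mapping = {}
        folds.append(evaluate(assign, test_labels, mapping))
    return CrossValidationReport(tuple(folds))


def subsample(
    aln: Alignment, labels: dict[str, str], fraction: float, seed: int = 0
) -> tuple[Alignment, dict[str, str]]:
    """Stratified random subsample for different-scale testing.

    Per class, ``round(fraction * size)`` records are drawn without
    replacement (half rounds up, never fewer than one per class).
    ``fraction=1`` is the identity.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return aln, labels
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, sid in enumerate(aln.ids):
        by_class.setdefault(labels[sid], []).append(i)
    chosen: list[int] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        size = max(1, math.floor(fraction * len(members) + 0.5))
        chosen.extend(rng.choice(members, size=size, replace=False))
    chosen.sort()
    sub = aln.subset(chosen)
    return sub, {sid: labels[sid] for sid in sub.ids}


def clusters_to_frame(
    assign: ClusterAssignment,
    patterns: Sequence[CovariantPattern],
    labels: Optional[dict[str, str]] = None,
    pattern_to_class: Optional[dict[int, str]] = None,
) -> pd.DataFrame:
    rows = []
    for pid, members in sorted(assign.memberships.items()):
        for sid, frac in members:
            rows.append(
                {
                    "pattern_id": pid,
                    "pattern": format_pattern(patterns[pid - 1]),
                    "class": (pattern_to_class or {}).get(pid, ""),
                    "sequence_id": sid,
                    "label": (labels or {}).get(sid, ""),
                    "match_fraction": round(frac, 6),
                }
            )
    cols = ["pattern_id", "pattern", "class", "sequence_id", "label", "match_fraction"]
    return pd.DataFrame(rows, columns=cols)


def report_to_text(report: EvaluationReport) -> str:
    lines = ["class\tTP\tFP\tFN\tTN\tSen\tSpe\tAcc"]
    for cls, m in sorted(report.per_class.items()):
        lines.append(
            f"{cls}\t{m.tp}\t{m.fp}\t{m.fn}\t{m.tn}"
            f"\t{m.sensitivity:.4f}\t{m.specificity:.4f}\t{m.accuracy:.4f}"
        )
    lines.append(
        "macro\t-\t-\t-\t-"
        f"\t{report.macro_sensitivity:.4f}"
        f"\t{report.macro_specificity:.4f}"
        f"\t{report.macro_accuracy:.4f}"
    )
    return "\n".join(lines) + "\n"


def cv_report_to_text(report: CrossValidationReport) -> str:
    sen, sen_sd = report.macro_sensitivity
    spe, spe_sd = report.macro_specificity
    acc, acc_sd = report.macro_accuracy
    lines = [
        f"folds\t{len(report.folds)}",
        f"macro_sensitivity\t{sen:.4f} +/- {sen_sd:.4f}",
        f"macro_specificity\t{spe:.4f} +/- {spe_sd:.4f}",
        f"macro_accuracy\t{acc:.4f} +/- {acc_sd:.4f}",
    ]
    return "\n".join(lines) + "\n"


__all__ = [
    "match_fraction",
    "ClusterAssignment",
    "assign_clusters",
    "ClassMetrics",
    "EvaluationReport",
    "evaluate",
    "CrossValidationReport",
    "cross_validate",
    "select_class_patterns",
    "majority_class",
    "subsample",
    "clusters_to_frame",
    "report_to_text",
    "cv_report_to_text",
]
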