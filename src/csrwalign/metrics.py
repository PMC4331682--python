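"""Alignment evaluation: accuracy, expected accuracy, and the
functional-coherence / conserved-interaction metric suite.

Accuracy compares the cross-network node pairs induced by an alignment
against those induced by a reference alignment.  The class-level metrics
(CN, SPE, MNE, CI, COI, coverage) follow the usual equivalence-class
evaluation protocol: unannotated nodes are removed first, then classes left
with fewer than two nodes or spanning a single network are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .consistency import CorrespondenceSet
from .netio import Alignment, AnnotationMap, NetworkSet

__all__ = [
    "MetricsReport",
    "induced_pairs",
    "alignment_accuracy",
    "expected_accuracy",
    "filter_classes",
    "class_metrics",
    "mean_normalized_entropy",
    "conserved_interactions",
    "coverage_profile",
    "evaluate",
]

Member = tuple[str, str]
Pair = frozenset[Member]


def induced_pairs(alignment: Alignment) -> set[Pair]:
    """All cross-network member pairs implied by the alignment's classes."""
    pairs: set[Pair] = set()
    for cls in alignment.classes:
        members = sorted(cls)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[i][0] != members[j][0]:
                    pairs.add(frozenset((members[i], members[j])))
    return pairs


def alignment_accuracy(alignment: Alignment, truth: Alignment) -> float:
    """Fraction of the alignment's induced pairs present in the reference."""
    pairs = induced_pairs(alignment)
    if not pairs:
        return 0.0
    true_pairs = induced_pairs(truth)
    return len(pairs & true_pairs) / len(pairs)


def expected_accuracy(alignment: Alignment, cset: CorrespondenceSet) -> float:
    """Mean correspondence score over the alignment's induced pairs.

    Pairs absent from the score tables contribute zero.
    """
    pairs = induced_pairs(alignment)
    if not pairs:
        raise ValueError("alignment induces no cross-network pairs")
    total = 0.0
    for pair in pairs:
        (lab_a, a), (lab_b, b) = sorted(pair)
        try:
            total += cset.score(lab_a, lab_b, a, b)
        except KeyError:
            pass
    return total / len(pairs)


def filter_classes(alignment: Alignment, ann: AnnotationMap) -> Alignment:
    """Drop unannotated nodes, then classes with < 2 nodes or a single network."""
    kept: list[frozenset[Member]] = []
    for cls in alignment.classes:
        annotated = frozenset(m for m in cls if ann.get(*m) is not None)
        if len(annotated) < 2:
            continue
        if len({label for label, _ in annotated}) < 2:
            continue
        kept.append(annotated)
    return Alignment(kept)


def _is_correct(cls: frozenset[Member], ann: AnnotationMap) -> bool:
    labels = {ann.get(*m) for m in cls}
    return len(labels) == 1 and None not in labels


def class_metrics(alignment: Alignment, ann: AnnotationMap) -> tuple[int, float]:
    """(CN, SPE): nodes in correct classes, and fraction of correct classes."""
    if not alignment.classes:
        raise ValueError("nothing to evaluate: no classes after filtering")
    correct = [cls for cls in alignment.classes if _is_correct(cls, ann)]
    cn = sum(len(cls) for cls in correct)
    spe = len(correct) / len(alignment.classes)
    return cn, spe


def _class_entropy(cls: frozenset[Member], ann: AnnotationMap) -> float:
    counts: dict[str, int] = {}
    for member in cls:
        lab = ann.get(*member)
        counts[lab] = counts.get(lab, 0) + 1
    d = len(counts)
    if d <= 1:
        return 0.0
    n = len(cls)
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return h / math.log(d)


def mean_normalized_entropy(alignment: Alignment, ann: AnnotationMap) -> float:
    """Mean per-class normalized label entropy; 0 for pure classes."""
    if not alignment.classes:
        raise ValueError("nothing to evaluate: no classes after filtering")
    return sum(_class_entropy(cls, ann) for cls in alignment.classes) / len(alignment.classes)


def conserved_interactions(alignment: Alignment, networks: NetworkSet,
                           ann: AnnotationMap) -> tuple[int, int]:
    """(CI, COI): edges running between class pairs that are supported in at
    least two distinct networks; COI restricts to correct class pairs.

    Each contributing edge counts once toward the totals.
    """
    # node -> class id
    where: dict[Member, int] = {}
    for idx, cls in enumerate(alignment.classes):
        for member in cls:
            where[member] = idx
    # (class id pair) -> {network: edge count}
    between: dict[tuple[int, int], dict[str, int]] = {}
    for net in networks:
        for edge in net.edges:
            x, y = tuple(edge)
            cx = where.get((net.label, x))
            cy = where.get((net.label, y))
            if cx is None or cy is None or cx == cy:
                continue
            key = (min(cx, cy), max(cx, cy))
            per_net = between.setdefault(key, {})
            per_net[net.label] = per_net.get(net.label, 0) + 1
    correct = [_is_correct(cls, ann) for cls in alignment.classes]
    ci = coi = 0
    for (c1, c2), per_net in between.items():
        if len(per_net) < 2:  # conservation needs >= 2 networks
            continue
        n_edges = sum(per_net.values())
        ci += n_edges
        if correct[c1] and correct[c2]:
            coi += n_edges
    return ci, coi


def coverage_profile(alignment: Alignment) -> tuple[dict[int, int], dict[int, int]]:
    """Class and node counts keyed by the number of networks a class spans."""
    class_coverage: dict[int, int] = {}
    node_coverage: dict[int, int] = {}
    for cls in alignment.classes:
        k = len({label for label, _ in cls})
        class_coverage[k] = class_coverage.get(k, 0) + 1
        node_coverage[k] = node_coverage.get(k, 0) + len(cls)
    return class_coverage, node_coverage


@dataclass
class MetricsReport:
    cn: int
    spe: float
    mne: float
    ci: int
    coi: int
    class_coverage: dict[int, int]
    node_coverage: dict[int, int]
    n_classes: int
    n_filtered_classes: int
    n_filtered_nodes: int
    accuracy: float | None = None

    def as_text(self) -> str:
        lines = [
            f"classes            {self.n_classes}",
            f"filtered_classes   {self.n_filtered_classes}",
            f"filtered_nodes     {self.n_filtered_nodes}",
            f"CN                 {self.cn}",
            f"SPE                {self.spe:.4f}",
            f"MNE                {self.mne:.4f}",
            f"CI                 {self.ci}",
            f"COI                {self.coi}",
        ]
        if self.accuracy is not None:
            lines.append(f"accuracy           {self.accuracy:.4f}")
        for k in sorted(self.class_coverage):
            lines.append(f"class_coverage[{k}]  {self.class_coverage[k]}")
        for k in sorted(self.node_coverage):
            lines.append(f"node_coverage[{k}]   {self.node_coverage[k]}")
        return "\n".join(lines)

    def as_tsv(self) -> str:
        fields = [self.cn, f"{self.spe:.6f}", f"{self.mne:.6f}", self.ci, self.coi,
                  "" if self.accuracy is None else f"{self.accuracy:.6f}"]
        return "\t".join(str(f) for f in fields)


def evaluate(alignment: Alignment, networks: NetworkSet, ann: AnnotationMap,
             truth: Alignment | None = None) -> MetricsReport:
    """Filter then compute the full metric suite; accuracy only with a truth."""
    filtered = filter_classes(alignment, ann)
    if not filtered.classes:
        raise ValueError("no classes survive filtering")
    cn, spe = class_metrics(filtered, ann)
    mne = mean_normalized_entropy(filtered, ann)
    ci, coi = conserved_interactions(filtered, networks, ann)
    class_cov, node_cov = coverage_profile(filtered)
    n_nodes_before = len(alignment.members())
    n_nodes_after = len(filtered.members())
    return MetricsReport(
        cn=cn, spe=spe, mne=mne, ci=ci, coi=coi,
        class_coverage=class_cov, node_coverage=node_cov,
        n_classes=len(filtered.classes),
        n_filtered_classes=len(alignment.classes) - len(filtered.classes),
        n_filtered_nodes=n_nodes_before - n_nodes_after,
        accuracy=None if truth is None else alignment_accuracy(alignment, truth),
    )
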