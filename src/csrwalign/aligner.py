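"""Greedy construction of the multiple network alignment.

Candidate node pairs from every network pair are pooled, sorted by
descending correspondence score, and added one by one: a pair of unassigned
nodes opens a new equivalence class, a pair with one assigned node extends
that node's class (up to the class-size cap), and a pair whose nodes are
both already assigned is skipped — classes are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consistency import CorrespondenceSet
from .netio import Alignment, NetworkSet

__all__ = ["AlignParams", "rank_pairs", "build_alignment"]

Candidate = tuple[float, tuple[str, str], str, str]


@dataclass(frozen=True)
class AlignParams:
    n_max: int = 10
    min_score: float = 0.0

    def __post_init__(self):
        if self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max}")


def rank_pairs(cset: CorrespondenceSet, params: AlignParams = AlignParams()) -> list[Candidate]:
    """Pool candidates from all network pairs into one globally sorted list.

    Sorted by descending score; ties broken lexicographically by
    (network labels, u, v) for a deterministic ordering.
    """
    candidates: list[Candidate] = []
    for lab_u, lab_v in cset.pair_keys():
        for u, v, score in cset.entries(lab_u, lab_v):
            if score > params.min_score:
                candidates.append((score, (lab_u, lab_v), u, v))
    if not candidates:
        raise ValueError("no alignment candidates (all tables empty after filtering)")
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    return candidates


def build_alignment(ranked: list[Candidate], networks: NetworkSet,
                    params: AlignParams = AlignParams()) -> Alignment:
    """Scan the ranked candidates once, greedily growing equivalence classes."""
    assignment: dict[tuple[str, str], int] = {}
    classes: list[set[tuple[str, str]]] = []
    for _score, (lab_u, lab_v), u, v in ranked:
        mu = (lab_u, u)
        mv = (lab_v, v)
        cu = assignment.get(mu)
        cv = assignment.get(mv)
        if cu is None and cv is None:
            assignment[mu] = assignment[mv] = len(classes)
            classes.append({mu, mv})
        elif cu is None and cv is not None:
            if len(classes[cv]) < params.n_max:
                classes[cv].add(mu)
                assignment[mu] = cv
        elif cv is None and cu is not None:
            if len(classes[cu]) < params.n_max:
                classes[cu].add(mv)
                assignment[mv] = cu
        # both assigned (same or different classes): inconsistent, skip
    alignment = Alignment([frozenset(c) for c in classes])
    alignment.validate(networks)
    return alignment
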