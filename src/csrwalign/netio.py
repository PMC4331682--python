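"""I/O for networks, similarity tables, annotations, and alignment files.

All formats are whitespace-delimited plain text (UTF-8, Unix newlines on
write).  Networks are two-column edge lists, similarity tables are
three-column ``nodeU nodeV score`` files, annotations are three-column
``network node function`` files, and alignments are written one equivalence
class per line with ``label|node`` member tokens separated by tabs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "Network",
    "NetworkSet",
    "SimilarityTable",
    "AnnotationMap",
    "Alignment",
    "read_network",
    "read_similarity",
    "read_annotations",
    "read_alignment",
    "write_alignment",
    "write_network",
    "write_similarity",
    "write_annotations",
]


class ParseError(ValueError):
    """Raised when an on-disk file cannot be parsed."""


class Network:
    """An undirected simple graph with a label.

    Self-loops and duplicate edges are never stored; isolated nodes are
    permitted and preserved.
    """

    def __init__(self, label: str, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = ()):
        self.label = label
        self._g = nx.Graph()
        self._g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed in network {label!r}")
            self._g.add_edge(u, v)

    @classmethod
    def from_graph(cls, label: str, graph: nx.Graph) -> "Network":
        net = cls(label)
        net._g = nx.Graph()
        net._g.add_nodes_from(graph.nodes)
        net._g.add_edges_from((u, v) for u, v in graph.edges if u != v)
        return net

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def neighbors(self, v: str) -> set[str]:
        return set(self._g.neighbors(v))

    def degree(self, v: str) -> int:
        return self._g.degree(v)

    def has_node(self, v: str) -> bool:
        return self._g.has_node(v)

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, v: str) -> bool:
        return self._g.has_node(v)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (self.label == other.label and self.nodes == other.nodes
                and self.edges == other.edges)

    def __repr__(self) -> str:
        return (f"Network({self.label!r}, |V|={self.number_of_nodes()}, "
                f"|E|={self.number_of_edges()})")


class NetworkSet:
    """An ordered collection of at least two networks with distinct labels."""

    def __init__(self, networks: Iterable[Network]):
        self.networks = list(networks)
        labels = [n.label for n in self.networks]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate network labels: {labels}")
        if len(labels) < 2:
            raise ValueError("a NetworkSet requires at least two networks")
        self._by_label = {n.label: n for n in self.networks}

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.networks]

    def __getitem__(self, label: str) -> Network:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __iter__(self) -> Iterator[Network]:
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered label pairs, in listed order."""
        labs = self.labels
        return [(labs[i], labs[j]) for i in range(len(labs))
                for j in range(i + 1, len(labs))]


class SimilarityTable:
    """Sparse, strictly positive node-pair similarity scores for one network pair."""

    def __init__(self, label_u: str, label_v: str,
                 scores: Mapping[tuple[str, str], float]):
        self.labels = (label_u, label_v)
        self._scores: dict[tuple[str, str], float] = {}
        for (u, v), s in scores.items():
            s = float(s)
            if s <= 0:
                raise ValueError(f"similarity score must be > 0, got {s} for ({u}, {v})")
            self._scores[(u, v)] = s

    def oriented(self, label_u: str, label_v: str) -> dict[tuple[str, str], float]:
        """Score dict with keys oriented as (node in label_u, node in label_v)."""
        if (label_u, label_v) == self.labels:
            return dict(self._scores)
        if (label_v, label_u) == self.labels:
            return {(v, u): s for (u, v), s in self._scores.items()}
        raise KeyError(f"table is for {self.labels}, not ({label_u}, {label_v})")

    def transpose(self) -> "SimilarityTable":
        return SimilarityTable(self.labels[1], self.labels[0],
                               {(v, u): s for (u, v), s in self._scores.items()})

    def score(self, u: str, v: str) -> float:
        return self._scores.get((u, v), 0.0)

    def pairs(self) -> set[tuple[str, str]]:
        """The support M: all pairs with positive score."""
        return set(self._scores)

    def items(self):
        return self._scores.items()

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._scores


class AnnotationMap:
    """Functional label per (network label, node); nodes may be unannotated."""

    def __init__(self, labels: Mapping[tuple[str, str], str] | None = None):
        self._labels: dict[tuple[str, str], str] = dict(labels or {})

    def get(self, network: str, node: str) -> str | None:
        return self._labels.get((network, node))

    def set(self, network: str, node: str, function: str) -> None:
        self._labels[(network, node)] = function

    def items(self):
        return self._labels.items()

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._labels


Member = tuple[str, str]  # (network label, node id)


@dataclass
class Alignment:
    """A set of disjoint equivalence classes of (network, node) members."""

    classes: list[frozenset[Member]] = field(default_factory=list)

    def validate(self, networks: NetworkSet | None = None) -> None:
        seen: set[Member] = set()
        for cls in self.classes:
            for member in cls:
                if member in seen:
                    raise ValueError(f"member {member} appears in more than one class")
                seen.add(member)
                if networks is not None:
                    label, node = member
                    if label not in networks:
                        raise ValueError(f"unknown network label {label!r}")
                    if node not in networks[label]:
                        raise ValueError(f"node {node!r} not in network {label!r}")

    def members(self) -> set[Member]:
        out: set[Member] = set()
        for cls in self.classes:
            out |= cls
        return out

    def canonical(self) -> list[list[Member]]:
        """Classes sorted by descending size then first member token; members sorted."""
        ordered = [sorted(cls, key=_member_token) for cls in self.classes]
        ordered.sort(key=lambda c: (-len(c), _member_token(c[0])))
        return ordered

    def __len__(self) -> int:
        return len(self.classes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return set(self.classes) == set(other.classes)


def _member_token(member: Member) -> str:
    return f"{member[0]}|{member[1]}"


# ---------------------------------------------------------------------------
# readers


def _data_lines(path) -> Iterator[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(path, label: str) -> Network:
    """Read a two-column edge list into a :class:`Network`.

    Lines starting with ``#`` are skipped; self-loops are dropped with a
    warning; duplicate edges are collapsed.
    """
    net = Network(label)
    n_self_loops = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}")
        u, v = tokens[0], tokens[1]
        if u == v:
            n_self_loops += 1
            net._g.add_node(u)
            continue
        net._g.add_edge(u, v)
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self_loops)
    return net


def read_similarity(path, net_u: Network, net_v: Network) -> SimilarityTable:
    """Read a three-column ``nodeU nodeV score`` similarity table.

    Scores <= 0 are discarded (the support M is strictly positive); rows
    naming unknown nodes are skipped with a warning count; duplicate pairs
    keep the maximum score.
    """
    scores: dict[tuple[str, str], float] = {}
    n_unknown = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tokens, got {len(tokens)}")
        u, v = tokens[0], tokens[1]
        try:
            s = float(tokens[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score {tokens[2]!r}") from exc
        if s <= 0:
            continue
        if u not in net_u or v not in net_v:
            n_unknown += 1
            continue
        key = (u, v)
        if key not in scores or s > scores[key]:
            scores[key] = s
    if n_unknown:
        logger.warning("%s: skipped %d row(s) naming unknown nodes", path, n_unknown)
    if not scores:
        raise ParseError(f"{path}: no similar node pairs (M is empty)")
    return SimilarityTable(net_u.label, net_v.label, scores)


def read_annotations(path) -> AnnotationMap:
    """Read ``network node function`` annotation rows; repeated node keeps the last."""
    ann = AnnotationMap()
    n_repeat = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tokens, got {len(tokens)}")
        key = (tokens[0], tokens[1])
        if key in ann:
            n_repeat += 1
        ann.set(tokens[0], tokens[1], tokens[2])
    if n_repeat:
        logger.warning("%s: %d repeated annotation(s) overwritten (last wins)", path, n_repeat)
    return ann


def read_alignment(path, networks: NetworkSet) -> Alignment:
    classes: list[frozenset[Member]] = []
    seen: set[Member] = set()
    for lineno, line in _data_lines(path):
        members: set[Member] = set()
        for token in line.split("\t"):
            token = token.strip()
            if "|" not in token:
                raise ParseError(f"{path}:{lineno}: member token {token!r} lacks '|'")
            label, node = token.split("|", 1)
            if label not in networks:
                raise ParseError(f"{path}:{lineno}: unknown network label {label!r}")
            member = (label, node)
            if member in seen or member in members:
                raise ParseError(f"{path}:{lineno}: duplicate member {token!r}")
            members.add(member)
        seen |= members
        classes.append(frozenset(members))
    aln = Alignment(classes)
    aln.validate(networks)
    return aln


# ---------------------------------------------------------------------------
# writers


def write_alignment(alignment: Alignment, path) -> None:
    alignment.validate()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for cls in alignment.canonical():
            fh.write("\t".join(_member_token(m) for m in cls) + "\n")


def write_network(network: Network, path) -> None:
    # Isolated nodes are written as self-loop lines: read_network drops the
    # loop but keeps the node, so the round trip preserves them.
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{u}\t{v}\n")
        connected = {n for e in network.edges for n in e}
        for node in sorted(network.nodes - connected):
            fh.write(f"{node}\t{node}\n")


def write_similarity(table: SimilarityTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for (u, v), s in sorted(table.items()):
            fh.write(f"{u}\t{v}\t{s:.6g}\n")


def write_annotations(ann: AnnotationMap, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for (network, node), function in sorted(ann.items()):
            fh.write(f"{network}\t{node}\t{function}\n")
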