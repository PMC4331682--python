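"""Synthetic benchmark families: networks grown from a common ancestor under
duplication-based models, ground-truth orthology classes, and noisy
similarity tables concentrated on true ortholog pairs.

Three growth models are provided: DMC (duplication-mutation-complementation),
DMR (duplication with random mutation), and CG (crystal growth, preferential
attachment to a seed node's neighbourhood).  A family is produced by growing
one ancestral network, copying it once per member network, and growing each
copy independently; nodes descending from the same ancestral node share a
family id, which defines the true alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .netio import (Alignment, AnnotationMap, Network, NetworkSet,
                    SimilarityTable, write_alignment, write_annotations,
                    write_network, write_similarity)

__all__ = [
    "GrowthParams",
    "FamilyTruth",
    "grow_network",
    "generate_family",
    "synth_similarity",
    "write_family",
    "random_pair_instance",
]

MODELS = ("DMC", "DMR", "CG")


@dataclass(frozen=True)
class GrowthParams:
    model: str = "DMC"
    seed_size: int = 50
    q_mod: float = 0.4
    q_con: float = 0.1
    q_del: float = 0.4
    r_new: float = 1.0
    m_att: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        for name in ("q_mod", "q_con", "q_del"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.seed_size < 2:
            raise ValueError("seed_size must be >= 2")
        if self.r_new < 0:
            raise ValueError("r_new must be >= 0")
        if self.m_att < 1:
            raise ValueError("m_att must be >= 1")


@dataclass
class FamilyTruth:
    """Family id per (network label, node), and the derived true alignment."""

    families: dict[tuple[str, str], str]

    def true_alignment(self) -> Alignment:
        """One class per family with members in >= 2 networks."""
        by_family: dict[str, set[tuple[str, str]]] = {}
        for member, fam in self.families.items():
            by_family.setdefault(fam, set()).add(member)
        classes = [frozenset(members) for fam, members in sorted(by_family.items())
                   if len({label for label, _ in members}) >= 2]
        return Alignment(classes)

    def annotations(self) -> AnnotationMap:
        """Family ids as functional labels, for the class-coherence metrics."""
        return AnnotationMap(dict(self.families))

    def per_network(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for (label, node) in sorted(self.families):
            out.setdefault(label, []).append(node)
        return out


def _dmc_step(g: nx.Graph, families: dict[str, str], new_node: str,
              params: GrowthParams, rng: np.random.Generator) -> None:
    parent = str(rng.choice(sorted(g.nodes)))
    inherited = sorted(g.neighbors(parent))
    g.add_node(new_node)
    families[new_node] = families[parent]
    for x in inherited:
        g.add_edge(new_node, x)
    for x in inherited:
        if rng.random() < params.q_mod:
            # complementation: exactly one of the two duplicate edges survives
            if rng.random() < 0.5:
                g.remove_edge(new_node, x)
            else:
                g.remove_edge(parent, x)
    if rng.random() < params.q_con:
        g.add_edge(parent, new_node)


def _dmr_step(g: nx.Graph, families: dict[str, str], new_node: str,
              params: GrowthParams, rng: np.random.Generator) -> None:
    parent = str(rng.choice(sorted(g.nodes)))
    inherited = sorted(g.neighbors(parent))
    g.add_node(new_node)
    families[new_node] = families[parent]
    for x in inherited:
        if rng.random() < 1 - params.q_del:
            g.add_edge(new_node, x)
    n_extra = rng.poisson(params.r_new)
    candidates = sorted(set(g.nodes) - {new_node} - set(g.neighbors(new_node)))
    for _ in range(int(n_extra)):
        if not candidates:
            break
        pick = int(rng.integers(len(candidates)))
        g.add_edge(new_node, candidates.pop(pick))


def _cg_step(g: nx.Graph, families: dict[str, str], new_node: str,
             params: GrowthParams, rng: np.random.Generator,
             fresh_family: str) -> None:
    anchor = str(rng.choice(sorted(g.nodes)))
    g.add_node(new_node)
    families[new_node] = fresh_family
    g.add_edge(new_node, anchor)
    neighbors = sorted(set(g.neighbors(anchor)) - {new_node})
    n_more = min(params.m_att - 1, len(neighbors))
    if n_more > 0:
        picks = rng.choice(len(neighbors), size=n_more, replace=False)
        for idx in sorted(picks):
            g.add_edge(new_node, neighbors[idx])


def grow_network(base: Network, target_size: int, params: GrowthParams,
                 families: dict[str, str] | None = None,
                 rng: np.random.Generator | None = None) -> tuple[Network, dict[str, str]]:
    """Grow ``base`` to ``target_size`` nodes under the configured model.

    Returns the grown network and a node -> family-id map.  Nodes added by
    duplication inherit the parent's family; CG nodes found fresh singleton
    families.  Deterministic for a fixed ``rng_seed``.
    """
    if target_size < base.number_of_nodes():
        raise ValueError(
            f"target_size {target_size} < base size {base.number_of_nodes()}")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    g = nx.Graph()
    g.add_nodes_from(base.nodes)
    g.add_edges_from(tuple(e) for e in base.edges)
    fam = dict(families) if families is not None else {v: f"F{v}" for v in base.nodes}
    counter = base.number_of_nodes()
    fresh_counter = 0
    while g.number_of_nodes() < target_size:
        new_node = f"{base.label}_n{counter}"
        while g.has_node(new_node):
            counter += 1
            new_node = f"{base.label}_n{counter}"
        counter += 1
        if params.model == "DMC":
            _dmc_step(g, fam, new_node, params, rng)
        elif params.model == "DMR":
            _dmr_step(g, fam, new_node, params, rng)
        else:
            _cg_step(g, fam, new_node, params, rng,
                     fresh_family=f"CG_{base.label}_{fresh_counter}")
            fresh_counter += 1
    return Network.from_graph(base.label, g), fam


def _seed_network(label: str, size: int, rng: np.random.Generator) -> Network:
    """Connected seed: a ring plus a few random chords."""
    g = nx.Graph()
    nodes = [f"a{i}" for i in range(size)]
    g.add_nodes_from(nodes)
    for i in range(size):
        g.add_edge(nodes[i], nodes[(i + 1) % size])
    n_chords = max(1, size // 5)
    for _ in range(n_chords):
        i, j = rng.integers(size), rng.integers(size)
        if i != j:
            g.add_edge(nodes[int(i)], nodes[int(j)])
    return Network.from_graph(label, g)


def generate_family(n_networks: int, sizes: list[int],
                    params: GrowthParams) -> tuple[NetworkSet, FamilyTruth]:
    """Grow an ancestor to min(sizes), copy it per network, and diverge.

    Family ids are shared across networks through the ancestral copy, so the
    truth's classes span all networks for pre-divergence nodes.
    """
    if len(sizes) != n_networks:
        raise ValueError(f"expected {n_networks} sizes, got {len(sizes)}")
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    if min(sizes) < params.seed_size:
        raise ValueError("every target size must be >= seed_size")
    rng = np.random.default_rng(params.rng_seed)
    seed = _seed_network("anc", params.seed_size, rng)
    ancestor, anc_fam = grow_network(seed, min(sizes), params, rng=rng)

    networks: list[Network] = []
    families: dict[tuple[str, str], str] = {}
    for i, size in enumerate(sizes):
        label = f"G{i + 1}"
        relabel = {v: f"{label}_{v}" for v in ancestor.nodes}
        g = nx.relabel_nodes(ancestor.graph, relabel, copy=True)
        base = Network.from_graph(label, g)
        base_fam = {relabel[v]: anc_fam[v] for v in ancestor.nodes}
        grown, fam = grow_network(base, size, params, families=base_fam, rng=rng)
        networks.append(grown)
        for node, family in fam.items():
            families[(label, node)] = family
    return NetworkSet(networks), FamilyTruth(families)


def synth_similarity(truth: FamilyTruth, mu_true: float = 100.0,
                     mu_noise: float = 10.0, fpr: float = 0.05,
                     rng_seed: int = 0) -> dict[tuple[str, str], SimilarityTable]:
    """Noisy positive similarity tables for every network pair.

    Same-family cross-network pairs score Gamma(shape 2, mean mu_true); each
    node additionally gains, with probability ``fpr``, one spurious partner
    from a different family scoring Gamma(shape 2, mean mu_noise).
    """
    if not (mu_true > mu_noise > 0):
        raise ValueError("need mu_true > mu_noise > 0")
    if not (0 <= fpr < 1):
        raise ValueError("fpr must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    per_net = truth.per_network()
    labels = sorted(per_net)
    tables: dict[tuple[str, str], SimilarityTable] = {}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            lab_u, lab_v = labels[a], labels[b]
            nodes_u = per_net[lab_u]
            nodes_v = per_net[lab_v]
            by_family_v: dict[str, list[str]] = {}
            for v in nodes_v:
                by_family_v.setdefault(truth.families[(lab_v, v)], []).append(v)
            scores: dict[tuple[str, str], float] = {}
            for u in nodes_u:
                fam = truth.families[(lab_u, u)]
                for v in by_family_v.get(fam, ()):
                    scores[(u, v)] = float(rng.gamma(2.0, mu_true / 2.0))
            # spurious partners, both directions
            for u in nodes_u:
                if rng.random() < fpr:
                    fam = truth.families[(lab_u, u)]
                    others = [v for v in nodes_v if truth.families[(lab_v, v)] != fam]
                    if others:
                        v = others[int(rng.integers(len(others)))]
                        score = float(rng.gamma(2.0, mu_noise / 2.0))
                        scores[(u, v)] = max(scores.get((u, v), 0.0), score)
            for v in nodes_v:
                if rng.random() < fpr:
                    fam = truth.families[(lab_v, v)]
                    others = [u for u in nodes_u if truth.families[(lab_u, u)] != fam]
                    if others:
                        u = others[int(rng.integers(len(others)))]
                        score = float(rng.gamma(2.0, mu_noise / 2.0))
                        scores[(u, v)] = max(scores.get((u, v), 0.0), score)
            tables[(lab_u, lab_v)] = SimilarityTable(lab_u, lab_v, scores)
    return tables


def write_family(outdir, networks: NetworkSet, truth: FamilyTruth,
                 tables: dict[tuple[str, str], SimilarityTable],
                 params: GrowthParams, sim_seed: int,
                 mu_true: float, mu_noise: float, fpr: float) -> None:
    """Write a family to a directory in the package's text formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for net in networks:
        write_network(net, out / f"network_{net.label}.tsv")
    for (lab_u, lab_v), table in sorted(tables.items()):
        write_similarity(table, out / f"sim_{lab_u}_{lab_v}.tsv")
    write_annotations(truth.annotations(), out / "annotations.tsv")
    write_alignment(truth.true_alignment(), out / "truth.aln")
    manifest = out / "manifest.txt"
    with open(manifest, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (
            ("model", params.model), ("seed_size", params.seed_size),
            ("q_mod", params.q_mod), ("q_con", params.q_con),
            ("q_del", params.q_del), ("r_new", params.r_new),
            ("m_att", params.m_att), ("rng_seed", params.rng_seed),
            ("sim_seed", sim_seed), ("mu_true", mu_true),
            ("mu_noise", mu_noise), ("fpr", fpr),
            ("networks", ",".join(networks.labels)),
            ("sizes", ",".join(str(n.number_of_nodes()) for n in networks)),
        ):
            fh.write(f"{key}={value}\n")


# ---------------------------------------------------------------------------
# small random instances for property tests and oracles


def random_pair_instance(rng: np.random.Generator, max_nodes: int = 8,
                         p_edge: float = 0.35, p_sim: float = 0.5,
                         max_pairs: int | None = None):
    """A random two-network instance with positive similarities on a random
    subset of cross pairs; guaranteed nonempty M.

    Returns ``(net_u, net_v, sim)``.
    """
    n_u = int(rng.integers(2, max_nodes + 1))
    n_v = int(rng.integers(2, max_nodes + 1))
    g_u = nx.Graph()
    g_u.add_nodes_from(f"u{i}" for i in range(n_u))
    for i in range(n_u):
        for j in range(i + 1, n_u):
            if rng.random() < p_edge:
                g_u.add_edge(f"u{i}", f"u{j}")
    g_v = nx.Graph()
    g_v.add_nodes_from(f"v{i}" for i in range(n_v))
    for i in range(n_v):
        for j in range(i + 1, n_v):
            if rng.random() < p_edge:
                g_v.add_edge(f"v{i}", f"v{j}")
    net_u = Network.from_graph("U", g_u)
    net_v = Network.from_graph("V", g_v)
    scores: dict[tuple[str, str], float] = {}
    for i in range(n_u):
        for j in range(n_v):
            if rng.random() < p_sim:
                scores[(f"u{i}", f"v{j}")] = float(rng.uniform(0.1, 10.0))
    if not scores:
        i = int(rng.integers(n_u))
        j = int(rng.integers(n_v))
        scores[(f"u{i}", f"v{j}")] = float(rng.uniform(0.1, 10.0))
    if max_pairs is not None and len(scores) > max_pairs:
        keep = sorted(scores)
        picks = rng.choice(len(keep), size=max_pairs, replace=False)
        scores = {keep[int(k)]: scores[keep[int(k)]] for k in picks}
    return net_u, net_v, SimilarityTable("U", "V", scores)
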