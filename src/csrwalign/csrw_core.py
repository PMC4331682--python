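"""Context-sensitive random walk over a pair of networks.

Builds the reduced transition structure over similar node pairs (the set M),
derives a restart probability from the fragmentation of the reduced product
graph, computes the walk's stationary distribution by damped power iteration,
and blends it with the normalized similarity scores into per-pair node
correspondence scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .netio import Network, SimilarityTable

__all__ = [
    "WalkParams",
    "PairIndex",
    "ReducedChain",
    "neighbor_pair_set",
    "build_reduced_chain",
    "compute_restart_lambda",
    "stationary_distribution",
    "correspondence_scores",
    "pair_correspondence",
    "simulate_walk",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class WalkParams:
    """Knobs for chain construction and the power iteration.

    K is the percentile used to set the restart probability from the
    component-size profile of the reduced product graph.
    """

    K: float = 99.0
    tol: float = 1e-10
    max_iter: int = 1000
    override_lambda: float | None = None

    def __post_init__(self):
        if not (0 < self.K <= 100):
            raise ValueError(f"K must be in (0, 100], got {self.K}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.override_lambda is not None and not (0 <= self.override_lambda <= 1):
            raise ValueError("override_lambda must be in [0, 1]")


class PairIndex:
    """Dense, lexicographically ordered index over the M-pairs of one network pair."""

    def __init__(self, pairs):
        self.pairs: list[tuple[str, str]] = sorted(pairs)
        self.index: dict[tuple[str, str], int] = {p: i for i, p in enumerate(self.pairs)}

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> tuple[str, str]:
        return self.pairs[i]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.index

    def index_of(self, pair: tuple[str, str]) -> int:
        return self.index[pair]


@dataclass
class ReducedChain:
    """Row-stochastic transition structure over M-pairs plus restart data.

    ``P`` stores the transition matrix with dangling rows left empty; the
    effective row of a dangling state is the restart distribution ``restart``.
    """

    index: PairIndex
    P: sp.csr_matrix
    restart: np.ndarray
    dangling: np.ndarray
    lam: float = float("nan")

    def n_states(self) -> int:
        return len(self.index)

    def effective_row_sums(self) -> np.ndarray:
        sums = np.asarray(self.P.sum(axis=1)).ravel()
        sums[self.dangling] += self.restart.sum()
        return sums

    def check(self) -> None:
        sums = self.effective_row_sums()
        if not np.all(np.abs(sums - 1.0) <= 1e-9):
            worst = float(np.max(np.abs(sums - 1.0)))
            raise RuntimeError(f"non-stochastic row detected (max |sum-1| = {worst:.3g})")
        if self.P.nnz and self.P.data.min() < 0:
            raise RuntimeError("negative transition probability")


def neighbor_pair_set(state: tuple[str, str], net_u: Network, net_v: Network,
                      sim: SimilarityTable) -> set[tuple[str, str]]:
    """Similar neighbouring pairs of ``state``: both coordinates move to a
    neighbour and the resulting pair has positive similarity."""
    uc, vc = state
    scores = sim.oriented(net_u.label, net_v.label)
    return {(ui, vj)
            for ui in net_u.neighbors(uc)
            for vj in net_v.neighbors(vc)
            if (ui, vj) in scores}


def build_reduced_chain(net_u: Network, net_v: Network, sim: SimilarityTable,
                        params: WalkParams = WalkParams()) -> ReducedChain:
    """Construct the reduced chain over M-pairs.

    A state with similar neighbouring pairs moves simultaneously on both
    networks, weighted by similarity.  Otherwise the walker moves on a single
    network (mass split by network size); individual-walk targets outside M
    are dropped and the row renormalized.  States whose entire row is lost
    are flagged dangling and restart from the similarity distribution.
    """
    scores = sim.oriented(net_u.label, net_v.label)
    if not scores:
        raise ValueError("no similar node pairs (M is empty)")
    index = PairIndex(scores)
    n = len(index)

    raw = np.array([scores[p] for p in index.pairs], dtype=float)
    restart = raw / raw.sum()

    size_u = net_u.number_of_nodes()
    size_v = net_v.number_of_nodes()
    w_u = size_u / (size_u + size_v)
    w_v = size_v / (size_u + size_v)

    rows, cols, vals = [], [], []
    dangling = np.zeros(n, dtype=bool)
    for i, (uc, vc) in enumerate(index.pairs):
        nb_u = net_u.neighbors(uc)
        nb_v = net_v.neighbors(vc)
        match = [(ui, vj) for ui in nb_u for vj in nb_v if (ui, vj) in scores]
        if match:
            weights = np.array([scores[p] for p in match], dtype=float)
            weights /= weights.sum()
            for p, w in zip(match, weights):
                rows.append(i)
                cols.append(index.index_of(p))
                vals.append(w)
            continue
        # individual walk; targets outside M are removed by the reduction
        targets: list[tuple[int, float]] = []
        if nb_u:
            p_each = w_u / len(nb_u)
            for ui in nb_u:
                j = index.index.get((ui, vc))
                if j is not None:
                    targets.append((j, p_each))
        if nb_v:
            p_each = w_v / len(nb_v)
            for vj in nb_v:
                j = index.index.get((uc, vj))
                if j is not None:
                    targets.append((j, p_each))
        if targets:
            total = sum(w for _, w in targets)
            for j, w in targets:
                rows.append(i)
                cols.append(j)
                vals.append(w / total)
        else:
            dangling[i] = True

    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    P.sum_duplicates()
    chain = ReducedChain(index=index, P=P, restart=restart, dangling=dangling)
    if params.override_lambda is not None:
        chain.lam = params.override_lambda
    else:
        chain.lam = compute_restart_lambda(chain, params.K)
    chain.check()
    return chain


def compute_restart_lambda(chain: ReducedChain, K: float = 99.0) -> float:
    """Restart probability from the fragmentation of the reduced product graph.

    Components are taken over the symmetrized support of the stored rows
    (dangling-substituted rows contribute no edges); lambda is the node
    fraction held by the floor(K% * C) smallest of the C components.
    """
    n = chain.n_states()
    sym = chain.P + chain.P.T
    n_comp, labels = connected_components(sym, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    # deterministic ordering: ascending size, ties by smallest member index
    first_index = np.full(n_comp, n, dtype=int)
    for i, lab in enumerate(labels):
        if i < first_index[lab]:
            first_index[lab] = i
    order = sorted(range(n_comp), key=lambda c: (sizes[c], first_index[c]))
    k = math.floor((K / 100.0) * n_comp)
    taken = sum(int(sizes[c]) for c in order[:k])
    return taken / n


def stationary_distribution(chain: ReducedChain, params: WalkParams = WalkParams()) -> np.ndarray:
    """Long-run distribution of the reduced chain, started at the restart vector.

    Iterates the half-lazy map x <- (x + xP)/2, whose fixed point equals the
    Cesaro (time-average) limit of the plain power iteration but converges
    geometrically even for periodic or reducible chains.
    """
    chain.check()
    P = chain.P
    s = chain.restart
    d = chain.dangling
    x = s.copy()
    for _ in range(params.max_iter):
        step = x @ P
        if d.any():
            step = step + x[d].sum() * s
        x_new = 0.5 * (x + step)
        if np.abs(x_new - x).sum() < params.tol:
            x = x_new
            break
        x = x_new
    total = x.sum()
    if total <= 0:
        raise RuntimeError("stationary iteration lost all mass")
    return x / total


def correspondence_scores(pi: np.ndarray, s: np.ndarray, lam: float) -> np.ndarray:
    """Blend stationary distribution and normalized similarity: c = lam*s + (1-lam)*pi."""
    if not (0 <= lam <= 1):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if pi.shape != s.shape:
        raise ValueError("pi and s must share the same index")
    return lam * s + (1.0 - lam) * pi


def pair_correspondence(net_u: Network, net_v: Network, sim: SimilarityTable,
                        params: WalkParams = WalkParams()):
    """Full per-pair scoring: build chain, stationary distribution, and c.

    Returns ``(chain, c)`` where ``c`` is indexed by ``chain.index``.
    """
    chain = build_reduced_chain(net_u, net_v, sim, params)
    pi = stationary_distribution(chain, params)
    c = correspondence_scores(pi, chain.restart, chain.lam)
    return chain, c


# ---------------------------------------------------------------------------
# full-chain simulation oracle


def simulate_walk(net_u: Network, net_v: Network, sim: SimilarityTable,
                  steps: int, seed: int) -> dict[tuple[str, str], float]:
    """Simulate the full (unreduced) walk over U x V and return the fraction
    of time spent at each M-pair, normalized over M-visits.

    Used as an independent check that reducing the chain to M barely
    perturbs the M-restricted long-run occupancy.  A walker with no move
    available restarts from the similarity distribution.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    nodes_u = sorted(net_u.nodes)
    nodes_v = sorted(net_v.nodes)
    iu = {u: i for i, u in enumerate(nodes_u)}
    iv = {v: i for i, v in enumerate(nodes_v)}
    nv = len(nodes_v)
    scores = sim.oriented(net_u.label, net_v.label)

    def code(u: str, v: str) -> int:
        return iu[u] * nv + iv[v]

    by_code = sorted(scores, key=lambda p: code(*p))
    m_codes = np.array([code(*p) for p in by_code], dtype=np.int64)
    code_to_pair = {c: p for c, p in zip(m_codes.tolist(), by_code)}
    m_weights = np.array([scores[p] for p in by_code])
    restart_cum = np.cumsum(m_weights / m_weights.sum())

    size_u, size_v = len(nodes_u), len(nodes_v)
    w_u = size_u / (size_u + size_v)
    w_v = size_v / (size_u + size_v)

    row_cache: dict[int, tuple[np.ndarray, np.ndarray] | None] = {}

    def row(state: int):
        if state in row_cache:
            return row_cache[state]
        u = nodes_u[state // nv]
        v = nodes_v[state % nv]
        nb_u = net_u.neighbors(u)
        nb_v = net_v.neighbors(v)
        match = [(ui, vj) for ui in nb_u for vj in nb_v if (ui, vj) in scores]
        if match:
            targets = np.array([code(ui, vj) for ui, vj in match], dtype=np.int64)
            weights = np.array([scores[p] for p in match], dtype=float)
        else:
            tgt, wts = [], []
            if nb_u:
                p_each = w_u / len(nb_u)
                for ui in nb_u:
                    tgt.append(code(ui, v))
                    wts.append(p_each)
            if nb_v:
                p_each = w_v / len(nb_v)
                for vj in nb_v:
                    tgt.append(code(u, vj))
                    wts.append(p_each)
            if not tgt:
                row_cache[state] = None  # stuck: restart
                return None
            targets = np.array(tgt, dtype=np.int64)
            weights = np.array(wts, dtype=float)
        cum = np.cumsum(weights / weights.sum())
        out = (targets, cum)
        row_cache[state] = out
        return out

    def restart_state() -> int:
        return int(m_codes[np.searchsorted(restart_cum, rng.random())])

    visits: dict[int, int] = {}
    state = restart_state()
    uniforms = rng.random(steps)
    for t in range(steps):
        visits[state] = visits.get(state, 0) + 1
        r = row(state)
        if r is None:
            state = restart_state()
        else:
            targets, cum = r
            state = int(targets[np.searchsorted(cum, uniforms[t])])

    m_visit_total = sum(cnt for st, cnt in visits.items() if st in code_to_pair)
    freqs = {p: 0.0 for p in scores}
    if m_visit_total:
        for st, cnt in visits.items():
            pair = code_to_pair.get(st)
            if pair is not None:
                freqs[pair] = cnt / m_visit_total
    return freqs
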