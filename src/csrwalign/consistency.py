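"""Probabilistic consistency transformation (PCT) of correspondence scores.

Scores for a network pair are refined in two stages: a neighbourhood
smoothing step within the pair's own networks, and a cross-network step that
composes scores through every third network.  Both stages keep the result on
the original positive-similarity support.  The transformation is applied
selectively: pairs whose restart probability exceeds a threshold are passed
through untouched, since a fragmented product graph makes consistency
propagation unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .csrw_core import PairIndex
from .netio import Network

__all__ = [
    "PCTParams",
    "CorrespondenceSet",
    "row_normalized_adjacency",
    "intra_network_smoothing",
    "cross_network_pct",
    "apply_selective_pct",
]


@dataclass(frozen=True)
class PCTParams:
    alpha: float = 0.9
    beta: float = 0.8
    lambda_t: float = 0.7

    def __post_init__(self):
        for name in ("alpha", "beta", "lambda_t"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


class CorrespondenceSet:
    """Per-network-pair correspondence score matrices plus each pair's lambda.

    One matrix is stored per unordered pair, oriented by sorted label order;
    the reverse orientation is served as a transpose view, so transpose
    consistency holds by construction.  Matrix rows/columns follow the
    lexicographic node order of each network.
    """

    def __init__(self, networks: dict[str, Network]):
        self.networks = dict(networks)
        self.node_order = {lab: sorted(net.nodes) for lab, net in self.networks.items()}
        self.node_index = {lab: {v: i for i, v in enumerate(order)}
                           for lab, order in self.node_order.items()}
        self._tables: dict[tuple[str, str], sp.csr_matrix] = {}
        self.lam: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(label_u: str, label_v: str) -> tuple[str, str]:
        if label_u == label_v:
            raise ValueError("a correspondence table needs two distinct networks")
        return (label_u, label_v) if label_u < label_v else (label_v, label_u)

    def set_pair(self, label_u: str, label_v: str, index: PairIndex,
                 scores: np.ndarray, lam: float) -> None:
        """Install the score vector over the pair's M-index, oriented (U, V)."""
        if np.any(scores < 0):
            raise ValueError("correspondence scores must be nonnegative")
        key = self._key(label_u, label_v)
        rows_lab, cols_lab = label_u, label_v
        if key != (label_u, label_v):
            rows_lab, cols_lab = label_v, label_u
        ri = self.node_index[rows_lab]
        ci = self.node_index[cols_lab]
        rows, cols = [], []
        for u, v in index.pairs:
            if key == (label_u, label_v):
                rows.append(ri[u])
                cols.append(ci[v])
            else:
                rows.append(ri[v])
                cols.append(ci[u])
        mat = sp.csr_matrix((scores, (rows, cols)),
                            shape=(len(ri), len(ci)))
        self._tables[key] = mat
        self.lam[key] = lam

    def set_matrix(self, label_u: str, label_v: str, mat: sp.csr_matrix,
                   lam: float | None = None) -> None:
        key = self._key(label_u, label_v)
        if key != (label_u, label_v):
            mat = mat.T.tocsr()
        self._tables[key] = mat.tocsr()
        if lam is not None:
            self.lam[key] = lam

    def matrix(self, label_u: str, label_v: str) -> sp.csr_matrix:
        key = self._key(label_u, label_v)
        mat = self._tables[key]
        return mat if key == (label_u, label_v) else mat.T.tocsr()

    def pair_lambda(self, label_u: str, label_v: str) -> float:
        return self.lam[self._key(label_u, label_v)]

    def pair_keys(self) -> list[tuple[str, str]]:
        return sorted(self._tables)

    def score(self, label_u: str, label_v: str, u: str, v: str) -> float:
        mat = self.matrix(label_u, label_v)
        return float(mat[self.node_index[label_u][u], self.node_index[label_v][v]])

    def entries(self, label_u: str, label_v: str):
        """Iterate (u, v, score) over stored entries, oriented (U, V)."""
        mat = self.matrix(label_u, label_v).tocoo()
        order_u = self.node_order[label_u]
        order_v = self.node_order[label_v]
        for i, j, val in zip(mat.row, mat.col, mat.data):
            yield order_u[i], order_v[j], float(val)

    def copy(self) -> "CorrespondenceSet":
        out = CorrespondenceSet(self.networks)
        out._tables = {k: m.copy() for k, m in self._tables.items()}
        out.lam = dict(self.lam)
        return out


def row_normalized_adjacency(net: Network) -> sp.csr_matrix:
    """Adjacency of ``net`` over lexicographic node order with rows summing to
    1 (rows of isolated nodes are zero)."""
    order = sorted(net.nodes)
    A = nx.adjacency_matrix(net.graph, nodelist=order).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return sp.diags(inv) @ A


def _support_mask(mat: sp.csr_matrix) -> sp.csr_matrix:
    mask = mat.copy()
    mask.data = np.ones_like(mask.data)
    return mask


def intra_network_smoothing(C: sp.csr_matrix, net_u: Network, net_v: Network,
                            alpha: float) -> sp.csr_matrix:
    """Blend each score with the mean score over the two nodes' neighbourhoods.

    C' = alpha*C + (1-alpha) * A_U C A_V^T with row-normalized adjacencies,
    restricted to the original support of C.
    """
    if not (0 <= alpha <= 1):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if alpha == 1:
        return C.copy()
    a_u = row_normalized_adjacency(net_u)
    a_v = row_normalized_adjacency(net_v)
    smoothed = (a_u @ C @ a_v.T).multiply(_support_mask(C))
    return (alpha * C + (1 - alpha) * smoothed).tocsr()


def cross_network_pct(cset: CorrespondenceSet, beta: float,
                      skip: set[tuple[str, str]] | None = None) -> CorrespondenceSet:
    """Refine each pair by averaging score compositions through third networks.

    C''(U,V) = beta*C(U,V) + (1-beta) * mean_W C(U,W) @ C(W,V), restricted to
    the original support of C(U,V).  With two networks this is the identity.
    Pairs in ``skip`` are copied through and excluded from receiving the
    transform (but still contribute to other pairs' cross terms).
    """
    if not (0 <= beta <= 1):
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    skip = skip or set()
    labels = sorted(cset.networks)
    out = cset.copy()
    if len(labels) < 3 or beta == 1:
        return out
    for key in cset.pair_keys():
        if key in skip:
            continue
        lab_u, lab_v = key
        C = cset.matrix(lab_u, lab_v)
        others = [w for w in labels if w not in key]
        acc = None
        for w in others:
            term = cset.matrix(lab_u, w) @ cset.matrix(w, lab_v)
            acc = term if acc is None else acc + term
        composed = (acc / len(others)).multiply(_support_mask(C))
        out.set_matrix(lab_u, lab_v, (beta * C + (1 - beta) * composed).tocsr())
    return out


def apply_selective_pct(cset: CorrespondenceSet,
                        params: PCTParams = PCTParams()) -> CorrespondenceSet:
    """Apply smoothing + cross-network PCT only to pairs with lambda <= lambda_t.

    A pair whose restart probability exceeds the threshold keeps its raw
    scores; such pairs still feed the cross terms of transformed pairs, as-is.
    """
    gated = {key for key, lam in cset.lam.items() if lam > params.lambda_t}
    stage1 = cset.copy()
    for key in cset.pair_keys():
        if key in gated:
            continue
        lab_u, lab_v = key
        C = cset.matrix(lab_u, lab_v)
        smoothed = intra_network_smoothing(C, cset.networks[lab_u],
                                           cset.networks[lab_v], params.alpha)
        stage1.set_matrix(lab_u, lab_v, smoothed)
    return cross_network_pct(stage1, params.beta, skip=gated)
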