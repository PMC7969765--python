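"""Network propagation: random walk with restart (RWR) priors.

The prior that a candidate is the risk gene of its locus, given the genes
currently selected at the other loci, is its RWR steady-state probability
when the walk restarts uniformly from those selected genes. Networks are
column-normalized by weighted degree; several networks are combined by
averaging their per-locus normalized candidate scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "RWRResult",
    "build_transition",
    "rwr",
    "rwr_propagator",
    "network_prior",
    "go_jaccard_network",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix over an ordered node universe."""

    nodes: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.nodes)}
        colsums = self.W.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-12):
            raise ValueError("transition matrix columns must sum to 1")

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class RWRResult:
    probabilities: np.ndarray
    restart_prob: float
    iterations: int
    residual: float


def build_transition(network: GeneNetwork, node_universe: list[str]) -> TransitionMatrix:
    """Column-normalize a network over a node universe.

    W[u, v] = weight(u, v) / strength(v). Universe nodes absent from the
    network, and zero-strength nodes, get a unit self-loop column so W stays
    stochastic without discarding genes.
    """
    if not node_universe:
        raise ValueError("empty node universe")
    missing = set(network.nodes) - set(node_universe)
    if missing:
        raise ValueError(f"universe lacks network nodes: {sorted(missing)[:5]}")
    n = len(node_universe)
    index = {g: i for i, g in enumerate(node_universe)}
    W = np.zeros((n, n))
    strength = np.zeros(n)
    for u, v, w in network.graph.edges(data="weight", default=1.0):
        iu, iv = index[u], index[v]
        W[iu, iv] += w
        W[iv, iu] += w
        strength[iu] += w
        strength[iv] += w
    dangling = strength <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(dangling[None, :], 0.0, W / np.where(dangling, 1.0, strength)[None, :])
    W[dangling, dangling] = 1.0
    return TransitionMatrix(nodes=list(node_universe), W=W)


def rwr(
    W: TransitionMatrix,
    restart: np.ndarray,
    r: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> RWRResult:
    """Random walk with restart by power iteration.

    Iterates p <- (1-r) W p + r e from p0 = e until the max-norm change
    drops below ``tol``; the fixed point solves p = r (I - (1-r)W)^{-1} e.
    """
    restart = np.asarray(restart, dtype=float)
    if restart.shape != (len(W),):
        raise ValueError("restart vector length mismatch")
    if not np.isclose(restart.sum(), 1.0, atol=1e-9) or np.any(restart < 0):
        raise ValueError("restart must be a probability vector")
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability r must be in (0, 1], got {r}")
    p = restart.copy()
    for it in range(1, max_iter + 1):
        p_new = (1.0 - r) * (W.W @ p) + r * restart
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol:
            return RWRResult(probabilities=p, restart_prob=r, iterations=it, residual=delta)
    raise ConvergenceError(f"RWR did not converge in {max_iter} iterations (residual {delta:.3g})")


def rwr_propagator(W: TransitionMatrix, r: float) -> np.ndarray:
    """Dense closed-form RWR kernel K = r (I - (1-r) W)^{-1}.

    K @ e gives the steady state for any restart vector e; used to make
    repeated Gibbs conditionals cheap. Agrees with :func:`rwr` to solver
    tolerance.
    """
    n = len(W)
    return r * np.linalg.inv(np.eye(n) - (1.0 - r) * W.W)


def network_prior(
    candidates: list[str],
    selected_others: list[str],
    networks: list[GeneNetwork],
    r: float = 0.5,
    floor_eps: float = 1e-6,
    combine: str = "mean",
    _propagators: list[tuple[TransitionMatrix, np.ndarray, set[str]]] | None = None,
) -> np.ndarray:
    """Network prior over a locus's candidates given the other loci's picks.

    Per network: restart uniformly from ``selected_others`` (restricted to
    that network's universe), read each candidate's steady-state
    probability, add ``floor_eps`` and renormalize over the candidates.
    Networks are combined by arithmetic mean (or elementwise product,
    renormalized). With no usable restart genes the prior is uniform.
    """
    k = len(candidates)
    if k == 0:
        raise ValueError("locus has no candidates")
    if k == 1:
        return np.ones(1)
    if not networks and _propagators is None:
        return np.full(k, 1.0 / k)

    if _propagators is None:
        universe = list(dict.fromkeys([*candidates, *selected_others]))
        seen = set(universe)
        for net in networks:
            for node in net.nodes:
                if node not in seen:
                    universe.append(node)
                    seen.add(node)
        _propagators = []
        for net in networks:
            T = build_transition(net, universe)
            _propagators.append((T, rwr_propagator(T, r), set(net.nodes)))

    per_network = []
    for T, K, member in _propagators:
        # restart restricted to genes the network actually contains
        seeds = [g for g in selected_others if g in member]
        if not seeds:
            per_network.append(np.full(k, 1.0 / k))
            continue
        # uniform restart over seeds == mean of the seed columns of K
        seed_idx = [T.index[g] for g in seeds]
        steady = K[:, seed_idx].mean(axis=1)
        raw = np.array([steady[T.index[g]] if g in T.index else 0.0 for g in candidates])
        raw = raw + floor_eps
        per_network.append(raw / raw.sum())

    if combine == "mean":
        prior = np.mean(per_network, axis=0)
    elif combine == "product":
        prior = np.prod(per_network, axis=0)
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return prior / prior.sum()


def go_jaccard_network(
    annotations: dict[str, set[str]], threshold: float = 0.3, name: str = "go_jaccard"
) -> GeneNetwork:
    """Build a gene network from annotation-term sets.

    Edges connect gene pairs whose term sets have Jaccard similarity above
    ``threshold`` (the >30% sharing convention), weighted by the similarity.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(annotations)
    genes = sorted(annotations)
    for i, gi in enumerate(genes):
        ti = annotations[gi]
        if not ti:
            continue
        for gj in genes[i + 1 :]:
            tj = annotations[gj]
            if not tj:
                continue
            jac = len(ti & tj) / len(ti | tj)
            if jac > threshold:
                graph.add_edge(gi, gj, weight=jac)
    return GeneNetwork(name=name, graph=graph)
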