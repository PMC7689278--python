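"""Time-bounded regulatory network construction and labeled influence maximization.

A gene regulatory network (TF → target), a protein-interaction network
(undirected gene–gene, instantiated in both directions) and the detected
perturbed sub-pathways are merged into one directed network whose edges all
pass the propagation-delay rule: delay ``d`` in ``[0, delay_threshold]`` and a
positive peak cross-correlation.  Each surviving edge carries a propagation
probability ``p = peak / T`` (peak concordance normalized by the number of
time points, floored at a small epsilon), optionally multiplied by a PIN
confidence.

Influence spreads under the independent-cascade model with a time budget:
activation along an edge consumes its delay, and activations arriving after
time ``T - 1`` (the observable window) are discarded.  Greedy labeled
influence maximization picks TF seeds by their marginal expected spread over
*target-labeled* nodes only (the sub-pathway genes).  The most influential
TF → sub-pathway regulatory paths are the highest-probability simple paths
within the delay budget, optionally required to pass through at least one
mediator gene.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from pertpath.mediators import MediatorGene
from pertpath.subpathway import DifferentialTimeVector, PerturbedSubpathway, propagation_delay

logger = logging.getLogger(__name__)

__all__ = [
    "TimeBoundedNetwork",
    "RegulatoryPath",
    "build_time_bounded_network",
    "influence_spread",
    "greedy_labeled_im",
    "extract_regulatory_paths",
    "terminator_proteins",
]

LABEL_PRIORITY = ("TF", "mediator", "pathway_gene", "other")


@dataclass
class TimeBoundedNetwork:
    """Directed network with node labels, per-edge delays and cascade probabilities."""

    graph: nx.DiGraph  # node attr: label; edge attrs: provenance, delay, peak, p
    n_time: int  # T, the observable window length

    @property
    def time_budget(self) -> int:
        return self.n_time - 1

    def nodes_with_label(self, label: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("label") == label]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TimeBoundedNetwork({self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges, T={self.n_time})"
        )


@dataclass
class RegulatoryPath:
    """An ordered TF → … → sub-pathway path with its influence score."""

    nodes: list[str]
    score: float  # product of edge probabilities
    cumulative_delay: int
    tf: str
    subpathway_id: str


def build_time_bounded_network(
    grn: Iterable[tuple[str, str]],
    pin: Iterable[tuple[str, str] | tuple[str, str, float]],
    subpathways: Sequence[PerturbedSubpathway],
    vectors: Mapping[str, DifferentialTimeVector],
    mediators: Sequence[MediatorGene] = (),
    delay_threshold: int | None = None,
    epsilon: float = 0.01,
) -> TimeBoundedNetwork:
    """Merge GRN, PIN and sub-pathway edges under the delay-validation rule.

    GRN edges stay directed; PIN edges are expanded to both directions and each
    direction validated independently; sub-pathway edges are imported with
    their existing validations.  Node labels are assigned with priority
    TF > mediator > pathway_gene > other.  Edge probability is
    ``clip(peak / T, epsilon, 1)``, multiplied by the PIN confidence when one
    is given.
    """
    if not subpathways:
        raise ValueError("no perturbed sub-pathways supplied; nothing to explain")
    some_vec = next(iter(vectors.values()))
    n_time = some_vec.T
    if delay_threshold is None:
        delay_threshold = int(math.ceil(n_time / 2))

    g = nx.DiGraph()

    def p_from_peak(peak: int, confidence: float = 1.0) -> float:
        return float(np.clip(peak / n_time * confidence, epsilon, 1.0))

    def try_add(u: str, v: str, provenance: str, confidence: float = 1.0) -> None:
        if u not in vectors or v not in vectors:
            logger.warning("%s edge %s->%s dropped (missing time vector)", provenance, u, v)
            return
        d, peak = propagation_delay(vectors[u], vectors[v])
        if 0 <= d <= delay_threshold and peak > 0:
            g.add_edge(u, v, provenance=provenance, delay=int(d), peak=int(peak),
                       p=p_from_peak(peak, confidence))

    for u, v in grn:
        try_add(u, v, "GRN")
    for edge in pin:
        if len(edge) == 3:
            a, b, conf = edge
        else:
            a, b = edge
            conf = 1.0
        try_add(a, b, "PIN", conf)
        try_add(b, a, "PIN", conf)
    for sp in subpathways:
        for ev in sp.edges:
            u, v = ev.edge
            if not ev.valid:
                continue
            g.add_edge(u, v, provenance="subpathway", delay=int(ev.delay),
                       peak=int(ev.peak), p=p_from_peak(ev.peak))

    tf_nodes = {u for u, _ in grn}
    mediator_nodes = {m.gene for m in mediators}
    pathway_nodes = {n for sp in subpathways for n in sp.genes}
    for n in g.nodes:
        if n in tf_nodes:
            label = "TF"
        elif n in mediator_nodes:
            label = "mediator"
        elif n in pathway_nodes:
            label = "pathway_gene"
        else:
            label = "other"
        g.nodes[n]["label"] = label
    return TimeBoundedNetwork(g, n_time)


# ---------------------------------------------------------------------------
# Independent-cascade influence
# ---------------------------------------------------------------------------


def _edge_arrays(net: TimeBoundedNetwork) -> tuple[list[str], dict[str, int], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nodes = sorted(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = sorted(net.graph.edges(data=True))
    src = np.array([index[u] for u, _, _ in edges], dtype=int)
    dst = np.array([index[v] for _, v, _ in edges], dtype=int)
    p = np.array([d["p"] for _, _, d in edges], dtype=float)
    delay = np.array([d["delay"] for _, _, d in edges], dtype=int)
    return nodes, index, src, dst, p, delay


def _cascade_reach(
    n_nodes: int,
    adj: list[list[tuple[int, int, int]]],
    seeds: Sequence[int],
    live: np.ndarray,
    budget: int,
) -> np.ndarray:
    """Earliest activation times over live edges from the seed set (Dijkstra)."""
    t = np.full(n_nodes, np.inf)
    heap: list[tuple[int, int]] = []
    for s in seeds:
        t[s] = 0
        heapq.heappush(heap, (0, s))
    while heap:
        tu, u = heapq.heappop(heap)
        if tu > t[u]:
            continue
        for eidx, v, d in adj[u]:
            if not live[eidx]:
                continue
            tv = tu + d
            if tv <= budget and tv < t[v]:
                t[v] = tv
                heapq.heappush(heap, (tv, v))
    return t


def _spread_over_draws(
    net: TimeBoundedNetwork,
    seeds: Sequence[str],
    targets: Sequence[str],
    draws: np.ndarray,
) -> float:
    nodes, index, src, dst, p, delay = _edge_arrays(net)
    n = len(nodes)
    adj: list[list[tuple[int, int, int]]] = [[] for _ in range(n)]
    for e in range(len(src)):
        adj[src[e]].append((e, int(dst[e]), int(delay[e])))
    seed_idx = [index[s] for s in seeds if s in index]
    target_mask = np.zeros(n, dtype=bool)
    for tgt in targets:
        if tgt in index:
            target_mask[index[tgt]] = True
    budget = net.time_budget
    total = 0.0
    live_all = draws < p  # (n_sim, E)
    for sim in range(draws.shape[0]):
        t = _cascade_reach(n, adj, seed_idx, live_all[sim], budget)
        total += float(np.sum(target_mask & np.isfinite(t)))
    return total / draws.shape[0]


def influence_spread(
    net: TimeBoundedNetwork,
    seeds: Iterable[str],
    targets: Iterable[str],
    n_sim: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo expected number of target nodes activated from the seeds.

    Independent-cascade semantics with a time budget: each edge fires at most
    once with its probability ``p``; a successful activation along an edge
    arrives after the edge's delay, and arrivals past ``T - 1`` are discarded.
    Seeds activate at time 0.  Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    seeds = list(seeds)
    targets = list(targets)
    rng = np.random.default_rng(seed)
    n_edges = net.graph.number_of_edges()
    draws = rng.random((n_sim, max(n_edges, 1)))[:, :n_edges]
    return _spread_over_draws(net, seeds, targets, draws)


def greedy_labeled_im(
    net: TimeBoundedNetwork,
    candidate_seeds: Iterable[str] | None = None,
    targets: Iterable[str] | None = None,
    k: int = 3,
    n_sim: int = 10_000,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Greedy seed selection maximizing expected spread over target-labeled nodes.

    At each step the TF with the largest marginal spread (estimated with
    common random numbers across candidates and iterations, for variance
    reduction) joins the seed set.  Returns ``(tf, marginal gain)`` pairs in
    selection order; stops early when no candidate adds positive gain.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cands = sorted(candidate_seeds) if candidate_seeds is not None else sorted(
        net.nodes_with_label("TF")
    )
    if not cands:
        raise ValueError("no candidate TF seeds supplied")
    tgts = list(targets) if targets is not None else net.nodes_with_label("pathway_gene")
    rng = np.random.default_rng(seed)
    n_edges = net.graph.number_of_edges()
    draws = rng.random((n_sim, max(n_edges, 1)))[:, :n_edges]

    chosen: list[str] = []
    gains: list[tuple[str, float]] = []
    base = 0.0
    for _ in range(min(k, len(cands))):
        best_tf, best_spread = None, base
        for tf in cands:
            if tf in chosen:
                continue
            spread = _spread_over_draws(net, chosen + [tf], tgts, draws)
            if spread > best_spread + 1e-12:
                best_tf, best_spread = tf, spread
        if best_tf is None:
            break
        chosen.append(best_tf)
        gains.append((best_tf, best_spread - base))
        base = best_spread
    if not gains:
        logger.warning("no TF reaches any target within the time budget")
    return gains


# ---------------------------------------------------------------------------
# Regulatory paths
# ---------------------------------------------------------------------------


def extract_regulatory_paths(
    net: TimeBoundedNetwork,
    tf: str,
    subpathway: PerturbedSubpathway,
    require_mediator: bool = False,
    max_paths: int = 10,
    max_candidates: int = 2000,
) -> list[RegulatoryPath]:
    """Highest-probability simple paths from a TF into a sub-pathway.

    Path score is the product of edge probabilities (found as minimal cost
    under additive ``-log p``); paths must respect the cumulative delay budget
    ``T - 1`` and, when ``require_mediator`` is set, contain at least one
    mediator-labeled interior node.  Ties are broken by shorter path, then by
    lexicographic node order.  Enumeration is by increasing cost via a virtual
    sink attached to every sub-pathway node, capped at ``max_candidates``
    pulls.
    """
    g = net.graph
    if tf not in g:
        return []
    if g.nodes[tf].get("label") != "TF":
        raise ValueError(f"{tf!r} is not labeled TF in the network")
    target_set = {n for n in subpathway.genes if n in g}
    target_set.discard(tf)
    if not target_set:
        return []

    work = nx.DiGraph()
    for u, v, d in g.edges(data=True):
        work.add_edge(u, v, nlogp=-math.log(d["p"]), p=d["p"], delay=d["delay"])
    for n in g.nodes:
        if n not in work:
            work.add_node(n)
    sink = object()  # unhashable-by-name sentinel that cannot collide with genes
    for tgt in target_set:
        work.add_edge(tgt, sink, nlogp=0.0, p=1.0, delay=0)

    budget = net.time_budget
    found: list[RegulatoryPath] = []
    try:
        gen = nx.shortest_simple_paths(work, tf, sink, weight="nlogp")
        for pulls, path in enumerate(gen):
            if pulls >= max_candidates:
                break
            nodes = path[:-1]  # strip the sink
            if len(nodes) < 2:
                continue
            delay_sum = sum(work.edges[u, v]["delay"] for u, v in zip(nodes, nodes[1:]))
            if delay_sum > budget:
                continue
            if require_mediator:
                interior = nodes[1:-1]
                if not any(g.nodes[n].get("label") == "mediator" for n in interior):
                    continue
            score = 1.0
            for u, v in zip(nodes, nodes[1:]):
                score *= work.edges[u, v]["p"]
            found.append(
                RegulatoryPath(
                    nodes=list(nodes),
                    score=score,
                    cumulative_delay=delay_sum,
                    tf=tf,
                    subpathway_id=f"{subpathway.pathway_name}:{subpathway.component_id}",
                )
            )
    except nx.NetworkXNoPath:
        pass
    if require_mediator and not found:
        logger.warning("no path from %s carries a mediator gene", tf)
    found.sort(key=lambda rp: (-rp.score, len(rp.nodes), rp.nodes))
    return found[:max_paths]


def terminator_proteins(net: TimeBoundedNetwork) -> set[str]:
    """Nodes without outgoing edges (includes isolated nodes)."""
    return {n for n in net.graph.nodes if net.graph.out_degree(n) == 0}
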