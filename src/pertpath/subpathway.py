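"""Perturbed sub-pathway detection from control/treated time-series expression.

Each gene receives a *differential time vector* ``v`` of length ``T`` with
entries in ``{-1, 0, +1}`` (under/unchanged/over-expressed at each time point,
treated vs. a reference).  For a directed pathway edge ``N1 -> N2`` the lagged
cross-correlation of the two vectors,

    (v1 * v2)(n) = sum_t v1(t) v2(t + n),      v(t) = 0 outside 1..T,

measures how well the change at ``N1`` is followed, ``n`` time points later, by
a concordant change at ``N2``.  The lag maximizing the cross-correlation is the
edge's propagation delay; edges with negative delay (propagation against the
edge direction), delay beyond a threshold, or non-positive peak are invalid.
Weakly connected components of the valid-edge subgraph with enough edges are
reported as perturbed sub-pathways, scored by the sum of per-edge peaks and
assessed by a permutation test that reassigns gene vectors from a donor pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialTimeVector",
    "PathwayGraph",
    "EdgeValidation",
    "PerturbedSubpathway",
    "moderated_t_deg",
    "build_time_vectors",
    "cross_correlation",
    "propagation_delay",
    "validate_edges",
    "extract_subpathways",
    "permutation_pvalue",
    "bh_fdr",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentialTimeVector:
    """Per-gene ternary call vector over time points.

    ``v[t]`` is +1 (over-expressed), -1 (under-expressed) or 0 (unchanged) at
    time point ``t+1``; entries outside ``1..T`` are treated as 0 wherever the
    vector enters a lagged sum.
    """

    gene: str
    v: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.v, dtype=int)
        if arr.ndim != 1:
            raise ValueError("time vector must be one-dimensional")
        if not np.isin(arr, (-1, 0, 1)).all():
            raise ValueError(f"time vector entries must be in {{-1,0,1}}: {arr}")
        object.__setattr__(self, "v", arr)

    @property
    def T(self) -> int:
        return self.v.shape[0]


class PathwayGraph:
    """Directed gene graph for one pathway.

    A thin wrapper around :class:`networkx.DiGraph` that forbids self-loops and
    carries an optional per-edge relation label (activation/inhibition labels
    from curated pathway sources are carried through but not interpreted).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str] | tuple[str, str, str]],
        name: str = "pathway",
        nodes: Iterable[str] | None = None,
    ) -> None:
        g = nx.DiGraph(name=name)
        if nodes is not None:
            g.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 3:
                u, v, rel = edge
            else:
                u, v = edge
                rel = None
            if u == v:
                raise ValueError(f"self-loop {u}->{v} not allowed in pathway {name!r}")
            g.add_edge(u, v, relation=rel)
        self.graph = g
        self.name = name

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PathwayGraph({self.name!r}, {self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges)"
        )


@dataclass(frozen=True)
class EdgeValidation:
    """Delay and peak cross-correlation for one directed edge."""

    edge: tuple[str, str]
    delay: int
    peak: int
    valid: bool


@dataclass
class PerturbedSubpathway:
    """A connected valid-edge subgraph with its propagation statistic."""

    pathway_name: str
    component_id: int
    edges: list[EdgeValidation]
    statistic: float
    p_value: float | None = None
    fdr: float | None = None

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.edges:
            seen.setdefault(ev.edge[0])
            seen.setdefault(ev.edge[1])
        return list(seen)

    @property
    def edge_tuples(self) -> list[tuple[str, str]]:
        return [ev.edge for ev in self.edges]

    @property
    def delays(self) -> dict[tuple[str, str], int]:
        return {ev.edge: ev.delay for ev in self.edges}


# ---------------------------------------------------------------------------
# Differential-expression calling
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the asymptotic start 0.5 + 1/x and iterates on the monotone decreasing
    trigamma; converges in a handful of steps for the range met in variance
    moderation.
    """
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes moderation of per-gene sample variances.

    Assumes the scaled inverse-chi-square hierarchy: each gene variance
    ``sigma_g^2`` is drawn from ``s0^2 * d0 / chi^2_{d0}``, so the observed
    ``s_g^2`` follow a scaled F distribution.  The prior df ``d0`` and prior
    variance ``s0^2`` are fitted by the method of moments on ``log s_g^2``:
    the excess variance of ``log s_g^2`` beyond ``trigamma(df/2)`` determines
    ``d0`` through the trigamma inverse, and the mean determines ``s0^2``.

    Returns ``(posterior variances, d0, s0sq)``; ``d0`` is ``inf`` when the
    observed variances show no excess dispersion (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        # Too few informative genes: no moderation possible.
        return s2.copy(), 0.0, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([excess]))[0])
        s0sq = float(np.exp(emean + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
        post = np.full_like(s2, s0sq)
    # Genes with zero sample variance still get the prior contribution.
    return post, d0, s0sq


def moderated_t_deg(
    control: np.ndarray,
    treated: np.ndarray,
    lfc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
    genes: Sequence[str] | None = None,
) -> np.ndarray:
    """Call per-gene differential expression at one time point.

    Parameters
    ----------
    control, treated
        ``(genes, replicates)`` matrices of (log-scale) expression for the two
        arms at a single time point.  Replicate counts may differ between arms.
    lfc_cutoff, p_cutoff
        A gene is called +1 when its moderated-t p-value is below ``p_cutoff``
        and its log-fold-change exceeds ``lfc_cutoff`` (−1 symmetrically),
        otherwise 0.

    With a single replicate in each arm no variance can be estimated and the
    call falls back to the fold-change criterion alone.

    Returns an integer array in ``{-1, 0, +1}`` of length ``genes``.
    """
    control = np.atleast_2d(np.asarray(control, dtype=float))
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    if control.shape[0] != treated.shape[0]:
        raise ValueError(
            f"gene sets differ between arms: {control.shape[0]} vs {treated.shape[0]}"
        )
    n_c, n_t = control.shape[1], treated.shape[1]
    lfc = treated.mean(axis=1) - control.mean(axis=1)
    calls = np.zeros(control.shape[0], dtype=int)

    if n_c == 1 and n_t == 1:
        calls[lfc > lfc_cutoff] = 1
        calls[lfc < -lfc_cutoff] = -1
        return calls

    df = n_c + n_t - 2
    ss = np.sum((control - control.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ss += np.sum((treated - treated.mean(axis=1, keepdims=True)) ** 2, axis=1)
    s2 = ss / df
    s2_post, d0, _ = squeeze_variances(s2, df)
    df_total = df + d0 if np.isfinite(d0) else np.inf
    se = np.sqrt(s2_post * (1.0 / n_c + 1.0 / n_t))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc != 0, np.inf * np.sign(lfc), 0.0))
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    up = (p < p_cutoff) & (lfc > lfc_cutoff)
    dn = (p < p_cutoff) & (lfc < -lfc_cutoff)
    calls[up] = 1
    calls[dn] = -1
    return calls


def build_time_vectors(
    treated_series: np.ndarray,
    genes: Sequence[str],
    control_series: np.ndarray | None = None,
    mode: str = "vs_control",
    lfc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
) -> dict[str, DifferentialTimeVector]:
    """Assemble one differential time vector per gene.

    Parameters
    ----------
    treated_series
        ``(genes, time, replicates)`` array of treated-arm expression.
    control_series
        Same-shape control arm; required for ``mode="vs_control"``.
    mode
        ``vs_control`` compares treated vs. control at each time point;
        ``vs_previous`` and ``vs_initial`` compare the treated arm against its
        own previous / first time point (used when no control arm exists).
        ``vs_previous`` leaves t=1 unchanged (0) by construction.
    """
    treated_series = np.asarray(treated_series, dtype=float)
    if treated_series.ndim != 3:
        raise ValueError("treated_series must be (genes, time, replicates)")
    n_gene, n_time, _ = treated_series.shape
    if n_time < 2:
        raise ValueError(f"need at least 2 time points, got {n_time}")
    if len(genes) != n_gene:
        raise ValueError("gene list length does not match expression array")

    calls = np.zeros((n_gene, n_time), dtype=int)
    if mode == "vs_control":
        if control_series is None:
            raise ValueError("mode='vs_control' requires a control arm")
        control_series = np.asarray(control_series, dtype=float)
        if control_series.shape[:2] != treated_series.shape[:2]:
            raise ValueError("control and treated arms must share gene/time axes")
        for t in range(n_time):
            calls[:, t] = moderated_t_deg(
                control_series[:, t, :], treated_series[:, t, :], lfc_cutoff, p_cutoff
            )
    elif mode == "vs_previous":
        for t in range(1, n_time):
            calls[:, t] = moderated_t_deg(
                treated_series[:, t - 1, :], treated_series[:, t, :], lfc_cutoff, p_cutoff
            )
    elif mode == "vs_initial":
        for t in range(1, n_time):
            calls[:, t] = moderated_t_deg(
                treated_series[:, 0, :], treated_series[:, t, :], lfc_cutoff, p_cutoff
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return {g: DifferentialTimeVector(g, calls[i]) for i, g in enumerate(genes)}


# ---------------------------------------------------------------------------
# Cross-correlation and edge validation
# ---------------------------------------------------------------------------


def _as_vec(v: DifferentialTimeVector | np.ndarray | Sequence[int]) -> np.ndarray:
    if isinstance(v, DifferentialTimeVector):
        return v.v
    return np.asarray(v, dtype=int)


def cross_correlation(
    v1: DifferentialTimeVector | Sequence[int],
    v2: DifferentialTimeVector | Sequence[int],
    n: int,
) -> int:
    """Lagged inner product ``sum_t v1(t) v2(t+n)`` with zero padding outside 1..T."""
    a, b = _as_vec(v1), _as_vec(v2)
    if a.shape != b.shape:
        raise ValueError("time vectors must have equal length")
    T = a.shape[0]
    if n >= 0:
        overlap = T - n
        if overlap <= 0:
            return 0
        return int(np.dot(a[:overlap], b[n:]))
    m = -n
    overlap = T - m
    if overlap <= 0:
        return 0
    return int(np.dot(a[m:], b[:overlap]))


def propagation_delay(
    v1: DifferentialTimeVector | Sequence[int],
    v2: DifferentialTimeVector | Sequence[int],
) -> tuple[int, int]:
    """Delay maximizing the cross-correlation, with its peak value.

    The argmax runs over lags ``n`` in ``[-(T-1), T-1]``.  Ties are broken
    toward the largest ``|n|``, preferring non-negative ``n`` on a sign tie.
    For sustained (step-like) responses the cross-correlation plateaus over
    the lags between 0 and the onset difference, and the far plateau endpoint
    is exactly that onset difference, so this rule recovers the true
    propagation delay; a plateau extending to negative lags signals reversed
    propagation and is reported as such.
    """
    a, b = _as_vec(v1), _as_vec(v2)
    T = a.shape[0]
    # Candidate lags sorted by the tie-break preference order.
    lags = sorted(range(-(T - 1), T), key=lambda n: (-abs(n), n < 0))
    best_n, best_val = lags[0], cross_correlation(a, b, lags[0])
    for n in lags[1:]:
        val = cross_correlation(a, b, n)
        if val > best_val:
            best_val, best_n = val, n
    return best_n, best_val


def validate_edges(
    pathway: PathwayGraph,
    vectors: Mapping[str, DifferentialTimeVector],
    delay_threshold: int | None = None,
) -> list[EdgeValidation]:
    """Validate every pathway edge by the delay rule.

    An edge is valid iff its propagation delay ``d`` satisfies
    ``0 <= d <= delay_threshold`` and its peak cross-correlation is positive.
    Edges with an endpoint lacking a time vector are skipped with a warning.
    ``delay_threshold`` defaults to ``ceil(T/2)``.
    """
    out: list[EdgeValidation] = []
    threshold = delay_threshold
    for u, v in pathway.edges:
        if u not in vectors or v not in vectors:
            logger.warning(
                "pathway %s: edge %s->%s skipped (missing time vector)", pathway.name, u, v
            )
            continue
        if threshold is None:
            threshold = int(np.ceil(vectors[u].T / 2))
        d, peak = propagation_delay(vectors[u], vectors[v])
        valid = (0 <= d <= threshold) and peak > 0
        out.append(EdgeValidation((u, v), d, peak, valid))
    return out


def extract_subpathways(
    pathway: PathwayGraph,
    validations: Sequence[EdgeValidation],
    min_edges: int = 3,
) -> list[PerturbedSubpathway]:
    """Weakly connected components of the valid-edge subgraph with >= min_edges edges.

    The component statistic is the sum of per-edge peak cross-correlations.
    """
    valid = [ev for ev in validations if ev.valid]
    g = nx.DiGraph()
    for ev in valid:
        g.add_edge(*ev.edge, validation=ev)
    out: list[PerturbedSubpathway] = []
    cid = 0
    for comp in nx.weakly_connected_components(g):
        sub = g.subgraph(comp)
        evs = [g.edges[e]["validation"] for e in sub.edges]
        if len(evs) < min_edges:
            continue
        out.append(
            PerturbedSubpathway(
                pathway_name=pathway.name,
                component_id=cid,
                edges=sorted(evs, key=lambda ev: ev.edge),
                statistic=float(sum(ev.peak for ev in evs)),
            )
        )
        cid += 1
    return out


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def _peak_stack(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Peak cross-correlation over all lags for stacked vector pairs.

    ``v1``, ``v2`` have shape ``(..., T)``; returns the per-pair maximum of the
    lagged inner product over lags ``-(T-1)..(T-1)``.
    """
    T = v1.shape[-1]
    best = None
    for n in range(-(T - 1), T):
        if n >= 0:
            val = np.einsum("...t,...t->...", v1[..., : T - n], v2[..., n:])
        else:
            val = np.einsum("...t,...t->...", v1[..., -n:], v2[..., : T + n])
        best = val if best is None else np.maximum(best, val)
    return best


def permutation_pvalue(
    subpathway: PerturbedSubpathway,
    vectors_pool: Mapping[str, DifferentialTimeVector],
    B: int = 999,
    seed: int = 0,
    ties: str = "upper",
) -> float:
    """Permutation p-value for a sub-pathway's propagation statistic.

    For each of ``B`` permutations the sub-pathway's genes are reassigned time
    vectors drawn without replacement from the genome-wide donor pool, and the
    statistic (sum of per-edge peak cross-correlations over the observed edge
    set, with no validity filtering) is recomputed.

    The statistic is a sum of small integers, so permuted values tie with the
    observed one often.  ``ties="upper"`` (default) counts every tie as
    exceeding, giving the conservative plus-one tail fraction
    ``(1 + #{perm >= obs}) / (B + 1)`` used for inference.  ``ties="random"``
    splits ties uniformly at random (seeded), making the p-value exactly
    uniform on ``{1/(B+1), ..., 1}`` under the null — the form to use when
    checking calibration.  Both are bounded in ``[1/(B+1), 1]`` and
    deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if ties not in ("upper", "random"):
        raise ValueError("ties must be 'upper' or 'random'")
    genes = subpathway.genes
    pool_genes = list(vectors_pool)
    if len(pool_genes) < len(genes):
        raise ValueError(
            f"donor pool ({len(pool_genes)} genes) smaller than sub-pathway ({len(genes)})"
        )
    pool = np.stack([vectors_pool[g].v for g in pool_genes])  # (N, T)
    gene_index = {g: i for i, g in enumerate(genes)}
    src = np.array([gene_index[ev.edge[0]] for ev in subpathway.edges])
    dst = np.array([gene_index[ev.edge[1]] for ev in subpathway.edges])

    rng = np.random.default_rng(seed)
    k = len(genes)
    # (B, k) donor indices, each row a draw without replacement.
    assign = np.array([rng.choice(pool.shape[0], size=k, replace=False) for _ in range(B)])
    v_genes = pool[assign]  # (B, k, T)
    peaks = _peak_stack(v_genes[:, src, :], v_genes[:, dst, :])  # (B, E)
    perm_stats = peaks.sum(axis=1)
    n_greater = int(np.sum(perm_stats > subpathway.statistic))
    n_tied = int(np.sum(perm_stats == subpathway.statistic))
    if ties == "upper":
        p = (1.0 + n_greater + n_tied) / (B + 1.0)
    else:
        # Rank of the observed value among {obs, perms} with ties split at
        # random: exactly uniform on {1/(B+1), ..., 1} under the null.
        k = int(rng.integers(0, n_tied + 1))
        p = (1.0 + n_greater + k) / (B + 1.0)
    return float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (reported alongside raw p)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
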