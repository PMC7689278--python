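"""Synthetic pipeline inputs with planted, recoverable ground truth.

Two generators cover the pipeline's input families:

* :func:`generate_timeseries` plants an additive perturbation that starts at a
  set of source genes at the first time point and propagates along directed
  pathway edges with a fixed per-edge lag, on top of a shared control
  baseline.  The planted propagating edge set and per-edge delays are recorded
  so sub-pathway recovery can be scored exactly.
* :func:`generate_multiomics` builds a low-rank (cell line × gene × omics)
  tensor from random CP factors, squashes the methylation slice to [0,1] and
  thresholds the mutation slice to sparse binary (latent value above its 80th
  percentile), then generates IC50 from a chosen subset of cell-line factor
  columns.  The factors and the causal subset are recorded.

Both are deterministic given their seed and write plain TSV files matching the
downstream readers, so the generator doubles as format documentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from pertpath.preprocess import GeneCentricMatrix
from pertpath.subpathway import PathwayGraph

__all__ = [
    "TimeSeriesFixture",
    "MultiOmicsFixture",
    "generate_timeseries",
    "generate_multiomics",
]

#: Sparsity threshold for the binary mutation slice: the latent continuous
#: value must exceed its 80th percentile, emulating the sparsity of real
#: mutation calls.
MUTATION_PERCENTILE = 80.0


@dataclass
class TimeSeriesFixture:
    """Control/treated time-series arrays with the planted propagation truth."""

    genes: list[str]
    control: np.ndarray  # (gene, time, replicate)
    treated: np.ndarray  # same shape
    truth_subpathway: set[tuple[str, str]]
    truth_delays: dict[tuple[str, str], int]
    seed: int

    @property
    def n_time(self) -> int:
        return self.control.shape[1]

    def write(self, outdir: str | Path) -> None:
        """Write long-format expression TSV plus a JSON truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for arm, arr in (("control", self.control), ("treated", self.treated)):
            for i, g in enumerate(self.genes):
                for t in range(arr.shape[1]):
                    for r in range(arr.shape[2]):
                        rows.append((g, t + 1, r + 1, arm, arr[i, t, r]))
        pd.DataFrame(
            rows, columns=["gene", "time", "replicate", "arm", "value"]
        ).to_csv(outdir / "timeseries.tsv", sep="\t", index=False)
        truth = {
            "edges": sorted([list(e) for e in self.truth_subpathway]),
            "delays": {f"{u}->{v}": d for (u, v), d in sorted(self.truth_delays.items())},
            "seed": self.seed,
        }
        (outdir / "timeseries_truth.json").write_text(json.dumps(truth, indent=2))


@dataclass
class MultiOmicsFixture:
    """Four gene-centric omics layers, IC50, and the planted factor truth."""

    cell_lines: list[str]
    genes: list[str]
    omics_matrices: dict[str, pd.DataFrame]  # kind -> (cell × gene)
    ic50: pd.Series  # per cell line; metadata records the scale
    truth_cell_factors: np.ndarray  # (cell, rank)
    truth_gene_factors: np.ndarray  # (gene, rank)
    truth_omics_factors: np.ndarray  # (4, rank)
    causal_factors: tuple[int, ...]  # 0-based factor indices driving IC50
    ic50_scale: str
    seed: int

    def gene_centric(self) -> list[GeneCentricMatrix]:
        return [
            GeneCentricMatrix(df.copy(), kind, {"source": "synthetic"})
            for kind, df in self.omics_matrices.items()
        ]

    def write(self, outdir: str | Path) -> None:
        """Write one wide TSV per omics layer, the IC50 table, and the truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for kind, df in self.omics_matrices.items():
            df.to_csv(outdir / f"{kind}.tsv", sep="\t", index_label="cell_line")
        self.ic50.rename("ic50").to_csv(outdir / "ic50.tsv", sep="\t", index_label="cell_line")
        truth = {
            "causal_factors": list(self.causal_factors),
            "cell_factors": self.truth_cell_factors.tolist(),
            "gene_factors": self.truth_gene_factors.tolist(),
            "omics_factors": self.truth_omics_factors.tolist(),
            "ic50_scale": self.ic50_scale,
            "seed": self.seed,
        }
        (outdir / "multiomics_truth.json").write_text(json.dumps(truth, indent=2))


def generate_timeseries(
    pathway: PathwayGraph,
    source_genes: Iterable[str],
    delay_per_edge: int = 1,
    amplitude: float = 10.0,
    noise_sd: float = 0.2,
    n_time: int = 4,
    n_rep: int = 3,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
) -> TimeSeriesFixture:
    """Plant a propagating perturbation on a pathway graph.

    The control arm is a per-gene constant baseline (drawn once, log2-intensity
    scale) plus replicate noise.  The treated arm adds ``amplitude`` to every
    gene from its activation time on: source genes activate at time 1, and
    activation propagates along each directed edge with lag ``delay_per_edge``
    (shortest-lag arrival wins when paths converge).  Edges whose propagation
    completes within the observed window form the recorded truth sub-pathway.
    """
    if delay_per_edge < 0:
        raise ValueError("delay_per_edge must be >= 0")
    if n_time < 2:
        raise ValueError("n_time must be >= 2")
    source_genes = list(source_genes)
    for g in source_genes:
        if g not in pathway:
            raise ValueError(f"unknown source gene {g!r}: not in pathway {pathway.name!r}")

    genes = pathway.nodes
    rng = np.random.default_rng(seed)

    # Activation time (1-based) = 1 + delay * hop distance from nearest source.
    dist: dict[str, int] = {}
    for src in source_genes:
        for node, d in nx.single_source_shortest_path_length(pathway.graph, src).items():
            if node not in dist or d < dist[node]:
                dist[node] = d
    activation = {g: 1 + delay_per_edge * d for g, d in dist.items()}

    truth_edges: set[tuple[str, str]] = set()
    truth_delays: dict[tuple[str, str], int] = {}
    for u, v in pathway.edges:
        if u in activation and v in activation:
            # Edge propagates iff v's activation is exactly one lag after u's
            # and both fall inside the observed window.
            if activation[v] == activation[u] + delay_per_edge and activation[v] <= n_time:
                truth_edges.add((u, v))
                truth_delays[(u, v)] = delay_per_edge

    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    shape = (len(genes), n_time, n_rep)
    control = baseline[:, None, None] + rng.normal(0.0, noise_sd, size=shape)
    treated = baseline[:, None, None] + rng.normal(0.0, noise_sd, size=shape)
    for i, g in enumerate(genes):
        t0 = activation.get(g)
        if t0 is not None and t0 <= n_time:
            treated[i, t0 - 1 :, :] += amplitude
    return TimeSeriesFixture(genes, control, treated, truth_edges, truth_delays, seed)


def _squash01(x: np.ndarray) -> np.ndarray:
    """Logistic squash to (0,1), centered on the array median for spread."""
    scale = np.std(x)
    scale = scale if scale > 0 else 1.0
    return 1.0 / (1.0 + np.exp(-(x - np.median(x)) / scale))


def generate_multiomics(
    n_cell: int = 60,
    n_gene: int = 200,
    rank: int = 3,
    causal_factors: Sequence[int] = (0,),
    effect_size: float = 5.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> MultiOmicsFixture:
    """Plant low-rank multi-omics structure whose cell-line factors drive IC50.

    The tensor is an exact rank-``rank`` CP construction plus Gaussian noise.
    The expression and copy-number slices keep the raw low-rank values; the
    methylation slice is squashed to [0,1]; the mutation slice is binarized at
    the 80th percentile of its latent values.  IC50 (reported on the natural
    scale, μM-like) is ``exp(effect_size * sum of causal cell-factor columns
    + noise)``, so the log-IC50 is linear in the planted factors.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if n_cell < rank:
        raise ValueError("need n_cell >= rank")
    causal = tuple(int(f) for f in causal_factors)
    for f in causal:
        if not 0 <= f < rank:
            raise ValueError(f"causal factor index {f} out of range for rank {rank}")

    rng = np.random.default_rng(seed)
    cells = [f"CELL{i:03d}" for i in range(n_cell)]
    genes = [f"G{j:04d}" for j in range(n_gene)]

    C = rng.standard_normal((n_cell, rank))
    G = rng.standard_normal((n_gene, rank))
    O = np.abs(rng.standard_normal((4, rank))) + 0.5  # keep every omics loaded
    low_rank = np.einsum("if,jf,kf->ijk", C, G, O)
    noisy = low_rank + rng.normal(0.0, noise_sd, size=low_rank.shape)

    expr = noisy[:, :, 0]
    cnv = noisy[:, :, 1]
    meth = _squash01(noisy[:, :, 2])
    mut_latent = noisy[:, :, 3]
    mut = (mut_latent > np.percentile(mut_latent, MUTATION_PERCENTILE)).astype(float)

    log_ic50 = effect_size * C[:, list(causal)].sum(axis=1) + rng.normal(
        0.0, noise_sd, size=n_cell
    )
    ic50 = pd.Series(np.exp(log_ic50), index=cells, name="ic50")

    mats = {
        "expression": pd.DataFrame(expr, index=cells, columns=genes),
        "copy_number": pd.DataFrame(cnv, index=cells, columns=genes),
        "methylation": pd.DataFrame(meth, index=cells, columns=genes),
        "mutation": pd.DataFrame(mut, index=cells, columns=genes),
    }
    return MultiOmicsFixture(
        cell_lines=cells,
        genes=genes,
        omics_matrices=mats,
        ic50=ic50,
        truth_cell_factors=C,
        truth_gene_factors=G,
        truth_omics_factors=O,
        causal_factors=causal,
        ic50_scale="natural (exp of linear factor model); log is linear in factors",
        seed=seed,
    )
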