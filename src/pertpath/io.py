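"""Readers and writers for the plain-text interchange formats.

Wide matrices are TSV with the first column naming one axis and the header row
the other; long tables carry one observation per row.  Gene identifiers are
opaque strings matched case-sensitively.  Pathway graphs are read from
edge-list TSV, GML, or a minimal KGML subset (gene-type entries and their
relations).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from pertpath.network import RegulatoryPath, TimeBoundedNetwork
from pertpath.subpathway import EdgeValidation, PathwayGraph, PerturbedSubpathway

logger = logging.getLogger(__name__)

__all__ = [
    "read_wide_matrix",
    "read_long_timeseries",
    "read_pathway_edgelist",
    "read_pathway_gml",
    "read_pathway_kgml",
    "read_grn",
    "read_pin",
    "read_literature_scores",
    "write_subpathway_tables",
    "write_network",
    "write_paths",
]


def read_wide_matrix(path: str | Path) -> pd.DataFrame:
    """Wide TSV: first column is the row axis, header row the column axis."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_long_timeseries(
    path: str | Path,
) -> tuple[list[str], np.ndarray | None, np.ndarray]:
    """Long TSV with columns (gene, time, replicate, arm, value).

    Returns ``(genes, control, treated)`` as (gene × time × replicate) arrays;
    ``control`` is None when the file has no control arm.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "time", "replicate", "arm", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"time-series file must have columns {sorted(required)}")
    genes = list(pd.unique(df["gene"]))
    times = sorted(df["time"].unique())
    reps = sorted(df["replicate"].unique())
    gidx = {g: i for i, g in enumerate(genes)}
    tidx = {t: i for i, t in enumerate(times)}
    ridx = {r: i for i, r in enumerate(reps)}

    def arm_array(arm: str) -> np.ndarray | None:
        sub = df[df["arm"] == arm]
        if sub.empty:
            return None
        arr = np.full((len(genes), len(times), len(reps)), np.nan)
        arr[
            sub["gene"].map(gidx).to_numpy(),
            sub["time"].map(tidx).to_numpy(),
            sub["replicate"].map(ridx).to_numpy(),
        ] = sub["value"].to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError(f"incomplete {arm} arm: missing gene/time/replicate cells")
        return arr

    treated = arm_array("treated")
    if treated is None:
        raise ValueError("time-series file has no treated arm")
    return genes, arm_array("control"), treated


def read_pathway_edgelist(path: str | Path, name: str | None = None) -> PathwayGraph:
    """Edge-list TSV with columns (source, target[, relation])."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("pathway edge list needs at least source and target columns")
    rel = df[cols[2]] if len(cols) > 2 else [None] * len(df)
    edges = [(str(u), str(v), r) for u, v, r in zip(df[cols[0]], df[cols[1]], rel)]
    return PathwayGraph(edges, name=name or Path(path).stem)


def read_pathway_gml(path: str | Path, name: str | None = None) -> PathwayGraph:
    g = nx.read_gml(path)
    edges = [(str(u), str(v), d.get("relation")) for u, v, d in g.edges(data=True)]
    return PathwayGraph(edges, name=name or Path(path).stem, nodes=[str(n) for n in g.nodes])


def read_pathway_kgml(path: str | Path, name: str | None = None) -> PathwayGraph:
    """Minimal KGML reader: gene-type entries and entry-to-entry relations.

    Only ``<entry type="gene">`` elements and ``<relation>`` elements between
    them are interpreted; an entry's first gene name stands for the node.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    entry_gene: dict[str, str] = {}
    for entry in root.iter("entry"):
        if entry.get("type") != "gene":
            continue
        names = (entry.get("name") or "").split()
        if names:
            entry_gene[entry.get("id")] = names[0]
    edges = []
    for rel in root.iter("relation"):
        u = entry_gene.get(rel.get("entry1"))
        v = entry_gene.get(rel.get("entry2"))
        if u is None or v is None or u == v:
            continue
        subtypes = ";".join(s.get("name", "") for s in rel.iter("subtype")) or None
        edges.append((u, v, subtypes))
    return PathwayGraph(edges, name=name or root.get("title") or Path(path).stem,
                        nodes=list(entry_gene.values()))


def read_grn(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return [(str(a), str(b)) for a, b in zip(df[cols[0]], df[cols[1]])]


def read_pin(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    conf = df[cols[2]].astype(float) if len(cols) > 2 else pd.Series(1.0, index=df.index)
    return [(str(a), str(b), float(c)) for a, b, c in zip(df[cols[0]], df[cols[1]], conf)]


def read_literature_scores(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return {str(g): float(s) for g, s in zip(df[cols[0]], df[cols[1]])}


def write_subpathway_tables(
    subpathways: Sequence[PerturbedSubpathway],
    validations: Sequence[EdgeValidation],
    outdir: str | Path,
) -> None:
    """Sub-pathway summary TSV plus the per-edge validation TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "pathway": sp.pathway_name,
            "component_id": sp.component_id,
            "n_edges": len(sp.edges),
            "statistic": sp.statistic,
            "p_value": sp.p_value,
            "fdr": sp.fdr,
        }
        for sp in subpathways
    ]
    pd.DataFrame(rows, columns=["pathway", "component_id", "n_edges", "statistic",
                                "p_value", "fdr"]).to_csv(
        outdir / "subpathways.tsv", sep="\t", index=False
    )
    erows = [
        {"source": ev.edge[0], "target": ev.edge[1], "delay": ev.delay,
         "peak": ev.peak, "valid": ev.valid}
        for ev in validations
    ]
    pd.DataFrame(erows, columns=["source", "target", "delay", "peak", "valid"]).to_csv(
        outdir / "edges.tsv", sep="\t", index=False
    )


def write_network(net: TimeBoundedNetwork, outdir: str | Path) -> None:
    """GraphML plus node/edge TSV exports of the time-bounded network."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.graph, outdir / "network.graphml")
    nodes = pd.DataFrame(
        [{"node": n, "label": d.get("label", "other")} for n, d in net.graph.nodes(data=True)]
    )
    nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "provenance": d["provenance"],
             "delay": d["delay"], "peak": d["peak"], "p": d["p"]}
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
    )
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)


def write_paths(paths: Sequence[RegulatoryPath], outfile: str | Path) -> None:
    rows = [
        {
            "tf": rp.tf,
            "subpathway_id": rp.subpathway_id,
            "path": ";".join(rp.nodes),
            "score": rp.score,
            "cumulative_delay": rp.cumulative_delay,
        }
        for rp in paths
    ]
    pd.DataFrame(rows, columns=["tf", "subpathway_id", "path", "score",
                                "cumulative_delay"]).to_csv(outfile, sep="\t", index=False)
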