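"""Gene-centric (cell line × gene) matrix construction from per-omics tables.

Four omics layers are harmonized onto shared cell-line and gene axes:
expression and copy number are min–max normalized to [0,1]; mutation calls are
binarized (1 iff any mutation record exists for the cell line / gene pair);
promoter methylation is the mean beta of probes within 1 kb upstream of the
transcription start site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCentricMatrix",
    "minmax_normalize",
    "binarize_mutation",
    "promoter_average_methylation",
    "align_matrices",
]

OMICS_KINDS = ("expression", "copy_number", "methylation", "mutation")


@dataclass
class GeneCentricMatrix:
    """One omics layer as a (cell line × gene) matrix with its transform record."""

    values: pd.DataFrame  # index = cell lines, columns = genes
    omics_kind: str
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.omics_kind not in OMICS_KINDS:
            raise ValueError(f"omics_kind must be one of {OMICS_KINDS}")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def minmax_normalize(matrix: pd.DataFrame | np.ndarray, axis: str = "per_gene") -> pd.DataFrame:
    """Map each unit to [0,1] via (x - min) / (max - min).

    ``axis="per_gene"`` normalizes each column (gene) across cell lines so each
    gene's dynamic range is comparable across omics; ``axis="global"`` uses one
    min/max for the whole matrix.  Constant units map to 0.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.isna().all().any() or (not np.isfinite(df.to_numpy()).all()):
        raise ValueError("matrix must be finite for min-max normalization")
    if axis == "per_gene":
        lo = df.min(axis=0)
        span = df.max(axis=0) - lo
        out = (df - lo).div(span.where(span > 0, np.inf), axis=1)
    elif axis == "global":
        lo = df.to_numpy().min()
        span = df.to_numpy().max() - lo
        out = (df - lo) / span if span > 0 else df * 0.0
    else:
        raise ValueError("axis must be 'per_gene' or 'global'")
    return out


def binarize_mutation(
    table: pd.DataFrame,
    cell_lines: Sequence[str],
    genes: Sequence[str],
) -> GeneCentricMatrix:
    """Binary mutation matrix: entry 1 iff >=1 mutation record exists for (cell, gene).

    ``table`` needs columns ``cell_line`` and ``gene``; further columns (variant
    class etc.) are ignored.  Records for genes or cell lines outside the target
    axes are dropped with a warning.
    """
    mat = pd.DataFrame(0, index=list(cell_lines), columns=list(genes), dtype=float)
    if len(table):
        known = table["gene"].isin(mat.columns) & table["cell_line"].isin(mat.index)
        unknown = int((~known).sum())
        if unknown:
            logger.warning("binarize_mutation: %d records outside target axes ignored", unknown)
        for _, row in table.loc[known, ["cell_line", "gene"]].drop_duplicates().iterrows():
            mat.loc[row["cell_line"], row["gene"]] = 1.0
    return GeneCentricMatrix(mat, "mutation", {"transform": "binarize"})


def promoter_average_methylation(
    probes: pd.DataFrame,
    cell_lines: Sequence[str],
    genes: Sequence[str],
    window_upstream: int = 1000,
) -> GeneCentricMatrix:
    """Mean beta per (cell line, gene) over promoter-window probes.

    ``probes`` needs columns ``cell_line``, ``gene``, ``offset`` (bases relative
    to the transcription start site, negative = upstream) and ``beta``.  Probes
    with offset in ``[-window_upstream, 0]`` qualify.  Genes with no qualifying
    probe in any cell line get 0; genes missing in some cell lines are imputed
    with the gene's cross-cell-line mean.
    """
    beta = probes["beta"].to_numpy(dtype=float) if len(probes) else np.array([])
    if len(beta) and ((beta < 0) | (beta > 1)).any():
        bad = beta[(beta < 0) | (beta > 1)][0]
        raise ValueError(f"beta value outside [0,1]: {bad}")
    mat = pd.DataFrame(np.nan, index=list(cell_lines), columns=list(genes), dtype=float)
    if len(probes):
        in_win = (probes["offset"] >= -window_upstream) & (probes["offset"] <= 0)
        known = probes["gene"].isin(mat.columns) & probes["cell_line"].isin(mat.index)
        sel = probes.loc[in_win & known]
        if len(sel):
            means = sel.groupby(["cell_line", "gene"], sort=False)["beta"].mean()
            for (c, g), val in means.items():
                mat.loc[c, g] = val
    gene_means = mat.mean(axis=0)
    mat = mat.fillna(gene_means).fillna(0.0)
    return GeneCentricMatrix(
        mat,
        "methylation",
        {"transform": "promoter_mean", "window_upstream": window_upstream},
    )


def align_matrices(matrices: Sequence[GeneCentricMatrix]) -> list[GeneCentricMatrix]:
    """Restrict all layers to the shared cell lines and genes, in a fixed order.

    The intersection is ordered by the first matrix's axes so the four layers
    stack into a tensor without reindexing surprises.
    """
    cells = [c for c in matrices[0].cell_lines if all(c in m.values.index for m in matrices)]
    genes = [g for g in matrices[0].genes if all(g in m.values.columns for m in matrices)]
    if not cells or not genes:
        raise ValueError("no shared cell lines or genes across omics layers")
    return [
        GeneCentricMatrix(m.values.loc[cells, genes], m.omics_kind, dict(m.normalization))
        for m in matrices
    ]
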