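"""Multi-omics tensor assembly and CP/PARAFAC decomposition.

The four gene-centric matrices stack into a 3-way tensor X indexed
(cell line i, gene j, omics k).  The canonical polyadic (CP / PARAFAC) model

    x_ijk = sum_{f=1..R} c_if g_jf o_kf + e_ijk

factorizes X into a cell-line component C_c (cells × R), a gene component C_g
(genes × R) and an omics component C_o (4 × R).  The cell-line component is the
low-dimensional embedding used downstream for drug-sensitivity regression; the
gene component maps selected features back to genes.

The fit is alternating least squares (ALS) with seeded random initialization
and no sign or non-negativity constraints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pertpath.preprocess import GeneCentricMatrix

logger = logging.getLogger(__name__)

__all__ = ["OMICS_ORDER", "OmicsTensor", "CPFactors", "assemble_tensor", "cp_decompose"]

#: Fixed slice order of the omics axis, independent of input file order.
OMICS_ORDER = ("expression", "copy_number", "methylation", "mutation")


@dataclass
class OmicsTensor:
    """(cell line × gene × omics) array with axis labels."""

    values: np.ndarray
    cell_lines: list[str]
    genes: list[str]
    omics: tuple[str, ...] = OMICS_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3-way (cell, gene, omics)")
        if self.values.shape != (len(self.cell_lines), len(self.genes), len(self.omics)):
            raise ValueError("tensor shape does not match axis labels")

    def slice(self, omics_kind: str) -> np.ndarray:
        return self.values[:, :, self.omics.index(omics_kind)]


@dataclass
class CPFactors:
    """CP factor matrices and fit diagnostics.

    ``cell_factors`` (C_c, cells × R) embeds cell lines; ``gene_factors``
    (C_g, genes × R) ties latent features back to genes; ``omics_factors``
    (C_o, omics × R) weights the four omics layers per feature.
    """

    cell_factors: np.ndarray
    gene_factors: np.ndarray
    omics_factors: np.ndarray
    rank: int
    rel_error: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        for m in (self.cell_factors, self.gene_factors, self.omics_factors):
            if m.shape[1] != self.rank:
                raise ValueError("factor column count must equal the rank")

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "if,jf,kf->ijk", self.cell_factors, self.gene_factors, self.omics_factors
        )


def assemble_tensor(matrices: Sequence[GeneCentricMatrix]) -> OmicsTensor:
    """Stack the four omics layers into a tensor in the fixed omics order."""
    by_kind = {m.omics_kind: m for m in matrices}
    missing = set(OMICS_ORDER) - set(by_kind)
    if missing:
        raise ValueError(f"missing omics layers: {sorted(missing)}")
    ref = by_kind[OMICS_ORDER[0]]
    for kind in OMICS_ORDER[1:]:
        m = by_kind[kind]
        if m.cell_lines != ref.cell_lines or m.genes != ref.genes:
            raise ValueError(f"axis mismatch between {kind} and {OMICS_ORDER[0]} layers")
    values = np.stack([by_kind[k].values.to_numpy(dtype=float) for k in OMICS_ORDER], axis=2)
    return OmicsTensor(values, ref.cell_lines, ref.genes)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product: (I*J) × R from (I×R) and (J×R)."""
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def cp_decompose(
    tensor: OmicsTensor | np.ndarray,
    rank: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 4,
) -> CPFactors:
    """Fit a rank-R CP model by alternating least squares.

    Each ALS sweep solves the exact least-squares update for one factor matrix
    with the other two fixed, using the Khatri-Rao structure of the unfoldings.
    Iteration stops when the relative reconstruction error decreases by less
    than ``tol`` between sweeps; non-convergence at ``max_iter`` returns the
    current factors with a warning.  ALS is sensitive to initialization on
    tensors that are only approximately low-rank, so ``n_restarts`` seeded
    random initializations are fitted and the lowest-error fit kept.
    Deterministic given ``seed``.

    The returned factors are in normalized form: cell-line and omics columns
    have unit norm and each component's weight is absorbed into the gene
    factors, making gene loadings comparable across features.
    """
    x = tensor.values if isinstance(tensor, OmicsTensor) else np.asarray(tensor, dtype=float)
    if x.ndim != 3:
        raise ValueError("CP decomposition expects a 3-way tensor")
    if not np.isfinite(x).all():
        raise ValueError("tensor contains non-finite entries")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    dims = x.shape
    norm_x = float(np.linalg.norm(x))
    if norm_x == 0.0:
        zeros = [np.zeros((d, rank)) for d in dims]
        return CPFactors(zeros[0], zeros[1], zeros[2], rank, 0.0, 0, True)

    best: CPFactors | None = None
    with warnings.catch_warnings():
        # Only the winning fit's convergence status should warn.
        warnings.simplefilter("ignore", RuntimeWarning)
        for restart in range(n_restarts):
            fit = _cp_als_single(x, rank, seed + 7919 * restart, tol, max_iter, norm_x)
            if best is None or fit.rel_error < best.rel_error:
                best = fit
    if not best.converged:
        warnings.warn(
            f"CP-ALS did not converge in {max_iter} iterations "
            f"(best rel err {best.rel_error:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return best


def _cp_als_single(
    x: np.ndarray, rank: int, seed: int, tol: float, max_iter: int, norm_x: float
) -> CPFactors:
    dims = x.shape
    rng = np.random.default_rng(seed)
    factors = [rng.standard_normal((d, rank)) for d in dims]
    unfolds = [_unfold(x, m) for m in range(3)]
    prev_err = np.inf
    err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # Unfolding convention: remaining modes in ascending order.
            kr = _khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            rhs = unfolds[mode] @ kr
            # pinv tolerates rank-deficient grams (e.g. overspecified R).
            factors[mode] = rhs @ np.linalg.pinv(gram)
        rec = np.einsum("if,jf,kf->ijk", *factors)
        err = float(np.linalg.norm(x - rec) / norm_x)
        if abs(prev_err - err) < tol:
            break
        prev_err = err
    # Fix the CP scale indeterminacy: unit-norm cell-line and omics columns,
    # with each component's weight absorbed into the gene factors, so gene
    # loadings are comparable across features.
    for mode in (0, 2):
        norms = np.linalg.norm(factors[mode], axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        factors[mode] = factors[mode] / norms
        factors[1] = factors[1] * norms
    converged = abs(prev_err - err) < tol or err < tol
    return CPFactors(factors[0], factors[1], factors[2], rank, err, it, converged)
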