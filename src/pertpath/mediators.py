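"""IC50-associated feature selection and mediator-gene scoring.

The per-cell-line embedding (CP cell-line factors or autoencoder codes) is
regressed on drug sensitivity (IC50, log-transformed by default) with an
L1 penalty; features with non-zero coefficients are the IC50-associated
features.  Genes are mapped back from selected features by either route:

* **tensor route** — each gene's most related feature is the row-wise argmax
  of the gene factor matrix C_g; a gene is a candidate mediator iff that
  feature was selected, with omics score ``C_g(g, f*) * coef(f*)`` (signed);
* **autoencoder route** — each selected latent feature is activated as a
  one-hot code and pushed through the trained decoder; the per-gene activation
  magnitude, summed over the four omics slots and weighted by |coef|, scores
  the gene, and the top fraction is kept.

Candidate mediators are finally ranked by a weighted combination of the
rank-normalized omics score and an optional literature relevance score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LassoCV
from sklearn.model_selection import LeaveOneOut

from pertpath.autoencoder import AutoencoderCodes

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelection",
    "MediatorGene",
    "lasso_select",
    "tensor_gene_scores",
    "autoencoder_gene_scores",
    "combine_scores",
]


@dataclass
class FeatureSelection:
    """LASSO fit summary on standardized embedding features."""

    coef: np.ndarray  # per-feature coefficient, standardized scale
    alpha: float  # chosen regularization strength
    target_transform: str  # e.g. "log" or "identity"
    intercept: float = 0.0

    @property
    def selected(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.coef)]


@dataclass
class MediatorGene:
    """One candidate mediator gene with its scores."""

    gene: str
    omics_score: float
    best_feature: int
    source_route: str  # "tensor" or "autoencoder"
    literature_score: float | None = None
    combined_score: float | None = None


def lasso_select(
    features: np.ndarray,
    ic50: np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    log_transform: bool = True,
) -> FeatureSelection:
    """L1-regularized regression of IC50 on embedding features.

    Features are standardized internally (zero mean, unit variance; constant
    columns stay zero) and coefficients are reported on the standardized
    scale.  The penalty is chosen by cross-validation over ``lambda_grid``
    (sklearn's automatic path when None); leave-one-out is used when there are
    fewer than ``2 * cv_folds`` cell lines.  IC50 is natural-log transformed by
    default (drug potencies span orders of magnitude).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(ic50, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and ic50 must have matching cell-line counts")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cell lines for cross-validated LASSO")
    if np.ptp(y) == 0:
        raise ValueError("ic50 is constant; nothing to regress")
    if log_transform:
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive IC50 values")
        y = np.log(y)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe
    Xs[:, sd == 0] = 0.0

    cv = LeaveOneOut() if X.shape[0] < 2 * cv_folds else cv_folds
    model = LassoCV(
        alphas=100 if lambda_grid is None else np.asarray(lambda_grid, dtype=float),
        cv=cv,
        random_state=seed,
        max_iter=50_000,
    )
    model.fit(Xs, y)
    return FeatureSelection(
        coef=model.coef_.copy(),
        alpha=float(model.alpha_),
        target_transform="log" if log_transform else "identity",
        intercept=float(model.intercept_),
    )


def tensor_gene_scores(
    gene_factors: np.ndarray,
    selection: FeatureSelection,
    genes: Sequence[str],
) -> list[MediatorGene]:
    """Map selected CP features back to genes via the row-wise argmax of C_g.

    The feature most related to a gene is the row-wise argmax of its loading
    magnitudes |C_g| (ties to the lowest index) — CP factors carry arbitrary
    per-component signs, so relatedness is magnitude while the loading's sign
    records direction.  A gene is emitted iff that feature carries a non-zero
    LASSO coefficient; the omics score is the signed product
    ``C_g(g, f*) * coef(f*)`` and the list is ordered by score magnitude.
    Assumes comparable column scales in C_g (the normalized CP form produced
    by :func:`pertpath.embedding.cp_decompose`).
    """
    C_g = np.atleast_2d(np.asarray(gene_factors, dtype=float))
    if C_g.shape[1] != selection.coef.shape[0]:
        raise ValueError("gene-factor columns must align with selection features")
    if C_g.shape[0] != len(genes):
        raise ValueError("gene list length must match gene-factor rows")
    selected = set(selection.selected)
    out: list[MediatorGene] = []
    best = np.argmax(np.abs(C_g), axis=1)  # np.argmax takes the lowest index on ties
    for i, gene in enumerate(genes):
        f = int(best[i])
        if f not in selected:
            continue
        score = float(C_g[i, f] * selection.coef[f])
        out.append(MediatorGene(gene, score, f, "tensor"))
    out.sort(key=lambda m: (-abs(m.omics_score), m.gene))
    return out


def autoencoder_gene_scores(
    codes: AutoencoderCodes,
    selection: FeatureSelection,
    genes: Sequence[str],
    top_fraction: float = 0.05,
) -> list[MediatorGene]:
    """Score genes by decoder activation of the selected latent features.

    For each selected feature ``f`` a one-hot latent vector is decoded; the
    per-gene activation ``a_g(f)`` is the sum of absolute reconstruction-layer
    outputs over the gene's four omics slots.  The omics score aggregates over
    selected features weighted by coefficient magnitude,
    ``sum_f a_g(f) |coef(f)|``, and the top ``top_fraction`` of genes (at
    least one) is emitted.
    """
    model = codes.model
    if not model.trained:
        raise RuntimeError("autoencoder decoder is untrained")
    if model.n_genes != len(genes):
        raise ValueError("gene list length must match the trained gene axis")
    selected = selection.selected
    if not selected:
        return []
    if any(f >= codes.latent_dim for f in selected):
        raise ValueError("selection features exceed the latent dimension")
    scores = np.zeros(len(genes))
    best_feature = np.zeros(len(genes), dtype=int)
    best_contrib = np.full(len(genes), -np.inf)
    for f in selected:
        contrib = model.decoder_activation(f) * abs(float(selection.coef[f]))
        scores += contrib
        better = contrib > best_contrib
        best_feature[better] = f
        best_contrib[better] = contrib[better]
    n_keep = max(1, int(np.ceil(top_fraction * len(genes))))
    order = np.lexsort((np.asarray(genes, dtype=object), -scores))
    out = [
        MediatorGene(genes[i], float(scores[i]), int(best_feature[i]), "autoencoder")
        for i in order[:n_keep]
    ]
    return out


def _rank_normalize(values: np.ndarray) -> np.ndarray:
    """Map scores to [0,1] by rank (highest score -> 1); single item -> 1."""
    n = values.size
    if n == 1:
        return np.ones(1)
    r = rankdata(values, method="average")
    return (r - 1.0) / (n - 1.0)


def combine_scores(
    mediators: Sequence[MediatorGene],
    literature: Mapping[str, float] | None = None,
    weight: float = 0.5,
) -> list[MediatorGene]:
    """Combine omics and literature scores into the final mediator ranking.

    Both score sets are rank-normalized to [0,1] (so the combination is
    invariant to monotone transforms of either raw score), then averaged with
    weight ``w`` on the omics side: ``combined = w * omics + (1-w) * lit``.
    Genes absent from the literature table score 0 on the literature side;
    with no table at all the ranking reduces to the omics ranking.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0,1]")
    if not mediators:
        return []
    omics_norm = _rank_normalize(np.abs([m.omics_score for m in mediators]))
    if literature is None:
        combined = omics_norm
        lit_norm = [None] * len(mediators)
    else:
        present = [m.gene in literature for m in mediators]
        raw = np.array([literature.get(m.gene, -np.inf) for m in mediators])
        lit_norm = np.zeros(len(mediators))
        if any(present):
            idx = np.flatnonzero(present)
            lit_norm[idx] = _rank_normalize(raw[idx]) if idx.size > 1 else 1.0
        combined = weight * omics_norm + (1.0 - weight) * lit_norm
    out = []
    for i, m in enumerate(mediators):
        out.append(
            MediatorGene(
                gene=m.gene,
                omics_score=m.omics_score,
                best_feature=m.best_feature,
                source_route=m.source_route,
                literature_score=None if literature is None else float(literature.get(m.gene, 0.0)),
                combined_score=float(combined[i]),
            )
        )
    out.sort(key=lambda m: (-m.combined_score, m.gene))
    return out
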