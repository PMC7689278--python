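"""Find IC50-associated mediator genes via CP tensor embedding.

Plants a rank-3 multi-omics structure in which one latent factor drives drug
sensitivity, embeds the (cell line x gene x omics) tensor by CP/PARAFAC, selects
IC50-associated features by cross-validated LASSO, and maps them back to genes.
"""

import numpy as np

from pertpath import (
    assemble_tensor,
    combine_scores,
    cp_decompose,
    generate_multiomics,
    lasso_select,
    tensor_gene_scores,
)

fixture = generate_multiomics(
    n_cell=60, n_gene=200, rank=3, causal_factors=(1,), effect_size=5.0,
    noise_sd=0.1, seed=7,
)

tensor = assemble_tensor(fixture.gene_centric())
factors = cp_decompose(tensor, rank=3, seed=0)
print(f"CP fit: rank {factors.rank}, relative reconstruction error "
      f"{factors.rel_error:.3f}")

selection = lasso_select(factors.cell_factors, fixture.ic50.to_numpy(), seed=0)
print(f"LASSO on log-IC50 selected features {selection.selected} "
      f"with coefficients {np.round(selection.coef, 2)}")

mediators = tensor_gene_scores(factors.gene_factors, selection, tensor.genes)
ranked = combine_scores(mediators, literature=None, weight=0.5)

planted = {tensor.genes[i]
           for i in np.argsort(-np.abs(fixture.truth_gene_factors[:, 1]))[:10]}
print("\ntop 10 mediator genes (omics score = gene loading x LASSO coefficient):")
for m in ranked[:10]:
    mark = "*" if m.gene in planted else " "
    print(f"  {mark} {m.gene}: omics_score={m.omics_score:+.2f} "
          f"(feature {m.best_feature})")

hits = sum(m.gene in planted for m in ranked[:10])
print(f"\n{hits}/10 of the list are planted top-loading genes on the causal")
print("factor (starred); the LASSO coefficient magnitudes show which latent")
print("factor carries the drug-sensitivity signal.")
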