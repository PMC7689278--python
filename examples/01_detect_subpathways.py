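"""Detect a perturbed sub-pathway in planted control/treated time series.

Builds a five-gene signaling chain, plants a drug response that starts at the
chain head and propagates one time point per edge, then runs differential
calling, edge validation and the permutation test.
"""

from pertpath import (
    PathwayGraph,
    build_time_vectors,
    extract_subpathways,
    generate_timeseries,
    permutation_pvalue,
    validate_edges,
)

# Signaling chain G0 -> G1 -> ... -> G4, plus 40 unperturbed background genes
# that will serve as the permutation donor pool.
chain = [f"G{i}" for i in range(5)]
background = [f"B{i}" for i in range(40)]
pathway = PathwayGraph(list(zip(chain, chain[1:])), name="chain")
full_graph = PathwayGraph(list(zip(chain, chain[1:])), name="chain",
                          nodes=chain + background)

fixture = generate_timeseries(
    full_graph, source_genes=["G0"], delay_per_edge=1, amplitude=10.0,
    noise_sd=0.3, n_time=5, n_rep=3, seed=42,
)

vectors = build_time_vectors(
    fixture.treated, fixture.genes, control_series=fixture.control,
    lfc_cutoff=1.0, p_cutoff=0.05,
)
validations = validate_edges(pathway, vectors, delay_threshold=2)
subpathways = extract_subpathways(pathway, validations, min_edges=3)

for sp in subpathways:
    sp.p_value = permutation_pvalue(sp, vectors, B=999, seed=0)
    print(f"sub-pathway in {sp.pathway_name}: {len(sp.edges)} edges, "
          f"statistic={sp.statistic:.0f}, p={sp.p_value:.4f}")
    for ev in sp.edges:
        print(f"  {ev.edge[0]} -> {ev.edge[1]}: delay={ev.delay}, peak={ev.peak}")

print()
print("The statistic sums each edge's peak lagged cross-correlation; delay=1 on")
print("every edge recovers the planted one-time-point propagation, and the small")
print("permutation p-value says such concordant propagation almost never arises")
print("when gene vectors are reassigned at random from the genome-wide pool.")
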