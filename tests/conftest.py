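from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pertpath.pipeline import RunConfig
from pertpath.subpathway import PathwayGraph
from pertpath.synthetic import generate_multiomics, generate_timeseries


@pytest.fixture
def chain_pathway() -> PathwayGraph:
    return PathwayGraph([("A", "B"), ("B", "C"), ("C", "D")], name="chain4")


@pytest.fixture
def chain_fixture(chain_pathway):
    """Noise-free planted propagation along A->B->C->D with unit delay."""
    return generate_timeseries(
        chain_pathway, ["A"], delay_per_edge=1, amplitude=10.0, noise_sd=0.0,
        n_time=4, n_rep=3, seed=1,
    )


@pytest.fixture(scope="session")
def multiomics_fixture():
    """Rank-3 planted multi-omics fixture with causal factor 1."""
    return generate_multiomics(
        n_cell=60, n_gene=200, rank=3, causal_factors=(1,), effect_size=5.0,
        noise_sd=0.1, seed=2,
    )


def random_time_vectors(rng: np.random.Generator, n: int, T: int) -> np.ndarray:
    """(n, T) i.i.d. uniform ternary vectors."""
    return rng.integers(-1, 2, size=(n, T))


CHAIN = [f"G{i:04d}" for i in range(5)]
BACKGROUND = [f"B{i:04d}" for i in range(40)]


def write_inputs(root: Path, seed: int = 7) -> RunConfig:
    """Planted fixture set covering every pipeline input file."""
    # Propagation graph: TF -> chain head; background genes stay flat and
    # serve as the permutation donor pool.
    full = PathwayGraph(
        [("TF1", CHAIN[0])] + list(zip(CHAIN, CHAIN[1:])),
        name="full",
        nodes=["TF1"] + CHAIN + BACKGROUND,
    )
    ts = generate_timeseries(full, ["TF1"], delay_per_edge=1, amplitude=10.0,
                             noise_sd=0.2, n_time=5, n_rep=3, seed=seed)
    ts.write(root / "ts")
    pd.DataFrame(list(zip(CHAIN, CHAIN[1:])), columns=["source", "target"]).to_csv(
        root / "ts" / "pathway.tsv", sep="\t", index=False
    )
    mo = generate_multiomics(n_cell=40, n_gene=60, rank=3, causal_factors=(0,),
                             effect_size=5.0, noise_sd=0.1, seed=seed)
    mo.write(root / "mo")
    pd.DataFrame([("TF1", CHAIN[0])], columns=["tf", "target"]).to_csv(
        root / "grn.tsv", sep="\t", index=False
    )
    pd.DataFrame([(CHAIN[1], CHAIN[2], 0.9)],
                 columns=["gene_a", "gene_b", "confidence"]).to_csv(
        root / "pin.tsv", sep="\t", index=False
    )
    return RunConfig(
        timeseries=str(root / "ts" / "timeseries.tsv"),
        pathway=str(root / "ts" / "pathway.tsv"),
        expression=str(root / "mo" / "expression.tsv"),
        copy_number=str(root / "mo" / "copy_number.tsv"),
        methylation=str(root / "mo" / "methylation.tsv"),
        mutation=str(root / "mo" / "mutation.tsv"),
        ic50=str(root / "mo" / "ic50.tsv"),
        grn=str(root / "grn.tsv"),
        pin=str(root / "pin.tsv"),
        rank=3, route="both", n_permutations=499, n_sim=2000, seed=11, epochs=150,
    )
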