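"""End-to-end orchestration of the four analysis stages.

A :class:`RunConfig` names the input files and the stage parameters; a single
master seed deterministically derives one sub-seed per randomized stage, so a
config plus seed fully determines every numeric output.  Each stage writes its
tables before the next starts, so any stage can be re-run standalone from
prior outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pertpath import io as pio
from pertpath.autoencoder import train_autoencoder
from pertpath.embedding import assemble_tensor, cp_decompose
from pertpath.mediators import (
    autoencoder_gene_scores,
    combine_scores,
    lasso_select,
    tensor_gene_scores,
)
from pertpath.network import (
    build_time_bounded_network,
    extract_regulatory_paths,
    greedy_labeled_im,
)
from pertpath.preprocess import GeneCentricMatrix, minmax_normalize
from pertpath.subpathway import (
    bh_fdr,
    build_time_vectors,
    extract_subpathways,
    permutation_pvalue,
    validate_edges,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

STAGES = ("subpathway", "embedding", "mediators", "network")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Input paths and stage parameters for one pipeline run."""

    # inputs
    timeseries: str = ""
    pathway: str = ""
    expression: str = ""
    copy_number: str = ""
    methylation: str = ""
    mutation: str = ""
    ic50: str = ""
    grn: str = ""
    pin: str = ""
    literature: str | None = None
    # sub-pathway stage
    deg_mode: str = "vs_control"
    lfc_cutoff: float = 1.0
    p_cutoff: float = 0.05
    min_edges: int = 3
    delay_threshold: int | None = None
    n_permutations: int = 999
    # embedding stage
    route: str = "tensor"  # tensor | autoencoder | both
    rank: int = 8
    specific_sizes: tuple[int, int] = (64, 32)
    integration_sizes: tuple[int, int] = (32, 8)
    l2: float = 0.0
    penalty: str = "l2"
    epochs: int = 500
    lr: float = 1e-3
    # mediator stage
    log_ic50: bool = True
    cv_folds: int = 5
    literature_weight: float = 0.5
    top_fraction: float = 0.05
    # network stage
    n_sim: int = 10_000
    k_seeds: int = 3
    require_mediator: bool = False
    max_paths: int = 10
    # global
    seed: int = 0

    REQUIRED = ("timeseries", "pathway", "expression", "copy_number", "methylation",
                "mutation", "ic50", "grn", "pin")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        return cfg

    def validate(self) -> None:
        if self.route not in ("tensor", "autoencoder", "both"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.deg_mode not in ("vs_control", "vs_previous", "vs_initial"):
            raise ValueError(f"unknown deg_mode {self.deg_mode!r}")
        if not 0.0 <= self.literature_weight <= 1.0:
            raise ValueError("literature_weight must be in [0,1]")
        for name in self.REQUIRED:
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: missing input file {p!r}")
        if self.literature and not Path(self.literature).exists():
            raise FileNotFoundError(f"literature score table not found: {self.literature}")

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed below 2^31 from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all four stages, writing every intermediate table under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: perturbed sub-pathways ----------------------------------
    try:
        genes, control, treated = pio.read_long_timeseries(config.timeseries)
        pathway = pio.read_pathway_edgelist(config.pathway)
        vectors = build_time_vectors(
            treated, genes, control_series=control, mode=config.deg_mode,
            lfc_cutoff=config.lfc_cutoff, p_cutoff=config.p_cutoff,
        )
        validations = validate_edges(pathway, vectors, config.delay_threshold)
        subpathways = extract_subpathways(pathway, validations, config.min_edges)
        sp_seed = config.stage_seed("subpathway")
        for i, sp in enumerate(subpathways):
            sp.p_value = permutation_pvalue(
                sp, vectors, B=config.n_permutations, seed=sp_seed + i
            )
        if subpathways:
            fdrs = bh_fdr([sp.p_value for sp in subpathways])
            for sp, q in zip(subpathways, fdrs):
                sp.fdr = float(q)
        pio.write_subpathway_tables(subpathways, validations, outdir)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError("subpathway", exc) from exc

    # -- stage 2 + 3: embedding and mediator selection ---------------------
    try:
        layers = []
        for kind in ("expression", "copy_number", "methylation", "mutation"):
            df = pio.read_wide_matrix(getattr(config, kind))
            if kind in ("expression", "copy_number"):
                df = minmax_normalize(df, axis="per_gene")
            layers.append(GeneCentricMatrix(df, kind, {"pipeline": "minmax" if kind in
                                                       ("expression", "copy_number") else "asis"}))
        tensor = assemble_tensor(layers)
        ic50 = pio.read_wide_matrix(config.ic50).iloc[:, 0].loc[tensor.cell_lines]
        literature = pio.read_literature_scores(config.literature) if config.literature else None
        emb_seed = config.stage_seed("embedding")
        med_seed = config.stage_seed("mediators")

        mediator_tables: dict[str, list] = {}
        if config.route in ("tensor", "both"):
            factors = cp_decompose(tensor, rank=config.rank, seed=emb_seed)
            _write_matrix(outdir / "cp_cell_factors.tsv", factors.cell_factors,
                          tensor.cell_lines)
            _write_matrix(outdir / "cp_gene_factors.tsv", factors.gene_factors, tensor.genes)
            _write_matrix(outdir / "cp_omics_factors.tsv", factors.omics_factors,
                          list(tensor.omics))
            sel = lasso_select(factors.cell_factors, ic50.to_numpy(),
                               cv_folds=config.cv_folds, seed=med_seed,
                               log_transform=config.log_ic50)
            meds = tensor_gene_scores(factors.gene_factors, sel, tensor.genes)
            mediator_tables["tensor"] = combine_scores(meds, literature,
                                                       config.literature_weight)
            manifest_embed = {"rank": config.rank, "rel_error": factors.rel_error,
                              "n_iter": factors.n_iter}
        if config.route in ("autoencoder", "both"):
            codes = train_autoencoder(
                layers, specific_sizes=config.specific_sizes,
                integration_sizes=config.integration_sizes, l2=config.l2,
                penalty=config.penalty, epochs=config.epochs, lr=config.lr,
                seed=emb_seed,
            )
            _write_matrix(outdir / "autoencoder_codes.tsv", codes.z, tensor.cell_lines)
            sel = lasso_select(codes.z, ic50.to_numpy(), cv_folds=config.cv_folds,
                               seed=med_seed, log_transform=config.log_ic50)
            meds = autoencoder_gene_scores(codes, sel, tensor.genes,
                                           top_fraction=config.top_fraction)
            mediator_tables["autoencoder"] = combine_scores(meds, literature,
                                                            config.literature_weight)
            manifest_embed = {"final_loss": codes.final_loss, "epochs": codes.epochs,
                              "architecture": codes.architecture}
        for route, meds in mediator_tables.items():
            rows = [{"gene": m.gene, "omics_score": m.omics_score,
                     "literature_score": m.literature_score,
                     "combined_score": m.combined_score,
                     "best_feature": m.best_feature, "route": m.source_route}
                    for m in meds]
            pd.DataFrame(rows, columns=["gene", "omics_score", "literature_score",
                                        "combined_score", "best_feature", "route"]).to_csv(
                outdir / f"mediators_{route}.tsv", sep="\t", index=False)
        if config.route == "both":
            _write_route_comparison(mediator_tables, outdir / "route_comparison.tsv")
        mediators = mediator_tables.get("tensor") or mediator_tables.get("autoencoder") or []
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("embedding/mediators", exc) from exc

    # -- stage 4: time-bounded network and regulatory paths ----------------
    try:
        grn = pio.read_grn(config.grn)
        pin = pio.read_pin(config.pin)
        net = build_time_bounded_network(
            grn, pin, subpathways, vectors, mediators, config.delay_threshold
        )
        pio.write_network(net, outdir)
        net_seed = config.stage_seed("network")
        targets = [n for sp in subpathways for n in sp.genes if n in net.graph]
        if net.nodes_with_label("TF"):
            ranking = greedy_labeled_im(net, k=config.k_seeds, n_sim=config.n_sim,
                                        seed=net_seed, targets=targets)
        else:
            logger.warning("no TF survived edge validation; skipping influence ranking")
            ranking = []
        pd.DataFrame(ranking, columns=["tf", "marginal_spread"]).to_csv(
            outdir / "tf_ranking.tsv", sep="\t", index=False)
        all_paths = []
        for tf, _ in ranking:
            for sp in subpathways:
                all_paths.extend(
                    extract_regulatory_paths(net, tf, sp,
                                             require_mediator=config.require_mediator,
                                             max_paths=config.max_paths)
                )
        pio.write_paths(all_paths, outdir / "regulatory_paths.tsv")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("network", exc) from exc

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "n_subpathways": len(subpathways),
        "embedding": manifest_embed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _write_matrix(path: Path, values, index) -> None:
    arr = np.asarray(values)
    pd.DataFrame(arr, index=index,
                 columns=[f"f{j}" for j in range(arr.shape[1])]).to_csv(
        path, sep="\t", index_label="id")


def _write_route_comparison(tables: dict, outfile: Path) -> None:
    """Rank comparison of the two mediator routes on their shared genes."""
    ranks = {}
    for route, meds in tables.items():
        ranks[route] = {m.gene: i for i, m in enumerate(meds)}
    shared = sorted(set(ranks["tensor"]) & set(ranks["autoencoder"]))
    rows = [{"gene": g, "rank_tensor": ranks["tensor"][g],
             "rank_autoencoder": ranks["autoencoder"][g]} for g in shared]
    pd.DataFrame(rows, columns=["gene", "rank_tensor", "rank_autoencoder"]).to_csv(
        outfile, sep="\t", index=False)
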