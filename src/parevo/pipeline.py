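"""Stage orchestration shared by the CLI and the test harness.

Each stage reads/writes the plain-text formats of :mod:`parevo.io`, so the
pipeline can be driven end to end from directories (as the CLI does) or
entirely in memory (as the tests do).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .coexpression import build_network, median_expression_subset, write_network
from .dosage import run_dosage_test
from .fates import classify_all, funnel_summary, shared_expression_domains
from .features import annotate_pair_dup_types, gene_feature_table
from .io import (
    ExpressionDataset,
    GeneModel,
    OrthogroupTable,
    gene_model_index,
    read_expression,
    read_gene_models,
    read_orthogroups,
    write_expression,
)
from .qc import average_replicates, drop_all_zero_genes, replicate_qc, singleton_pca
from .simulate import SimConfig, write_simulation

log = logging.getLogger(__name__)


def load_sim_dir(simdir: str | Path):
    """Load a simulation (or identically laid out real-data) directory."""
    simdir = Path(simdir)
    sheet_path = simdir / "samples.tsv"
    datasets: dict[str, ExpressionDataset] = {}
    gene_models: dict[str, dict[str, GeneModel]] = {}
    for path in sorted(simdir.glob("expression_*.tsv")):
        species = path.stem.removeprefix("expression_")
        datasets[species] = read_expression(path, sheet_path)
        gff = simdir / f"genes_{species}.gff3"
        if gff.exists():
            gene_models[species] = gene_model_index(read_gene_models(gff))
    if not datasets:
        raise FileNotFoundError(f"no expression_*.tsv matrices under {simdir}")
    orthogroups = read_orthogroups(simdir / "orthogroups.tsv")
    return datasets, orthogroups, gene_models


def stage_qc(
    datasets: dict[str, ExpressionDataset], config: RunConfig
) -> tuple[dict[str, ExpressionDataset], pd.DataFrame]:
    """Replicate QC + all-zero gene removal, per species."""
    filtered: dict[str, ExpressionDataset] = {}
    reports = []
    for species in sorted(datasets):
        ds, report = replicate_qc(datasets[species], min_rho=config.spearman_min)
        filtered[species] = drop_all_zero_genes(ds)
        reports.append(report)
    return filtered, pd.concat(reports, ignore_index=True)


def stage_mean_expression(datasets: dict[str, ExpressionDataset]):
    merged = {}
    for species in sorted(datasets):
        merged.update(average_replicates(datasets[species]).tables)
    from .qc import MeanExpression

    return MeanExpression(merged)


def run_all(
    sim_config: SimConfig,
    run_config: RunConfig,
    outdir: str | Path,
    write_networks: bool = False,
) -> dict:
    """simulate -> qc -> networks -> classify -> dosage test -> features.

    Writes every stage output under ``outdir`` and returns the run summary
    (also written as ``run_summary.json``).
    """
    outdir = Path(outdir)
    simdir = outdir / "sim"
    resdir = outdir / "results"
    resdir.mkdir(parents=True, exist_ok=True)

    datasets, orthogroups, gene_models_list, truth = write_simulation(
        sim_config, simdir
    )
    gene_models = {
        sp: gene_model_index(models) for sp, models in gene_models_list.items()
    }

    # QC
    filtered, qc_report = stage_qc(datasets, run_config)
    qc_report.to_csv(resdir / "qc_report.tsv", sep="\t", index=False)
    for sp, ds in filtered.items():
        write_expression(ds, resdir / f"filtered_{sp}.tsv")
    mean_expr = stage_mean_expression(filtered)

    # singleton PCA sanity check
    pca_scores, evr, pca_accuracy = singleton_pca(filtered, orthogroups)
    pca_scores.to_csv(resdir / "pca_scores.tsv", sep="\t", index=False)

    # networks
    networks = {}
    for sp in sorted(filtered):
        subset = median_expression_subset(filtered[sp])
        networks[sp] = build_network(filtered[sp], subset)
        if write_networks:
            write_network(networks[sp], resdir / f"network_{sp}.tsv.gz")

    # fate classification
    records = classify_all(orthogroups, filtered, networks, run_config)
    records = annotate_pair_dup_types(records, gene_models, run_config)
    records["shared_domains"] = [
        shared_expression_domains(
            r.gene_a, r.gene_b, mean_expr, r.species, run_config.breadth_tpm
        )
        for r in records.itertuples()
    ]
    records.to_csv(resdir / "pair_fates.tsv", sep="\t", index=False)
    funnel = funnel_summary(records)
    with open(resdir / "funnel_summary.json", "w") as fh:
        json.dump(funnel, fh, indent=2, sort_keys=True)

    # dosage test
    comparisons, calls = run_dosage_test(mean_expr, orthogroups, run_config)
    comparisons.to_csv(resdir / "dosage_comparisons.tsv", sep="\t", index=False)
    calls.to_csv(resdir / "dosage_calls.tsv", sep="\t", index=False)

    # gene features
    features = gene_feature_table(mean_expr, gene_models, run_config)
    features.to_csv(resdir / "gene_features.tsv", sep="\t", index=False)

    summary = {
        "versions": _versions(),
        "config_hash": run_config.hash(),
        "seed": sim_config.seed,
        "pca": {
            "explained_variance_ratio": [float(v) for v in evr],
            "tissue_accuracy": pca_accuracy,
        },
        "funnel": funnel,
        "record_counts": {
            "qc_report": int(len(qc_report)),
            "pca_scores": int(len(pca_scores)),
            "pair_fates": int(len(records)),
            "dosage_comparisons": int(len(comparisons)),
            "dosage_calls": int(len(calls)),
            "gene_features": int(len(features)),
        },
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _versions() -> dict:
    import scipy

    return {
        "parevo": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
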