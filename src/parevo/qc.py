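"""Replicate-level quality control, replicate averaging and the singleton PCA.

Replicate agreement is judged by pairwise Spearman correlation over genes
within each (species, tissue) replicate set. Samples whose mean pairwise
rho is at or below the threshold are removed; removal is iterative (worst
sample first, then re-evaluate) so a single discordant replicate does not
drag its well-correlated partners below the threshold.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import ExpressionDataset, OrthogroupTable

log = logging.getLogger(__name__)

__all__ = [
    "replicate_qc",
    "drop_all_zero_genes",
    "average_replicates",
    "MeanExpression",
    "singleton_pca",
    "paralogue_sum_matrix",
]


def _pairwise_spearman(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho between columns; undefined correlations -> 0.

    A constant expression vector has no rank variance, so Spearman is
    undefined; such samples get rho 0 (and will be flagged for removal).
    """
    import warnings

    n = values.shape[1]
    rho = np.ones((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for i in range(n):
            for j in range(i + 1, n):
                r = stats.spearmanr(values[:, i], values[:, j]).statistic
                if not np.isfinite(r):
                    r = 0.0
                rho[i, j] = rho[j, i] = r
    return rho


def replicate_qc(
    dataset: ExpressionDataset, min_rho: float = 0.75
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Remove discordant replicates; returns the filtered dataset + report.

    Within each (species, tissue) group, each sample is summarized by the
    mean of its pairwise Spearman rho with the other replicates; samples at
    or below ``min_rho`` fail. Groups of three or more drop the single
    worst sample and are re-evaluated (isolating one bad replicate); a
    failing two-sample group is dropped entirely. Single-replicate groups
    pass untouched.
    """
    report_rows = []
    removed: list[str] = []
    for (species, tissue), group in dataset.sheet.groupby(
        ["species", "tissue"], sort=True
    ):
        sample_ids = list(group.index)
        if len(sample_ids) == 1:
            report_rows.append(
                {
                    "sample_id": sample_ids[0],
                    "species": species,
                    "tissue": tissue,
                    "mean_spearman": np.nan,
                    "kept": True,
                    "reason": "single_replicate",
                }
            )
            continue
        current = list(sample_ids)
        decisions: dict[str, tuple[float, bool, str]] = {}
        while len(current) >= 2:
            idx = dataset.samples.get_indexer(current)
            rho = _pairwise_spearman(dataset.values[:, idx])
            np.fill_diagonal(rho, np.nan)
            mean_rho = np.nanmean(rho, axis=0)
            failing = mean_rho <= min_rho
            if not failing.any():
                for s, m in zip(current, mean_rho):
                    decisions[s] = (float(m), True, "pass")
                break
            if len(current) == 2:
                # a failing pair is mutually discordant: neither sample can
                # be blamed, so the whole group is dropped
                for s, m in zip(current, mean_rho):
                    decisions[s] = (float(m), False, "all_replicates_discordant")
                log.warning(
                    "dropping whole group (%s, %s): replicates have mean "
                    "Spearman rho <= %g", species, tissue, min_rho,
                )
                current = []
                break
            worst = int(np.argmin(mean_rho))
            decisions[current[worst]] = (
                float(mean_rho[worst]),
                False,
                "low_replicate_correlation",
            )
            log.warning(
                "removing sample %s (mean Spearman rho %.3f <= %g)",
                current[worst], mean_rho[worst], min_rho,
            )
            current.pop(worst)
        for s in sample_ids:
            m, kept, reason = decisions[s]
            report_rows.append(
                {
                    "sample_id": s,
                    "species": species,
                    "tissue": tissue,
                    "mean_spearman": m,
                    "kept": kept,
                    "reason": reason,
                }
            )
            if not kept:
                removed.append(s)
    report = pd.DataFrame(
        report_rows,
        columns=["sample_id", "species", "tissue", "mean_spearman", "kept", "reason"],
    )
    keep = dataset.samples.difference(pd.Index(removed), sort=False)
    return dataset.subset_samples(keep), report


def drop_all_zero_genes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Exclude genes with zero expression across all samples."""
    keep = dataset.genes[(dataset.values > 0).any(axis=1)]
    n_dropped = dataset.n_genes - len(keep)
    if n_dropped:
        log.info("dropping %d all-zero genes", n_dropped)
    return dataset.subset_genes(keep)


class MeanExpression:
    """Per species: gene x tissue matrix of replicate-mean TPM."""

    def __init__(self, tables: dict[str, pd.DataFrame]):
        for sp, table in tables.items():
            if (table.to_numpy() < 0).any():
                raise ValueError(f"negative mean expression for species {sp!r}")
        self.tables = tables

    def __getitem__(self, species: str) -> pd.DataFrame:
        return self.tables[species]

    def __contains__(self, species: str) -> bool:
        return species in self.tables

    @property
    def species(self) -> list[str]:
        return sorted(self.tables)

    def tissues(self, species: str) -> list[str]:
        return list(self.tables[species].columns)


def average_replicates(dataset: ExpressionDataset) -> MeanExpression:
    """Arithmetic mean of TPM over replicates per (species, tissue, gene)."""
    tables: dict[str, pd.DataFrame] = {}
    for species in dataset.species:
        ds = dataset.for_species(species)
        cols = {}
        for tissue, group in ds.sheet.groupby("tissue", sort=True):
            idx = ds.samples.get_indexer(group.index)
            cols[tissue] = ds.values[:, idx].mean(axis=1)
        tables[species] = pd.DataFrame(cols, index=ds.genes)
    return MeanExpression(tables)


# ---------------------------------------------------------------------------
# singleton PCA


def _stack_singleton_matrix(
    datasets: dict[str, ExpressionDataset], orthogroups: OrthogroupTable
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    species = sorted(datasets)
    singles = orthogroups.singleton_orthogroups(species)
    # keep orthogroups whose gene is present in every species' matrix
    usable = []
    for og in singles:
        if all(
            orthogroups.genes(og, sp)[0] in datasets[sp].genes for sp in species
        ):
            usable.append(og)
    blocks, meta = [], []
    for sp in species:
        ds = datasets[sp]
        gene_ids = [orthogroups.genes(og, sp)[0] for og in usable]
        idx = ds.genes.get_indexer(gene_ids)
        blocks.append(ds.values[idx].T)  # samples x orthogroups
        meta.append(ds.sheet.reset_index())
    X = np.vstack(blocks)
    meta_df = pd.concat(meta, ignore_index=True)
    return X, meta_df, usable


def singleton_pca(
    datasets: dict[str, ExpressionDataset],
    orthogroups: OrthogroupTable,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """PCA of samples over singleton-gene expression, stacked across species.

    Expression is log2(TPM+1) transformed and features centred. Returns
    ``(scores, explained_variance_ratio, tissue_accuracy)`` where the
    accuracy is the fraction of samples whose nearest tissue centroid (in
    component space) is their own tissue — the "samples cluster by tissue"
    sanity metric.
    """
    X, meta, usable = _stack_singleton_matrix(datasets, orthogroups)
    if len(usable) < n_components:
        raise ValueError(
            f"only {len(usable)} singleton genes shared across species; "
            f"need at least {n_components} for {n_components} components"
        )
    X = np.log2(X + 1.0)
    X = X - X.mean(axis=0, keepdims=True)
    tissues = meta["tissue"].to_numpy()
    if not np.any(X != 0):
        # degenerate: all samples identical; no structure to recover
        scores = np.zeros((X.shape[0], n_components))
        evr = np.zeros(n_components)
        accuracy = 1.0 / len(np.unique(tissues))
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
        centroids = {
            t: scores[tissues == t].mean(axis=0) for t in np.unique(tissues)
        }
        names = list(centroids)
        cmat = np.array([centroids[t] for t in names])
        d = ((scores[:, None, :] - cmat[None, :, :]) ** 2).sum(axis=2)
        nearest = np.array(names)[d.argmin(axis=1)]
        accuracy = float((nearest == tissues).mean())
    out = meta[["sample_id", "species", "tissue"]].copy()
    for k in range(n_components):
        out[f"PC{k + 1}"] = scores[:, k]
    return out, np.asarray(evr), accuracy


def paralogue_sum_matrix(
    datasets: dict[str, ExpressionDataset], orthogroups: OrthogroupTable
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Samples x orthogroups matrix of summed two-copy pair expression.

    Alternative PCA substrate: orthogroups with exactly two copies in every
    species, each column the sum of the pair's TPM.
    """
    species = sorted(datasets)
    usable = []
    for og in sorted(orthogroups.members):
        if all(len(orthogroups.genes(og, sp)) == 2 for sp in species) and all(
            g in datasets[sp].genes
            for sp in species
            for g in orthogroups.genes(og, sp)
        ):
            usable.append(og)
    blocks, meta = [], []
    for sp in species:
        ds = datasets[sp]
        cols = []
        for og in usable:
            ga, gb = orthogroups.genes(og, sp)
            cols.append(ds.gene_row(ga) + ds.gene_row(gb))
        blocks.append(np.array(cols).T if cols else np.empty((ds.n_samples, 0)))
        meta.append(ds.sheet.reset_index())
    return np.vstack(blocks), pd.concat(meta, ignore_index=True), usable
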