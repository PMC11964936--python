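"""Per-species rank-standardized coexpression networks.

Construction: Pearson correlation between all gene pairs over all retained
samples of the species; per gene, off-diagonal correlations are ranked
ascending (average ranks for ties, undefined correlations assigned the
median rank); the directed rank matrix is symmetrized by averaging the two
directions and divided by its maximum, giving weights in [0, 1] where the
most strongly co-expressed partners sit near 1.
"""
from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset

log = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "median_expression_subset",
    "build_network",
    "pair_coexpression",
    "write_network",
]


@dataclass
class CoexpressionNetwork:
    species: str
    genes: pd.Index
    weights: np.ndarray  # symmetric, [0, 1], NaN diagonal

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene_id")
        n = len(self.genes)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match gene list")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


def median_expression_subset(dataset: ExpressionDataset) -> pd.Index:
    """Genes with greater-than-median expression in at least one sample.

    The median is computed per sample over all genes currently in the
    dataset; the comparison is strict.
    """
    medians = np.median(dataset.values, axis=0)
    keep = (dataset.values > medians[None, :]).any(axis=1)
    return dataset.genes[keep]


def build_network(
    dataset: ExpressionDataset, gene_subset: pd.Index | list[str] | None = None
) -> CoexpressionNetwork:
    """Build the rank-standardized coexpression network for one species."""
    species_list = dataset.species
    if len(species_list) != 1:
        raise ValueError("build_network expects a single-species dataset")
    if gene_subset is None:
        gene_subset = median_expression_subset(dataset)
    ds = dataset.subset_genes(pd.Index(gene_subset))
    if ds.n_samples < 3:
        raise ValueError(
            f"insufficient samples for correlation: {ds.n_samples} < 3"
        )
    if ds.n_genes < 2:
        raise ValueError("need at least 2 genes to build a network")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ds.values)
    np.fill_diagonal(corr, np.nan)

    n = ds.n_genes
    ranks = np.full((n, n), np.nan)
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = corr[i, off[i]]
        finite = np.isfinite(row)
        k = int(finite.sum())
        out = np.empty(len(row))
        if k:
            out[finite] = stats.rankdata(row[finite], method="average")
            out[~finite] = (k + 1) / 2.0  # NAs get the median rank of the row
        else:
            out[:] = (len(row) + 1) / 2.0
        ranks[i, off[i]] = out

    sym = (ranks + ranks.T) / 2.0
    max_rank = np.nanmax(sym)
    weights = sym / max_rank
    np.fill_diagonal(weights, np.nan)
    return CoexpressionNetwork(species_list[0], ds.genes, weights)


def pair_coexpression(
    network: CoexpressionNetwork, gene_a: str, gene_b: str
) -> float | None:
    """Standardized weight for a gene pair, or None if undefined.

    Undefined when either gene is absent from the network (it failed the
    median-expression subset) or when the pair is a gene against itself.
    """
    if gene_a == gene_b:
        return None
    if gene_a not in network.genes or gene_b not in network.genes:
        return None
    i = network.genes.get_loc(gene_a)
    j = network.genes.get_loc(gene_b)
    return float(network.weights[i, j])


def write_network(network: CoexpressionNetwork, path: str | Path) -> None:
    """Dump the upper triangle as a (gene_a, gene_b, weight) TSV (.gz aware)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    iu = np.triu_indices(len(network.genes), k=1)
    with opener(path, "wt") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for i, j in zip(*iu):
            fh.write(
                f"{network.genes[i]}\t{network.genes[j]}\t"
                f"{network.weights[i, j]:.10g}\n"
            )
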