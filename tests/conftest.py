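import numpy as np
import pandas as pd
import pytest

from parevo.io import ExpressionDataset
from parevo.simulate import SimConfig, simulate


def make_dataset(values, sample_meta, genes=None, species="spx"):
    """Build an ExpressionDataset from a value matrix and (tissue, replicate)
    tuples (or (species, tissue, replicate) triples) per sample."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    meta = []
    for m in sample_meta:
        if len(m) == 2:
            meta.append((species, *m))
        else:
            meta.append(tuple(m))
    sample_ids = [f"{sp}_{t}_{r}" for sp, t, r in meta]
    sheet = pd.DataFrame(
        {
            "species": [m[0] for m in meta],
            "tissue": [m[1] for m in meta],
            "replicate": [m[2] for m in meta],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionDataset(
        pd.Index(genes), pd.Index(sample_ids), values, sheet
    )


def dataset_with_correlations(target, n_samples=6, seed=0, genes=None):
    """Dataset whose empirical gene-gene Pearson matrix equals ``target``."""
    target = np.asarray(target, dtype=float)
    k = target.shape[0]
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n_samples, k))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    X = (Q @ np.linalg.cholesky(target).T).T
    X = X - X.min() + 1.0  # strictly positive; Pearson is shift-invariant
    meta = [("t1", i + 1) for i in range(n_samples)]
    return make_dataset(X, meta, genes=genes)


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(n_species=2, seed=1)
    datasets, orthogroups, gene_models, truth = simulate(cfg)
    return cfg, datasets, orthogroups, gene_models, truth


@pytest.fixture(scope="session")
def noise_free_sim():
    cfg = SimConfig(
        n_species=2, noise_sd=0.0, replicate_sd=0.0, seed=2,
        n_pairs_per_mode={"I": 10, "II": 10, "III": 10, "IV": 10},
        n_singletons=200, n_orthogroups_constrained=10, n_orthogroups_drift=2,
    )
    datasets, orthogroups, gene_models, truth = simulate(cfg)
    return cfg, datasets, orthogroups, gene_models, truth
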