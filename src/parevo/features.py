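"""Gene- and pair-level annotations.

Expression breadth (tissues with replicate-mean above a TPM floor), the
tau tissue-specificity index, tissue-specific calls, functional status and
the positional tandem/proximal/dispersed duplication classification.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import GeneModel
from .qc import MeanExpression

log = logging.getLogger(__name__)

__all__ = [
    "expression_breadth",
    "tau_specificity",
    "tissue_specific_call",
    "functional_status",
    "positional_dup_classify",
    "gene_feature_table",
    "annotate_pair_dup_types",
]


def expression_breadth(tissue_means, tpm_min: float = 3.0) -> int:
    """Number of tissues with replicate-mean expression strictly > tpm_min."""
    x = np.asarray(tissue_means, dtype=float)
    return int((x > tpm_min).sum())


def tau_specificity(tissue_means) -> float:
    """Tau tissue-specificity index on replicate-mean per-tissue values.

    tau = sum_i (1 - x_i/max) / (N - 1); 1 for single-tissue expression,
    0 for a uniform profile. Undefined (NaN) when all means are zero or
    there are fewer than two tissues.
    """
    x = np.asarray(tissue_means, dtype=float)
    if len(x) < 2:
        return float("nan")
    m = x.max()
    if m <= 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def tissue_specific_call(
    tissue_means: pd.Series, tau_min: float = 0.7, tpm_min: float = 5.0
) -> str | None:
    """The argmax tissue if tau > tau_min and its mean > tpm_min, else None.

    Ties at the maximum are ambiguous and yield None.
    """
    x = tissue_means.astype(float)
    tau = tau_specificity(x.to_numpy())
    if not np.isfinite(tau) or tau <= tau_min:
        return None
    m = x.max()
    if m <= tpm_min:
        return None
    top = x.index[x == m]
    if len(top) != 1:
        return None
    return str(top[0])


def functional_status(
    tissue_means, pseudogene_flag: bool, tpm_min: float = 3.0
) -> bool:
    """False (non-functional) if annotated pseudogene or the mean over
    tissue means falls below tpm_min."""
    if pseudogene_flag:
        return False
    x = np.asarray(tissue_means, dtype=float)
    return bool(x.mean() >= tpm_min)


def positional_dup_classify(
    gene_a: str,
    gene_b: str,
    gene_models: dict[str, GeneModel],
    proximal_max_gap: int = 10,
) -> str:
    """tandem / proximal / dispersed from gene-order adjacency.

    Same chromosome with |gene_index difference| of 1 is tandem, of
    2..proximal_max_gap is proximal; anything else (including different
    chromosomes) is dispersed. Applies to pairs not already labelled WGD or
    transposed upstream.
    """
    for g in (gene_a, gene_b):
        if g not in gene_models:
            raise KeyError(f"no gene model for gene {g!r}")
    ma, mb = gene_models[gene_a], gene_models[gene_b]
    if ma.chromosome != mb.chromosome:
        return "dispersed"
    gap = abs(ma.gene_index - mb.gene_index)
    if gap == 1:
        return "tandem"
    if 2 <= gap <= proximal_max_gap:
        return "proximal"
    return "dispersed"


def gene_feature_table(
    mean_expression: MeanExpression,
    gene_models: dict[str, dict[str, GeneModel]] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-gene feature record for every gene of every species."""
    cfg = config or RunConfig()
    rows = []
    for species in mean_expression.species:
        table = mean_expression[species]
        models = (gene_models or {}).get(species, {})
        for gene_id, means in table.iterrows():
            pseudo = models[gene_id].pseudogene_flag if gene_id in models else False
            specific = tissue_specific_call(
                means, tau_min=cfg.tau_min, tpm_min=cfg.tissue_specific_tpm
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "species": species,
                    "breadth": expression_breadth(means, cfg.breadth_tpm),
                    "tau": tau_specificity(means.to_numpy()),
                    "tissue_specific_in": specific or "none",
                    "functional": functional_status(
                        means, pseudo, cfg.functional_tpm
                    ),
                    "pseudogene": pseudo,
                }
            )
    return pd.DataFrame(rows)


def annotate_pair_dup_types(
    records: pd.DataFrame,
    gene_models: dict[str, dict[str, GeneModel]],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Fill the dup_type column of a pair table by gene positioning.

    Existing WGD / transposed labels (from upstream syntenic tools) pass
    through untouched; everything else is classified positionally.
    """
    cfg = config or RunConfig()
    records = records.copy()
    if "dup_type" not in records.columns:
        records["dup_type"] = pd.NA
    out = []
    for _, row in records.iterrows():
        if isinstance(row["dup_type"], str) and row["dup_type"] in (
            "WGD", "transposed"
        ):
            out.append(row["dup_type"])
            continue
        out.append(
            positional_dup_classify(
                row["gene_a"],
                row["gene_b"],
                gene_models[row["species"]],
                cfg.proximal_max_gap,
            )
        )
    records["dup_type"] = out
    return records
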