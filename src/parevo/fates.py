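"""Paralogue-pair fold-change statistics and expression-fate classification.

Every within-species gene pair from the orthogroup table flows through a
filtration funnel: pairs whose genes fail the median-expression subset are
"low_or_no_expression"; pairs with fewer than two samples where both copies
are non-zero (or no defined coexpression) are "insufficient"; the rest are
classified into groups I-IV by coexpression and log2 fold-change
statistics, or land in "threshold_gap" when no rule matches.

Group rules (strict/non-strict boundaries as stated):
  I   dosage balanced:     coexpr > high; mean < 1 and sd < 1
  II  paralogue dominance: coexpr > high; mean >= 1 and sd < 1
  III specialized:         coexpr > high; mean >= 1 and sd >= 1
  IV  diverged:            coexpr < low;  mean >= 1 and sd >= 1
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .coexpression import CoexpressionNetwork, pair_coexpression
from .io import ExpressionDataset, OrthogroupTable
from .qc import MeanExpression

log = logging.getLogger(__name__)

BUCKETS = ("low_or_no_expression", "insufficient", "classified", "threshold_gap")
GROUPS = ("I", "II", "III", "IV")

__all__ = [
    "BUCKETS",
    "GROUPS",
    "fold_change_stats",
    "classify_pair",
    "classify_all",
    "shared_expression_domains",
    "funnel_summary",
]


def fold_change_stats(
    a_values: np.ndarray, b_values: np.ndarray
) -> tuple[float, float, int] | None:
    """(|mean|, sd, n) of per-sample log2 fold change, or None if < 2 samples.

    Samples where either copy is zero are excluded (the log ratio is
    undefined there); sd uses the n-1 denominator.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    usable = (a > 0) & (b > 0)
    n = int(usable.sum())
    if n < 2:
        return None
    l2fc = np.log2(a[usable] / b[usable])
    return float(abs(l2fc.mean())), float(l2fc.std(ddof=1)), n


def classify_pair(
    coexpression: float,
    mean_abs_l2fc: float,
    sd_l2fc: float,
    config: RunConfig | None = None,
) -> str:
    """Assign a group I-IV or 'none' (threshold gap) to one statistics triple."""
    cfg = config or _DEFAULT_CONFIG
    high, low = cfg.coexpr_high, cfg.coexpr_low
    m, s = cfg.fc_mean, cfg.fc_sd
    if coexpression > high:
        if mean_abs_l2fc < m and sd_l2fc < s:
            return "I"
        if mean_abs_l2fc >= m and sd_l2fc < s:
            return "II"
        if mean_abs_l2fc >= m and sd_l2fc >= s:
            return "III"
        return "none"  # mean < m with sd >= s matches no rule
    if coexpression < low and mean_abs_l2fc >= m and sd_l2fc >= s:
        return "IV"
    return "none"


def classify_all(
    orthogroups: OrthogroupTable,
    datasets: dict[str, ExpressionDataset],
    networks: dict[str, CoexpressionNetwork],
    config: RunConfig | None = None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One PairFateRecord row per within-species pair, across all species.

    ``annotations`` may carry per-pair ``dup_type``, ``ka``, ``ks`` columns
    keyed by (species, gene_a, gene_b) (unordered); they are merged through.
    """
    cfg = config or _DEFAULT_CONFIG
    rows = []
    for species in sorted(datasets):
        ds = datasets[species]
        net = networks[species]
        net_genes = set(net.genes)
        for og, gene_a, gene_b in orthogroups.pairs(species):
            for g in (gene_a, gene_b):
                if g not in ds.genes:
                    raise KeyError(
                        f"gene {g!r} (orthogroup {og}) absent from the "
                        f"expression matrix of species {species!r}"
                    )
            coexpr = pair_coexpression(net, gene_a, gene_b)
            stats3 = fold_change_stats(ds.gene_row(gene_a), ds.gene_row(gene_b))
            if gene_a not in net_genes or gene_b not in net_genes:
                bucket, group = "low_or_no_expression", "none"
                mean_abs = sd = np.nan
                n_used = 0 if stats3 is None else stats3[2]
            elif stats3 is None or coexpr is None:
                bucket, group = "insufficient", "none"
                mean_abs = sd = np.nan
                n_used = 0 if stats3 is None else stats3[2]
            else:
                mean_abs, sd, n_used = stats3
                group = classify_pair(coexpr, mean_abs, sd, cfg)
                bucket = "classified" if group != "none" else "threshold_gap"
            rows.append(
                {
                    "species": species,
                    "orthogroup_id": og,
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "family_size": orthogroups.family_size(og),
                    "coexpression": np.nan if coexpr is None else coexpr,
                    "mean_abs_l2fc": mean_abs,
                    "sd_l2fc": sd,
                    "n_samples_used": n_used,
                    "bucket": bucket,
                    "group": group,
                }
            )
    records = pd.DataFrame(rows)
    if annotations is not None:
        records = _merge_annotations(records, annotations)
    return records


def _merge_annotations(records: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    ann = annotations.copy()
    for df in (records, ann):
        lo = df[["gene_a", "gene_b"]].min(axis=1)
        hi = df[["gene_a", "gene_b"]].max(axis=1)
        df["_key"] = df["species"] + "|" + lo + "|" + hi
    keep = [c for c in ("dup_type", "ka", "ks") if c in ann.columns]
    merged = records.merge(ann[["_key", *keep]], on="_key", how="left")
    return merged.drop(columns="_key")


def funnel_summary(records: pd.DataFrame) -> dict:
    """Counts and fractions per bucket and group (the filtration funnel)."""
    total = len(records)
    buckets = {b: int((records["bucket"] == b).sum()) for b in BUCKETS}
    groups = {g: int((records["group"] == g).sum()) for g in GROUPS}
    n_classified = buckets["classified"]
    summary = {
        "n_pairs": total,
        "buckets": buckets,
        "bucket_fractions": {
            b: (c / total if total else 0.0) for b, c in buckets.items()
        },
        "groups": groups,
        "group_fractions_of_classified": {
            g: (c / n_classified if n_classified else 0.0)
            for g, c in groups.items()
        },
        # share of classified pairs with correlated expression (groups I-III)
        "correlated_share_of_classified": (
            (groups["I"] + groups["II"] + groups["III"]) / n_classified
            if n_classified
            else 0.0
        ),
    }
    return summary


def shared_expression_domains(
    gene_a: str,
    gene_b: str,
    mean_expression: MeanExpression,
    species: str,
    breadth_tpm: float = 3.0,
) -> int:
    """Number of tissues where both copies have replicate-mean > breadth_tpm."""
    table = mean_expression[species]
    a = table.loc[gene_a]
    b = table.loc[gene_b]
    return int(((a > breadth_tpm) & (b > breadth_tpm)).sum())


def wgd_ssd_strata(records: pd.DataFrame, config: RunConfig | None = None) -> pd.Series:
    """WGD / SSD stratum per pair using the configured Ks windows.

    WGD pairs within ks_wgd and tandem/proximal pairs within ks_ssd (closed
    intervals); everything else — including pairs without Ks — is excluded
    from this summary only.
    """
    cfg = config or _DEFAULT_CONFIG
    if "dup_type" not in records.columns or "ks" not in records.columns:
        return pd.Series("excluded", index=records.index, name="stratum")
    ks = pd.to_numeric(records["ks"], errors="coerce")
    wgd = (
        (records["dup_type"] == "WGD")
        & (ks >= cfg.ks_wgd[0])
        & (ks <= cfg.ks_wgd[1])
    )
    ssd = (
        records["dup_type"].isin(["tandem", "proximal"])
        & (ks >= cfg.ks_ssd[0])
        & (ks <= cfg.ks_ssd[1])
    )
    out = pd.Series("excluded", index=records.index, name="stratum")
    out[wgd] = "WGD"
    out[ssd] = "SSD"
    return out


_DEFAULT_CONFIG = RunConfig()
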