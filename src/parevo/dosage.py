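"""Cross-species test for constraint on the total dosage of paralogue pairs.

Per tissue and species pair, orthogroups with exactly two copies in each
species and non-zero replicate-mean expression of all four genes are
retained. The log2 ratio of summed pair expression between the species is
z-scored against the ratio distribution over retained orthogroups, giving a
two-sided normal p per comparison. Per (orthogroup, species, tissue) the p
values over all partner species are averaged, Benjamini-Hochberg adjusted
across orthogroups within (species, tissue), and orthogroups with adjusted
average p below alpha are called dosage-unconstrained; all others are
assumed to evolve under constraint.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import OrthogroupTable
from .qc import MeanExpression

log = logging.getLogger(__name__)

__all__ = [
    "retained_orthogroups",
    "dosage_comparisons",
    "bh_adjust",
    "aggregate_and_call",
    "run_dosage_test",
]


def retained_orthogroups(
    tissue: str,
    species_a: str,
    species_b: str,
    mean_expression: MeanExpression,
    orthogroups: OrthogroupTable,
) -> list[str]:
    """Orthogroups with exactly 2 copies in each species, all four genes
    having non-zero replicate-mean expression in the tissue."""
    ta = mean_expression[species_a]
    tb = mean_expression[species_b]
    if tissue not in ta.columns or tissue not in tb.columns:
        return []
    retained = []
    for og in orthogroups.two_copy_orthogroups(species_a, species_b):
        genes_a = orthogroups.genes(og, species_a)
        genes_b = orthogroups.genes(og, species_b)
        try:
            va = ta.loc[list(genes_a), tissue]
            vb = tb.loc[list(genes_b), tissue]
        except KeyError:
            continue
        if (va > 0).all() and (vb > 0).all():
            retained.append(og)
    return retained


def dosage_comparisons(
    tissue: str,
    focal: str,
    other: str,
    retained: list[str],
    mean_expression: MeanExpression,
    orthogroups: OrthogroupTable,
    robust: bool = False,
) -> pd.DataFrame:
    """Per-orthogroup log2 ratio of summed pair expression, z score and p.

    z centres/scales by mean and sample sd of the log2 ratios over the
    retained orthogroups (median/1.4826*MAD when ``robust``); p is the
    two-sided standard-normal tail 2*(1-Phi(|z|)).
    """
    tf = mean_expression[focal]
    to = mean_expression[other]
    totals_f, totals_o = [], []
    for og in retained:
        totals_f.append(tf.loc[list(orthogroups.genes(og, focal)), tissue].sum())
        totals_o.append(to.loc[list(orthogroups.genes(og, other)), tissue].sum())
    return _comparison_frame(
        tissue, focal, other, pd.Index(retained, name="orthogroup_id"),
        np.asarray(totals_f, dtype=float), np.asarray(totals_o, dtype=float),
        robust,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def aggregate_and_call(
    comparisons: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Average p over species comparisons, BH-adjust, call constraint.

    ``comparisons`` holds one row per (tissue, focal, other, orthogroup);
    both orientations of a species pair carry the same p (|z| is symmetric),
    so each unordered comparison contributes identically to both species.
    BH runs across orthogroups within each (species, tissue); the call is
    unconstrained iff adjusted mean p < alpha (optionally also requiring
    mean |z| >= z_cutoff when configured).
    """
    cfg = config or RunConfig()
    if comparisons.empty:
        return pd.DataFrame(
            columns=[
                "orthogroup_id", "species", "tissue", "n_comparisons",
                "mean_p", "mean_abs_z", "adj_p", "call",
            ]
        )
    grouped = (
        comparisons.assign(abs_z=comparisons["z"].abs())
        .groupby(["orthogroup_id", "focal", "tissue"], sort=True)
        .agg(n_comparisons=("p", "size"), mean_p=("p", "mean"),
             mean_abs_z=("abs_z", "mean"))
        .reset_index()
        .rename(columns={"focal": "species"})
    )
    parts = []
    for (_, _), sub in grouped.groupby(["species", "tissue"], sort=True):
        sub = sub.copy()
        sub["adj_p"] = bh_adjust(sub["mean_p"].to_numpy())
        parts.append(sub)
    calls = pd.concat(parts, ignore_index=True)
    unconstrained = calls["adj_p"] < cfg.alpha
    if cfg.z_cutoff is not None:
        unconstrained &= calls["mean_abs_z"] >= cfg.z_cutoff
    calls["call"] = np.where(unconstrained, "unconstrained", "constrained")
    return calls


def _species_pair_totals(
    mean_expression: MeanExpression, orthogroups: OrthogroupTable
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Per species: (summed pair expression, all-copies-positive mask),
    both gene-x-tissue frames indexed by two-copy orthogroup ID."""
    out = {}
    for sp in mean_expression.species:
        table = mean_expression[sp]
        ogs, first, second = [], [], []
        for og in sorted(orthogroups.members):
            genes = orthogroups.genes(og, sp)
            if len(genes) == 2 and all(g in table.index for g in genes):
                ogs.append(og)
                first.append(genes[0])
                second.append(genes[1])
        if not ogs:
            out[sp] = (
                pd.DataFrame(columns=table.columns),
                pd.DataFrame(columns=table.columns),
            )
            continue
        va = table.loc[first].to_numpy()
        vb = table.loc[second].to_numpy()
        idx = pd.Index(ogs, name="orthogroup_id")
        out[sp] = (
            pd.DataFrame(va + vb, index=idx, columns=table.columns),
            pd.DataFrame((va > 0) & (vb > 0), index=idx, columns=table.columns),
        )
    return out


def _comparison_frame(
    tissue: str, focal: str, other: str, ogs: pd.Index,
    totals_f: np.ndarray, totals_o: np.ndarray, robust: bool,
) -> pd.DataFrame:
    ratio = np.log2(totals_f / totals_o)
    if robust:
        centre = float(np.median(ratio))
        scale = float(1.4826 * np.median(np.abs(ratio - centre)))
    else:
        centre = float(ratio.mean())
        scale = float(ratio.std(ddof=1)) if len(ratio) > 1 else 0.0
    if scale == 0.0:
        log.warning(
            "zero spread of log2 ratios for (%s, %s vs %s): all z set to 0",
            tissue, focal, other,
        )
        z = np.zeros_like(ratio)
    else:
        z = (ratio - centre) / scale
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "tissue": tissue,
            "focal": focal,
            "other": other,
            "orthogroup_id": ogs,
            "total_focal": totals_f,
            "total_other": totals_o,
            "log2_ratio": ratio,
            "z": z,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
        }
    )


def run_dosage_test(
    mean_expression: MeanExpression,
    orthogroups: OrthogroupTable,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full test over every tissue shared by >= 2 species.

    Returns ``(comparisons, calls)``; ``calls`` gains a species-level
    roll-up column ``unconstrained_any_tissue``. Comparisons with fewer
    retained orthogroups than ``min_orthogroups_per_comparison`` are
    skipped with a log message; tissues present in < 2 species are skipped
    automatically.
    """
    cfg = config or RunConfig()
    species = mean_expression.species
    tissue_species: dict[str, list[str]] = {}
    for sp in species:
        for t in mean_expression.tissues(sp):
            tissue_species.setdefault(t, []).append(sp)
    cache = _species_pair_totals(mean_expression, orthogroups)

    all_comparisons = []
    for tissue in sorted(tissue_species):
        sps = tissue_species[tissue]
        if len(sps) < 2:
            log.info("tissue %s present in < 2 species; skipped", tissue)
            continue
        for a, b in itertools.combinations(sorted(sps), 2):
            totals_a, pos_a = cache[a]
            totals_b, pos_b = cache[b]
            common = totals_a.index.intersection(totals_b.index)
            keep = pos_a.loc[common, tissue] & pos_b.loc[common, tissue]
            retained = common[keep]
            if len(retained) < cfg.min_orthogroups_per_comparison:
                log.info(
                    "skipping comparison (%s, %s vs %s): only %d retained "
                    "orthogroups", tissue, a, b, len(retained),
                )
                continue
            fwd = _comparison_frame(
                tissue, a, b, retained,
                totals_a.loc[retained, tissue].to_numpy(),
                totals_b.loc[retained, tissue].to_numpy(),
                robust=cfg.robust_z,
            )
            # reverse orientation: negated ratio/z, identical p
            rev = fwd.assign(
                focal=b, other=a,
                total_focal=fwd["total_other"], total_other=fwd["total_focal"],
                log2_ratio=-fwd["log2_ratio"], z=-fwd["z"],
            )
            all_comparisons.extend([fwd, rev])
    comparisons = (
        pd.concat(all_comparisons, ignore_index=True)
        if all_comparisons
        else pd.DataFrame(
            columns=["tissue", "focal", "other", "orthogroup_id",
                     "total_focal", "total_other", "log2_ratio", "z", "p"]
        )
    )
    calls = aggregate_and_call(comparisons, cfg)
    if not calls.empty:
        any_unconstrained = (
            calls.assign(u=calls["call"] == "unconstrained")
            .groupby(["orthogroup_id", "species"])["u"]
            .transform("any")
        )
        calls["unconstrained_any_tissue"] = any_unconstrained
    return comparisons, calls
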