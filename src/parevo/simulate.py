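"""Multi-species expression simulator with planted ground truth.

Generates per-species TPM matrices, a matching orthogroup table, gene
models on synthetic chromosomes, and a truth table recording, for every
two-copy orthogroup, the planted expression-fate mode (I-IV) and the
planted dosage regime (constrained vs drift) so every downstream stage can
be tested without external data.

All expression is built on the log2 scale and exponentiated (log-normal:
expression is positive and noise is multiplicative). Per-tissue profiles
and mode offsets are standardized to their target mean/spread after
drawing, so the planted mode is recoverable at the default classification
thresholds by construction — a separability device, not a biological claim.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_TISSUES
from .io import (
    ExpressionDataset,
    GeneModel,
    OrthogroupTable,
    write_expression,
    write_gene_models,
    write_orthogroups,
)

log = logging.getLogger(__name__)

MODES = ("I", "II", "III", "IV")
LAYOUTS = ("tandem", "proximal", "dispersed")


@dataclass
class SimConfig:
    """Knobs of the simulator; defaults give a small but complete dataset."""

    n_species: int = 5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 3
    n_singletons: int = 600
    n_pairs_per_mode: dict[str, int] = field(
        default_factory=lambda: {"I": 50, "II": 50, "III": 50, "IV": 50}
    )
    n_orthogroups_constrained: int = 60
    n_orthogroups_drift: int = 10
    #: log2 shift of the dominated copy in mode II
    dominance_delta: float = 2.0
    #: per-tissue log2 offsets for mode III are standardized to the mean and
    #: sd implied by this uniform range (mean=(lo+hi)/2, sd=(hi-lo)/sqrt(12))
    specialization_delta_range: tuple[float, float] = (1.0, 6.0)
    #: constant log2 offset of the inverted copy in mode IV
    divergence_delta: float = 2.0
    #: fraction of the mode III offset aligned with the tissue profile
    #: (1 = fully aligned, the separable default; 0 = fully random draws,
    #: which at 5 tissues is not reliably recoverable through the rank
    #: network)
    specialization_alignment: float = 1.0
    #: magnitude (log2) of the planted per-species dosage drift multiplier
    drift_sd: float = 2.0
    #: log2 sd of per-cell measurement noise
    noise_sd: float = 0.1
    #: log2 sd of additional per-cell replicate noise
    replicate_sd: float = 0.05
    base_expression_logmean: float = 6.0
    #: log2 spread of per-tissue profiles of pair/dosage genes
    profile_sd: float = 2.0
    #: singletons sit this many log2 units below base (background mass that
    #: anchors the per-sample median below the pair genes)
    singleton_logmean_offset: float = -6.0
    singleton_profile_sd: float = 1.0
    n_tissue_specific: int = 20
    n_pseudogenes: int = 10
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not self.tissues:
            raise ValueError("tissues must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.tissues = tuple(self.tissues)  # type: ignore[assignment]
        for name in ("n_singletons", "n_orthogroups_constrained",
                     "n_orthogroups_drift", "n_tissue_specific",
                     "n_pseudogenes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for mode in MODES:
            if self.n_pairs_per_mode.get(mode, 0) < 0:
                raise ValueError("pair counts must be >= 0")
        for name in ("noise_sd", "replicate_sd", "drift_sd", "profile_sd",
                     "singleton_profile_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.specialization_alignment <= 1.0:
            raise ValueError("specialization_alignment must be in [0, 1]")
        if self.n_chromosomes < 2:
            raise ValueError("n_chromosomes must be >= 2")
        extra = set(self.n_pairs_per_mode) - set(MODES)
        if extra:
            raise ValueError(f"unknown fate modes: {sorted(extra)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissues"] = list(self.tissues)
        d["specialization_delta_range"] = list(self.specialization_delta_range)
        return d

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthTable:
    """Planted ground truth, exported separately from the analysis inputs."""

    #: one row per (orthogroup, species) pair: gene_a, gene_b, mode, dup_type
    pairs: pd.DataFrame
    #: one row per two-copy (orthogroup, species): constraint label
    dosage: pd.DataFrame
    #: one row per (gene, species): planted tissue specificity + functional
    genes: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
        self.dosage.to_csv(outdir / "truth_dosage.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthTable":
        outdir = Path(outdir)
        return cls(
            pairs=pd.read_csv(outdir / "truth_pairs.tsv", sep="\t"),
            dosage=pd.read_csv(outdir / "truth_dosage.tsv", sep="\t"),
            genes=pd.read_csv(outdir / "truth_genes.tsv", sep="\t"),
        )


def summarize_truth(truth: TruthTable) -> dict:
    """Counts per planted mode / constraint label / gene flag."""
    pairs_per_og = truth.pairs.drop_duplicates("orthogroup_id")
    return {
        "n_pair_orthogroups": int(len(pairs_per_og)),
        "n_pair_records": int(len(truth.pairs)),
        "pairs_per_mode": {
            m: int((pairs_per_og["mode"] == m).sum()) for m in MODES
        },
        "constraint_counts": truth.dosage["constraint"]
        .value_counts()
        .to_dict(),
        "n_tissue_specific_genes": int(
            (truth.genes["tissue_specific_in"] != "none").sum()
        ),
        "n_functional_genes": int(truth.genes["functional"].sum()),
    }


# ---------------------------------------------------------------------------
# internals


def _standardize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale draws so the realized mean/sd hit their targets.

    Guarantees planted fold-change statistics sit where the mode definition
    needs them regardless of the particular draw.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or sd == 0:
        return np.full_like(values, mean)
    centred = values - values.mean()
    s = centred.std(ddof=1)
    if s == 0:
        return np.full_like(values, mean)
    return mean + centred * (sd / s)


@dataclass
class _Gene:
    slot: int
    kind: str  # singleton | pair_a | pair_b | dosage_a | dosage_b
    orthogroup: str
    profile: np.ndarray  # shared log2 tissue profile
    pseudogene: bool = False
    tissue_specific_in: str | None = None


def simulate(config: SimConfig):
    """Generate the full planted dataset.

    Returns ``(datasets, orthogroups, gene_models, truth)`` where
    ``datasets`` and ``gene_models`` are dicts keyed by species name.
    """
    rng = np.random.default_rng(config.seed)
    tissues = list(config.tissues)
    n_t = len(tissues)
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    base = config.base_expression_logmean

    genes: list[_Gene] = []
    slot = itertools.count()
    og_counter = itertools.count(1)

    def new_og() -> str:
        return f"OG{next(og_counter):07d}"

    # -- singletons (background + planted gene-level features) ------------
    singleton_base = base + config.singleton_logmean_offset
    singleton_genes: list[_Gene] = []
    for i in range(config.n_singletons):
        og = new_og()
        if i < config.n_pseudogenes:
            profile = np.full(n_t, singleton_base - 4.0)
            g = _Gene(next(slot), "singleton", og, profile, pseudogene=True)
        elif i < config.n_pseudogenes + config.n_tissue_specific:
            t = (i - config.n_pseudogenes) % n_t
            profile = np.full(n_t, base - 8.0)
            profile[t] = base
            g = _Gene(next(slot), "singleton", og, profile,
                      tissue_specific_in=tissues[t])
        else:
            draws = rng.normal(0.0, 1.0, n_t)
            profile = singleton_base + _standardize(
                draws, 0.0, config.singleton_profile_sd
            )
            g = _Gene(next(slot), "singleton", og, profile)
        singleton_genes.append(g)
        genes.append(g)

    # -- fate pairs -------------------------------------------------------
    lo, hi = config.specialization_delta_range
    spec_mean = (lo + hi) / 2.0
    spec_sd = (hi - lo) / np.sqrt(12.0)
    pair_truth_rows = []  # (og, mode)
    pair_genes: list[tuple[_Gene, _Gene, str]] = []
    for mode in MODES:
        for _ in range(config.n_pairs_per_mode.get(mode, 0)):
            og = new_og()
            alpha = _standardize(rng.normal(0.0, 1.0, n_t), 0.0, config.profile_sd)
            a_prof = base + alpha
            if mode == "I":
                b_prof = a_prof.copy()
            elif mode == "II":
                b_prof = a_prof - config.dominance_delta
            elif mode == "III":
                lam = config.specialization_alignment
                zeta = _standardize(rng.uniform(lo, hi, n_t), 0.0, 1.0)
                aligned = _standardize(alpha, 0.0, 1.0)
                delta = _standardize(
                    lam * aligned + (1.0 - lam) * zeta, spec_mean, spec_sd
                )
                b_prof = a_prof - delta
            else:  # IV: inverted profile, offset so the mean log2 FC is planted
                b_prof = (base - config.divergence_delta) - alpha
            ga = _Gene(next(slot), "pair_a", og, a_prof)
            gb = _Gene(next(slot), "pair_b", og, b_prof)
            genes.extend([ga, gb])
            pair_genes.append((ga, gb, mode))
            pair_truth_rows.append((og, ga, gb, mode))

    # -- dosage orthogroups ----------------------------------------------
    # Totals are shared across species; constrained orthogroups split the
    # total between copies with a per-species fraction (reciprocal drift of
    # the copies, conserved sum). Drift orthogroups additionally scale the
    # total of one species by 2^(+-drift_sd).
    dosage_rows = []  # (og, ga, gb, total_profile, split_per_species, drift_species, sign)
    n_dosage = config.n_orthogroups_constrained + config.n_orthogroups_drift
    for i in range(n_dosage):
        og = new_og()
        beta = _standardize(rng.normal(0.0, 1.0, n_t), 0.0, config.profile_sd)
        total = base + 1.0 + beta  # +1: pair sum sits above single-copy genes
        fractions = rng.uniform(0.3, 0.7, config.n_species)
        is_drift = i >= config.n_orthogroups_constrained
        drift_species = rng.integers(config.n_species) if is_drift else -1
        drift_sign = rng.choice([-1.0, 1.0]) if is_drift else 0.0
        ga = _Gene(next(slot), "dosage_a", og, total)  # profiles set per species
        gb = _Gene(next(slot), "dosage_b", og, total)
        genes.extend([ga, gb])
        dosage_rows.append((og, ga, gb, total, fractions, drift_species, drift_sign))

    # -- chromosome layout (shared across species) ------------------------
    chrom_of: dict[int, tuple[int, int]] = {}  # slot -> (chrom, position)
    chroms: list[list[int]] = [[] for _ in range(config.n_chromosomes)]
    spacers = deque(g.slot for g in singleton_genes)
    layout_of_pair: dict[str, str] = {}
    layout_cycle = itertools.cycle(LAYOUTS)
    gap_cycle = itertools.cycle(range(2, 11))
    chrom_cycle = itertools.cycle(range(config.n_chromosomes))
    all_pairs = [(ga, gb, og) for og, ga, gb, _ in pair_truth_rows] + [
        (ga, gb, og) for og, ga, gb, *_ in dosage_rows
    ]
    for ga, gb, og in all_pairs:
        layout = next(layout_cycle)
        c = next(chrom_cycle)
        if layout == "tandem":
            chroms[c].extend([ga.slot, gb.slot])
        elif layout == "proximal":
            gap = next(gap_cycle)
            n_spacers = min(gap - 1, len(spacers))
            chroms[c].append(ga.slot)
            for _ in range(n_spacers):
                chroms[c].append(spacers.popleft())
            chroms[c].append(gb.slot)
            if n_spacers == 0:
                layout = "tandem"  # ran out of spacers: record what was built
        else:
            c2 = (c + config.n_chromosomes // 2 + 1) % config.n_chromosomes
            chroms[c].append(ga.slot)
            chroms[c2].append(gb.slot)
        layout_of_pair[og] = layout
    while spacers:
        chroms[next(chrom_cycle)].append(spacers.popleft())
    for c, slots in enumerate(chroms):
        for pos, s in enumerate(slots):
            chrom_of[s] = (c, pos)

    # -- per-species expression ------------------------------------------
    sub_rngs = {sp: r for sp, r in zip(species, rng.spawn(config.n_species))}
    gene_order = sorted(genes, key=lambda g: g.slot)
    n_genes = len(gene_order)

    def gene_id(sp: str, g: _Gene) -> str:
        return f"{sp}_g{g.slot:05d}"

    datasets: dict[str, ExpressionDataset] = {}
    gene_models: dict[str, list[GeneModel]] = {}
    members: dict[str, dict[str, tuple[str, ...]]] = {}
    for g in genes:
        members.setdefault(g.orthogroup, {})
    for og, ga, gb, mode in pair_truth_rows:
        for sp in species:
            members[og][sp] = (gene_id(sp, ga), gene_id(sp, gb))
    for og, ga, gb, *_ in dosage_rows:
        for sp in species:
            members[og][sp] = (gene_id(sp, ga), gene_id(sp, gb))
    for g in singleton_genes:
        for sp in species:
            members[g.orthogroup][sp] = (gene_id(sp, g),)
    orthogroups = OrthogroupTable(members, tuple(species))

    tissue_of_sample = []
    sample_names_tpl = []
    for t in tissues:
        for r in range(1, config.n_replicates + 1):
            tissue_of_sample.append(tissues.index(t))
            sample_names_tpl.append((t, r))
    tissue_idx = np.array(tissue_of_sample)
    n_samples = len(tissue_idx)

    for si, sp in enumerate(species):
        profiles = np.empty((n_genes, n_t))
        for gi, g in enumerate(gene_order):
            profiles[gi] = g.profile
        # dosage orthogroups: per-species copy split and planted drift
        for og, ga, gb, total, fractions, drift_species, drift_sign in dosage_rows:
            t_prof = total.copy()
            if drift_species == si:
                t_prof = t_prof + drift_sign * config.drift_sd
            f = fractions[si]
            profiles[_slot_index(gene_order, ga.slot)] = t_prof + np.log2(f)
            profiles[_slot_index(gene_order, gb.slot)] = t_prof + np.log2(1.0 - f)

        sp_rng = sub_rngs[sp]
        log2m = profiles[:, tissue_idx]
        noise = sp_rng.normal(0.0, config.noise_sd, (n_genes, n_samples))
        rep_noise = sp_rng.normal(0.0, config.replicate_sd, (n_genes, n_samples))
        values = np.exp2(log2m + noise + rep_noise)

        sample_ids = [f"{sp}_{t}_{r}" for t, r in sample_names_tpl]
        sheet = pd.DataFrame(
            {
                "species": sp,
                "tissue": [t for t, _ in sample_names_tpl],
                "replicate": [r for _, r in sample_names_tpl],
                "pct_uniquely_mapped": 95.0,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        gids = pd.Index([gene_id(sp, g) for g in gene_order], name="gene_id")
        datasets[sp] = ExpressionDataset(gids, pd.Index(sample_ids), values, sheet)

        models = []
        for g in gene_order:
            c, pos = chrom_of[g.slot]
            start = 1 + pos * 1000
            models.append(
                GeneModel(
                    gene_id=gene_id(sp, g),
                    chromosome=f"chr{c + 1}",
                    start=start,
                    end=start + 500,
                    strand="+" if g.slot % 2 == 0 else "-",
                    gene_index=pos,
                    pseudogene_flag=g.pseudogene,
                )
            )
        gene_models[sp] = models

    # -- truth table ------------------------------------------------------
    pair_rows = []
    for og, ga, gb, mode in pair_truth_rows:
        for sp in species:
            pair_rows.append(
                {
                    "orthogroup_id": og,
                    "species": sp,
                    "gene_a": gene_id(sp, ga),
                    "gene_b": gene_id(sp, gb),
                    "mode": mode,
                    "dup_type": layout_of_pair[og],
                }
            )
    dosage_truth = []
    for og, ga, gb, mode in pair_truth_rows:
        for sp in species:
            dosage_truth.append(
                {"orthogroup_id": og, "species": sp, "constraint": "constrained"}
            )
    for og, ga, gb, total, fractions, drift_species, drift_sign in dosage_rows:
        for si, sp in enumerate(species):
            dosage_truth.append(
                {
                    "orthogroup_id": og,
                    "species": sp,
                    "constraint": "drift" if si == drift_species else "constrained",
                }
            )
    gene_rows = []
    for g in gene_order:
        mean_tpm = float(np.mean(np.exp2(g.profile)))
        if g.kind.startswith("dosage"):
            mean_tpm = float("nan")  # per-species; functional by construction
            functional = True
        else:
            functional = (not g.pseudogene) and mean_tpm >= 3.0
        for sp in species:
            gene_rows.append(
                {
                    "gene_id": gene_id(sp, g),
                    "species": sp,
                    "tissue_specific_in": g.tissue_specific_in or "none",
                    "functional": functional,
                    "pseudogene": g.pseudogene,
                }
            )
    truth = TruthTable(
        pairs=pd.DataFrame(pair_rows),
        dosage=pd.DataFrame(dosage_truth),
        genes=pd.DataFrame(gene_rows),
    )
    return datasets, orthogroups, gene_models, truth


def _slot_index(gene_order: list[_Gene], slot: int) -> int:
    # gene_order is sorted by slot and slots are consecutive from 0
    return slot


def write_simulation(
    config: SimConfig, outdir: str | Path
) -> tuple[dict, OrthogroupTable, dict, TruthTable]:
    """Run :func:`simulate` and write everything in pipeline input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, orthogroups, gene_models, truth = simulate(config)
    sheets = []
    for sp, ds in datasets.items():
        write_expression(ds, outdir / f"expression_{sp}.tsv")
        write_gene_models(gene_models[sp], outdir / f"genes_{sp}.gff3")
        sheets.append(ds.sheet)
    pd.concat(sheets).to_csv(outdir / "samples.tsv", sep="\t",
                             index_label="sample_id")
    write_orthogroups(orthogroups, outdir / "orthogroups.tsv")
    truth.write(outdir)
    import json

    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return datasets, orthogroups, gene_models, truth
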