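"""Readers and writers for the on-disk formats.

Expression matrices are dense TSV (first column gene IDs, one column per
sample); sample sheets are TSV with columns ``sample_id``, ``species``,
``tissue``, ``replicate`` and optionally ``pct_uniquely_mapped``.
Orthogroups use the OrthoFinder ``Orthogroups.tsv`` dialect (header
``Orthogroup`` plus one column per species, comma+space separated gene
lists, empty cell = species absent). Gene coordinates come from GFF3.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SHEET_COLUMNS = ("sample_id", "species", "tissue", "replicate")

__all__ = [
    "ExpressionDataset",
    "OrthogroupTable",
    "GeneModel",
    "read_sample_sheet",
    "read_expression",
    "write_expression",
    "read_orthogroups",
    "write_orthogroups",
    "read_gene_models",
    "write_gene_models",
]


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionDataset:
    """A TPM matrix (genes x samples) plus its sample metadata.

    ``sheet`` is indexed by sample_id and aligned with ``samples``. Values
    are dense and non-negative; absence must be encoded as 0.
    """

    genes: pd.Index
    samples: pd.Index
    values: np.ndarray
    sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene_id")
        self.samples = pd.Index(self.samples, name="sample_id")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) == 0:
            raise ValueError("no genes")
        if self.genes.has_duplicates:
            dup = self.genes[self.genes.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if self.samples.has_duplicates:
            dup = self.samples[self.samples.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression for gene {self.genes[i]!r} "
                f"in sample {self.samples[j]!r}"
            )
        missing = self.samples.difference(self.sheet.index)
        if len(missing):
            raise ValueError(f"sample {missing[0]!r} missing from sample sheet")
        self.sheet = self.sheet.loc[self.samples]
        key = self.sheet[["species", "tissue", "replicate"]]
        if key.duplicated().any():
            bad = self.sheet.index[key.duplicated()][0]
            raise ValueError(
                f"duplicate (species, tissue, replicate) for sample {bad!r}"
            )

    # -- convenience ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def species(self) -> list[str]:
        return sorted(self.sheet["species"].unique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def gene_row(self, gene_id: str) -> np.ndarray:
        i = self.genes.get_loc(gene_id)
        return self.values[i]

    def subset_genes(self, keep: pd.Index | list[str]) -> "ExpressionDataset":
        keep = pd.Index(keep)
        idx = self.genes.get_indexer(keep)
        if (idx < 0).any():
            missing = keep[idx < 0][0]
            raise KeyError(f"gene {missing!r} not in dataset")
        return ExpressionDataset(keep, self.samples, self.values[idx], self.sheet)

    def subset_samples(self, keep: pd.Index | list[str]) -> "ExpressionDataset":
        keep = pd.Index(keep)
        idx = self.samples.get_indexer(keep)
        if (idx < 0).any():
            missing = keep[idx < 0][0]
            raise KeyError(f"sample {missing!r} not in dataset")
        return ExpressionDataset(
            self.genes, keep, self.values[:, idx], self.sheet.loc[keep]
        )

    def for_species(self, species: str) -> "ExpressionDataset":
        keep = self.sheet.index[self.sheet["species"] == species]
        if len(keep) == 0:
            raise KeyError(f"no samples for species {species!r}")
        return self.subset_samples(keep)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV, indexed by sample_id."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id in sheet: {dup!r}")
    if (sheet["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    if "pct_uniquely_mapped" in sheet.columns:
        pct = sheet["pct_uniquely_mapped"].dropna()
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("pct_uniquely_mapped must be in [0, 100]")
    return sheet.set_index("sample_id")


def read_expression(
    path: str | Path,
    sheet_path: str | Path,
    min_pct_uniquely_mapped: float = 50.0,
) -> ExpressionDataset:
    """Read a TPM matrix and its sample sheet.

    Samples whose ``pct_uniquely_mapped`` is at or below
    ``min_pct_uniquely_mapped`` are dropped with a logged warning (upstream
    mapping QC). Samples present in the matrix but absent from the sheet are
    a hard error.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    sheet = read_sample_sheet(sheet_path)
    samples = pd.Index(frame.columns.astype(str), name="sample_id")
    missing = samples.difference(sheet.index)
    if len(missing):
        raise ValueError(f"sample {missing[0]!r} missing from sample sheet")
    sheet = sheet.loc[samples]
    if "pct_uniquely_mapped" in sheet.columns:
        pct = sheet["pct_uniquely_mapped"]
        bad = sheet.index[pct.notna() & (pct <= min_pct_uniquely_mapped)]
        for sample in bad:
            log.warning(
                "dropping sample %s: %.1f%% uniquely mapped reads (<= %g%%)",
                sample, pct[sample], min_pct_uniquely_mapped,
            )
        keep = samples.difference(bad, sort=False)
        frame = frame[keep]
        sheet = sheet.loc[keep]
        samples = keep
    return ExpressionDataset(frame.index, samples, frame.to_numpy(float), sheet)


def write_expression(
    dataset: ExpressionDataset, path: str | Path, sheet_path: str | Path | None = None
) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    if sheet_path is not None:
        dataset.sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# orthogroups


@dataclass
class OrthogroupTable:
    """Orthogroup -> species -> gene lists.

    A gene may belong to at most one orthogroup; family size is the total
    gene count over all species.
    """

    members: dict[str, dict[str, tuple[str, ...]]]
    species: tuple[str, ...]
    _gene_to_og: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._gene_to_og = {}
        for og, by_species in self.members.items():
            for sp, genes in by_species.items():
                for g in genes:
                    if g in self._gene_to_og:
                        raise ValueError(
                            f"gene {g!r} listed in both "
                            f"{self._gene_to_og[g]!r} and {og!r}"
                        )
                    self._gene_to_og[g] = og

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def family_size(self, orthogroup_id: str) -> int:
        return sum(len(g) for g in self.members[orthogroup_id].values())

    def genes(self, orthogroup_id: str, species: str) -> tuple[str, ...]:
        return self.members[orthogroup_id].get(species, ())

    def orthogroup_of(self, gene_id: str) -> str | None:
        return self._gene_to_og.get(gene_id)

    def pairs(self, species: str):
        """All unordered within-species gene pairs, per orthogroup.

        Yields ``(orthogroup_id, gene_a, gene_b)`` for every combination of
        two genes the species has in the orthogroup.
        """
        for og in sorted(self.members):
            genes = self.genes(og, species)
            for a, b in itertools.combinations(genes, 2):
                yield og, a, b

    def singleton_orthogroups(self, species: list[str] | None = None) -> list[str]:
        """Orthogroups with exactly one gene in every listed species."""
        species = list(species) if species is not None else list(self.species)
        return [
            og
            for og in sorted(self.members)
            if all(len(self.genes(og, sp)) == 1 for sp in species)
        ]

    def two_copy_orthogroups(self, species_a: str, species_b: str) -> list[str]:
        """Orthogroups with exactly two genes in each of the two species."""
        return [
            og
            for og in sorted(self.members)
            if len(self.genes(og, species_a)) == 2
            and len(self.genes(og, species_b)) == 2
        ]


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Parse an OrthoFinder-style Orthogroups.tsv."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "Orthogroup":
            raise ValueError(
                f"malformed orthogroup header: first column is "
                f"{header[0]!r}, expected 'Orthogroup'"
            )
        species = tuple(header[1:])
        if len(set(species)) != len(species):
            raise ValueError("duplicate species column in orthogroup header")
        members: dict[str, dict[str, tuple[str, ...]]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} columns")
            og = cells[0]
            if og in members:
                raise ValueError(f"duplicate orthogroup ID: {og!r}")
            row: dict[str, tuple[str, ...]] = {}
            for sp, cell in zip(species, cells[1:]):
                cell = cell.strip()
                if cell:
                    row[sp] = tuple(g.strip() for g in cell.split(",") if g.strip())
            members[og] = row
    return OrthogroupTable(members, species)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og in sorted(table.members):
            cells = [", ".join(table.genes(og, sp)) for sp in table.species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates plus its rank along the chromosome.

    ``gene_index`` is the 0-based rank by ascending start coordinate within
    the chromosome (ties broken by gene ID); it is the adjacency metric used
    for tandem/proximal classification, so strand is ignored.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    gene_index: int
    pseudogene_flag: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: coordinates are 1-based")


_PSEUDO_TYPES = {"pseudogene", "pseudogenic_gene"}


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Load gene features from GFF3 and assign per-chromosome gene ranks."""
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    raw = []
    for ftype in ("gene", *sorted(_PSEUDO_TYPES)):
        for feat in db.features_of_type(ftype):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            if feat.start is None or feat.end is None:
                log.warning("skipping gene %s: missing coordinates", gene_id)
                continue
            biotype = (
                feat.attributes.get("biotype", [])
                or feat.attributes.get("gene_biotype", [])
            )
            pseudo = ftype in _PSEUDO_TYPES or "pseudogene" in biotype
            raw.append((gene_id, feat.seqid, feat.start, feat.end,
                        feat.strand or ".", pseudo))
    models: list[GeneModel] = []
    raw.sort(key=lambda r: (r[1], r[2], r[0]))
    for chrom, group in itertools.groupby(raw, key=lambda r: r[1]):
        for index, (gene_id, _, start, end, strand, pseudo) in enumerate(group):
            models.append(GeneModel(gene_id, chrom, start, end, strand, index, pseudo))
    return models


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (genes only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chromosome, m.start, m.gene_id)):
            ftype = "pseudogene" if m.pseudogene_flag else "gene"
            fh.write(
                f"{m.chromosome}\tparevo\t{ftype}\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )


def gene_model_index(models: list[GeneModel]) -> dict[str, GeneModel]:
    return {m.gene_id: m for m in models}
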