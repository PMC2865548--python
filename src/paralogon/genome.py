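"""Gene and genome containers used throughout the package.

Coordinates are 0-based half-open ``[start, end)`` base pairs. Strand is
recorded for completeness but ignored by every downstream analysis (synteny
membership and paralogon detection depend only on chromosome and start).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

GENE_TABLE_COLUMNS = [
    "gene_id",
    "species",
    "chromosome",
    "start",
    "end",
    "strand",
    "family_id",
]


@dataclass(frozen=True)
class GeneRecord:
    """A single gene: identity, location and family assignment."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    family_id: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: start must be non-negative")
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def moved(self, *, chromosome: str | None = None, start: int | None = None) -> "GeneRecord":
        """Copy of this record relocated, preserving gene length."""
        chrom = self.chromosome if chromosome is None else chromosome
        if start is None:
            return replace(self, chromosome=chrom)
        return replace(self, chromosome=chrom, start=start, end=start + self.length)


@dataclass
class Genome:
    """Ordered gene collection for one species.

    Invariants (checked by :meth:`validate`): gene ids unique, genes on one
    chromosome non-overlapping, every gene's chromosome declared in
    ``chromosome_lengths``.
    """

    species: str
    genes: list[GeneRecord] = field(default_factory=list)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chromosome not in self.chromosome_lengths:
                raise ValueError(
                    f"{g.gene_id}: chromosome {g.chromosome!r} not in chromosome_lengths"
                )
            if g.end > self.chromosome_lengths[g.chromosome]:
                raise ValueError(f"{g.gene_id}: extends past end of {g.chromosome}")
        for chrom in self.chromosomes():
            ordered = sorted(self.genes_on(chrom), key=lambda g: g.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlap on {chrom}: {a.gene_id} [{a.start},{a.end}) and "
                        f"{b.gene_id} [{b.start},{b.end})"
                    )

    def chromosomes(self) -> list[str]:
        return sorted(self.chromosome_lengths)

    def genes_on(self, chromosome: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene id {gene_id!r}")

    def __contains__(self, gene_id: str) -> bool:
        return any(g.gene_id == gene_id for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def families(self) -> dict[str, list[GeneRecord]]:
        fams: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            fams.setdefault(g.family_id, []).append(g)
        return fams

    def copy(self) -> "Genome":
        return Genome(
            species=self.species,
            genes=list(self.genes),
            chromosome_lengths=dict(self.chromosome_lengths),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.gene_id, g.species, g.chromosome, g.start, g.end, g.strand, g.family_id)
            for g in self.genes
        ]
        return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def write_gene_table(genomes: Iterable[Genome], path: str | Path) -> None:
    """Write one or more genomes as a tab-separated gene table."""
    frames = [g.to_frame() for g in genomes]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-table TSV, validating schema and per-row coordinates."""
    table = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene_id": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table {path}: missing columns {missing}")
    bad = table[table["start"] >= table["end"]]
    if not bad.empty:
        rows = ", ".join(str(i) for i in bad.index[:5])
        raise ValueError(f"gene table {path}: start >= end at row(s) {rows}")
    return table


def genomes_from_frame(table: pd.DataFrame, chromosome_lengths: dict[str, dict[str, int]] | None = None) -> dict[str, Genome]:
    """Group a gene-table frame into per-species Genome objects.

    When chromosome lengths are not supplied they are inferred as the maximal
    gene end per chromosome (sufficient for region work on real tables).
    """
    out: dict[str, Genome] = {}
    for species, sub in table.groupby("species", sort=True):
        genes = [
            GeneRecord(
                gene_id=str(r.gene_id),
                species=str(species),
                chromosome=str(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                family_id=str(r.family_id),
            )
            for r in sub.itertuples()
        ]
        if chromosome_lengths and species in chromosome_lengths:
            lengths = dict(chromosome_lengths[species])
        else:
            lengths = {}
            for g in genes:
                lengths[g.chromosome] = max(lengths.get(g.chromosome, 0), g.end)
        out[str(species)] = Genome(species=str(species), genes=genes, chromosome_lengths=lengths)
    return out
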