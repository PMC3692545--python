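"""Tabular and FASTA IO plus the elementary set operations of the pipeline.

All tables are tab-separated with a header row.  Identification tables carry
one row per protein with the number of distinct peptides and the spectral
count observed in one sample; gene identifiers are opaque, case-sensitive
strings throughout (no namespace validation is attempted).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

logger = logging.getLogger(__name__)

IDENT_COLUMNS = ["protein_accession", "distinct_peptides", "spectral_count", "observed_peptides"]


@dataclass
class IdentificationTable:
    """Per-sample protein identification records.

    ``records`` holds one row per protein accession with columns
    ``protein_accession`` (str), ``distinct_peptides`` (int >= 0),
    ``spectral_count`` (int >= 0) and ``observed_peptides`` (semicolon-joined
    peptide strings, possibly empty).
    """

    sample_id: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in IDENT_COLUMNS[:3] if c not in df.columns]
        if missing:
            raise InputError(f"identification table {self.sample_id!r} missing columns {missing}")
        if "observed_peptides" not in df.columns:
            df = df.assign(observed_peptides="")
        df = df[IDENT_COLUMNS].copy()
        df["observed_peptides"] = df["observed_peptides"].fillna("").astype(str)
        if df["protein_accession"].duplicated().any():
            dups = df.loc[df["protein_accession"].duplicated(), "protein_accession"].tolist()
            raise InputError(
                f"duplicate accessions in sample {self.sample_id!r}: {sorted(set(dups))[:5]}"
            )
        if (df["distinct_peptides"] < 0).any() or (df["spectral_count"] < 0).any():
            raise InputError(f"negative counts in sample {self.sample_id!r}")
        n_obs = df["observed_peptides"].map(lambda s: len({p for p in s.split(";") if p}))
        bad = df.loc[n_obs > df["distinct_peptides"], "protein_accession"]
        if len(bad):
            raise InputError(
                f"sample {self.sample_id!r}: observed peptide sets larger than "
                f"distinct_peptides for {bad.tolist()[:5]}"
            )
        df = df.reset_index(drop=True)
        object.__setattr__(self, "records", df)

    @property
    def accessions(self) -> set[str]:
        return set(self.records["protein_accession"])

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ReferenceSet:
    """A named, non-redundant set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# ---------------------------------------------------------------------------
# IO


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an accession -> sequence mapping (input order kept)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise InputError(f"duplicate FASTA accession {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=acc, description="") for acc, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_identification_table(path: str | Path, sample_id: str | None = None) -> IdentificationTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_accession": str})
    return IdentificationTable(sample_id or path.stem, df)


def write_identification_table(table: IdentificationTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path, name: str | None = None) -> ReferenceSet:
    """Read a one-column TSV (header row) as a reference gene set."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 1:
        raise InputError(f"gene set file {path} has no columns")
    genes = frozenset(df.iloc[:, 0].dropna())
    return ReferenceSet(name or path.stem, genes)


def write_gene_set(refset: ReferenceSet, path: str | Path, column: str = "gene_id") -> None:
    pd.DataFrame({column: sorted(refset.genes)}).to_csv(path, sep="\t", index=False)


def read_id_map(path: str | Path) -> pd.DataFrame:
    """Read a protein->gene mapping TSV; many-to-many pairs allowed, duplicates dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    df = df.rename(columns={cols[0]: "protein_accession", cols[1]: "gene_id"})
    before = len(df)
    df = df.drop_duplicates(["protein_accession", "gene_id"]).reset_index(drop=True)
    if len(df) < before:
        logger.warning("%s: dropped %d duplicate mapping rows", path, before - len(df))
    return df[["protein_accession", "gene_id"]]


# ---------------------------------------------------------------------------
# Operations


def filter_by_peptides(table: IdentificationTable, min_distinct: int = 2) -> IdentificationTable:
    """Retain records identified with at least ``min_distinct`` distinct peptides."""
    if min_distinct < 1:
        raise InputError("min_distinct must be >= 1")
    kept = table.records[table.records["distinct_peptides"] >= min_distinct]
    return IdentificationTable(table.sample_id, kept.reset_index(drop=True))


def intersect_samples(tables: Sequence[IdentificationTable]) -> set[str]:
    """Accessions present in every sample (the cross-platform profiling consensus)."""
    if len(tables) < 2:
        raise InputError("need at least two identification tables to intersect")
    common = tables[0].accessions
    for t in tables[1:]:
        common &= t.accessions
    return common


def map_to_genes(
    accessions: Iterable[str],
    id_map: pd.DataFrame,
    on_unmapped: str = "warn",
) -> tuple[set[str], list[str]]:
    """Map protein accessions to gene identifiers, expanding many-to-many pairs.

    Returns ``(genes, unmapped)``.  ``on_unmapped`` is ``"warn"`` (drop the
    accession with a logged warning) or ``"error"``.
    """
    if on_unmapped not in ("warn", "error"):
        raise InputError(f"unknown unmapped policy {on_unmapped!r}")
    accessions = set(accessions)
    hits = id_map[id_map["protein_accession"].isin(accessions)]
    genes = set(hits["gene_id"])
    unmapped = sorted(accessions - set(hits["protein_accession"]))
    if unmapped:
        if on_unmapped == "error":
            raise InputError(f"unmapped accession {unmapped[0]!r}")
        logger.warning("%d accessions had no gene mapping and were dropped", len(unmapped))
    return genes, unmapped


def pool_reference_sets(sets: Sequence[ReferenceSet], name: str) -> ReferenceSet:
    """Union several reference sets into one non-redundant set."""
    if not sets:
        raise InputError("need at least one reference set to pool")
    genes: frozenset[str] = frozenset()
    for s in sets:
        genes |= s.genes
    return ReferenceSet(name, genes)
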