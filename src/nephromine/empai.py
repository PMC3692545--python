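"""In-silico tryptic digestion and emPAI label-free quantitation.

The exponentially modified protein abundance index,

    emPAI = 10^(N_observed / N_observable) - 1,

is a coverage-based proxy for protein amount in a mixture: ``N_observed`` is
the number of distinct peptides matched to the protein, ``N_observable`` the
number of tryptic peptides the instrument could in principle detect.  A
peptide is observable when its monoisotopic m/z at some charge state falls in
the instrument scan window and it is long enough to be identifiable.

Defaults follow an Orbitrap-style survey scan: m/z 300-2000, charge 2-3,
fully tryptic peptides (no missed cleavage) of length >= 6, with fixed
carbamidomethylation of cysteine (+57.02146 Da).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from pyteomics import mass as _pmass

from .errors import DegenerateProteinError, InputError

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTON_MASS = 1.00727646688
CARBAMIDOMETHYL = 57.02146


@dataclass(frozen=True)
class DigestParams:
    """Digestion and observability settings.

    missed_cleavages: maximum missed tryptic sites per peptide.
    min_len: minimum peptide length (residues) to count as observable.
    mz window and charge range define instrument observability.
    """

    missed_cleavages: int = 0
    min_len: int = 6
    min_mz: float = 300.0
    max_mz: float = 2000.0
    z_min: int = 2
    z_max: int = 3

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise InputError("missed_cleavages must be >= 0")
        if self.min_len < 1:
            raise InputError("min_len must be >= 1")
        if not self.min_mz < self.max_mz:
            raise InputError("require min_mz < max_mz")
        if not 1 <= self.z_min <= self.z_max:
            raise InputError("require 1 <= z_min <= z_max")


def digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Tryptic digest: cleave C-terminal to K or R except before P.

    Returns all products with up to ``missed_cleavages`` missed sites,
    ordered by start position, then by increasing length at the same start.
    """
    if not sequence:
        raise InputError("empty sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise InputError(f"non-standard residues {sorted(bad)} in sequence")
    if missed_cleavages < 0:
        raise InputError("missed_cleavages must be >= 0")
    # fully cleaved fragments
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    fragments = [sequence[cuts[i]: cuts[i + 1]] for i in range(len(cuts) - 1)]
    peptides: list[str] = []
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            peptides.append("".join(fragments[i: j + 1]))
    return peptides


def peptide_mz(peptide: str, charge: int) -> float:
    """Monoisotopic m/z with fixed Cys carbamidomethylation."""
    neutral = _pmass.fast_mass(peptide) + CARBAMIDOMETHYL * peptide.count("C")
    return (neutral + charge * PROTON_MASS) / charge


def count_observable(peptides: Iterable[str], params: DigestParams = DigestParams()) -> int:
    """Number of distinct peptides observable under the instrument constraints.

    Raises DegenerateProteinError when no peptide is observable (such a
    protein cannot receive an emPAI and is excluded upstream with a warning).
    """
    unique = set(peptides)
    if not unique:
        raise InputError("empty peptide list")
    n = 0
    for pep in unique:
        if len(pep) < params.min_len:
            continue
        for z in range(params.z_min, params.z_max + 1):
            if params.min_mz <= peptide_mz(pep, z) <= params.max_mz:
                n += 1
                break
    if n == 0:
        raise DegenerateProteinError("no observable tryptic peptide")
    return n


def compute_empai(n_obsd: int, n_obsbl: int) -> float:
    """emPAI = 10^(n_obsd/n_obsbl) - 1."""
    if n_obsbl < 1:
        raise DegenerateProteinError("n_obsbl must be >= 1")
    if n_obsd < 0:
        raise InputError("n_obsd must be >= 0")
    return 10.0 ** (n_obsd / n_obsbl) - 1.0


def empai_table(
    proteome: Mapping[str, str],
    identifications: pd.DataFrame | None,
    params: DigestParams = DigestParams(),
    search_missed_cleavages: int = 2,
) -> pd.DataFrame:
    """Per-protein emPAI for the accessions of one identification table.

    ``identifications`` needs columns ``protein_accession`` and
    ``distinct_peptides``.  The observed count is clamped to the protein's
    total number of distinct tryptic peptides at ``search_missed_cleavages``
    missed sites (the search-engine setting), so coverage cannot exceed what
    the digest can produce.  Proteins absent from the proteome or without any
    observable peptide are excluded with a warning.
    """
    rows = []
    for rec in identifications.itertuples(index=False):
        acc = rec.protein_accession
        seq = proteome.get(acc)
        if seq is None:
            logger.warning("accession %s not in proteome FASTA; excluded from emPAI", acc)
            continue
        try:
            n_obsbl = count_observable(digest(seq, params.missed_cleavages), params)
        except DegenerateProteinError:
            logger.warning("protein %s has no observable peptide; excluded from emPAI", acc)
            continue
        ceiling = len(set(digest(seq, search_missed_cleavages)))
        n_obsd = int(rec.distinct_peptides)
        if n_obsd > ceiling:
            logger.warning("%s: %d observed peptides exceeds digest ceiling %d; clamped",
                           acc, n_obsd, ceiling)
            n_obsd = ceiling
        rows.append((acc, n_obsd, n_obsbl, compute_empai(n_obsd, n_obsbl)))
    return pd.DataFrame(rows, columns=["protein_accession", "n_obsd", "n_obsbl", "empai"])


def rank_by_empai(
    records: pd.DataFrame,
    universe: Iterable[str],
    id_column: str = "protein_accession",
) -> dict[str, int]:
    """Abundance ranks from emPAI values over a fixed identifier universe.

    Rank 1 is the most abundant.  Ties in emPAI break by ascending identifier
    (deterministic).  Universe members absent from ``records`` all share the
    terminal rank ``m + 1`` where ``m`` identifiers were ranked; no artificial
    order is imposed among unobserved proteins.
    """
    universe = set(universe)
    if records[id_column].duplicated().any():
        raise InputError("duplicate identifiers in emPAI records")
    extra = set(records[id_column]) - universe
    if extra:
        raise InputError(f"records contain identifiers outside the universe: {sorted(extra)[:5]}")
    ordered = records.sort_values(["empai", id_column], ascending=[False, True])
    ranks = {ident: i + 1 for i, ident in enumerate(ordered[id_column])}
    terminal = len(ranks) + 1
    for ident in universe - ranks.keys():
        ranks[ident] = terminal
    return ranks


def gene_level_empai(
    empai_records: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Collapse protein-level emPAI to gene level via ortholog pairs.

    ``pairs`` needs columns ``rat_protein`` and ``human_gene``.  A gene mapped
    by several proteins takes the maximum emPAI among them (the strongest
    evidence for its abundance).
    """
    merged = empai_records.merge(
        pairs[["rat_protein", "human_gene"]],
        left_on="protein_accession", right_on="rat_protein", how="inner",
    )
    if merged.empty:
        return pd.DataFrame(columns=["gene_id", "empai"])
    out = (merged.groupby("human_gene", as_index=False)["empai"].max()
           .rename(columns={"human_gene": "gene_id"}))
    return out.sort_values("gene_id").reset_index(drop=True)
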