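"""Consensus ortholog mapping across several rat-protein -> human-gene tables.

Orthology databases disagree; a pair is trusted only when reported by at
least ``min_support`` distinct databases.  Pairs are kept many-to-many: one
rat protein may map to several human genes and vice versa.
"""
from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


def consensus_orthologs(maps: Mapping[str, pd.DataFrame], min_support: int = 2) -> pd.DataFrame:
    """Merge mapping tables, retaining pairs supported by >= min_support databases.

    ``maps`` is database-name -> DataFrame with columns ``rat_protein`` (or
    ``protein_accession``) and ``human_gene`` (or ``gene_id``).  Support counts
    distinct databases: a database repeating a pair is one vote.  Returns a
    DataFrame (rat_protein, human_gene, support, supporting_dbs) sorted by
    (rat_protein, human_gene); supporting_dbs is pipe-joined in sorted order.
    """
    if min_support < 1:
        raise InputError("min_support must be >= 1")
    if len(maps) < min_support:
        raise InputError(f"only {len(maps)} mapping tables but min_support={min_support}")
    frames = []
    for db in sorted(maps):
        df = maps[db].rename(columns={"protein_accession": "rat_protein", "gene_id": "human_gene"})
        if not {"rat_protein", "human_gene"} <= set(df.columns):
            raise InputError(f"mapping table {db!r} lacks rat_protein/human_gene columns")
        before = len(df)
        df = df[["rat_protein", "human_gene"]].drop_duplicates()
        if len(df) < before:
            logger.warning("database %s: %d duplicate rows deduplicated", db, before - len(df))
        frames.append(df.assign(db=db))
    allpairs = pd.concat(frames, ignore_index=True)
    grouped = (allpairs.groupby(["rat_protein", "human_gene"])["db"]
               .agg(["nunique", lambda s: "|".join(sorted(s))]))
    grouped.columns = ["support", "supporting_dbs"]
    out = grouped[grouped["support"] >= min_support].reset_index()
    return out.sort_values(["rat_protein", "human_gene"]).reset_index(drop=True)


def orthologs_to_gene_set(pairs: pd.DataFrame) -> set[str]:
    """Non-redundant human gene set of an ortholog pair table."""
    if pairs.empty:
        return set()
    return set(pairs["human_gene"])
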