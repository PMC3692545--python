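"""Candidate tier classification of kidney-expressed orthologs.

Kidney-origin genes (orthologs expressed in the kidney) are partitioned by
membership in the pooled normal urine+exosome proteome and the plasma
proteome:

* zero_background  — absent from normal urine+exosome: any detection under
  disease is signal.
* kidney_specific  — absent from plasma: not confounded by other organs.
* sensitive        — both at once.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .formats import ReferenceSet


@dataclass
class TierReport:
    """Per-gene membership flags plus the four-way Venn partition counts."""

    table: pd.DataFrame = field(repr=False)
    partition: dict[str, int] = field(default_factory=dict)

    @property
    def kidney_origin(self) -> set[str]:
        return set(self.table["gene_id"])

    @property
    def zero_background(self) -> set[str]:
        return set(self.table.loc[self.table["zero_background"], "gene_id"])

    @property
    def kidney_specific(self) -> set[str]:
        return set(self.table.loc[self.table["kidney_specific"], "gene_id"])

    @property
    def sensitive(self) -> set[str]:
        return set(self.table.loc[self.table["sensitive"], "gene_id"])

    def counts(self) -> dict[str, int]:
        return {
            "kidney_origin": len(self.table),
            "zero_background": int(self.table["zero_background"].sum()),
            "kidney_specific": int(self.table["kidney_specific"].sum()),
            "sensitive": int(self.table["sensitive"].sum()),
            **self.partition,
        }


def venn_partition(genes: Iterable[str], set_a: ReferenceSet, set_b: ReferenceSet) -> dict[str, int]:
    """Four-way membership partition of ``genes`` over two reference sets."""
    genes = set(genes)
    both = sum(1 for g in genes if g in set_a and g in set_b)
    a_only = sum(1 for g in genes if g in set_a and g not in set_b)
    b_only = sum(1 for g in genes if g not in set_a and g in set_b)
    return {
        "both": both,
        "urine_only": a_only,
        "plasma_only": b_only,
        "neither": len(genes) - both - a_only - b_only,
    }


def classify_tiers(
    orthologs: Iterable[str],
    kidney: ReferenceSet,
    urine_exo: ReferenceSet,
    plasma: ReferenceSet,
) -> TierReport:
    """Classify kidney-expressed orthologs into candidate tiers.

    kidney-origin = orthologs ∩ kidney; zero_background = kidney-origin not in
    urine_exo; kidney_specific = kidney-origin not in plasma; sensitive = both.
    """
    kidney_origin = sorted(set(orthologs) & kidney.genes)
    rows = []
    for g in kidney_origin:
        in_ue = g in urine_exo
        in_pl = g in plasma
        rows.append({
            "gene_id": g,
            "in_kidney": True,
            "in_urine_or_exosome": in_ue,
            "in_plasma": in_pl,
            "zero_background": not in_ue,
            "kidney_specific": not in_pl,
            "sensitive": not in_ue and not in_pl,
        })
    table = pd.DataFrame(rows, columns=[
        "gene_id", "in_kidney", "in_urine_or_exosome", "in_plasma",
        "zero_background", "kidney_specific", "sensitive",
    ])
    return TierReport(table, venn_partition(kidney_origin, urine_exo, plasma))


def pool_candidates(
    report: TierReport,
    hypoxia_increased: Iterable[str],
    rank_shifted: Iterable[str],
) -> pd.DataFrame:
    """Pool kidney-origin genes with hypoxia-increased genes into the candidate list.

    Every candidate row carries its qualifying reasons (pipe-joined) and a
    ``high_quality`` flag: zero-background, kidney-specific, hypoxia-increased
    or rank-shifted.
    """
    hypoxia = set(hypoxia_increased)
    shifted = set(rank_shifted)
    pool = report.kidney_origin | hypoxia
    zb, ks = report.zero_background, report.kidney_specific
    rows = []
    for g in sorted(pool):
        reasons = []
        if g in report.kidney_origin:
            reasons.append("kidney_origin")
        if g in zb:
            reasons.append("zero_background")
        if g in ks:
            reasons.append("kidney_specific")
        if g in hypoxia:
            reasons.append("hypoxia_increased")
        if g in shifted:
            reasons.append("rank_shifted")
        hq = bool({"zero_background", "kidney_specific", "hypoxia_increased", "rank_shifted"}
                  & set(reasons))
        rows.append({"gene_id": g, "reasons": "|".join(reasons), "high_quality": hq})
    return pd.DataFrame(rows, columns=["gene_id", "reasons", "high_quality"])


@dataclass
class OverlapReport:
    overlap: list[str]
    novel: list[str]

    def counts(self) -> dict[str, int]:
        return {"overlap": len(self.overlap), "novel": len(self.novel)}


def biomarker_overlap(candidates: Iterable[str], prior: ReferenceSet) -> OverlapReport:
    """Split candidates into those already studied as biomarkers and novel ones."""
    candidates = set(candidates)
    return OverlapReport(
        overlap=sorted(candidates & prior.genes),
        novel=sorted(candidates - prior.genes),
    )
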