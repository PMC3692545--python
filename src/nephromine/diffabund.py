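"""Differential abundance between perfusion with and without oxygen.

Each rat supplies one urine sample per condition.  Spectral counts are
normalized so every sample has the same total (the mean of the raw totals),
then each protein gets a Welch two-sample, two-sided t-test of no-oxygen vs
oxygen.  A protein is called significant when p < alpha AND its normalized
count is higher without oxygen in every rat — the all-samples direction rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

CONDITIONS = ("oxygen", "no_oxygen")


@dataclass
class ConditionMatrix:
    """Protein x sample spectral counts with per-sample condition and rat labels.

    ``counts`` is indexed by protein accession with one column per sample;
    ``samples`` has one row per column of ``counts`` with columns
    ``sample_id``, ``condition`` (oxygen / no_oxygen) and ``rat``.
    """

    counts: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        s = self.samples
        if not {"sample_id", "condition", "rat"} <= set(s.columns):
            raise InputError("samples needs sample_id, condition and rat columns")
        if list(self.counts.columns) != list(s["sample_id"]):
            raise InputError("counts columns must match samples.sample_id in order")
        bad = set(s["condition"]) - set(CONDITIONS)
        if bad:
            raise InputError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        per_rat = s.groupby("rat")["condition"].agg(lambda c: sorted(c))
        for rat, conds in per_rat.items():
            if conds != sorted(CONDITIONS):
                raise InputError(f"rat {rat!r} must contribute exactly one sample per condition")

    @property
    def rats(self) -> list[str]:
        return sorted(self.samples["rat"].unique())

    def columns_for(self, condition: str) -> list[str]:
        return list(self.samples.loc[self.samples["condition"] == condition, "sample_id"])


def build_condition_matrix(tables: dict[str, pd.DataFrame], manifest: pd.DataFrame) -> ConditionMatrix:
    """Assemble a ConditionMatrix from identification tables and a sample manifest.

    ``manifest`` has columns sample_id, condition, rat; ``tables`` maps
    sample_id to a DataFrame with protein_accession and spectral_count.
    Proteins absent from a sample get count 0.
    """
    missing = set(manifest["sample_id"]) - set(tables)
    if missing:
        raise InputError(f"manifest samples without tables: {sorted(missing)}")
    cols = {}
    for sid in manifest["sample_id"]:
        df = tables[sid]
        cols[sid] = df.set_index("protein_accession")["spectral_count"]
    counts = pd.DataFrame(cols).fillna(0.0).sort_index()
    counts = counts[list(manifest["sample_id"])]
    return ConditionMatrix(counts, manifest.reset_index(drop=True))


def normalize_counts(matrix: ConditionMatrix) -> ConditionMatrix:
    """Scale each sample so its total count equals the mean of all sample totals."""
    totals = matrix.counts.sum(axis=0)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0].tolist()
        raise InputError(f"samples with zero total counts: {zero}")
    scaled = matrix.counts * (totals.mean() / totals)
    return ConditionMatrix(scaled, matrix.samples)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0  # no within-group variability: the test is uninformative
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def differential_test(matrix: ConditionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test + all-rats direction rule per protein.

    Returns one row per protein: condition means of the (already normalized)
    counts, fold change (no-oxygen over oxygen), two-sided p-value,
    ``increased_in_all`` (no-oxygen > oxygen within every rat) and
    ``significant`` (p < alpha and increased_in_all).
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if len(matrix.rats) < 2:
        raise InputError("need at least two rats for a t-test")
    oxy_cols = matrix.columns_for("oxygen")
    noo_cols = matrix.columns_for("no_oxygen")
    sample_rat = matrix.samples.set_index("sample_id")["rat"]
    pairs = [(
        noo, next(o for o in oxy_cols if sample_rat[o] == sample_rat[noo]),
    ) for noo in noo_cols]

    oxy = matrix.counts[oxy_cols].to_numpy(float)
    noo = matrix.counts[noo_cols].to_numpy(float)
    rows = []
    for i, acc in enumerate(matrix.counts.index):
        mean_oxy, mean_noo = oxy[i].mean(), noo[i].mean()
        p = _welch_p(noo[i], oxy[i])
        increased = all(
            matrix.counts.at[acc, n] > matrix.counts.at[acc, o] for n, o in pairs
        )
        fold = mean_noo / mean_oxy if mean_oxy > 0 else np.inf if mean_noo > 0 else np.nan
        rows.append({
            "protein_accession": acc,
            "mean_oxygen": mean_oxy,
            "mean_no_oxygen": mean_noo,
            "fold_change": fold,
            "p_value": p,
            "increased_in_all": increased,
            "significant": bool(p < alpha and increased),
        })
    return pd.DataFrame(rows)


def map_diff_to_orthologs(significant: Iterable[str], pairs: pd.DataFrame) -> set[str]:
    """Consensus-mapped human genes of the significant rat proteins (non-redundant)."""
    significant = set(significant)
    hits = pairs[pairs["rat_protein"].isin(significant)]
    unmapped = significant - set(hits["rat_protein"])
    if unmapped:
        import logging
        logging.getLogger(__name__).warning(
            "%d significant proteins had no consensus ortholog", len(unmapped))
    return set(hits["human_gene"])
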