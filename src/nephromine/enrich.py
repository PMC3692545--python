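"""Hypergeometric over-representation analysis of gene sets.

Annotations are gene -> term pairs plus a term parent-edge table forming a
DAG; a gene annotated to a term is implicitly annotated to all of the term's
ancestors (true-path propagation).  Each term carrying at least one study
gene gets an exact upper-tail hypergeometric p-value; the family of tested
terms is Benjamini-Hochberg adjusted and thresholded on the adjusted value
(default alpha 0.001).
"""
from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


def propagate_annotations(annotations: pd.DataFrame, edges: pd.DataFrame) -> pd.DataFrame:
    """Extend gene->term annotations to all ancestor terms (idempotent).

    ``annotations``: columns gene_id, term_id.  ``edges``: columns child,
    parent.  Raises InputError if the parent graph has a cycle.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges[["child", "parent"]].itertuples(index=False, name=None))
    if not nx.is_directed_acyclic_graph(g):
        raise InputError("term parent graph contains a cycle")
    ancestors = {t: nx.descendants(g, t) for t in g.nodes}  # child->parent edges: reachable = ancestors
    rows = set()
    for gene, term in annotations[["gene_id", "term_id"]].itertuples(index=False, name=None):
        rows.add((gene, term))
        for anc in ancestors.get(term, ()):
            rows.add((gene, anc))
    out = pd.DataFrame(sorted(rows), columns=["gene_id", "term_id"])
    return out


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= K <= N and k <= n <= N):
        raise InputError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study: Iterable[str],
    universe: Iterable[str],
    annotations: pd.DataFrame,
    edges: pd.DataFrame | None = None,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Over-representation of annotation terms in ``study`` against ``universe``.

    Only terms annotating at least one study gene are tested and enter the BH
    family.  Annotations outside the universe are ignored.  Returns a
    DataFrame (term_id, k, n, K, N, p_value, q_value, significant) sorted by
    (q_value, p_value, term_id).
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    study, universe = set(study), set(universe)
    if not study <= universe:
        raise InputError(f"study genes outside the universe: {sorted(study - universe)[:5]}")
    ann = annotations[annotations["gene_id"].isin(universe)]
    if edges is not None and len(edges):
        ann = propagate_annotations(ann, edges)
    else:
        ann = ann.drop_duplicates(["gene_id", "term_id"])
    N, n = len(universe), len(study)
    per_term = ann.groupby("term_id")["gene_id"].agg(set)
    rows = []
    for term, genes in per_term.items():
        k = len(genes & study)
        if k == 0:
            continue
        K = len(genes)
        rows.append({"term_id": term, "k": k, "n": n, "K": K, "N": N,
                     "p_value": hypergeom_upper_tail(k, K, n, N)})
    result = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_value"])
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q_value"] = bh_adjust(result["p_value"])
    result["significant"] = result["q_value"] < alpha
    return result.sort_values(["q_value", "p_value", "term_id"]).reset_index(drop=True)
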