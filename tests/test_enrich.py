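"""Annotation propagation, the hypergeometric test and BH correction."""
import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nephromine.enrich import bh_adjust, enrich, hypergeom_upper_tail, propagate_annotations
from nephromine.errors import InputError


def ann_df(pairs):
    return pd.DataFrame(pairs, columns=["gene_id", "term_id"])


def edge_df(pairs):
    return pd.DataFrame(pairs, columns=["child", "parent"])


class TestPropagation:
    def test_chain_propagates_to_all_ancestors(self):
        out = propagate_annotations(ann_df([("g", "t1")]), edge_df([("t1", "t2"), ("t2", "t3")]))
        assert set(map(tuple, out.values)) == {("g", "t1"), ("g", "t2"), ("g", "t3")}

    def test_no_edges_is_identity(self):
        ann = ann_df([("g1", "t1"), ("g2", "t2")])
        out = propagate_annotations(ann, edge_df([]))
        assert set(map(tuple, out.values)) == set(map(tuple, ann.values))

    def test_idempotent(self):
        ann = ann_df([("g", "t1")])
        edges = edge_df([("t1", "t2")])
        once = propagate_annotations(ann, edges)
        twice = propagate_annotations(once, edges)
        pd.testing.assert_frame_equal(once, twice)

    def test_cycle_rejected(self):
        with pytest.raises(InputError, match="cycle"):
            propagate_annotations(ann_df([("g", "a")]), edge_df([("a", "b"), ("b", "a")]))

    def test_random_dag_matches_reachability_oracle(self, rng):
        terms = [f"t{i}" for i in range(30)]
        edges = [(terms[i], terms[j]) for i in range(30) for j in range(i + 1, 30)
                 if rng.random() < 0.1]
        ann = [(f"g{k}", terms[rng.integers(0, 30)]) for k in range(25)]
        out = set(map(tuple, propagate_annotations(ann_df(ann), edge_df(edges)).values))
        # oracle: exhaustive reachability on the edge list
        adj = {}
        for c, p in edges:
            adj.setdefault(c, set()).add(p)

        def reach(t):
            seen, todo = set(), [t]
            while todo:
                cur = todo.pop()
                for p in adj.get(cur, ()):
                    if p not in seen:
                        seen.add(p)
                        todo.append(p)
            return seen

        expect = {(g, t2) for g, t in ann for t2 in ({t} | reach(t))}
        assert out == expect


def enum_upper_tail(k, K, n, N):
    """Exhaustive enumeration of P(X >= k) over all draw counts."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


class TestHypergeom:
    def test_zero_successes_has_probability_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_combinatorial_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_enumeration_for_small_populations(self, rng):
        for _ in range(200):
            N = int(rng.integers(1, 21))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                enum_upper_tail(k, K, n, N), rel=1e-9, abs=1e-12)

    def test_non_increasing_in_k(self):
        vals = [hypergeom_upper_tail(k, 8, 6, 20) for k in range(0, 7)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(InputError):
            hypergeom_upper_tail(5, 4, 6, 10)


def bh_oracle(p):
    """Hand-applied step-up: q_(i) = min_{j>=i} p_(j) * m / j, in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = math.inf
    for idx in range(m - 1, -1, -1):
        running = min(running, p[order[idx]] * m / (idx + 1))
        q_sorted[idx] = min(running, 1.0)
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_values_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_is_monotone(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(bh_oracle(p), rel=1e-12, abs=1e-15)
        for i, j in itertools.combinations(range(len(p)), 2):
            if p[i] <= p[j]:
                assert q[i] <= q[j] + 1e-15

    def test_permutation_invariant_after_restoring_order(self, rng):
        p = list(rng.random(20))
        q = np.array(bh_adjust(p))
        perm = rng.permutation(20)
        q_perm = np.array(bh_adjust([p[i] for i in perm]))
        assert np.allclose(q[perm], q_perm)


class TestEnrich:
    def test_study_equal_to_universe_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        ann = ann_df([(g, "t1") for g in genes[:6]] + [(g, "t2") for g in genes])
        out = enrich(set(genes), set(genes), ann, None, alpha=0.05)
        assert (out["p_value"] == 1.0).all()

    def test_concentrated_rare_term_is_significant(self):
        universe = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(5)}
        ann = ann_df([(f"g{i}", "rare") for i in range(5)]
                     + [(g, "common") for g in universe])
        out = enrich(study, universe, ann, None, alpha=0.001).set_index("term_id")
        assert out.loc["rare", "p_value"] < 1e-3
        assert bool(out.loc["rare", "significant"])

    def test_study_outside_universe_rejected(self):
        with pytest.raises(InputError, match="outside"):
            enrich({"x"}, {"g1"}, ann_df([("g1", "t")]), None)

    def test_per_term_p_values_match_enumeration(self, rng):
        universe = [f"g{i}" for i in range(15)]
        ann = ann_df([(g, f"t{rng.integers(0, 4)}") for g in universe])
        study = set(rng.choice(universe, size=6, replace=False))
        out = enrich(study, set(universe), ann, None, alpha=0.05)
        per_term = ann.groupby("term_id")["gene_id"].agg(set)
        for row in out.itertuples():
            k = len(per_term[row.term_id] & study)
            assert row.p_value == pytest.approx(
                enum_upper_tail(k, len(per_term[row.term_id]), len(study), 15), rel=1e-9)

    def test_only_terms_with_study_genes_enter_the_family(self):
        universe = {"g1", "g2", "g3"}
        ann = ann_df([("g1", "a"), ("g2", "b"), ("g3", "c")])
        out = enrich({"g1"}, universe, ann, None, alpha=0.05)
        assert list(out["term_id"]) == ["a"]

    def test_uniform_study_draws_control_fdr(self, rng):
        """Stochastic: a random study set has no enriched terms, so any
        rejection is false; the mean false discovery proportion stays near 0."""
        universe = [f"g{i}" for i in range(60)]
        ann = ann_df([(g, f"t{rng.integers(0, 8)}") for g in universe])
        alpha = 0.05
        fdps = []
        for _ in range(60):
            study = set(rng.choice(universe, size=12, replace=False))
            out = enrich(study, set(universe), ann, None, alpha=alpha)
            n_rej = int(out["significant"].sum())
            fdps.append(1.0 if n_rej else 0.0)  # all rejections are false here
        assert np.mean(fdps) <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / len(fdps))
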