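"""Abundance rank-shift detection between normal urine and perfusion-driven urine.

A gene whose abundance rank rises sharply from normal urine to perfusion
samples is a candidate kidney-origin marker.  Rank change is
``reference_rank - perfusion_rank`` (positive = moved toward the top of the
abundance list).  The significance threshold is either fixed (300 in the
original calibration) or calibrated so that a stated fraction of
between-replicate rank changes falls strictly below it.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .formats import ReferenceSet
from .tiers import venn_partition

DEFAULT_THRESHOLD = 300
DEFAULT_COVERAGE = 0.94


def calibrate_threshold(replicate_changes: Sequence[int], coverage: float = DEFAULT_COVERAGE) -> int:
    """Smallest positive integer T with fraction(|changes| < T) >= coverage.

    ``replicate_changes`` are rank changes between replicate samples of the
    same condition; their magnitude reflects pure measurement noise, so a
    shift exceeding essentially all of them is meaningful.
    """
    changes = np.abs(np.asarray(list(replicate_changes)))
    if changes.size == 0:
        raise InputError("empty replicate change list")
    if not 0 < coverage <= 1:
        raise InputError("coverage must be in (0, 1]")
    # fraction strictly below T jumps only at T = c+1 for observed values c
    for t in sorted({1} | {int(c) + 1 for c in changes}):
        if np.mean(changes < t) >= coverage:
            return t
    raise AssertionError("unreachable: coverage <= 1 is always met at max+1")


def rank_shift(
    reference_ranks: Mapping[str, int],
    perfusion_ranks: Mapping[str, Mapping[str, int]],
    threshold: int = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene rank changes and significance flags.

    ``perfusion_ranks`` maps sample-id -> gene -> rank.  All rank assignments
    must cover the same gene universe.  A gene is significant when its rank
    change is >= threshold in every perfusion sample.  Output is sorted by the
    minimum rank change, descending (most consistently shifted first).
    """
    if threshold < 1:
        raise InputError("threshold must be >= 1")
    if not perfusion_ranks:
        raise InputError("need at least one perfusion rank assignment")
    universe = set(reference_ranks)
    for sid, ranks in perfusion_ranks.items():
        if set(ranks) != universe:
            raise InputError(f"rank universe of sample {sid!r} differs from reference")
    sample_ids = sorted(perfusion_ranks)
    rows = []
    for g in sorted(universe):
        changes = {sid: reference_ranks[g] - perfusion_ranks[sid][g] for sid in sample_ids}
        min_change = min(changes.values())
        rows.append({
            "gene_id": g,
            "rank_reference": reference_ranks[g],
            **{f"rank_{sid}": perfusion_ranks[sid][g] for sid in sample_ids},
            **{f"change_{sid}": changes[sid] for sid in sample_ids},
            "min_change": min_change,
            "significant": min_change >= threshold,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["min_change", "gene_id"], ascending=[False, True]).reset_index(drop=True)


def significant_genes(shift_table: pd.DataFrame) -> set[str]:
    return set(shift_table.loc[shift_table["significant"], "gene_id"])


def tier_annotate_shifted(
    shifted: Iterable[str],
    urine_exo: ReferenceSet,
    plasma: ReferenceSet,
) -> dict[str, int]:
    """Four-way urine/plasma membership partition of the rank-shifted gene set."""
    return venn_partition(shifted, urine_exo, plasma)
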