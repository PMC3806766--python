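"""Rank-based per-sample module activity scores.

For each tumor, all G analyzed genes are ranked by expression (ascending,
average ranks for ties).  A gene set's activity in that tumor is the
standardized mean rank of its m members against the random-set null:

    activity = (mean member rank - (G+1)/2) / sqrt((G+1)(G-m) / (12 m))

so random sets score ~ N(0, 1) and the statistic is invariant under any
strictly monotone transform of the sample's expression values.  Group
comparisons use the Wilcoxon rank-sum test with BH correction across sets.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection, OmicsMatrix
from .stats import wilcoxon_rank_sum

__all__ = ["activity_scores", "compare_activity"]

log = logging.getLogger(__name__)


def activity_scores(expr: OmicsMatrix, sets: GeneSetCollection) -> pd.DataFrame:
    """Sample x set matrix of standardized mean-rank activity scores.

    Sets are intersected with the analyzed gene universe first; sets with
    fewer than 2 members present, or equal to the whole universe (null
    variance zero), are skipped with a warning and get no column.
    """
    genes = expr.genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    ranks = sps.rankdata(expr.values, axis=0)  # rank genes within each sample

    columns: dict[str, np.ndarray] = {}
    for name, members in sets:
        idx = [gene_pos[g] for g in members if g in gene_pos]
        m = len(idx)
        if m < 2:
            log.warning("activity_scores: set %r has <2 members present, skipped", name)
            continue
        if m >= G:
            log.warning(
                "activity_scores: set %r equals the gene universe, skipped", name
            )
            continue
        mean_rank = ranks[idx].mean(axis=0)
        null_sd = math.sqrt((G + 1) * (G - m) / (12.0 * m))
        columns[name] = (mean_rank - (G + 1) / 2.0) / null_sd
    return pd.DataFrame(columns, index=pd.Index(expr.samples, name="sample_id"))


def compare_activity(
    scores: pd.DataFrame,
    groups: tuple[Sequence[str], Sequence[str]],
) -> pd.DataFrame:
    """Per-set Wilcoxon rank-sum comparison of activity between two groups.

    Returns a frame indexed by set name with columns ``statistic``, ``p``
    and BH-adjusted ``q``.  Groups smaller than 3 yield NA p-values with a
    warning (the normal approximation is meaningless there).
    """
    group_a, group_b = [list(g) for g in groups]
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    rows = []
    for name in scores.columns:
        a = scores.loc[group_a, name].to_numpy(dtype=float)
        b = scores.loc[group_b, name].to_numpy(dtype=float)
        if min(a.size, b.size) < 3:
            log.warning("compare_activity: group of size <3 for %r, p=NA", name)
            rows.append((name, math.nan, math.nan))
            continue
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append((name, stat, p))
    out = pd.DataFrame(rows, columns=["set", "statistic", "p"]).set_index("set")
    ok = out["p"].notna()
    q = np.full(len(out), math.nan)
    if ok.any():
        q[ok.to_numpy()] = sps.false_discovery_control(
            out.loc[ok, "p"].to_numpy(), method="bh"
        )
    out["q"] = q
    return out
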