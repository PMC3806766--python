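"""Group-level statistics downstream of driver discovery.

Tumors are split into driver-high and driver-low groups at a driver's split
value (the root threshold of its top-scoring module), and the groups are
compared with the study's statistical toolkit: Fisher's exact association
with categorical labels, Wilcoxon rank-sum comparisons, a module-gene
correlation validation test, hypergeometric gene-set enrichment with BH
correction, and a Kaplan-Meier / log-rank comparison of distant
metastasis-free survival (DMFS).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ClinicalTable, GeneSetCollection, OmicsMatrix

__all__ = [
    "split_by_driver",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "module_correlation_test",
    "gene_set_enrichment",
    "km_logrank",
    "KMResult",
]

log = logging.getLogger(__name__)


def split_by_driver(
    expr: OmicsMatrix,
    driver,
    modules: Sequence,
) -> tuple[list[str], list[str], float]:
    """Partition samples at the driver's split value.

    Uses the root split value of the driver's top-scoring module.  Samples
    with driver expression strictly above the split go high; expression
    exactly at the split goes low (documented boundary rule).  Samples not
    seen in training are assigned by the same rule, so the split transfers
    to new cohort members.  Returns (high samples, low samples, split).
    """
    by_id = {m.module_id: m for m in modules}
    top = None
    for mid in driver.modules:
        m = by_id.get(mid)
        if m is not None and m.program is not None:
            top = m
            break
    if top is None:
        raise ValueError(f"driver {driver.gene_id!r} regulates no module with a program")
    split = float(top.program.split)
    values = expr.row(driver.gene_id)  # KeyError -> hard error per contract
    high = [s for s, v in zip(expr.samples, values) if v > split]
    low = [s for s, v in zip(expr.samples, values) if v <= split]
    if not high or not low:
        warnings.warn(
            f"split_by_driver: one group is empty at split {split:g}; "
            "downstream tests will report NA",
            stacklevel=2,
        )
    return high, low, split


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Two-sidedness by probability ordering: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.  A zero margin
    gives p = 1 by convention (with a warning).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("fisher_exact_2x2: zero margin, p = 1 by convention", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum test (normal approximation, ties + continuity).

    Returns ``(W, p)`` where W is the rank-sum of ``x`` in the pooled
    ranking (average ranks for ties); the two-sided p uses the
    tie-corrected normal approximation with continuity correction.  If all
    pooled values are identical, p = 1 and W sits at its null mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return (w, 1.0)
    u1 = w - n1 * (n1 + 1) / 2.0
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    assert math.isclose(float(res.statistic), u1, rel_tol=0, abs_tol=1e-9)
    return (w, float(res.pvalue))


def module_correlation_test(
    expr: OmicsMatrix,
    driver_gene: str,
    module_genes: Sequence[str],
) -> tuple[float, float, float]:
    """Are module genes more correlated with their driver than the rest?

    Computes |Pearson r| between every analyzed gene and the driver's
    expression, then compares in-module vs background |r| with the Wilcoxon
    rank-sum test.  The background is every analyzed gene outside the
    module, excluding the driver itself; the module must not reduce to the
    driver alone.  Returns (two-sided p, median |r| in module, median |r|
    background).
    """
    module = [g for g in module_genes if g != driver_gene]
    if not module:
        raise ValueError("module must contain genes other than the driver")
    module_set = set(module)
    background = [g for g in expr.genes if g not in module_set and g != driver_gene]
    if not background:
        raise ValueError("background gene set is empty")
    d = expr.row(driver_gene)
    d_c = d - d.mean()
    denom_d = math.sqrt(float((d_c * d_c).sum()))

    def abs_r(gene_ids: Sequence[str]) -> np.ndarray:
        rows = expr.values[expr.gene_positions(gene_ids)]
        rows_c = rows - rows.mean(axis=1, keepdims=True)
        num = rows_c @ d_c
        den = np.sqrt((rows_c * rows_c).sum(axis=1)) * denom_d
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        return np.abs(r)

    r_mod = abs_r(module)
    r_bg = abs_r(background)
    _, p = wilcoxon_rank_sum(r_mod, r_bg)
    return (p, float(np.median(r_mod)), float(np.median(r_bg)))


def gene_set_enrichment(
    module_genes: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a module in each gene set.

    Sets are intersected with the universe; the module must be a subset of
    the universe.  Returns a frame indexed by set name with columns
    ``overlap``, ``set_size``, ``p`` and BH-adjusted ``q``.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    module = set(module_genes)
    if not module <= universe_set:
        raise ValueError("module genes must be a subset of the universe")
    N, n = len(universe_set), len(module)
    rows = []
    for name, members in sets:
        inset = set(members) & universe_set
        K = len(inset)
        k = len(inset & module)
        # P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives p = 1
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]).set_index(
        "set"
    )
    if len(out):
        out["q"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    else:
        out["q"] = []
    return out


@dataclass
class KMResult:
    """Kaplan-Meier curves per group plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival
    at_risk: pd.DataFrame  # groups x requested time points
    statistic: float
    p: float  # NaN when no events


def km_logrank(
    clinical: ClinicalTable,
    groups: dict[str, Sequence[str]],
    at_risk_times: Sequence[float] = (0, 50, 100, 150),
) -> KMResult:
    """Kaplan-Meier estimation and log-rank test between two sample groups.

    Returns the product-limit curve and numbers-at-risk per group plus the
    1-df log-rank chi-square and two-sided p.  With zero events overall the
    KM estimate is 1 everywhere and p is NA (warned).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if len(groups) != 2:
        raise ValueError("km_logrank expects exactly two groups")
    names = list(groups)
    if any(len(groups[g]) == 0 for g in names):
        raise ValueError("both groups must be non-empty")

    times, events, curves, at_risk_rows = {}, {}, {}, []
    for name in names:
        t, e = clinical.times_events(groups[name])
        times[name], events[name] = t, e
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=name)
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[name].to_numpy()}
        )
        at_risk_rows.append(
            [int(np.sum(t >= tau)) for tau in at_risk_times]
        )
    at_risk = pd.DataFrame(
        at_risk_rows, index=names, columns=[f"t={tau:g}" for tau in at_risk_times]
    )

    total_events = int(events[names[0]].sum() + events[names[1]].sum())
    if total_events == 0:
        warnings.warn("km_logrank: zero events overall, p = NA", stacklevel=2)
        return KMResult(curves, at_risk, 0.0, math.nan)
    res = logrank_test(
        times[names[0]], times[names[1]], events[names[0]], events[names[1]]
    )
    return KMResult(
        curves, at_risk, float(res.test_statistic), float(res.p_value)
    )
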