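"""Normal-Gamma Bayesian scoring of regulatory programs.

A regulatory program is a shallow regression tree over a modulator gene's
expression: the root split value partitions tumors into low/high groups, and
each branch may be split once more by a second modulator (depth <= 2).  Module
genes are scored at the tree leaves with the marginal likelihood of a Normal
model under a conjugate Normal-Gamma prior on (mean, precision):

    p(x) = int int prod_i N(x_i | mu, 1/tau) dNG(mu, tau | mu0, kappa0, alpha0, beta0)

which has the closed form implemented in :func:`leaf_log_marginal`.  Splits
are penalized by a Bayes-factor multiplicity correction equal to the log of
the number of (modulator, split-point) candidates evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .io import OmicsMatrix

__all__ = [
    "NGHyperParams",
    "ScoringConfig",
    "RegulatoryProgram",
    "leaf_log_marginal",
    "program_leaves",
    "program_score",
    "best_split",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class NGHyperParams:
    """Hyperparameters of the Normal-Gamma prior on a leaf's (mean, precision).

    Defaults (0, 1, 1, 1) are weakly informative and scale-free on
    median-centered log2 expression.
    """

    mu0: float = 0.0
    kappa0: float = 1.0
    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kappa0 > 0 and self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("kappa0, alpha0, beta0 must all be positive")


#: A second-level split on one branch: (modulator gene_id, split value).
ChildSplit = tuple[str, float]


@dataclass(frozen=True)
class RegulatoryProgram:
    """A depth-<=2 regression tree over modulator expression.

    ``children[0]`` refines the low branch (modulator <= split),
    ``children[1]`` the high branch; each is ``None`` or a
    (modulator, split value) pair.  Sample partitions are derived against a
    modulator matrix via :func:`program_leaves`.
    """

    modulator: str
    split: float
    children: tuple[Optional[ChildSplit], Optional[ChildSplit]] = (None, None)

    def __post_init__(self) -> None:
        if not math.isfinite(self.split):
            raise ValueError("split value must be finite")
        for child in self.children:
            if child is not None and not math.isfinite(child[1]):
                raise ValueError("child split value must be finite")

    @property
    def n_internal(self) -> int:
        return 1 + sum(c is not None for c in self.children)

    @property
    def modulators(self) -> tuple[str, ...]:
        mods = [self.modulator]
        mods.extend(c[0] for c in self.children if c is not None)
        return tuple(mods)


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring knobs: prior, leaf-size floor, tree depth, structure penalty.

    ``structure_penalty_per_split=None`` means "log of the number of
    (modulator, split-point) candidates evaluated", computed by each search
    routine from its own candidate space.
    """

    hyper: NGHyperParams = field(default_factory=NGHyperParams)
    min_leaf_size: int = 5
    max_depth: int = 2
    structure_penalty_per_split: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_leaf_size < 2:
            raise ValueError("min_leaf_size must be >= 2")
        if self.max_depth not in (1, 2):
            raise ValueError("max_depth must be 1 or 2")

    def resolve_penalty(self, n_candidates: int) -> float:
        if self.structure_penalty_per_split is not None:
            return self.structure_penalty_per_split
        return math.log(max(n_candidates, 1))


# ---------------------------------------------------------------------------
# leaf marginal likelihood


def leaf_log_marginal(x: Sequence[float] | np.ndarray, hyper: NGHyperParams) -> float:
    """Log marginal likelihood of values ``x`` under the Normal-Gamma prior.

    Empty input returns 0 (log of an empty product).  Non-finite values are a
    hard error; missing values must be dropped upstream.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    if not np.all(np.isfinite(x)):
        raise ValueError("leaf_log_marginal requires finite input values")
    n = x.size
    s = float(x.sum())
    ss = float((x * x).sum())
    return float(_logml_from_stats(np.array(n), np.array(s), np.array(ss), hyper))


def _logml_from_stats(
    n: np.ndarray, s: np.ndarray, ss: np.ndarray, hyper: NGHyperParams
) -> np.ndarray:
    """Vectorized leaf log-marginal from sufficient statistics (n, sum, sum-sq).

    All arrays broadcast; entries with n == 0 return 0.
    """
    mu0, k0, a0, b0 = hyper.mu0, hyper.kappa0, hyper.alpha0, hyper.beta0
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xbar = np.where(n > 0, s / np.maximum(n, 1), 0.0)
        sxx = np.maximum(ss - n * xbar * xbar, 0.0)
        kn = k0 + n
        an = a0 + 0.5 * n
        bn = b0 + 0.5 * sxx + k0 * n * (xbar - mu0) ** 2 / (2.0 * kn)
        out = (
            -0.5 * n * math.log(2.0 * math.pi)
            + 0.5 * (np.log(k0) - np.log(kn))
            + gammaln(an)
            - gammaln(a0)
            + a0 * math.log(b0)
            - an * np.log(bn)
        )
    return np.where(n > 0, out, 0.0)


# ---------------------------------------------------------------------------
# programs


def program_leaves(
    program: RegulatoryProgram,
    modulators: OmicsMatrix,
    min_leaf_size: int | None = None,
) -> list[np.ndarray]:
    """Sample-index partition induced by a program (low leaves first).

    ``modulators`` must contain every modulator gene of the program.  If
    ``min_leaf_size`` is given, leaves below it raise ``ValueError``
    (programs are validated at construction time by the searchers).
    """
    root = modulators.row(program.modulator)
    if not np.all(np.isfinite(root)):
        raise ValueError(f"modulator {program.modulator!r} has non-finite values")
    low = np.flatnonzero(root <= program.split)
    high = np.flatnonzero(root > program.split)
    leaves: list[np.ndarray] = []
    for branch_idx, child in zip((low, high), program.children):
        if child is None:
            leaves.append(branch_idx)
        else:
            mod, split = child
            vals = modulators.row(mod)[branch_idx]
            leaves.append(branch_idx[vals <= split])
            leaves.append(branch_idx[vals > split])
    if min_leaf_size is not None:
        for leaf in leaves:
            if leaf.size < min_leaf_size:
                raise ValueError(
                    f"program leaf of size {leaf.size} below min_leaf_size "
                    f"{min_leaf_size}"
                )
    return leaves


def program_score(
    module_expr: OmicsMatrix,
    program: Optional[RegulatoryProgram],
    cfg: ScoringConfig,
    modulators: Optional[OmicsMatrix] = None,
    penalty_per_split: Optional[float] = None,
) -> float:
    """Penalized Bayesian score of a module under a program.

    Sum over module genes and tree leaves of the leaf log-marginal, minus
    ``penalty_per_split`` per internal node.  ``program=None`` scores the
    unsplit (single-leaf) model with no penalty.  ``modulators`` supplies the
    modulator expression rows (defaults to ``module_expr``).
    """
    values = module_expr.values
    if not np.all(np.isfinite(values)):
        raise ValueError("program_score requires finite module expression")
    hyper = cfg.hyper
    if program is None:
        return float(
            _logml_from_stats(
                np.full(values.shape[0], values.shape[1]),
                values.sum(axis=1),
                (values * values).sum(axis=1),
                hyper,
            ).sum()
        )
    mods = modulators if modulators is not None else module_expr
    leaves = program_leaves(program, mods, min_leaf_size=cfg.min_leaf_size)
    total = 0.0
    for leaf in leaves:
        sub = values[:, leaf]
        total += float(
            _logml_from_stats(
                np.full(sub.shape[0], sub.shape[1]),
                sub.sum(axis=1),
                (sub * sub).sum(axis=1),
                hyper,
            ).sum()
        )
    if penalty_per_split is None:
        penalty_per_split = cfg.resolve_penalty(values.shape[1])
    return total - penalty_per_split * program.n_internal


# ---------------------------------------------------------------------------
# split search


class SplitScan(NamedTuple):
    """Depth-1 scan of one modulator against a block of gene rows.

    ``two_leaf``: (n_genes, n_cuts) summed left+right leaf log-marginals;
    ``no_split``: (n_genes,) single-leaf log-marginals;
    ``midpoints``: candidate split values (midpoints of consecutive distinct
    sorted modulator values with both leaves >= min_leaf_size);
    ``left_sizes``: samples on the low side of each cut;
    ``order``: the modulator sort order used.
    """

    two_leaf: np.ndarray
    no_split: np.ndarray
    midpoints: np.ndarray
    left_sizes: np.ndarray
    order: np.ndarray


def depth1_scan(
    modulator: np.ndarray,
    values: np.ndarray,
    hyper: NGHyperParams,
    min_leaf_size: int,
) -> SplitScan:
    """Evaluate every admissible depth-1 split of ``modulator`` for all rows
    of ``values`` at once.

    The heavy lifting of both the Single-Modulator stage and program refits:
    prefix sums over the modulator-sorted sample order give the sufficient
    statistics of every (gene, cut) leaf pair in O(genes x samples).
    """
    modulator = np.asarray(modulator, dtype=float)
    n = modulator.size
    order = np.argsort(modulator, kind="stable")
    ms = modulator[order]
    k = np.arange(min_leaf_size, n - min_leaf_size + 1)
    if k.size:
        distinct = ms[k] > ms[k - 1]
        k = k[distinct]
    X = values[:, order]
    c1 = np.cumsum(X, axis=1)
    c2 = np.cumsum(X * X, axis=1)
    tot1 = c1[:, -1] if n else np.zeros(values.shape[0])
    tot2 = c2[:, -1] if n else np.zeros(values.shape[0])
    no_split = _logml_from_stats(np.full(values.shape[0], n), tot1, tot2, hyper)
    if k.size == 0:
        empty = np.empty((values.shape[0], 0))
        return SplitScan(empty, no_split, np.empty(0), k, order)
    left = _logml_from_stats(k[None, :], c1[:, k - 1], c2[:, k - 1], hyper)
    right = _logml_from_stats(
        (n - k)[None, :], tot1[:, None] - c1[:, k - 1], tot2[:, None] - c2[:, k - 1], hyper
    )
    midpoints = 0.5 * (ms[k - 1] + ms[k])
    return SplitScan(left + right, no_split, midpoints, k, order)


def best_split(
    modulator_expr: np.ndarray,
    module_expr: OmicsMatrix | np.ndarray,
    cfg: ScoringConfig,
    candidate_multiplicity: int = 1,
) -> tuple[float, float]:
    """Best depth-1 split of a modulator for a gene module.

    Returns ``(split value, gain)`` where gain is the penalized split score
    minus the no-split score; the penalty is the log of the number of
    candidates evaluated here times ``candidate_multiplicity`` (for callers
    searching several modulators).  With no admissible candidate returns
    ``(nan, -inf)`` and the caller keeps the unsplit program.
    """
    values = (
        module_expr.values if isinstance(module_expr, OmicsMatrix) else np.asarray(module_expr)
    )
    if values.ndim == 1:
        values = values[None, :]
    modulator_expr = np.asarray(modulator_expr, dtype=float)
    if modulator_expr.size < 2 * cfg.min_leaf_size:
        return (math.nan, NEG_INF)
    scan = depth1_scan(modulator_expr, values, cfg.hyper, cfg.min_leaf_size)
    if scan.midpoints.size == 0:
        return (math.nan, NEG_INF)
    totals = scan.two_leaf.sum(axis=0)
    best = int(np.argmax(totals))
    penalty = cfg.resolve_penalty(scan.midpoints.size * candidate_multiplicity)
    gain = float(totals[best] - penalty - scan.no_split.sum())
    return (float(scan.midpoints[best]), gain)
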