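"""Driver learning: candidate selection, Single Modulator, Module Network.

The three learning steps mirror the integrative copy-number/expression
driver-discovery scheme:

1. candidate drivers are the genes inside significantly recurrent aberrant
   regions (capped per region by the correlation between a gene's copy
   number and its own expression);
2. a Single Modulator step associates every other gene with the one
   candidate whose depth-1 expression split best explains it, under
   non-parametric bootstrap stability selection (candidates kept when
   selected in at least 90% of resampled runs by default);
3. the surviving modules (split by correlation sign, plus K-means seeds for
   unassigned genes) are refined by an iterative module-network step that
   alternates program refits and gene re-assignments, each accepted only on
   strict improvement so the total Bayesian score is monotone
   non-decreasing; a second bootstrap keeps drivers selected in at least
   40% of runs.

Drivers are finally ranked by their CONEXIC score: the summed score gains of
the modules whose regulatory program they root.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .aberrations import AberrantRegion
from .io import GenomicGene, OmicsMatrix, annotation_index
from .ng import (
    NEG_INF,
    RegulatoryProgram,
    ScoringConfig,
    _logml_from_stats,
    depth1_scan,
)

__all__ = [
    "CandidateDriver",
    "Module",
    "DriverResult",
    "LearningConfig",
    "select_candidates",
    "single_modulator",
    "sign_split",
    "bootstrap_select",
    "kmeans_seed",
    "learn_network",
    "conexic_scores",
    "run_driver_discovery",
    "DiscoveryResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateDriver:
    """A gene from a significant aberrant region, eligible as a driver."""

    gene_id: str
    direction: str  # "amplified" | "deleted"
    region: AberrantRegion
    cn_expr_correlation: float


@dataclass
class Module:
    """A gene module: members, the driver rooting its program, its sign.

    ``gain`` is the penalized program score minus the unsplit score of the
    module (the quantity summed into its driver's CONEXIC score).
    """

    module_id: str
    genes: tuple[str, ...]
    driver: Optional[str]
    sign: str  # positive | negative | mixed | none
    program: Optional[RegulatoryProgram] = None
    gain: float = 0.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.module_id!r} has no members")


@dataclass(frozen=True)
class DriverResult:
    """One row of the ranked driver table."""

    gene_id: str
    direction: str
    cytoband: str
    conexic_score: float
    bootstrap_frequency: float
    modules: tuple[str, ...]


@dataclass(frozen=True)
class LearningConfig:
    """Knobs of the three learning steps.

    The bootstrap defaults are the published protocol: 100 resampled runs,
    keep thresholds 0.90 (Single Modulator) and 0.40 (Module Network).
    Bootstrap replicates of the network stage run depth-1 programs with a
    small iteration cap — they only assess root-driver stability; full-depth
    refinement happens on the final full-data run.
    """

    bootstrap_runs: int = 100
    single_modulator_keep: float = 0.90
    network_keep: float = 0.40
    min_module_size: int = 5
    candidates_per_region_cap: int = 20
    kmeans_k: Optional[int] = None  # None = auto from the unassigned pool size
    kmeans_restarts: int = 20
    kmeans_stability_jaccard: float = 0.6
    max_iterations: int = 50
    tolerance: float = 1e-6
    seed: int = 0
    bootstrap_max_depth: int = 1
    bootstrap_max_iterations: int = 4

    def __post_init__(self) -> None:
        if self.bootstrap_runs < 1:
            raise ValueError("bootstrap_runs must be >= 1")
        for name in ("single_modulator_keep", "network_keep"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


# ---------------------------------------------------------------------------
# step 1: candidate selection


def select_candidates(
    regions: Sequence[AberrantRegion],
    expr: OmicsMatrix,
    cn: OmicsMatrix,
    cfg: LearningConfig = LearningConfig(),
) -> list[CandidateDriver]:
    """Candidate drivers from aberrant regions.

    Every region member present in the expression matrix becomes a
    candidate; regions larger than ``candidates_per_region_cap`` are trimmed
    to the members with the largest |Spearman correlation| between their own
    copy number and expression.  A gene significant in several regions is
    kept once (first region wins).
    """
    candidates: list[CandidateDriver] = []
    seen: set[str] = set()
    for region in regions:
        direction = "amplified" if region.direction == "gain" else "deleted"
        scored: list[tuple[float, str]] = []
        rho_of: dict[str, float] = {}
        for gid in region.genes:
            if gid in seen:
                continue
            try:
                e = expr.row(gid)
                c = cn.row(gid)
            except KeyError:
                log.info("select_candidates: %s absent from matrices, skipped", gid)
                continue
            rho = _spearman(c, e)
            rho_of[gid] = rho
            scored.append((-abs(rho), gid))
        scored.sort()
        for _, gid in scored[: cfg.candidates_per_region_cap]:
            seen.add(gid)
            candidates.append(
                CandidateDriver(
                    gene_id=gid,
                    direction=direction,
                    region=region,
                    cn_expr_correlation=rho_of[gid],
                )
            )
    if not regions:
        log.info("select_candidates: no aberrant regions given; no candidates")
    return candidates


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return 0.0
    rx, ry = rankdata(x[ok]), rankdata(y[ok])
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx * rx).sum() * (ry * ry).sum()))
    if denom == 0.0:
        return 0.0
    return float((rx * ry).sum() / denom)


# ---------------------------------------------------------------------------
# step 2: Single Modulator


def single_modulator(
    expr: OmicsMatrix,
    candidates: Sequence[CandidateDriver],
    cfg: LearningConfig = LearningConfig(),
    scoring_cfg: ScoringConfig = ScoringConfig(),
) -> dict[str, Module]:
    """Initial driver-module association via depth-1 splits.

    For every non-candidate gene g and candidate d, the gain is the best
    penalized depth-1 split of d's expression for the one-gene module {g};
    g joins the argmax candidate's module when that gain is positive.  The
    structure penalty is the log of the total number of (modulator, split)
    candidates evaluated.  Modules below ``min_module_size`` dissolve.
    """
    cand_ids = [c.gene_id for c in candidates]
    cand_set = set(cand_ids)
    assign_genes = [g for g in expr.genes if g not in cand_set]
    if not cand_ids or not assign_genes:
        return {}
    X = expr.values[expr.gene_positions(assign_genes)]
    hyper, min_leaf = scoring_cfg.hyper, scoring_cfg.min_leaf_size
    if len(expr.samples) < 2 * min_leaf:
        return {}

    best_gain = np.full(len(assign_genes), NEG_INF)
    best_cand = np.full(len(assign_genes), -1, dtype=int)
    best_split_value = np.full(len(assign_genes), np.nan)
    total_cuts = 0
    for ci, cid in enumerate(cand_ids):
        scan = depth1_scan(expr.row(cid), X, hyper, min_leaf)
        if scan.midpoints.size == 0:
            continue
        total_cuts += scan.midpoints.size
        j = np.argmax(scan.two_leaf, axis=1)
        gains = scan.two_leaf[np.arange(len(assign_genes)), j] - scan.no_split
        better = gains > best_gain
        best_gain[better] = gains[better]
        best_cand[better] = ci
        best_split_value[better] = scan.midpoints[j[better]]
    if total_cuts == 0:
        return {}
    penalty = scoring_cfg.resolve_penalty(total_cuts)

    assigned = (best_gain - penalty > 0) & (best_cand >= 0)
    modules: dict[str, Module] = {}
    for ci, cid in enumerate(cand_ids):
        members = [g for g, a, c in zip(assign_genes, assigned, best_cand) if a and c == ci]
        if len(members) < cfg.min_module_size:
            continue
        mod_expr = expr.values[expr.gene_positions(members)]
        scan = depth1_scan(expr.row(cid), mod_expr, hyper, min_leaf)
        totals = scan.two_leaf.sum(axis=0)
        split = float(scan.midpoints[int(np.argmax(totals))])
        modules[cid] = Module(
            module_id=f"sm_{cid}",
            genes=tuple(members),
            driver=cid,
            sign="mixed",
            program=RegulatoryProgram(modulator=cid, split=split),
        )
    return modules


def sign_split(
    modules: dict[str, Module] | Sequence[Module],
    expr: OmicsMatrix,
    cfg: LearningConfig = LearningConfig(),
) -> list[Module]:
    """Split each driver's module by the sign of gene-driver correlation.

    Genes positively (Pearson r >= 0; exact zero and zero-variance members
    count positive — documented tie rule) and negatively correlated with the
    driver form separate modules; empty halves are not emitted, and halves
    below ``min_module_size`` dissolve.
    """
    mods = list(modules.values()) if isinstance(modules, dict) else list(modules)
    out: list[Module] = []
    for m in mods:
        if m.driver is None:
            raise ValueError(f"module {m.module_id} has no driver to sign against")
        d = expr.row(m.driver)
        halves: dict[str, list[str]] = {"positive": [], "negative": []}
        for g in m.genes:
            x = expr.row(g)
            r = _pearson(x, d)
            if math.isnan(r):
                log.info("sign_split: zero-variance member %s treated as positive", g)
                r = 0.0
            halves["positive" if r >= 0 else "negative"].append(g)
        for sign, members in halves.items():
            if not members:
                continue
            if len(members) < cfg.min_module_size:
                log.info(
                    "sign_split: %s %s half of size %d dissolved",
                    m.driver,
                    sign,
                    len(members),
                )
                continue
            out.append(
                Module(
                    module_id=f"{m.module_id}_{sign[:3]}",
                    genes=tuple(members),
                    driver=m.driver,
                    sign=sign,
                    program=m.program,
                )
            )
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    xs, ys = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    denom = math.sqrt(float((xs * xs).sum() * (ys * ys).sum()))
    if denom == 0.0:
        return float("nan")
    return float((xs * ys).sum() / denom)


# ---------------------------------------------------------------------------
# K-means seeding of unassigned genes


def kmeans_seed(
    unassigned_expr: OmicsMatrix,
    cfg: LearningConfig = LearningConfig(),
) -> list[Module]:
    """Stable K-means clusters of unassigned genes as seed modules.

    Rows are z-scored; K-means runs ``kmeans_restarts`` seeded restarts and
    the best-inertia run's clusters are kept when their mean best-match
    Jaccard against the other restarts reaches ``kmeans_stability_jaccard``.
    Unstable clusters' genes stay unassigned.  ``kmeans_k=None`` picks
    k = clip(n_genes // 100, 2, 20).
    """
    n = len(unassigned_expr.genes)
    k = cfg.kmeans_k if cfg.kmeans_k is not None else min(20, max(2, n // 100))
    if k > n:
        log.info("kmeans_seed: k reduced from %d to %d (pool size)", k, n)
        k = n
    if k < 2:
        log.info("kmeans_seed: k < 2, no seeding")
        return []
    X = unassigned_expr.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)

    labelings: list[np.ndarray] = []
    inertias: list[float] = []
    for r in range(cfg.kmeans_restarts):
        km = KMeans(n_clusters=k, n_init=1, random_state=cfg.seed + r).fit(Z)
        labelings.append(km.labels_.copy())
        inertias.append(float(km.inertia_))
    best = int(np.argmin(inertias))
    best_labels = labelings[best]

    out: list[Module] = []
    for c in range(k):
        members_mask = best_labels == c
        if not members_mask.any():
            continue
        stability = _mean_best_jaccard(members_mask, labelings, best, k)
        if stability < cfg.kmeans_stability_jaccard:
            continue
        members = [g for g, m in zip(unassigned_expr.genes, members_mask) if m]
        out.append(
            Module(
                module_id=f"km_{len(out) + 1:02d}",
                genes=tuple(members),
                driver=None,
                sign="none",
            )
        )
    return out


def _mean_best_jaccard(
    mask: np.ndarray, labelings: list[np.ndarray], best: int, k: int
) -> float:
    scores = []
    size = mask.sum()
    for r, labels in enumerate(labelings):
        if r == best:
            continue
        best_j = 0.0
        for c in range(k):
            other = labels == c
            inter = np.sum(mask & other)
            union = size + other.sum() - inter
            if union > 0:
                best_j = max(best_j, inter / union)
        scores.append(best_j)
    return float(np.mean(scores)) if scores else 1.0


# ---------------------------------------------------------------------------
# step 3: iterative Module Network


@dataclass
class _Prog:
    root_ci: int
    split: float
    children: list  # per branch: None or (ci, split)

    @property
    def n_internal(self) -> int:
        return 1 + sum(c is not None for c in self.children)


def _prog_leaves(prog: _Prog, cand_rows: np.ndarray) -> list[np.ndarray]:
    root = cand_rows[prog.root_ci]
    branches = [np.flatnonzero(root <= prog.split), np.flatnonzero(root > prog.split)]
    leaves: list[np.ndarray] = []
    for branch, child in zip(branches, prog.children):
        if child is None:
            leaves.append(branch)
        else:
            ci, split = child
            vals = cand_rows[ci][branch]
            leaves.append(branch[vals <= split])
            leaves.append(branch[vals > split])
    return leaves


def learn_network(
    expr: OmicsMatrix,
    candidates: Sequence[CandidateDriver],
    initial_modules: Sequence[Module],
    cfg: LearningConfig = LearningConfig(),
    scoring_cfg: ScoringConfig = ScoringConfig(),
    max_depth: Optional[int] = None,
    max_iterations: Optional[int] = None,
) -> tuple[list[Module], list[float]]:
    """Iterative module-network refinement.

    Alternates (a) refitting each module's regulatory program — searching
    the kept candidates x admissible split points, depth <= ``max_depth`` —
    and (b) re-assigning each gene to the container (a module, or the
    unassigned background scored as a single leaf) that maximizes its
    leaf-likelihood contribution under the fixed programs.  Membership in a
    module with a program carries a per-gene assignment charge equal to the
    structure penalty (log of the candidate-split space): adopting a
    module's split structure is the same model event as joining a module in
    the Single-Modulator step, so it pays the same multiplicity cost, and
    without it passenger genes drift into modules they do not belong to.
    Both steps accept strict improvements only, so the emitted total-score
    trace is monotone non-decreasing; ties keep the current state
    (oscillation guard).  Undersized modules dissolve mid-run only when
    dissolution does not decrease the score, and unconditionally in the
    final cleanup, which also drops modules whose program gain is not
    positive.

    Returns the fitted modules (with programs, signs and gains) and the
    score trace recorded after every half-iteration.
    """
    depth = max_depth if max_depth is not None else scoring_cfg.max_depth
    iters = max_iterations if max_iterations is not None else cfg.max_iterations
    hyper, min_leaf = scoring_cfg.hyper, scoring_cfg.min_leaf_size

    cand_ids = [c.gene_id for c in candidates]
    cand_set = set(cand_ids)
    assign_genes = [g for g in expr.genes if g not in cand_set]
    gene_pos = {g: i for i, g in enumerate(assign_genes)}
    if not cand_ids or not assign_genes:
        return [], []
    X = expr.values[expr.gene_positions(assign_genes)]
    X2 = X * X
    S = X.shape[1]
    cand_rows = expr.values[expr.gene_positions(cand_ids)]
    ci_of = {cid: i for i, cid in enumerate(cand_ids)}

    ns = _logml_from_stats(
        np.full(X.shape[0], S), X.sum(axis=1), X2.sum(axis=1), hyper
    )  # background (single leaf) contribution per gene

    # one structure-penalty constant per internal node: log of the full
    # (modulator, split-point) candidate space
    total_cuts = sum(
        _count_cuts(cand_rows[i], min_leaf) for i in range(len(cand_ids))
    )
    if total_cuts == 0:
        return [], []
    penalty = scoring_cfg.resolve_penalty(total_cuts)
    charge = penalty  # per-gene assignment charge for programmed modules

    # internal state: member[g] = module slot or -1; programs per slot
    member = np.full(X.shape[0], -1, dtype=int)
    progs: list[Optional[_Prog]] = []
    slots: list[set[int]] = []
    for m in initial_modules:
        rows = {gene_pos[g] for g in m.genes if g in gene_pos}
        rows = {r for r in rows if member[r] == -1}
        if not rows:
            continue
        prog = None
        if m.program is not None and m.program.modulator in ci_of:
            children = []
            for child in m.program.children:
                if child is not None and child[0] in ci_of:
                    children.append((ci_of[child[0]], child[1]))
                else:
                    children.append(None)
            prog = _Prog(ci_of[m.program.modulator], m.program.split, children)
            if any(len(l) < min_leaf for l in _prog_leaves(prog, cand_rows)):
                prog = None  # stale split from another sample set
        slots.append(rows)
        progs.append(prog)
        for r in rows:
            member[r] = len(slots) - 1

    def leaf_contrib(leaves: list[np.ndarray]) -> np.ndarray:
        out = np.zeros(X.shape[0])
        for leaf in leaves:
            if leaf.size == 0:
                continue
            out += _logml_from_stats(
                np.full(X.shape[0], leaf.size),
                X[:, leaf].sum(axis=1),
                X2[:, leaf].sum(axis=1),
                hyper,
            )
        return out

    def contrib_of(slot: int) -> np.ndarray:
        prog = progs[slot]
        if prog is None:
            return ns
        return leaf_contrib(_prog_leaves(prog, cand_rows))

    def total_score(contribs: list[np.ndarray]) -> float:
        t = 0.0
        for slot, rows in enumerate(slots):
            if not rows:
                continue
            idx = np.fromiter(rows, dtype=int)
            prog = progs[slot]
            t += float(contribs[slot][idx].sum())
            if prog is not None:
                t -= penalty * prog.n_internal + charge * len(rows)
        t += float(ns[member == -1].sum())
        return t

    trace: list[float] = []
    prev_total = -np.inf
    for _ in range(iters):
        # (a) program refits
        scans = [depth1_scan(cand_rows[ci], X, hyper, min_leaf) for ci in range(len(cand_ids))]
        for slot, rows in enumerate(slots):
            if not rows:
                continue
            idx = np.fromiter(rows, dtype=int)
            cur = contrib_of(slot)
            cur_pen = float(cur[idx].sum()) - (
                penalty * progs[slot].n_internal + charge * len(rows)
                if progs[slot] is not None
                else 0.0
            )
            best_val, best_prog = NEG_INF, None
            for ci, scan in enumerate(scans):
                if scan.midpoints.size == 0:
                    continue
                tot = scan.two_leaf[idx].sum(axis=0)
                j = int(np.argmax(tot))
                if tot[j] > best_val:
                    best_val = tot[j]
                    best_prog = _Prog(ci, float(scan.midpoints[j]), [None, None])
            if (
                best_prog is not None
                and best_val - penalty - charge * len(rows) > cur_pen + 1e-12
            ):
                progs[slot] = best_prog
            prog = progs[slot]
            if depth >= 2 and prog is not None and prog.children == [None, None]:
                _try_children(
                    prog, idx, X, X2, cand_rows, hyper, min_leaf, penalty
                )
        contribs = [contrib_of(s) for s in range(len(slots))]
        trace.append(total_score(contribs))

        # (b) gene moves (strict improvement; ties keep current container);
        # membership in a programmed module pays the assignment charge
        charged = [
            c - (charge if progs[s] is not None else 0.0)
            for s, c in enumerate(contribs)
        ]
        options = np.vstack([ns[None, :], *[c[None, :] for c in charged]]) if charged else ns[None, :]
        current = np.where(member >= 0, options[member + 1, np.arange(X.shape[0])], ns)
        dest = np.argmax(options, axis=0) - 1  # -1 = background
        dest_val = options.max(axis=0)
        move = dest_val > current + 1e-12
        changed = np.flatnonzero(move & (dest != member))
        for r in changed:
            old = member[r]
            if old >= 0:
                slots[old].discard(int(r))
            member[r] = dest[r]
            if dest[r] >= 0:
                slots[dest[r]].add(int(r))

        # (c) dissolve empty modules; undersized ones only when score-safe
        for slot, rows in enumerate(slots):
            if rows and len(rows) < cfg.min_module_size and progs[slot] is not None:
                idx = np.fromiter(rows, dtype=int)
                delta = (
                    float((ns[idx] - contribs[slot][idx]).sum())
                    + penalty * progs[slot].n_internal
                    + charge * len(rows)
                )
                if delta >= 0:
                    for r in list(rows):
                        member[r] = -1
                    slots[slot] = set()
            if not slots[slot]:
                progs[slot] = None

        contribs = [contrib_of(s) for s in range(len(slots))]
        total = total_score(contribs)
        trace.append(total)
        if np.isfinite(prev_total) and total - prev_total <= cfg.tolerance * max(
            1.0, abs(prev_total)
        ):
            prev_total = total
            break
        prev_total = total

    # final cleanup: drop undersized, program-less and non-positive-gain modules
    fitted: list[Module] = []
    for slot, rows in enumerate(slots):
        prog = progs[slot]
        if not rows or len(rows) < cfg.min_module_size or prog is None:
            continue
        idx = np.fromiter(rows, dtype=int)
        idx.sort()
        gain = float(
            (contrib_of(slot)[idx] - ns[idx]).sum() - penalty * prog.n_internal
        )
        if gain <= 0:
            continue
        driver = cand_ids[prog.root_ci]
        members = tuple(assign_genes[i] for i in idx)
        children = tuple(
            (cand_ids[c[0]], c[1]) if c is not None else None for c in prog.children
        )
        program = RegulatoryProgram(
            modulator=driver, split=prog.split, children=(children[0], children[1])
        )
        sign = _module_sign(expr, members, driver)
        fitted.append(
            Module(
                module_id=f"net_{len(fitted) + 1:02d}",
                genes=members,
                driver=driver,
                sign=sign,
                program=program,
                gain=gain,
            )
        )
    return fitted, trace


def _count_cuts(mod: np.ndarray, min_leaf: int) -> int:
    n = mod.size
    if n < 2 * min_leaf:
        return 0
    ms = np.sort(mod)
    k = np.arange(min_leaf, n - min_leaf + 1)
    return int(np.count_nonzero(ms[k] > ms[k - 1]))


def _try_children(
    prog: _Prog,
    idx: np.ndarray,
    X: np.ndarray,
    X2: np.ndarray,
    cand_rows: np.ndarray,
    hyper,
    min_leaf: int,
    penalty: float,
) -> None:
    """Greedy second-level splits: accept a child on a branch when its
    improvement over the branch's single leaf exceeds the structure penalty."""
    root = cand_rows[prog.root_ci]
    branches = [np.flatnonzero(root <= prog.split), np.flatnonzero(root > prog.split)]
    sub_rows = X[idx]
    for b, branch in enumerate(branches):
        if branch.size < 2 * min_leaf:
            continue
        sub = sub_rows[:, branch]
        best_delta, best_child = 0.0, None
        for ci in range(cand_rows.shape[0]):
            scan = depth1_scan(cand_rows[ci][branch], sub, hyper, min_leaf)
            if scan.midpoints.size == 0:
                continue
            tot = scan.two_leaf.sum(axis=0)
            j = int(np.argmax(tot))
            delta = float(tot[j] - scan.no_split.sum())
            if delta - penalty > best_delta + 1e-12:
                best_delta = delta - penalty
                best_child = (ci, float(scan.midpoints[j]))
        if best_child is not None:
            prog.children[b] = best_child


def _module_sign(expr: OmicsMatrix, members: Sequence[str], driver: str) -> str:
    d = expr.row(driver)
    signs = set()
    for g in members:
        r = _pearson(expr.row(g), d)
        signs.add("positive" if (math.isnan(r) or r >= 0) else "negative")
    return signs.pop() if len(signs) == 1 else "mixed"


# ---------------------------------------------------------------------------
# bootstrap stability selection


def bootstrap_select(
    stage: str,
    expr: OmicsMatrix,
    candidates: Sequence[CandidateDriver],
    cfg: LearningConfig = LearningConfig(),
    scoring_cfg: ScoringConfig = ScoringConfig(),
    initial_modules: Sequence[Module] = (),
    rng: np.random.Generator | int | None = None,
) -> tuple[list[CandidateDriver], dict[str, float]]:
    """Non-parametric bootstrap stability selection for a learning stage.

    Samples are resampled with replacement ``bootstrap_runs`` times; the
    stage runs on each replicate's distinct samples and a candidate counts
    as selected when it regulates at least one surviving module there.
    Duplicated tumors carry no independent evidence under a conjugate
    marginal likelihood — they only inflate split gains — so each draw is
    scored on its unique-sample support (~63% of the cohort), which makes
    the stage a subsampling stability selector.  Candidates with selection
    frequency at or above the stage threshold (0.90 for
    ``"single_modulator"``, 0.40 for ``"network"``) are kept for the final
    full-data run.  Replicates with fewer than ``2 x min_leaf_size``
    distinct samples are redrawn.
    """
    if stage not in ("single_modulator", "network"):
        raise ValueError("stage must be 'single_modulator' or 'network'")
    threshold = (
        cfg.single_modulator_keep if stage == "single_modulator" else cfg.network_keep
    )
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(cfg.seed if rng is None else rng)
    )
    S = len(expr.samples)
    counts = {c.gene_id: 0 for c in candidates}
    if not candidates:
        return [], {}
    for _ in range(cfg.bootstrap_runs):
        for _attempt in range(1000):
            idx = np.unique(rng.integers(0, S, size=S))  # distinct support
            if idx.size >= 2 * scoring_cfg.min_leaf_size:
                break
            log.info("bootstrap_select: replicate redrawn (too few distinct samples)")
        repl = OmicsMatrix(
            expr.kind,
            expr.genes,
            [expr.samples[j] for j in idx],
            expr.values[:, idx],
        )
        if stage == "single_modulator":
            mods = single_modulator(repl, candidates, cfg, scoring_cfg)
            selected = set(mods.keys())
        else:
            init = [replace(m, program=None) for m in initial_modules]
            fitted, _ = learn_network(
                repl,
                candidates,
                init,
                cfg,
                scoring_cfg,
                max_depth=cfg.bootstrap_max_depth,
                max_iterations=cfg.bootstrap_max_iterations,
            )
            selected = {m.driver for m in fitted if m.driver is not None}
        for gid in selected:
            if gid in counts:
                counts[gid] += 1
    freq = {gid: counts[gid] / cfg.bootstrap_runs for gid in counts}
    kept = [c for c in candidates if freq[c.gene_id] >= threshold]
    return kept, freq


# ---------------------------------------------------------------------------
# ranking


def conexic_scores(
    modules: Sequence[Module],
    candidates: Sequence[CandidateDriver],
    annotation: Sequence[GenomicGene] | None = None,
    bootstrap_frequency: dict[str, float] | None = None,
) -> list[DriverResult]:
    """Rank drivers by the summed score gains of their rooted modules.

    A driver's CONEXIC score sums the (non-negative) program-score gains of
    every module whose program it roots; drivers regulating no module are
    omitted from the table (logged).  Results are sorted by descending
    score, ties by gene_id.
    """
    ann = annotation_index(annotation) if annotation is not None else {}
    freq = bootstrap_frequency or {}
    by_driver: dict[str, list[Module]] = {}
    for m in modules:
        if m.driver is not None:
            by_driver.setdefault(m.driver, []).append(m)
    results: list[DriverResult] = []
    for c in candidates:
        mods = by_driver.get(c.gene_id)
        if not mods:
            log.info("conexic_scores: %s regulates no module, omitted", c.gene_id)
            continue
        mods = sorted(mods, key=lambda m: -m.gain)
        gene_ann = ann.get(c.gene_id)
        results.append(
            DriverResult(
                gene_id=c.gene_id,
                direction=c.direction,
                cytoband=gene_ann.cytoband if gene_ann is not None else "NA",
                conexic_score=float(sum(m.gain for m in mods)),
                bootstrap_frequency=float(freq.get(c.gene_id, math.nan)),
                modules=tuple(m.module_id for m in mods),
            )
        )
    results.sort(key=lambda d: (-d.conexic_score, d.gene_id))
    return results


# ---------------------------------------------------------------------------
# end-to-end driver discovery


@dataclass
class DiscoveryResult:
    """Everything the driver-learning pipeline produces."""

    drivers: list[DriverResult]
    modules: list[Module]
    trace: list[float]
    single_modulator_frequency: dict[str, float]
    network_frequency: dict[str, float]
    log_lines: list[str] = field(default_factory=list)


def run_driver_discovery(
    expr: OmicsMatrix,
    cn: OmicsMatrix,
    annotation: Sequence[GenomicGene],
    regions: Sequence[AberrantRegion],
    cfg: LearningConfig = LearningConfig(),
    scoring_cfg: ScoringConfig = ScoringConfig(),
) -> DiscoveryResult:
    """Run candidate selection, both bootstrap-filtered learning stages and
    CONEXIC ranking end to end.  Returns an empty result (with a log note)
    when no candidates survive — e.g. on data without recurrent aberrations.
    """
    lines: list[str] = []
    rng = np.random.default_rng(cfg.seed)

    candidates = select_candidates(regions, expr, cn, cfg)
    lines.append(f"candidates: {len(candidates)} from {len(regions)} regions")
    if not candidates:
        lines.append("halting: no candidate drivers (no significant regions)")
        return DiscoveryResult([], [], [], {}, {}, lines)

    sm_kept, sm_freq = bootstrap_select(
        "single_modulator", expr, candidates, cfg, scoring_cfg, rng=rng
    )
    lines.append(
        f"single-modulator bootstrap ({cfg.bootstrap_runs} runs, keep >= "
        f"{cfg.single_modulator_keep:g}): kept {len(sm_kept)}/{len(candidates)}"
    )
    if not sm_kept:
        lines.append("halting: no candidate passed the single-modulator bootstrap")
        return DiscoveryResult([], [], [], sm_freq, {}, lines)

    sm_modules = single_modulator(expr, sm_kept, cfg, scoring_cfg)
    signed = sign_split(sm_modules, expr, cfg)
    lines.append(
        f"single-modulator final: {len(sm_modules)} modules, {len(signed)} after sign split"
    )

    assigned = {g for m in signed for g in m.genes}
    cand_genes = {c.gene_id for c in candidates}
    unassigned = [g for g in expr.genes if g not in assigned and g not in cand_genes]
    seeds = (
        kmeans_seed(expr.subset_genes(unassigned), cfg) if len(unassigned) >= 2 else []
    )
    lines.append(f"k-means seeding: {len(seeds)} stable clusters from {len(unassigned)} genes")

    initial = list(signed) + seeds
    net_kept, net_freq = bootstrap_select(
        "network", expr, sm_kept, cfg, scoring_cfg, initial_modules=initial, rng=rng
    )
    lines.append(
        f"network bootstrap ({cfg.bootstrap_runs} runs, keep >= {cfg.network_keep:g}): "
        f"kept {len(net_kept)}/{len(sm_kept)}"
    )
    if not net_kept:
        lines.append("halting: no candidate passed the network bootstrap")
        return DiscoveryResult([], [], [], sm_freq, net_freq, lines)

    kept_ids = {c.gene_id for c in net_kept}
    initial_final = [m for m in initial if m.driver is None or m.driver in kept_ids]
    modules, trace = learn_network(expr, net_kept, initial_final, cfg, scoring_cfg)
    drivers = conexic_scores(modules, net_kept, annotation, net_freq)
    lines.append(
        f"module network: {len(modules)} modules, {len(drivers)} ranked drivers"
    )
    return DiscoveryResult(drivers, modules, trace, sm_freq, net_freq, lines)
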