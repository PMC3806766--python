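"""Recurrent copy-number aberration calling (GISTIC/JISTIC-style).

Per-gene G-scores combine the frequency and magnitude of gains (or losses)
across samples: the sum over samples of the log2-ratio exceedance beyond an
amplitude threshold theta.  Significance comes from an empirical null built
by permuting each sample's gene-level values across genes; pooled permuted
G-scores give per-gene p-values, Benjamini-Hochberg gives q-values.
Significant genes are grouped into maximal contiguous runs per chromosome,
and a peel-off pass removes each recorded region's signal so nested
secondary peaks inside large events can surface on later rounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import GenomicGene, OmicsMatrix

__all__ = [
    "AberrationConfig",
    "AberrantRegion",
    "compute_gscores",
    "permutation_significance",
    "call_regions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AberrationConfig:
    """Knobs of the region caller.

    ``amplitude_threshold`` (theta) is the minimum |log2 ratio| that counts
    toward a G-score; ``q_threshold`` is the BH q-value cutoff for calling a
    gene significantly recurrent; ``max_peel_rounds`` bounds the peel-off
    iterations that expose nested peaks.
    """

    amplitude_threshold: float = 0.1
    n_permutations: int = 1000
    q_threshold: float = 0.25
    max_peel_rounds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_threshold < 0:
            raise ValueError("amplitude_threshold must be >= 0")
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold must be in (0, 1)")
        if self.max_peel_rounds < 1:
            raise ValueError("max_peel_rounds must be >= 1")


@dataclass(frozen=True)
class AberrantRegion:
    """A contiguous run of significantly recurrently gained/lost genes."""

    direction: str  # "gain" | "loss"
    chromosome: str
    genes: tuple[str, ...]
    peak_gene: str
    gscores: tuple[float, ...]
    qvalues: tuple[float, ...]
    pass_index: int

    def __post_init__(self) -> None:
        if self.peak_gene not in self.genes:
            raise ValueError("peak_gene must be a member of the region span")


def _exceedance(values: np.ndarray, direction: str, theta: float) -> np.ndarray:
    """Per-cell amplitude beyond theta in the given direction; NA counts 0."""
    signed = values if direction == "gain" else -values
    with np.errstate(invalid="ignore"):
        exc = np.clip(signed - theta, 0.0, None)
    return np.nan_to_num(exc, nan=0.0)


def compute_gscores(
    cn: OmicsMatrix | np.ndarray, direction: str, theta: float = 0.1
) -> np.ndarray:
    """Per-gene G-score: sum over samples of max(0, +/-ratio - theta)."""
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    values = cn.values if isinstance(cn, OmicsMatrix) else np.asarray(cn, dtype=float)
    return _exceedance(values, direction, theta).sum(axis=1)


def permutation_significance(
    cn: OmicsMatrix | np.ndarray,
    gscores: np.ndarray,
    direction: str,
    theta: float,
    n_permutations: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical p- and BH q-values for per-gene G-scores.

    Each permutation independently shuffles every sample's gene-level values
    across genes and recomputes all G-scores; the pooled null over all
    permutations gives p_g = (1 + #{null >= G_g}) / (1 + P * n_genes).
    """
    values = cn.values if isinstance(cn, OmicsMatrix) else np.asarray(cn, dtype=float)
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} < 100: p-values will be coarse",
            stacklevel=2,
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    exc = _exceedance(values, direction, theta)
    n_genes = exc.shape[0]
    null = np.empty((n_permutations, n_genes))
    for p in range(n_permutations):
        null[p] = rng.permuted(exc, axis=0).sum(axis=1)
    pooled = np.sort(null, axis=None)
    n_null = pooled.size
    # count of null values >= G via searchsorted on the sorted pool
    ge = n_null - np.searchsorted(pooled, gscores, side="left")
    pvals = (1.0 + ge) / (1.0 + n_null)
    qvals = stats.false_discovery_control(pvals, method="bh")
    return pvals, qvals


def _contiguous_runs(indices: np.ndarray, chrom_of: np.ndarray) -> list[np.ndarray]:
    """Split sorted gene indices into runs contiguous on one chromosome."""
    runs: list[np.ndarray] = []
    if indices.size == 0:
        return runs
    start = 0
    for i in range(1, indices.size + 1):
        boundary = (
            i == indices.size
            or indices[i] != indices[i - 1] + 1
            or chrom_of[indices[i]] != chrom_of[indices[i - 1]]
        )
        if boundary:
            runs.append(indices[start:i])
            start = i
    return runs


def call_regions(
    cn: OmicsMatrix,
    annotation: Sequence[GenomicGene],
    config: AberrationConfig = AberrationConfig(),
) -> list[AberrantRegion]:
    """Detect significantly recurrent gains and losses with peel-off.

    Genes must all be annotated (hard error otherwise); they are analyzed in
    karyotype order.  Per direction: score, test, group significant genes
    (q < q_threshold) into maximal contiguous runs, record each run with its
    peak gene, then peel off the recorded genes' contributions (zeroing their
    values in samples exceeding theta) and repeat until nothing is
    significant or ``max_peel_rounds`` is reached.  Later passes carry a
    higher ``pass_index``.
    """
    ann_by_id = {g.gene_id: g for g in annotation}
    missing = [g for g in cn.genes if g not in ann_by_id]
    if missing:
        raise ValueError(f"annotation missing analyzed genes: {missing[:5]}")

    ordered = sorted((ann_by_id[g] for g in cn.genes), key=lambda g: g.sort_key)
    gene_ids = [g.gene_id for g in ordered]
    chrom_of = np.array([g.chromosome for g in ordered])
    values = cn.subset_genes(gene_ids).values

    theta = config.amplitude_threshold
    regions: list[AberrantRegion] = []
    for direction in ("gain", "loss"):
        rng = np.random.default_rng(config.seed)
        work = values.copy()
        for pass_index in range(1, config.max_peel_rounds + 1):
            g = compute_gscores(work, direction, theta)
            _, q = permutation_significance(
                work, g, direction, theta, config.n_permutations, rng
            )
            sig = np.flatnonzero(q < config.q_threshold)
            if sig.size == 0:
                break
            for run in _contiguous_runs(sig, chrom_of):
                peak = run[int(np.argmax(g[run]))]
                regions.append(
                    AberrantRegion(
                        direction=direction,
                        chromosome=str(chrom_of[run[0]]),
                        genes=tuple(gene_ids[i] for i in run),
                        peak_gene=gene_ids[peak],
                        gscores=tuple(float(x) for x in g[run]),
                        qvalues=tuple(float(x) for x in q[run]),
                        pass_index=pass_index,
                    )
                )
            # peel off: remove recorded genes' contributions in the samples
            # where they exceed theta, then rescore
            signed = work[sig] if direction == "gain" else -work[sig]
            mask = signed > theta
            sub = work[sig]
            sub[mask] = 0.0
            work[sig] = sub
            log.info(
                "call_regions: %s pass %d recorded %d significant genes",
                direction,
                pass_index,
                sig.size,
            )
    _assert_region_invariants(regions, gene_ids, chrom_of, config.q_threshold)
    order_key = {gid: i for i, gid in enumerate(gene_ids)}
    regions.sort(key=lambda r: (r.pass_index, order_key[r.genes[0]], r.direction))
    return regions


def _assert_region_invariants(
    regions: Sequence[AberrantRegion],
    gene_ids: list[str],
    chrom_of: np.ndarray,
    q_threshold: float,
) -> None:
    """Post-hoc check: member genes contiguous, one chromosome, q-significant."""
    pos = {gid: i for i, gid in enumerate(gene_ids)}
    for r in regions:
        idx = [pos[g] for g in r.genes]
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise AssertionError(f"region {r.genes[0]}..{r.genes[-1]} not contiguous")
        if len({str(chrom_of[i]) for i in idx}) != 1:
            raise AssertionError("region spans multiple chromosomes")
        if not all(q < q_threshold for q in r.qvalues):
            raise AssertionError("region contains non-significant gene")
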