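"""Gene-filtering funnel from raw gene-level matrices to the analysis set.

Inputs are assumed normalized log2 matrices.  The funnel is: drop
low-variance genes (sample SD below a threshold), merge multi-probe genes
whose probes agree (dropping inconsistent ones), restrict expression and copy
number to their common gene set, and optionally intersect gene universes
across cohorts.  Each step's output gene set is a subset of its input's.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import OmicsMatrix

__all__ = [
    "filter_low_variance",
    "merge_probes",
    "align_to_copy_number",
    "intersect_gene_universes",
]

log = logging.getLogger(__name__)


def filter_low_variance(expr: OmicsMatrix, sd_threshold: float = 0.25) -> OmicsMatrix:
    """Drop genes whose sample standard deviation is below ``sd_threshold``.

    The SD is the NA-omitting sample SD (denominator n-1) on the log2 scale;
    genes with SD exactly at the threshold are retained (removal uses the
    strict inequality).  Genes with fewer than two non-missing values cannot
    have an SD and are removed (logged with the reason).
    """
    values = expr.values
    n_obs = np.sum(np.isfinite(values), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.full(values.shape[0], np.nan)
        ok = n_obs >= 2
        if ok.any():
            sd[ok] = np.nanstd(values[ok], axis=1, ddof=1)
    keep = np.zeros(values.shape[0], dtype=bool)
    keep[ok] = sd[ok] >= sd_threshold
    for i in np.flatnonzero(~ok):
        log.info("filter_low_variance: dropped %s (<2 non-missing values)", expr.genes[i])
    kept_genes = [g for g, k in zip(expr.genes, keep) if k]
    return OmicsMatrix(expr.kind, kept_genes, expr.samples, values[keep])


def merge_probes(
    probe_matrix: OmicsMatrix,
    probe_to_gene: Mapping[str, str] | Iterable[tuple[str, str]],
    consistency_r: float = 0.7,
) -> OmicsMatrix:
    """Merge probe rows into gene rows, dropping inconsistent genes.

    Multi-probe genes are kept only if the minimum pairwise Pearson
    correlation across their probes is >= ``consistency_r``; surviving groups
    are merged by the per-sample mean.  Single-probe genes pass through
    unchanged.  A probe mapped to two different genes is a hard error.
    """
    if isinstance(probe_to_gene, Mapping):
        pairs = list(probe_to_gene.items())
    else:
        pairs = list(probe_to_gene)
    mapping: dict[str, str] = {}
    for probe, gene in pairs:
        if probe in mapping and mapping[probe] != gene:
            raise ValueError(
                f"probe {probe!r} mapped to both {mapping[probe]!r} and {gene!r}"
            )
        mapping[probe] = gene
    missing = [p for p in probe_matrix.genes if p not in mapping]
    if missing:
        raise ValueError(f"probes without gene mapping: {missing[:5]}")

    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for i, probe in enumerate(probe_matrix.genes):
        gene = mapping[probe]
        if gene not in groups:
            groups[gene] = []
            order.append(gene)
        groups[gene].append(i)

    values = probe_matrix.values
    out_genes: list[str] = []
    out_rows: list[np.ndarray] = []
    for gene in order:
        idx = groups[gene]
        if len(idx) == 1:
            out_genes.append(gene)
            out_rows.append(values[idx[0]])
            continue
        sub = values[idx]
        r_min = _min_pairwise_pearson(sub)
        if np.isnan(r_min) or r_min < consistency_r:
            log.info(
                "merge_probes: dropped inconsistent gene %s (min pairwise r=%.3f)",
                gene,
                r_min,
            )
            continue
        out_genes.append(gene)
        out_rows.append(np.nanmean(sub, axis=0))
    out = (
        np.vstack(out_rows)
        if out_rows
        else np.empty((0, len(probe_matrix.samples)))
    )
    return OmicsMatrix(probe_matrix.kind, out_genes, probe_matrix.samples, out)


def _min_pairwise_pearson(rows: np.ndarray) -> float:
    """Minimum pairwise Pearson correlation among rows, NA-omitting pairwise."""
    k = rows.shape[0]
    r_min = np.inf
    for a in range(k):
        for b in range(a + 1, k):
            x, y = rows[a], rows[b]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                return float("nan")
            xs, ys = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
            denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
            if denom == 0:
                return float("nan")
            r_min = min(r_min, float((xs * ys).sum() / denom))
    return r_min


def align_to_copy_number(
    expr: OmicsMatrix, cn: OmicsMatrix
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both matrices to their common genes, identically ordered.

    Both matrices must cover the same samples (a hard error lists the
    asymmetric difference otherwise); the output sample order follows the
    expression matrix, the gene order follows the expression matrix
    restricted to the intersection.  Genes without copy-number data are
    thereby filtered out.
    """
    e_samples, c_samples = set(expr.samples), set(cn.samples)
    if e_samples != c_samples:
        only_e = sorted(e_samples - c_samples)
        only_c = sorted(c_samples - e_samples)
        raise ValueError(
            f"sample sets differ: expression-only={only_e}, copy-number-only={only_c}"
        )
    common = set(expr.genes) & set(cn.genes)
    if not common:
        raise ValueError("expression and copy-number matrices share no genes")
    genes = [g for g in expr.genes if g in common]
    expr_out = expr.subset_genes(genes)
    cn_out = cn.subset_genes(genes).subset_samples(expr.samples)
    return expr_out, cn_out


def intersect_gene_universes(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Sorted intersection of two gene universes (e.g. two cohorts' gene sets)."""
    return sorted(set(a) & set(b))
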