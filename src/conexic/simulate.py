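"""Synthetic paired copy-number/expression cohorts with planted drivers.

The generator emulates the structure of a small breast-tumor cohort profiled
on both aCGH and expression arrays: tens of samples, thousands of genes,
contiguous gained/lost blocks carried by a subset of samples, driver genes
whose expression is coupled to their own copy number, and driver-controlled
gene modules whose means shift between the driver-high and driver-low tumor
groups.  Survival times follow an exponential model with a configurable
hazard ratio between the high/low groups of one designated driver.  The
returned ground truth (planted spans, drivers, split values, module
membership, survival groups) is what the recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ClinicalTable, GenomicGene, OmicsMatrix

__all__ = [
    "SimulationConfig",
    "PlantedRegion",
    "GroundTruth",
    "generate_dataset",
    "default_fixture",
    "default_fixture_annotation",
    "synthetic_annotation",
    "simulate_survival",
    "DEFAULT_FIXTURE_CONFIG",
]

#: SD of the copy-number background noise (log2 ratio scale).
CN_BACKGROUND_SD = 0.05
#: Baseline hazard (events per month) of the survival-low group; median
#: DMFS ~ 70 months, typical of a breast-cancer cohort with long follow-up.
BASELINE_HAZARD = 0.01
#: Target overall censoring fraction under independent uniform censoring.
CENSORING_FRACTION = 0.30


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the documented fixture.

    ``effect_size`` is the mean shift of module genes between driver-high and
    driver-low samples, in units of ``noise_sd``; ``cn_expression_coupling``
    is the slope of driver expression on its own copy number;
    ``carrier_fraction`` is the fraction of samples bearing each aberration.
    """

    n_samples: int = 60
    n_genes: int = 2000
    n_gain_regions: int = 3
    n_loss_regions: int = 2
    region_width: int = 15
    carrier_fraction: float = 0.35
    cn_amplitude: float = 0.8
    drivers_per_region: int = 1
    module_size: int = 40
    effect_size: float = 1.5
    noise_sd: float = 1.0
    cn_expression_coupling: float = 0.7
    survival_hazard_ratio: float = 3.0
    seed: int = 17

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "n_gain_regions": self.n_gain_regions,
            "n_loss_regions": self.n_loss_regions,
            "region_width": self.region_width,
            "drivers_per_region": self.drivers_per_region,
            "module_size": self.module_size,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (0.0 < self.carrier_fraction < 1.0):
            raise ValueError("carrier_fraction must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("survival_hazard_ratio must be positive")
        n_regions = self.n_gain_regions + self.n_loss_regions
        if self.n_genes < n_regions * self.region_width:
            raise ValueError(
                "n_genes must be at least n_regions * region_width "
                f"({n_regions * self.region_width}), got {self.n_genes}"
            )
        needed = n_regions * (self.region_width + self.drivers_per_region * self.module_size)
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small to also host the planted "
                f"modules (need >= {needed})"
            )


DEFAULT_FIXTURE_CONFIG = SimulationConfig()


@dataclass(frozen=True)
class PlantedRegion:
    """A contiguous planted aberration: gene-index span and direction."""

    direction: str  # "gain" | "loss"
    chromosome: str
    gene_indices: tuple[int, ...]
    gene_ids: tuple[str, ...]
    carrier_samples: tuple[str, ...]


@dataclass(frozen=True)
class GroundTruth:
    """Everything the recovery tests need: what was planted and where."""

    regions: tuple[PlantedRegion, ...]
    drivers: tuple[str, ...]
    driver_direction: dict[str, str]
    true_split: dict[str, float]
    module_genes: dict[str, tuple[str, ...]]
    module_gene_sign: dict[str, int]
    survival_driver: str
    survival_high_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        driver_set = set(self.drivers)
        for d, genes in self.module_genes.items():
            if driver_set & set(genes):
                raise ValueError("module genes must be disjoint from driver genes")
        region_genes = {g for r in self.regions for g in r.gene_ids}
        if not driver_set <= region_genes:
            raise ValueError("drivers must lie inside planted regions")


def synthetic_annotation(n_genes: int) -> list[GenomicGene]:
    """Deterministic annotation for ``n_genes`` synthetic genes.

    Genes are laid out consecutively across autosomes 1..22 in equal blocks,
    100 kb apart, with plausible p/q cytoband labels.  Purely positional
    bookkeeping so planted spans are contiguous in karyotype order.
    """
    per_chrom = -(-n_genes // 22)  # ceil
    genes: list[GenomicGene] = []
    for i in range(n_genes):
        chrom = str(i // per_chrom + 1)
        j = i % per_chrom
        arm = "p" if j < per_chrom / 2 else "q"
        j_arm = j if arm == "p" else j - per_chrom // 2
        band = f"{chrom}{arm}{11 + j_arm // 10}.{1 + j_arm % 10}"
        start = 1 + j * 100_000
        genes.append(
            GenomicGene(
                gene_id=f"G{i + 1:04d}",
                chromosome=chrom,
                start=start,
                end=start + 999,
                cytoband=band,
            )
        )
    return genes


def _chromosome_blocks(n_genes: int) -> list[tuple[int, int]]:
    per_chrom = -(-n_genes // 22)
    blocks = []
    for c in range(22):
        lo = c * per_chrom
        hi = min(lo + per_chrom, n_genes)
        if lo < hi:
            blocks.append((lo, hi))
    return blocks


def _place_regions(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[str, int]]:
    """Choose non-overlapping, within-chromosome start indices for regions."""
    blocks = _chromosome_blocks(config.n_genes)
    width = config.region_width
    taken: list[tuple[int, int]] = []
    placements: list[tuple[str, int]] = []
    directions = ["gain"] * config.n_gain_regions + ["loss"] * config.n_loss_regions
    for direction in directions:
        for _ in range(10_000):
            b_lo, b_hi = blocks[int(rng.integers(0, len(blocks)))]
            if b_hi - b_lo < width:
                continue
            start = int(rng.integers(b_lo, b_hi - width + 1))
            if all(start + width <= lo or start >= hi for lo, hi in taken):
                taken.append((start, start + width))
                placements.append((direction, start))
                break
        else:  # pragma: no cover - config validation prevents this
            raise RuntimeError("could not place planted regions without overlap")
    return placements


def simulate_survival(
    is_high: np.ndarray,
    hazard_ratio: float,
    rng: np.random.Generator,
    baseline_hazard: float = BASELINE_HAZARD,
    censoring_fraction: float = CENSORING_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with uniform censoring.

    The high group's hazard is ``baseline_hazard * hazard_ratio``.  Censoring
    times are Uniform(0, u) with u set so the expected overall censoring
    fraction matches ``censoring_fraction`` (solved from
    (1 - exp(-lambda u)) / (lambda u) = fraction at the mean hazard).
    Returns (observed time in months, event indicator).
    """
    is_high = np.asarray(is_high, dtype=bool)
    rates = np.where(is_high, baseline_hazard * hazard_ratio, baseline_hazard)
    t = rng.exponential(1.0 / rates)
    # solve (1 - exp(-x)) / x = censoring_fraction for x, then u = x / mean rate
    x = _solve_censoring(censoring_fraction)
    u = x / rates.mean()
    c = rng.uniform(0.0, u, size=is_high.size)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event


def _solve_censoring(fraction: float) -> float:
    lo, hi = 1e-6, 500.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (1.0 - np.exp(-mid)) / mid > fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, ClinicalTable, GroundTruth]:
    """Generate a paired copy-number/expression cohort with planted structure.

    Model (one shared RNG stream seeded from ``config.seed``):

    * copy number: background N(0, 0.05^2); carriers of each planted region
      shifted by +/- ``cn_amplitude``;
    * driver expression: ``cn_expression_coupling`` x its own copy number
      plus N(0, noise_sd^2);
    * module genes: N(+/- effect_size x noise_sd, noise_sd^2) in samples where
      their driver exceeds its true split (the median of driver expression),
      N(0, noise_sd^2) otherwise; signs fixed per gene, half positive;
    * passengers: N(0, noise_sd^2) independent of copy number;
    * survival: exponential with ``survival_hazard_ratio`` between the
      high/low groups of the first planted driver, ~30% uniform censoring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples
    annotation = synthetic_annotation(G)
    gene_ids = [g.gene_id for g in annotation]  # index i <-> G{i+1:04d}
    sample_ids = [f"S{j + 1:03d}" for j in range(S)]

    n_carriers = max(1, round(config.carrier_fraction * S))
    placements = _place_regions(rng, config)

    cn = rng.normal(0.0, CN_BACKGROUND_SD, size=(G, S))
    regions: list[PlantedRegion] = []
    region_gene_idx: set[int] = set()
    for direction, start in placements:
        span = tuple(range(start, start + config.region_width))
        carriers = np.sort(rng.choice(S, size=n_carriers, replace=False))
        shift = config.cn_amplitude if direction == "gain" else -config.cn_amplitude
        cn[np.ix_(span, carriers)] += shift
        region_gene_idx.update(span)
        regions.append(
            PlantedRegion(
                direction=direction,
                chromosome=annotation[start].chromosome,
                gene_indices=span,
                gene_ids=tuple(gene_ids[i] for i in span),
                carrier_samples=tuple(sample_ids[j] for j in carriers),
            )
        )

    expr = rng.normal(0.0, config.noise_sd, size=(G, S))

    # drivers inside each region
    drivers: list[str] = []
    driver_direction: dict[str, str] = {}
    driver_idx: dict[str, int] = {}
    for region in regions:
        chosen = rng.choice(
            region.gene_indices, size=config.drivers_per_region, replace=False
        )
        for i in np.sort(chosen):
            gid = gene_ids[int(i)]
            drivers.append(gid)
            driver_direction[gid] = (
                "amplified" if region.direction == "gain" else "deleted"
            )
            driver_idx[gid] = int(i)
            expr[int(i)] = config.cn_expression_coupling * cn[int(i)] + expr[int(i)]

    # driver-high masks from the true split (median of driver expression)
    true_split: dict[str, float] = {}
    high_mask: dict[str, np.ndarray] = {}
    for gid in drivers:
        s = float(np.median(expr[driver_idx[gid]]))
        true_split[gid] = s
        high_mask[gid] = expr[driver_idx[gid]] > s

    # module genes: drawn outside planted regions, disjoint across modules
    free = np.array(sorted(set(range(G)) - region_gene_idx), dtype=int)
    free = rng.permutation(free)
    module_genes: dict[str, tuple[str, ...]] = {}
    module_gene_sign: dict[str, int] = {}
    cursor = 0
    shift = config.effect_size * config.noise_sd
    for gid in drivers:
        members = free[cursor : cursor + config.module_size]
        cursor += config.module_size
        signs = np.ones(config.module_size, dtype=int)
        signs[config.module_size // 2 :] = -1
        for i, sign in zip(members, signs):
            expr[int(i)] += sign * shift * high_mask[gid]
            module_gene_sign[gene_ids[int(i)]] = int(sign)
        module_genes[gid] = tuple(gene_ids[int(i)] for i in members)

    # survival keyed to the first planted driver
    survival_driver = drivers[0]
    is_high = high_mask[survival_driver]
    time, event = simulate_survival(is_high, config.survival_hazard_ratio, rng)
    clinical = ClinicalTable(
        pd.DataFrame(
            {"dmfs_time_months": time, "dmfs_event": event},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = GroundTruth(
        regions=tuple(regions),
        drivers=tuple(drivers),
        driver_direction=driver_direction,
        true_split=true_split,
        module_genes=module_genes,
        module_gene_sign=module_gene_sign,
        survival_driver=survival_driver,
        survival_high_samples=tuple(
            sid for sid, h in zip(sample_ids, is_high) if h
        ),
    )
    cn_matrix = OmicsMatrix("copy_number", gene_ids, sample_ids, cn)
    expr_matrix = OmicsMatrix("expression", gene_ids, sample_ids, expr)
    return cn_matrix, expr_matrix, clinical, truth


@lru_cache(maxsize=4)
def _cached_fixture(config: SimulationConfig):
    return generate_dataset(config)


def default_fixture(
    seed: int | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, ClinicalTable, GroundTruth]:
    """The documented small cohort used across the test suite and docs.

    60 samples x 2,000 genes; 3 gain + 2 loss regions of 15 genes at log2
    amplitude 0.8 in 35% of samples; 1 driver per region with coupling 0.7;
    40-gene modules shifted by 1.5 noise-SD; hazard ratio 3.0; seed 17.
    ``seed`` overrides the fixture seed (for replicate studies).
    """
    cfg = DEFAULT_FIXTURE_CONFIG
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return _cached_fixture(cfg)


def default_fixture_annotation() -> list[GenomicGene]:
    return synthetic_annotation(DEFAULT_FIXTURE_CONFIG.n_genes)


def write_truth_tables(truth: GroundTruth, out_dir) -> None:
    """Write ground-truth TSVs (regions, drivers, modules) next to a simulated
    dataset so recovery can be checked outside Python."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "truth_regions.tsv"), "wt") as fh:
        fh.write("direction\tchromosome\tfirst_gene\tlast_gene\tcarriers\n")
        for r in truth.regions:
            fh.write(
                f"{r.direction}\t{r.chromosome}\t{r.gene_ids[0]}\t{r.gene_ids[-1]}"
                f"\t{','.join(r.carrier_samples)}\n"
            )
    with open(os.path.join(out_dir, "truth_drivers.tsv"), "wt") as fh:
        fh.write("driver\tdirection\ttrue_split\tmodule_genes\n")
        for d in truth.drivers:
            fh.write(
                f"{d}\t{truth.driver_direction[d]}\t{truth.true_split[d]:.6g}"
                f"\t{','.join(truth.module_genes[d])}\n"
            )
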