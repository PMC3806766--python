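"""Readers and writers for the tab-delimited artifacts used across the pipeline.

All on-disk formats are plain text: genes x samples matrices of log2 values
(expression or aCGH copy-number ratios), a gene annotation TSV carrying
chromosome/position/cytoband, GMT gene-set collections, a clinical table with
distant-metastasis-free-survival (DMFS) endpoints, and the results bundle
(driver table, module membership, regulatory-program trees).  Every writer has
a matching reader and ``read(write(x)) == x`` on valid objects.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOMES",
    "GenomicGene",
    "OmicsMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "write_results_bundle",
    "read_results_bundle",
]

#: Karyotype chromosome order: autosomes 1..22, then X, Y.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Output floats use 6 significant digits, plain decimal notation.
FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


@dataclass(frozen=True)
class GenomicGene:
    """A gene as a positional unit for recurrent-aberration calling.

    Coordinates are 1-based inclusive base pairs; ``cytoband`` is the
    cytogenetic band reported alongside drivers (e.g. ``"11q23.3"``).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    cytoband: str

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROM_ORDER:
            raise ValueError(
                f"unknown chromosome {self.chromosome!r} for gene {self.gene_id!r}"
            )
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (_CHROM_ORDER[self.chromosome], self.start, self.gene_id)


@dataclass
class OmicsMatrix:
    """A genes x samples matrix of log2 values with row/column identity.

    ``kind`` is ``"expression"`` or ``"copy_number"``; missing values are
    ``NaN`` (written as the literal ``NA``).
    """

    kind: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "copy_number"):
            raise ValueError(f"kind must be expression|copy_number, got {self.kind!r}")
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )
        for label, ids in (("gene", self.genes), ("sample", self.samples)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {label} id {dup!r}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def gene_positions(self, gene_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "OmicsMatrix":
        idx = self.gene_positions(gene_ids)
        return OmicsMatrix(self.kind, list(gene_ids), self.samples, self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        pos = {s: j for j, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return OmicsMatrix(self.kind, self.genes, list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str) -> "OmicsMatrix":
        return cls(kind, list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class ClinicalTable:
    """Per-sample clinical endpoints: DMFS time (months) and event indicator.

    Extra categorical covariate columns (e.g. a transcriptional-subgroup
    label) are carried through untouched.
    """

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("dmfs_time_months", "dmfs_event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in clinical table")
        if (df["dmfs_time_months"] < 0).any():
            raise ValueError("dmfs_time_months must be non-negative")
        if not df["dmfs_event"].isin((0, 1)).all():
            raise ValueError("dmfs_event must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def times_events(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = self.frame.loc[list(sample_ids)]
        return (
            sub["dmfs_time_months"].to_numpy(dtype=float),
            sub["dmfs_event"].to_numpy(dtype=int),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, unique members)."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path: str | os.PathLike, kind: str) -> OmicsMatrix:
    """Read a tab-delimited genes x samples matrix.

    First row is the sample header, first column the gene id; cells are
    numeric or the literal ``NA``.  Duplicate ids and ragged rows are hard
    errors (pandas would silently mangle or pad them, so structure is checked
    line by line before parsing).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        dup = _first_duplicate(samples)
        if dup is not None:
            raise ValueError(f"duplicate sample id {dup!r} in {path}")
        ncol = len(header)
        genes: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}"
                )
            genes.append(fields[0])
            try:
                rows.append(
                    np.array(
                        [math.nan if f == "NA" else float(f) for f in fields[1:]],
                        dtype=float,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    dup = _first_duplicate(genes)
    if dup is not None:
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    values = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=float)
    )
    return OmicsMatrix(kind, genes, samples, values)


def write_matrix(matrix: OmicsMatrix, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.samples) + "\n")
        for g, row in zip(matrix.genes, matrix.values):
            cells = ["NA" if math.isnan(v) else _fmt(v) for v in row]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path: str | os.PathLike) -> list[GenomicGene]:
    """Read a gene annotation TSV (gene_id, chromosome, start, end, cytoband).

    Output is sorted in karyotype order (1..22, X, Y) then by start position.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "chromosome": str, "cytoband": str}
    )
    required = ["gene_id", "chromosome", "start", "end", "cytoband"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation missing columns {missing}")
    dup = _first_duplicate(df["gene_id"])
    if dup is not None:
        raise ValueError(f"duplicate gene id {dup!r} in annotation {path}")
    genes = [
        GenomicGene(r.gene_id, r.chromosome, int(r.start), int(r.end), r.cytoband)
        for r in df.itertuples(index=False)
    ]
    return sorted(genes, key=lambda g: g.sort_key)


def write_gene_annotation(genes: Sequence[GenomicGene], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\tcytoband\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.cytoband}\n")


def annotation_index(genes: Sequence[GenomicGene]) -> dict[str, GenomicGene]:
    return {g.gene_id: g for g in genes}


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line.

    Repeated members within a line are de-duplicated (set semantics);
    duplicate set names and lines with fewer than three fields are errors.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, need >= 3"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = tuple(dict.fromkeys(m for m in members if m))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# clinical table


def read_clinical(path: str | os.PathLike) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table missing 'sample_id' column")
    return ClinicalTable(df.set_index("sample_id"))


def write_clinical(table: ClinicalTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# results bundle


def _program_lines(program, indent: str) -> list[str]:
    from .ng import RegulatoryProgram  # local import to avoid cycle at import time

    assert isinstance(program, RegulatoryProgram)
    lines = [
        f"{indent}modulator {program.modulator}",
        f"{indent}split {_fmt(program.split)}",
    ]
    for branch, child in (("low", program.children[0]), ("high", program.children[1])):
        if child is not None:
            mod, split = child
            lines.append(f"{indent}child {branch}")
            lines.append(f"{indent}  modulator {mod}")
            lines.append(f"{indent}  split {_fmt(split)}")
    return lines


def write_results_bundle(
    drivers: Sequence,
    modules: Sequence,
    out_dir: str | os.PathLike,
    log_lines: Sequence[str] = (),
) -> dict[str, str]:
    """Write drivers.tsv, modules.tsv, programs.txt and run.log to ``out_dir``.

    Drivers are ordered by descending CONEXIC score (ties by gene_id);
    floats use 6 significant digits.  Returns the mapping of artifact name
    to path.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir!r} is not writable")
    paths = {
        name: os.path.join(out_dir, name)
        for name in ("drivers.tsv", "modules.tsv", "programs.txt", "run.log")
    }

    ordered = sorted(drivers, key=lambda d: (-d.conexic_score, d.gene_id))
    with open(paths["drivers.tsv"], "wt", encoding="utf-8") as fh:
        fh.write(
            "gene\tdirection\tcytoband\tconexic_score\tbootstrap_frequency\tmodules\n"
        )
        for d in ordered:
            fh.write(
                "\t".join(
                    [
                        d.gene_id,
                        d.direction,
                        d.cytoband,
                        _fmt(d.conexic_score),
                        _fmt(d.bootstrap_frequency),
                        ";".join(d.modules),
                    ]
                )
                + "\n"
            )

    mod_ordered = sorted(modules, key=lambda m: m.module_id)
    with open(paths["modules.tsv"], "wt", encoding="utf-8") as fh:
        fh.write("gene\tmodule_id\tdriver\tsign\n")
        for m in mod_ordered:
            driver = m.driver if m.driver is not None else "NA"
            for g in m.genes:
                fh.write(f"{g}\t{m.module_id}\t{driver}\t{m.sign}\n")

    with open(paths["programs.txt"], "wt", encoding="utf-8") as fh:
        for m in mod_ordered:
            fh.write(f"module {m.module_id}\n")
            if m.program is not None:
                for line in _program_lines(m.program, "  "):
                    fh.write(line + "\n")

    with open(paths["run.log"], "wt", encoding="utf-8") as fh:
        for line in log_lines:
            fh.write(line + "\n")
    return paths


def read_results_bundle(out_dir: str | os.PathLike):
    """Re-read a results bundle; inverse of :func:`write_results_bundle`."""
    from .learning import DriverResult, Module
    from .ng import RegulatoryProgram

    out_dir = os.fspath(out_dir)
    drivers: list[DriverResult] = []
    with open(os.path.join(out_dir, "drivers.tsv"), "rt", encoding="utf-8") as fh:
        next(fh)  # header
        for line in fh:
            gene, direction, cytoband, score, freq, mods = line.rstrip("\n").split("\t")
            drivers.append(
                DriverResult(
                    gene_id=gene,
                    direction=direction,
                    cytoband=cytoband,
                    conexic_score=float(score),
                    bootstrap_frequency=float(freq),
                    modules=tuple(m for m in mods.split(";") if m),
                )
            )

    membership: dict[str, dict] = {}
    with open(os.path.join(out_dir, "modules.tsv"), "rt", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            gene, module_id, driver, sign = line.rstrip("\n").split("\t")
            rec = membership.setdefault(
                module_id,
                {"genes": [], "driver": None if driver == "NA" else driver, "sign": sign},
            )
            rec["genes"].append(gene)

    programs: dict[str, RegulatoryProgram] = {}
    with open(os.path.join(out_dir, "programs.txt"), "rt", encoding="utf-8") as fh:
        current: str | None = None
        spec: dict | None = None
        branch: str | None = None

        def flush():
            if current is not None and spec is not None and "modulator" in spec:
                children = [spec.get("low"), spec.get("high")]
                programs[current] = RegulatoryProgram(
                    modulator=spec["modulator"],
                    split=spec["split"],
                    children=(children[0], children[1]),
                )

        for raw in fh:
            line = raw.rstrip("\n")
            stripped = line.strip()
            if stripped.startswith("module "):
                flush()
                current = stripped.split(" ", 1)[1]
                spec = {}
                branch = None
            elif stripped.startswith("child "):
                branch = stripped.split(" ", 1)[1]
                spec[branch] = [None, None]
            elif stripped.startswith("modulator "):
                value = stripped.split(" ", 1)[1]
                if branch is None or not line.startswith("    "):
                    spec["modulator"] = value
                    branch = None
                else:
                    spec[branch][0] = value
            elif stripped.startswith("split "):
                value = float(stripped.split(" ", 1)[1])
                if branch is None or not line.startswith("    "):
                    spec["split"] = value
                else:
                    spec[branch][1] = value
                    spec[branch] = (spec[branch][0], spec[branch][1])
        flush()

    modules = [
        Module(
            module_id=module_id,
            genes=tuple(rec["genes"]),
            driver=rec["driver"],
            sign=rec["sign"],
            program=programs.get(module_id),
        )
        for module_id, rec in membership.items()
    ]
    modules.sort(key=lambda m: m.module_id)
    return drivers, modules
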