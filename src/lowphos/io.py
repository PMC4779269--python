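"""File formats, configuration and the core in-memory containers.

The pipeline operates on a log2 expression matrix (genes x samples, TSV),
a sample sheet describing the 2 accessions x 2 tissues x 2 treatments x 3
replicates design, GMT-style gene-set annotations and a small configuration
object holding the analysis thresholds.

Gene identity is the full transcript-level identifier string everywhere:
``Glyma20g33710.1`` and ``Glyma20g33710.2`` are distinct genes for every set
operation in this package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

ACCESSIONS = ("tolerant", "sensitive")
TISSUES = ("root", "leaf")
TREATMENTS = ("normalP", "lowP")

#: the eight design cells (accession, tissue, treatment), canonical order
CELLS = tuple(
    (a, t, tr) for a in ACCESSIONS for t in TISSUES for tr in TREATMENTS
)


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class ConfigError(ValueError):
    """Raised when a configuration value is out of range."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ("sample_id", "accession", "tissue", "treatment", "replicate")


@dataclass
class SampleSheet:
    """Sample metadata for the two-accession, two-tissue, two-treatment design.

    The canonical design has exactly three biological replicates per
    (accession, tissue, treatment) cell, 24 samples in total.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        f = self.frame
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample_ids: {dup}")
        for col, allowed in (
            ("accession", ACCESSIONS),
            ("tissue", TISSUES),
            ("treatment", TREATMENTS),
        ):
            bad = sorted(set(f[col]) - set(allowed))
            if bad:
                raise FormatError(f"invalid {col} values {bad}; allowed {allowed}")
        if (f["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples(
        self,
        accession: str | None = None,
        tissue: str | None = None,
        treatment: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given factor levels (None = any)."""
        f = self.frame
        mask = pd.Series(True, index=f.index)
        if accession is not None:
            mask &= f["accession"] == accession
        if tissue is not None:
            mask &= f["tissue"] == tissue
        if treatment is not None:
            mask &= f["treatment"] == treatment
        return list(f.loc[mask, "sample_id"])

    def cell_samples(self, cell: tuple[str, str, str]) -> list[str]:
        a, t, tr = cell
        return self.samples(accession=a, tissue=t, treatment=tr)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return cls(frame)

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_design_sheet(n_replicates: int = 3) -> SampleSheet:
    """The canonical 2x2x2 design sheet with ``n_replicates`` per cell."""
    rows = []
    for a, t, tr in CELLS:
        for r in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{a}_{t}_{tr}_r{r}",
                    "accession": a,
                    "tissue": t,
                    "treatment": tr,
                    "replicate": r,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 intensities, genes in rows and samples in columns.

    ``values`` is a DataFrame indexed by gene id with one column per sample.
    ``normalized`` records whether between-array normalization has run.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values.index.name = "gene_id"
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dup[:5]}")
        bad = [
            c
            for c in self.values.columns
            if not pd.api.types.is_numeric_dtype(self.values[c])
        ]
        if bad:
            raise FormatError(f"non-numeric sample columns: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.normalized)

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def read_expression_matrix(
    path: str | Path, sheet: SampleSheet | None = None
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV matrix, optionally aligned to a sample sheet.

    The first column must be ``gene_id``; remaining columns are sample ids.
    Gene ids are preserved verbatim, including transcript suffixes such as
    ``.1``/``.2``. When a sheet is given, every sheet sample must be present
    and the columns are reordered to sheet order.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene_id":
        raise FormatError(
            f"first column must be 'gene_id', found {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene_id")
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            row = raw.index[converted.isna()][0]
            raise FormatError(
                f"non-numeric value at gene {row!r}, sample column {col!r}"
            )
        raw[col] = converted
    if sheet is not None:
        missing = [s for s in sheet.sample_ids if s not in raw.columns]
        if missing:
            raise FormatError(
                f"sample(s) in sheet but not in matrix header: {missing}"
            )
        raw = raw[sheet.sample_ids]
    return ExpressionMatrix(raw)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    genes: frozenset[str]


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file: term id, description, then tab-separated genes.

    Duplicate genes within a term are collapsed; a line with fewer than
    three fields (i.e. an empty term) is a format error.
    """
    gene_sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected term, description and at least one gene"
                )
            term, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: term {term!r} is empty")
            gene_sets[term] = GeneSet(term, desc, frozenset(genes))
    return gene_sets


def write_gene_sets(gene_sets: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in gene_sets:
            gs = gene_sets[term]
            fh.write("\t".join([gs.term_id, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Analysis thresholds and knobs.

    The defaults implement the three-part DEG criterion
    (|log2 ratio| >= 1, FDR-adjusted significance < 0.05, complete
    triplicates) and the 4-fold rescue rule on the linear scale.
    """

    log2_ratio_threshold: float = 1.0
    fdr_alpha: float = 0.05
    rescue_fold_threshold: float = 4.0
    enrichment_alpha: float = 0.05
    permutations: int = 20
    rng_seed: int = 0
    linkage: str = "average"
    gene_metric: str = "correlation"
    sample_metric: str = "euclidean"
    #: "sam" = permutation median-false-call q-values; "bh" = Benjamini-Hochberg
    #: on pooled permutation p-values
    fdr_method: str = "sam"
    #: SAM fudge factor; None = choose by the coefficient-of-variation rule
    s0: float | None = None
    #: how "no difference under normal P" is decided in pattern classification:
    #: "criteria" = fails any of the three DEG criteria; "ratio_only" =
    #: |log2 ratio| below threshold
    normal_no_difference: str = "criteria"
    #: significance on raw enrichment p (False) or BH-adjusted p (True)
    enrichment_adjust: bool = False
    min_replicates: int = 3

    def __post_init__(self) -> None:
        if self.log2_ratio_threshold < 0:
            raise ConfigError("log2_ratio_threshold must be non-negative")
        for name in ("fdr_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.rescue_fold_threshold <= 0:
            raise ConfigError("rescue_fold_threshold must be positive")
        if self.permutations < 1:
            raise ConfigError("permutations must be a positive integer")
        if self.linkage not in ("average", "complete", "single"):
            raise ConfigError(f"unsupported linkage {self.linkage!r}")
        if self.fdr_method not in ("sam", "bh"):
            raise ConfigError(f"unsupported fdr_method {self.fdr_method!r}")
        if self.normal_no_difference not in ("criteria", "ratio_only"):
            raise ConfigError(
                f"unsupported normal_no_difference {self.normal_no_difference!r}"
            )
        if self.s0 is not None and self.s0 < 0:
            raise ConfigError("s0 must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                data = yaml.safe_load(fh) or {}
            else:
                data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
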