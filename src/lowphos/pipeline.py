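"""End-to-end orchestration: contrasts -> classification -> set algebra ->
enrichment -> clustering, with TSV/JSON reporting.

The stage order follows the comparative design: treatment contrasts within
each (accession, tissue) cell first, then the inter-accession and
inter-tissue comparisons under both treatments, then the pattern
classification and marked-DEG assembly, the overlap sets, term enrichment
of the common genes and a two-way hierarchical clustering of the DEG
union. Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import crossclass, detest, enrich, normalize
from .io import (
    ACCESSIONS,
    TISSUES,
    TREATMENTS,
    ExpressionMatrix,
    GeneSet,
    PipelineConfig,
    SampleSheet,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a pipeline stage, with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def standard_contrasts(sheet: SampleSheet) -> dict[str, detest.ContrastSpec]:
    """The twelve two-group contrasts of the design.

    Orientation follows the reporting convention: low P over normal P,
    tolerant over sensitive, roots over leaves.
    """
    out: dict[str, detest.ContrastSpec] = {}
    for a in ACCESSIONS:
        for t in TISSUES:
            out[f"treatment_{a}_{t}"] = detest.ContrastSpec(
                f"treatment_{a}_{t}",
                tuple(sheet.samples(accession=a, tissue=t, treatment="lowP")),
                tuple(sheet.samples(accession=a, tissue=t, treatment="normalP")),
            )
    for t in TISSUES:
        for tr in TREATMENTS:
            out[f"material_{t}_{tr}"] = detest.ContrastSpec(
                f"material_{t}_{tr}",
                tuple(sheet.samples(accession="tolerant", tissue=t, treatment=tr)),
                tuple(sheet.samples(accession="sensitive", tissue=t, treatment=tr)),
            )
    for a in ACCESSIONS:
        for tr in TREATMENTS:
            out[f"tissue_{a}_{tr}"] = detest.ContrastSpec(
                f"tissue_{a}_{tr}",
                tuple(sheet.samples(accession=a, tissue="root", treatment=tr)),
                tuple(sheet.samples(accession=a, tissue="leaf", treatment=tr)),
            )
    return out


#: comparison name -> (low-P contrast, normal-P contrast)
COMPARISON_CONTRASTS = {
    "material_roots": ("material_root_lowP", "material_root_normalP"),
    "material_leaves": ("material_leaf_lowP", "material_leaf_normalP"),
    "tissue_tolerant": ("tissue_tolerant_lowP", "tissue_tolerant_normalP"),
    "tissue_sensitive": ("tissue_sensitive_lowP", "tissue_sensitive_normalP"),
}


@dataclass
class PipelineResult:
    contrasts: dict[str, pd.DataFrame]
    patterns: pd.DataFrame
    marked_material: crossclass.DEGSetCollection
    marked_tissue: crossclass.DEGSetCollection
    treatment_sets: dict[str, frozenset[str]]
    treatment_accounting: crossclass.UnionAccounting
    overlaps: dict[str, frozenset[str]]
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    gene_newick: str | None = None
    sample_newick: str | None = None
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    gene_sets: dict[str, GeneSet] | None = None,
    outdir: str | Path | None = None,
    normalize_first: bool = True,
) -> PipelineResult:
    """Run every stage on one dataset and return the result bundle.

    With ``outdir`` set, per-stage TSV tables, Newick dendrograms and a
    JSON cardinality summary are written (byte-identical across runs with
    the same config and seed).
    """
    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # attach stage name for diagnosis
            raise StageError(name, exc) from exc

    if normalize_first and not matrix.normalized:
        matrix = stage("normalize", lambda: normalize.quantile_normalize(matrix))
        logger.info("normalize: %d genes x %d samples", *matrix.shape)

    specs = standard_contrasts(sheet)
    contrasts: dict[str, pd.DataFrame] = {}
    for i, name in enumerate(sorted(specs)):
        params = detest.SamParameters(
            s0=config.s0,
            n_permutations=config.permutations,
            rng_seed=config.rng_seed + i,
        )
        contrasts[name] = stage(
            f"detest:{name}",
            lambda spec=specs[name], p=params: detest.test_contrast(
                matrix, spec, config, p
            ),
        )
        n_deg = int(contrasts[name]["is_deg"].sum())
        logger.info("detest %s: %d DEGs of %d genes", name, n_deg, len(matrix.gene_ids))

    # treatment DEG sets and non-redundant accounting
    treatment_sets: dict[str, frozenset[str]] = {}
    for a in ACCESSIONS:
        for t in TISSUES:
            per = detest.deg_sets(contrasts[f"treatment_{a}_{t}"])
            for direction in ("up", "down"):
                if per[direction]:
                    treatment_sets[f"{a}_{t}_{direction}"] = per[direction]
    treatment_accounting = crossclass.nonredundant_union(treatment_sets)
    treatment_union = frozenset().union(*treatment_sets.values()) if treatment_sets else frozenset()

    # pattern classification of the four comparisons
    pattern_frames = []
    for cmp_name, (low_name, norm_name) in COMPARISON_CONTRASTS.items():
        pattern_frames.append(
            stage(
                f"crossclass:{cmp_name}",
                lambda l=low_name, n=norm_name, c=cmp_name: crossclass.classify_patterns(
                    contrasts[l], contrasts[n], config, comparison=c
                ),
            )
        )
    patterns = pd.concat(pattern_frames, ignore_index=True)
    marked_material = crossclass.marked_degs(
        patterns[patterns["comparison"].str.startswith("material")]
    )
    marked_tissue = crossclass.marked_degs(
        patterns[patterns["comparison"].str.startswith("tissue")]
    )

    overlaps = {
        "treatment_and_material": crossclass.overlap_genes(
            treatment_union, marked_material.union
        )
        if treatment_union and marked_material.sets
        else frozenset(),
        "treatment_and_tissue": crossclass.overlap_genes(
            treatment_union, marked_tissue.union
        )
        if treatment_union and marked_tissue.sets
        else frozenset(),
    }
    if treatment_union and marked_material.sets and marked_tissue.sets:
        overlaps["common"] = crossclass.overlap_genes(
            treatment_union, marked_material.union, marked_tissue.union
        )
    else:
        overlaps["common"] = frozenset()
    logger.info(
        "crossclass: %d marked material, %d marked tissue, %d common",
        marked_material.nonredundant_count,
        marked_tissue.nonredundant_count,
        len(overlaps["common"]),
    )

    # enrichment of the treatment union and the common set
    enrichment: dict[str, pd.DataFrame] = {}
    if gene_sets:
        background = set(matrix.gene_ids)
        for qname, query in (
            ("treatment_degs", treatment_union),
            ("common_degs", overlaps["common"]),
        ):
            enrichment[qname] = stage(
                f"enrich:{qname}",
                lambda q=query: enrich.enrich_sets(
                    set(q), gene_sets, background, config
                ),
            )

    # two-way clustering of the treatment DEG union
    gene_newick = sample_newick = None
    if len(treatment_union) >= 2:
        sub = matrix.subset_genes(sorted(treatment_union))
        gd = stage(
            "cluster:genes",
            lambda: _cluster.distance_matrix(sub, "genes", config.gene_metric),
        )
        gene_newick = _cluster.to_newick(
            _cluster.hierarchical_cluster(gd, config.linkage)
        )
        sd = stage(
            "cluster:samples",
            lambda: _cluster.distance_matrix(sub, "samples", config.sample_metric),
        )
        sample_newick = _cluster.to_newick(
            _cluster.hierarchical_cluster(sd, config.linkage)
        )

    summary = _summarize(
        contrasts,
        patterns,
        marked_material,
        marked_tissue,
        treatment_sets,
        treatment_accounting,
        overlaps,
        enrichment,
        config,
    )

    result = PipelineResult(
        contrasts=contrasts,
        patterns=patterns,
        marked_material=marked_material,
        marked_tissue=marked_tissue,
        treatment_sets=treatment_sets,
        treatment_accounting=treatment_accounting,
        overlaps=overlaps,
        enrichment=enrichment,
        gene_newick=gene_newick,
        sample_newick=sample_newick,
        summary=summary,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _summarize(
    contrasts,
    patterns,
    marked_material,
    marked_tissue,
    treatment_sets,
    treatment_accounting,
    overlaps,
    enrichment,
    config,
) -> dict:
    summary = {
        "config": config.to_dict(),
        "contrast_deg_counts": {
            name: {
                "up": int((df["direction"] == "up").sum()),
                "down": int((df["direction"] == "down").sum()),
            }
            for name, df in contrasts.items()
        },
        "treatment_set_sizes": {k: len(v) for k, v in treatment_sets.items()},
        "treatment_raw_total": treatment_accounting.raw_total,
        "treatment_nonredundant": treatment_accounting.distinct_count,
        "pattern_category_counts": crossclass.category_counts(patterns).to_dict(
            orient="records"
        ),
        "marked_material_raw": marked_material.raw_total,
        "marked_material_nonredundant": marked_material.nonredundant_count,
        "marked_tissue_raw": marked_tissue.raw_total,
        "marked_tissue_nonredundant": marked_tissue.nonredundant_count,
        "overlap_sizes": {k: len(v) for k, v in overlaps.items()},
    }
    if enrichment:
        summary["enriched_term_counts"] = {
            k: int(df["enriched"].sum()) if len(df) else 0
            for k, df in enrichment.items()
        }
    return summary


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in result.contrasts.items():
        df.to_csv(outdir / f"contrast_{name}.tsv", sep="\t")
    result.patterns.to_csv(outdir / "patterns.tsv", sep="\t", index=False)
    marked_rows = []
    for label, coll in (
        ("material", result.marked_material),
        ("tissue", result.marked_tissue),
    ):
        for cmp_name, genes in coll.sets.items():
            for g in sorted(genes):
                marked_rows.append(
                    {"axis": label, "comparison": cmp_name, "gene_id": g}
                )
    pd.DataFrame(
        marked_rows, columns=["axis", "comparison", "gene_id"]
    ).to_csv(outdir / "marked_degs.tsv", sep="\t", index=False)
    overlap_rows = [
        {"overlap": name, "gene_id": g}
        for name, genes in result.overlaps.items()
        for g in sorted(genes)
    ]
    pd.DataFrame(overlap_rows, columns=["overlap", "gene_id"]).to_csv(
        outdir / "overlaps.tsv", sep="\t", index=False
    )
    for qname, df in result.enrichment.items():
        df.to_csv(outdir / f"enrichment_{qname}.tsv", sep="\t", index=False)
    if result.gene_newick:
        (outdir / "genes.nwk").write_text(result.gene_newick + "\n")
    if result.sample_newick:
        (outdir / "samples.nwk").write_text(result.sample_newick + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
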