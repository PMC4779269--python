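"""Synthetic microarray datasets with the study design and planted truth.

The generator emulates a 24-array experiment — 2 accessions (low-P tolerant
vs sensitive) x 2 tissues (root, leaf) x 2 treatments (normal P, low P) x 3
biological replicates — at gene level: per-gene baseline log2 intensities
are Gaussian, per-replicate noise is additive Gaussian on the log2 scale,
and differential expression is planted as additive shifts on designated
design cells. Two kinds of structure are planted:

* treatment DEGs — a shift on the low-P cell of a chosen
  (accession, tissue), so the within-cell treatment contrast sees it;
* pattern genes — shifts on the numerator cell of an inter-accession or
  inter-tissue comparison, chosen separately under low P and normal P so
  that the cross-classification (concordant / opposite / rescued / dropped)
  of each gene is known by construction.

All gene ids are deterministic synthetic ids (``SYN000001`` ...), never real
locus names. Deterministic fixtures reproduce the printed two-way category
multiplicities of the study's tables, for exercising the set accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ACCESSIONS,
    CELLS,
    GeneSet,
    ExpressionMatrix,
    SampleSheet,
    build_design_sheet,
)
from .crossclass import COMPARISONS

DIRECTIONS = ("up", "down")
PLANT_CATEGORIES = ("concordant", "opposite", "rescued", "dropped")

#: numerator cell (gets the shift) per comparison, by (tissue or accession)
_COMPARISON_NUMERATOR = {
    "material_roots": ("tolerant", "root"),
    "material_leaves": ("tolerant", "leaf"),
    "tissue_tolerant": ("tolerant", "root"),
    "tissue_sensitive": ("sensitive", "root"),
}


class ScenarioError(ValueError):
    """Raised when a scenario specification is inconsistent."""


@dataclass
class ScenarioSpec:
    """What to plant and how noisy the arrays are.

    Effect ranges are on the log2 scale and must stay clear of (-1, 1) so
    planted genes exceed the 2-fold DEG criterion in expectation. The
    rescued range must exceed the 4-fold rescue threshold (|log2| > 2) and
    the dropped range must sit between the DEG and rescue thresholds.
    """

    n_genes: int = 2000
    #: (accession, tissue) -> {"up": count, "down": count}
    treatment_degs: Mapping[tuple[str, str], Mapping[str, int]] = field(
        default_factory=dict
    )
    #: comparison -> {(direction, category): count}
    pattern_degs: Mapping[str, Mapping[tuple[str, str], int]] = field(
        default_factory=dict
    )
    up_log2_range: tuple[float, float] = (2.0, 5.0)
    down_log2_range: tuple[float, float] = (-5.0, -2.0)
    rescued_log2_magnitude: tuple[float, float] = (2.8, 5.0)
    dropped_log2_magnitude: tuple[float, float] = (1.2, 1.8)
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ScenarioError("noise_sd must be > 0")
        if self.n_genes < 1:
            raise ScenarioError("n_genes must be positive")
        lo, hi = self.up_log2_range
        if not (1.0 <= lo <= hi):
            raise ScenarioError("up_log2_range must lie in [1, inf)")
        lo, hi = self.down_log2_range
        if not (lo <= hi <= -1.0):
            raise ScenarioError("down_log2_range must lie in (-inf, -1]")
        total = self.total_planted()
        if total > self.n_genes:
            raise ScenarioError(
                f"planted gene counts ({total}) exceed n_genes ({self.n_genes})"
            )
        for cell in self.treatment_degs:
            if cell not in {(a, t) for a, t, _ in CELLS}:
                raise ScenarioError(f"unknown design cell {cell}")
        for cmp_name in self.pattern_degs:
            if cmp_name not in COMPARISONS:
                raise ScenarioError(f"unknown comparison {cmp_name!r}")

    def total_planted(self) -> int:
        n = sum(
            int(c)
            for counts in self.treatment_degs.values()
            for c in counts.values()
        )
        n += sum(
            int(c)
            for counts in self.pattern_degs.values()
            for c in counts.values()
        )
        return n


def default_scenario(rng_seed: int = 0, n_genes: int = 2000) -> ScenarioSpec:
    """The canonical planted scenario: log2 effects >= 2, noise sd 0.25.

    Planted counts are shaped like the study's design — most treatment
    DEGs in the tolerant accession's roots — plus every pattern category
    in all four comparisons.
    """
    treatment = {
        ("tolerant", "root"): {"up": 60, "down": 20},
        ("tolerant", "leaf"): {"up": 8, "down": 0},
        ("sensitive", "root"): {"up": 0, "down": 3},
        ("sensitive", "leaf"): {"up": 0, "down": 5},
    }
    per_comparison = {
        ("up", "concordant"): 12,
        ("up", "opposite"): 3,
        ("up", "rescued"): 8,
        ("up", "dropped"): 8,
        ("down", "concordant"): 8,
        ("down", "opposite"): 2,
        ("down", "rescued"): 5,
        ("down", "dropped"): 6,
    }
    patterns = {cmp_name: dict(per_comparison) for cmp_name in COMPARISONS}
    return ScenarioSpec(
        n_genes=n_genes,
        treatment_degs=treatment,
        pattern_degs=patterns,
        rng_seed=rng_seed,
    )


def null_scenario(rng_seed: int = 0, n_genes: int = 2000) -> ScenarioSpec:
    """No planted structure at all: pure noise around the baseline."""
    return ScenarioSpec(n_genes=n_genes, rng_seed=rng_seed)


def table1_scenario(rng_seed: int = 0, n_genes: int = 2000) -> ScenarioSpec:
    """Treatment effects drawn from the printed fold-change intervals:
    up-regulated ratios in [2.00, 33.78], down-regulated in [0.11, 0.49]."""
    treatment = {
        ("tolerant", "root"): {"up": 120, "down": 20},
        ("tolerant", "leaf"): {"up": 6, "down": 0},
        ("sensitive", "root"): {"up": 0, "down": 3},
        ("sensitive", "leaf"): {"up": 0, "down": 5},
    }
    return ScenarioSpec(
        n_genes=n_genes,
        treatment_degs=treatment,
        up_log2_range=(np.log2(2.00), np.log2(33.78)),
        down_log2_range=(np.log2(0.11), np.log2(0.49)),
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------


def _cell_key(cell: tuple[str, str, str]) -> str:
    return "|".join(cell)


@dataclass
class PlantedTruth:
    """Everything the generator planted, in analysis-ready form."""

    #: genes x 8 design cells: the additive log2 shift of each cell
    cell_effects: pd.DataFrame
    #: one row per planted treatment DEG: gene_id, accession, tissue,
    #: direction, log2_effect
    treatment_degs: pd.DataFrame
    #: one row per planted pattern gene: gene_id, comparison,
    #: lowP_direction, category, low_effect, normal_effect
    patterns: pd.DataFrame

    def contrast_effect(
        self, exp_cell: tuple[str, str, str], ctl_cell: tuple[str, str, str]
    ) -> pd.Series:
        """True log2 effect of a one-cell-vs-one-cell contrast per gene."""
        return (
            self.cell_effects[_cell_key(exp_cell)]
            - self.cell_effects[_cell_key(ctl_cell)]
        )

    def treatment_deg_ids(
        self, accession: str, tissue: str, direction: str | None = None
    ) -> frozenset[str]:
        t = self.treatment_degs
        mask = (t["accession"] == accession) & (t["tissue"] == tissue)
        if direction is not None:
            mask &= t["direction"] == direction
        return frozenset(t.loc[mask, "gene_id"])


def simulate_dataset(
    spec: ScenarioSpec,
) -> tuple[ExpressionMatrix, SampleSheet, PlantedTruth]:
    """Generate one 24-array dataset with the planted structure of ``spec``.

    Identical spec (including seed) gives identical output. Planted shifts
    are applied to the low-P group only for treatment DEGs, keeping normal
    P as the reference, and to the numerator cell of each comparison for
    pattern genes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    G = spec.n_genes
    gene_ids = [f"SYN{i:06d}" for i in range(1, G + 1)]
    sheet = build_design_sheet()

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    cell_eff = pd.DataFrame(
        np.zeros((G, len(CELLS))),
        index=gene_ids,
        columns=[_cell_key(c) for c in CELLS],
    )

    free = list(rng.permutation(G))

    def take(count: int) -> list[str]:
        picked = [gene_ids[free.pop()] for _ in range(count)]
        return picked

    def draw(count: int, lo: float, hi: float) -> np.ndarray:
        return rng.uniform(lo, hi, size=count)

    # --- treatment DEGs: shift the low-P cell only
    t_rows = []
    for (a, t), counts in spec.treatment_degs.items():
        for direction in DIRECTIONS:
            count = int(counts.get(direction, 0))
            if count == 0:
                continue
            genes = take(count)
            rng_range = (
                spec.up_log2_range if direction == "up" else spec.down_log2_range
            )
            effects = draw(count, *rng_range)
            cell_eff.loc[genes, _cell_key((a, t, "lowP"))] += effects
            for g, e in zip(genes, effects):
                t_rows.append(
                    {
                        "gene_id": g,
                        "accession": a,
                        "tissue": t,
                        "direction": direction,
                        "log2_effect": float(e),
                    }
                )

    # --- pattern genes: shift the comparison's numerator cell per treatment
    p_rows = []
    for cmp_name, counts in spec.pattern_degs.items():
        acc, tis = _COMPARISON_NUMERATOR[cmp_name]
        low_cell = _cell_key((acc, tis, "lowP"))
        norm_cell = _cell_key((acc, tis, "normalP"))
        for (direction, category), count in counts.items():
            count = int(count)
            if count == 0:
                continue
            if direction not in DIRECTIONS or category not in PLANT_CATEGORIES:
                raise ScenarioError(
                    f"unknown pattern key {(direction, category)!r}"
                )
            genes = take(count)
            sign = 1.0 if direction == "up" else -1.0
            if category == "concordant":
                low = sign * draw(count, *_magnitude(spec, direction))
                norm = sign * draw(count, *_magnitude(spec, direction))
            elif category == "opposite":
                low = sign * draw(count, *_magnitude(spec, direction))
                norm = -sign * draw(count, *_magnitude(spec, direction))
            elif category == "rescued":
                low = sign * draw(count, *spec.rescued_log2_magnitude)
                norm = np.zeros(count)
            else:  # dropped
                low = sign * draw(count, *spec.dropped_log2_magnitude)
                norm = np.zeros(count)
            cell_eff.loc[genes, low_cell] += low
            cell_eff.loc[genes, norm_cell] += norm
            for g, lo_e, no_e in zip(genes, low, norm):
                p_rows.append(
                    {
                        "gene_id": g,
                        "comparison": cmp_name,
                        "lowP_direction": direction,
                        "category": category,
                        "low_effect": float(lo_e),
                        "normal_effect": float(no_e),
                    }
                )

    # --- assemble the matrix
    values = np.empty((G, len(sheet.sample_ids)))
    for j, sid in enumerate(sheet.sample_ids):
        row = sheet.frame.loc[sheet.frame["sample_id"] == sid].iloc[0]
        cell = _cell_key((row["accession"], row["tissue"], row["treatment"]))
        values[:, j] = (
            baseline + cell_eff[cell].to_numpy() + rng.normal(0, spec.noise_sd, G)
        )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sheet.sample_ids)
    )
    truth = PlantedTruth(
        cell_effects=cell_eff,
        treatment_degs=pd.DataFrame(
            t_rows,
            columns=["gene_id", "accession", "tissue", "direction", "log2_effect"],
        ),
        patterns=pd.DataFrame(
            p_rows,
            columns=[
                "gene_id",
                "comparison",
                "lowP_direction",
                "category",
                "low_effect",
                "normal_effect",
            ],
        ),
    )
    return matrix, sheet, truth


def _magnitude(spec: ScenarioSpec, direction: str) -> tuple[float, float]:
    if direction == "up":
        return spec.up_log2_range
    lo, hi = spec.down_log2_range
    return (-hi, -lo)


# ---------------------------------------------------------------------------
# deterministic fixtures reproducing the printed table multiplicities
# ---------------------------------------------------------------------------

#: per comparison and direction: (concordant, opposite, rescued, dropped)
TABLE2_COUNTS: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("material_roots", "up"): (941, 10, 93, 733),
    ("material_roots", "down"): (610, 0, 14, 310),
    ("material_leaves", "up"): (2636, 1, 40, 935),
    ("material_leaves", "down"): (1040, 0, 38, 488),
    ("tissue_tolerant", "up"): (5137, 1, 97, 1135),
    ("tissue_tolerant", "down"): (4696, 0, 19, 874),
    ("tissue_sensitive", "up"): (6149, 0, 63, 1144),
    ("tissue_sensitive", "down"): (4156, 0, 73, 1002),
}

#: the one gene up-regulated >4-fold in both the root and leaf
#: inter-accession comparisons (shared between their rescued sets)
SHARED_MATERIAL_RESCUED = "T2SHARED_UP_RESCUED"

_CATEGORY_VALUES = {
    # (lowP log2 ratio, normalP log2 ratio, normalP is_deg)
    ("up", "concordant"): (1.5, 1.5, True),
    ("up", "opposite"): (1.5, -1.5, True),
    ("up", "rescued"): (2.5, 0.2, False),  # fold 5.66 > 4
    ("up", "dropped"): (1.5, 0.1, False),  # fold 2.83 < 4
    ("down", "concordant"): (-1.5, -1.5, True),
    ("down", "opposite"): (-1.5, 1.5, True),
    ("down", "rescued"): (-2.5, -0.2, False),  # fold 0.177 < 1/4
    ("down", "dropped"): (-1.5, -0.1, False),  # fold 0.354 > 1/4
}


def simulate_table2_fixture() -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Deterministic contrast tables whose cross-classification reproduces
    the printed two-way category multiplicities exactly.

    Returns ``comparison -> (lowP_table, normalP_table)`` ready for
    ``crossclass.classify_patterns``. Exactly one gene (an up-rescued one)
    is shared between the root and leaf inter-accession comparisons; all
    other ids are unique, so the marked material sets count 196 raw and
    195 non-redundant and the tissue comparisons yield 253 marked genes.
    """
    fixtures: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for cmp_name in COMPARISONS:
        low_rows, norm_rows = [], []
        serial = 0
        for direction in DIRECTIONS:
            conc, opp, resc, drop = TABLE2_COUNTS[(cmp_name, direction)]
            for category, count in zip(PLANT_CATEGORIES, (conc, opp, resc, drop)):
                low_lfc, norm_lfc, norm_deg = _CATEGORY_VALUES[
                    (direction, category)
                ]
                for i in range(count):
                    serial += 1
                    if (
                        category == "rescued"
                        and direction == "up"
                        and i == 0
                        and cmp_name in ("material_roots", "material_leaves")
                    ):
                        gid = SHARED_MATERIAL_RESCUED
                    else:
                        gid = f"T2_{cmp_name}_{serial:05d}"
                    low_rows.append(_contrast_row(gid, low_lfc, True))
                    norm_rows.append(_contrast_row(gid, norm_lfc, norm_deg))
        low = pd.DataFrame(low_rows).set_index("gene_id")
        norm = pd.DataFrame(norm_rows).set_index("gene_id")
        fixtures[cmp_name] = (low, norm)
    return fixtures


def _contrast_row(gene_id: str, log2_ratio: float, is_deg: bool) -> dict:
    return {
        "gene_id": gene_id,
        "log2_ratio": log2_ratio,
        "fold_change": float(2.0**log2_ratio),
        "q_value": 0.01 if is_deg else 0.5,
        "n_complete_replicates": 3,
        "is_deg": is_deg,
        "direction": ("up" if log2_ratio > 0 else "down") if is_deg else "none",
    }


#: treatment-contrast DEG set sizes of the printed one-way table
TABLE1_SIZES = {
    "tolerant_root_up": 257,
    "tolerant_root_down": 41,
    "tolerant_leaf_up": 11,
    "sensitive_root_down": 3,
    "sensitive_leaf_down": 7,
}

#: the gene down-regulated in the roots of both accessions
SHARED_ROOT_DOWN = "T1SHARED_ROOT_DOWN"
#: the gene up-regulated in both roots and leaves of the tolerant accession
SHARED_TOLERANT_UP = "T1SHARED_TOLERANT_UP"


def simulate_table1_fixture() -> dict[str, frozenset[str]]:
    """Named treatment-DEG id sets with the printed sizes and exactly the
    two printed cross-set memberships, so the union counts 319 raw and
    317 non-redundant ids."""
    sets: dict[str, frozenset[str]] = {}
    for name, size in TABLE1_SIZES.items():
        ids = {f"T1_{name}_{i:04d}" for i in range(1, size + 1)}
        sets[name] = frozenset(ids)

    def swap(name: str, shared: str) -> None:
        ids = set(sets[name])
        ids.pop()
        ids.add(shared)
        sets[name] = frozenset(ids)

    swap("tolerant_root_down", SHARED_ROOT_DOWN)
    swap("sensitive_root_down", SHARED_ROOT_DOWN)
    swap("tolerant_root_up", SHARED_TOLERANT_UP)
    swap("tolerant_leaf_up", SHARED_TOLERANT_UP)
    return sets


def simulate_overlap_fixture() -> dict[str, frozenset[str]]:
    """Synthetic stand-in sets with the printed intersection cardinalities.

    Three engineered id sets — treatment DEGs (317), marked material DEGs
    (195), marked tissue DEGs (253) — built so that
    |treatment & material| = 85, |treatment & tissue| = 68 and the triple
    intersection (the "common DEGs") is 42. The membership is synthetic;
    only the set arithmetic is meaningful.
    """
    regions = {
        "core": 42,  # in all three
        "tm_only": 85 - 42,  # treatment & material only
        "tt_only": 68 - 42,  # treatment & tissue only
        "t_only": 317 - 42 - 43 - 26,
        "m_only": 195 - 85,
        "s_only": 253 - 68,
    }
    ids = {
        name: frozenset(f"OV_{name}_{i:04d}" for i in range(1, n + 1))
        for name, n in regions.items()
    }
    treatment = ids["core"] | ids["tm_only"] | ids["tt_only"] | ids["t_only"]
    material = ids["core"] | ids["tm_only"] | ids["m_only"]
    tissue = ids["core"] | ids["tt_only"] | ids["s_only"]
    return {
        "treatment": treatment,
        "marked_material": material,
        "marked_tissue": tissue,
    }


# ---------------------------------------------------------------------------
# annotation simulator
# ---------------------------------------------------------------------------


def simulate_annotation(
    genes: list[str] | set[str],
    n_terms: int,
    seed: int,
    enriched_terms: Mapping[str, float] | None = None,
    target_genes: set[str] | None = None,
    term_size_range: tuple[int, int] = (10, 40),
) -> dict[str, GeneSet]:
    """Toy term->gene-set annotations with optional planted enrichment.

    Each term samples its genes without replacement; genes in
    ``target_genes`` get sampling weight equal to the term's planted odds
    (1 = null), producing over-representation of the target subset in
    enriched terms. Reproducible by seed.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("empty gene universe")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    enriched_terms = dict(enriched_terms or {})
    target = set(target_genes or set())
    rng = np.random.default_rng(seed)
    lo, hi = term_size_range
    lo = max(1, min(lo, len(genes)))
    hi = max(lo, min(hi, len(genes)))
    out: dict[str, GeneSet] = {}
    gene_arr = np.array(genes)
    in_target = np.array([g in target for g in genes], dtype=float)
    for t in range(1, n_terms + 1):
        term = f"TERM{t:04d}"
        odds = float(enriched_terms.get(term, 1.0))
        weights = np.where(in_target > 0, odds, 1.0)
        weights = weights / weights.sum()
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_arr, size=size, replace=False, p=weights)
        out[term] = GeneSet(term, f"synthetic term {t}", frozenset(members))
    return out
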