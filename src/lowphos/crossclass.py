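"""Cross-accession / cross-tissue pattern classification and DEG set algebra.

Low-P DEGs from an inter-accession (tolerant/sensitive) or inter-tissue
(root/leaf) contrast are classified by how the same gene behaves in the
matching normal-P contrast:

* ``concordant`` — differential in the same direction under normal P;
* ``opposite``   — differential in the opposite direction under normal P;
* ``rescued``    — no normal-P difference, but the low-P fold change exceeds
  the 4-fold rescue threshold (>4 for up-regulated genes, <1/4 for
  down-regulated ones);
* ``dropped``    — no normal-P difference and below the rescue threshold.

"Marked DEGs" are the union of the opposite and rescued categories; they are
the genes whose accession (or tissue) difference is specific to low-P
conditions. Set accounting reports both raw totals (with multiplicity
across comparisons) and non-redundant counts over distinct transcript ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PipelineConfig

CATEGORIES = ("concordant", "opposite", "rescued", "dropped")

#: the four inter-accession / inter-tissue comparisons of the design
COMPARISONS = (
    "material_roots",  # tolerant/sensitive within roots
    "material_leaves",  # tolerant/sensitive within leaves
    "tissue_tolerant",  # roots/leaves within the tolerant accession
    "tissue_sensitive",  # roots/leaves within the sensitive accession
)

PATTERN_COLUMNS = (
    "gene_id",
    "comparison",
    "lowP_direction",
    "normalP_status",
    "lowP_log2_ratio",
    "lowP_fold_change",
    "category",
)


class IncompleteInputError(ValueError):
    """A low-P DEG has no matching record in the normal-P table."""


def classify_patterns(
    lowP_results: pd.DataFrame,
    normalP_results: pd.DataFrame,
    config: PipelineConfig,
    comparison: str = "",
) -> pd.DataFrame:
    """Assign every low-P DEG of one comparison to exactly one category.

    Both inputs are contrast tables (as produced by ``detest.test_contrast``)
    for the same gene-pair orientation under the two treatments. Genes that
    are not DEGs under low P are absent from the output.
    """
    for col in ("log2_ratio", "fold_change", "is_deg", "direction"):
        for name, df in (("lowP", lowP_results), ("normalP", normalP_results)):
            if col not in df.columns:
                raise ValueError(f"{name} table missing column {col!r}")
    degs = lowP_results[lowP_results["is_deg"]]
    missing = [g for g in degs.index if g not in normalP_results.index]
    if missing:
        raise IncompleteInputError(
            f"low-P DEGs missing from the normal-P table: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    normal = normalP_results.loc[degs.index]

    if config.normal_no_difference == "criteria":
        normal_diff = normal["is_deg"].to_numpy(bool)
    else:  # ratio_only
        normal_diff = (
            normal["log2_ratio"].abs() >= config.log2_ratio_threshold
        ).to_numpy(bool)

    low_dir = degs["direction"].to_numpy()
    same_sign = np.sign(normal["log2_ratio"].to_numpy()) == np.where(
        low_dir == "up", 1, -1
    )
    status = np.where(
        normal_diff,
        np.where(same_sign, "same_direction", "opposite_direction"),
        "no_difference",
    )

    fold = degs["fold_change"].to_numpy(dtype=float)
    thr = config.rescue_fold_threshold
    beyond = np.where(low_dir == "up", fold > thr, fold < 1.0 / thr)
    category = np.where(
        status == "same_direction",
        "concordant",
        np.where(
            status == "opposite_direction",
            "opposite",
            np.where(beyond, "rescued", "dropped"),
        ),
    )
    return pd.DataFrame(
        {
            "gene_id": degs.index,
            "comparison": comparison,
            "lowP_direction": low_dir,
            "normalP_status": status,
            "lowP_log2_ratio": degs["log2_ratio"].to_numpy(),
            "lowP_fold_change": fold,
            "category": category,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# set accounting
# ---------------------------------------------------------------------------


@dataclass
class UnionAccounting:
    raw_total: int
    distinct_count: int
    #: gene -> names of the sets containing it, for genes in more than one set
    duplicates: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class DEGSetCollection:
    """Named gene-id sets with provenance and non-redundancy accounting."""

    sets: dict[str, frozenset[str]]
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def raw_total(self) -> int:
        return sum(len(s) for s in self.sets.values())

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)

    @property
    def nonredundant_count(self) -> int:
        return len(self.union)

    def accounting(self) -> UnionAccounting:
        return nonredundant_union(self.sets)


def marked_degs(patterns: pd.DataFrame) -> DEGSetCollection:
    """The marked-DEG sets: {rescued} union {opposite}, per comparison.

    ``patterns`` may stack several comparisons; one set per comparison is
    emitted and the collection reports raw (with cross-comparison
    multiplicity) and non-redundant totals.
    """
    marked = patterns[patterns["category"].isin(("rescued", "opposite"))]
    sets: dict[str, frozenset[str]] = {}
    provenance: dict[str, dict] = {}
    for comparison, grp in marked.groupby("comparison", sort=True):
        sets[str(comparison)] = frozenset(grp["gene_id"])
        provenance[str(comparison)] = {
            "categories": ("opposite", "rescued"),
            "n_opposite": int((grp["category"] == "opposite").sum()),
            "n_rescued": int((grp["category"] == "rescued").sum()),
        }
    return DEGSetCollection(sets, provenance)


def nonredundant_union(
    sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
) -> UnionAccounting:
    """Raw and distinct cardinality of a union, with a duplicate report.

    Accepts a name->set mapping or a plain sequence of sets (auto-named).
    The duplicate report lists each gene occurring in more than one set,
    with the names of the sets containing it.
    """
    if not isinstance(sets, Mapping):
        sets = {f"set_{i}": s for i, s in enumerate(sets)}
    membership: dict[str, list[str]] = {}
    raw_total = 0
    for name, genes in sets.items():
        genes = set(genes)
        raw_total += len(genes)
        for g in genes:
            membership.setdefault(g, []).append(name)
    duplicates = {
        g: tuple(names) for g, names in membership.items() if len(names) > 1
    }
    return UnionAccounting(
        raw_total=raw_total,
        distinct_count=len(membership),
        duplicates=duplicates,
    )


def overlap_genes(*sets: Iterable[str]) -> frozenset[str]:
    """Exact intersection of two or more gene-id sets (order-invariant)."""
    if len(sets) < 2:
        raise ValueError("overlap_genes needs at least 2 sets")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return frozenset(out)


def category_counts(patterns: pd.DataFrame) -> pd.DataFrame:
    """Per (comparison, lowP_direction) counts of the four categories plus
    the total — the machine-readable twin of the printed two-way table."""
    rows = []
    for (comparison, direction), grp in patterns.groupby(
        ["comparison", "lowP_direction"], sort=True
    ):
        row = {"comparison": comparison, "lowP_direction": direction}
        for cat in CATEGORIES:
            row[cat] = int((grp["category"] == cat).sum())
        row["no_difference"] = row["rescued"] + row["dropped"]
        row["total"] = len(grp)
        rows.append(row)
    return pd.DataFrame(rows)
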