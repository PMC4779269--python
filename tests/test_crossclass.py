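import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lowphos as lp
from lowphos import crossclass
from lowphos.crossclass import IncompleteInputError

from conftest import make_contrast_table


class TestClassifyPatterns:
    def test_category_assignment_matrix(self, config):
        low = make_contrast_table(
            [
                ("up_conc", 1.5, 0.01, 3),
                ("up_opp", 1.5, 0.01, 3),
                ("up_resc", np.log2(5.0), 0.01, 3),  # 5-fold, > 4
                ("up_drop", np.log2(3.0), 0.01, 3),  # 3-fold, <= 4
                ("down_resc", np.log2(1 / 5), 0.01, 3),
                ("down_drop", np.log2(1 / 3), 0.01, 3),
                ("not_deg", 0.2, 0.8, 3),
            ]
        )
        norm = make_contrast_table(
            [
                ("up_conc", 1.2, 0.01, 3),
                ("up_opp", -1.2, 0.01, 3),
                ("up_resc", 0.1, 0.9, 3),
                ("up_drop", 0.0, 1.0, 3),
                ("down_resc", 0.1, 0.9, 3),
                ("down_drop", 0.2, 0.9, 3),
                ("not_deg", 0.0, 1.0, 3),
            ]
        )
        pat = lp.classify_patterns(low, norm, config, comparison="m")
        got = pat.set_index("gene_id")["category"].to_dict()
        assert got == {
            "up_conc": "concordant",
            "up_opp": "opposite",
            "up_resc": "rescued",
            "up_drop": "dropped",
            "down_resc": "rescued",
            "down_drop": "dropped",
        }
        assert "not_deg" not in set(pat["gene_id"])

    def test_rescue_threshold_is_strict(self, config):
        low = make_contrast_table([("g4", 2.0, 0.01, 3)])  # exactly 4-fold
        norm = make_contrast_table([("g4", 0.0, 1.0, 3)])
        pat = lp.classify_patterns(low, norm, config)
        assert pat.loc[0, "category"] == "dropped"

    def test_missing_normal_record_is_an_error(self, config):
        low = make_contrast_table([("g1", 1.5, 0.01, 3)])
        norm = make_contrast_table([("other", 0.0, 1.0, 3)])
        with pytest.raises(IncompleteInputError, match="g1"):
            lp.classify_patterns(low, norm, config)

    def test_ratio_only_mode_uses_threshold_not_criteria(self):
        cfg = lp.PipelineConfig(normal_no_difference="ratio_only")
        # |normal lfc| = 1.2 >= 1 counts as a difference even though the
        # normal-P q-value fails the DEG criteria
        low = make_contrast_table([("g1", 1.5, 0.01, 3)])
        norm = make_contrast_table([("g1", 1.2, 0.9, 3)])
        pat = lp.classify_patterns(low, norm, cfg)
        assert pat.loc[0, "category"] == "concordant"


class TestMarkedDegs:
    def test_marked_is_exactly_opposite_union_rescued(self, config):
        low = make_contrast_table(
            [
                ("a", 1.5, 0.01, 3),
                ("b", np.log2(6), 0.01, 3),
                ("c", 1.5, 0.01, 3),
                ("d", 1.2, 0.01, 3),
            ]
        )
        norm = make_contrast_table(
            [
                ("a", -1.5, 0.01, 3),  # opposite
                ("b", 0.0, 1.0, 3),  # rescued
                ("c", 1.5, 0.01, 3),  # concordant
                ("d", 0.0, 1.0, 3),  # dropped
            ]
        )
        pat = lp.classify_patterns(low, norm, config, comparison="cmp")
        marked = lp.marked_degs(pat)
        assert marked.sets["cmp"] == frozenset({"a", "b"})
        concordant = set(pat.loc[pat["category"] == "concordant", "gene_id"])
        assert not (set(marked.union) & concordant)

    def test_no_opposite_or_rescued_gives_empty_collection(self, config):
        low = make_contrast_table([("a", 1.5, 0.01, 3)])
        norm = make_contrast_table([("a", 1.5, 0.01, 3)])
        marked = lp.marked_degs(lp.classify_patterns(low, norm, config, "cmp"))
        assert marked.raw_total == 0 or marked.sets["cmp"] == frozenset()


class TestSetAccounting:
    def test_disjoint_sets(self):
        acc = lp.nonredundant_union([{"a", "b"}, {"c", "d", "e"}])
        assert (acc.raw_total, acc.distinct_count) == (5, 5)
        assert acc.duplicates == {}

    def test_identical_sets_double_raw_count(self):
        acc = lp.nonredundant_union({"x": {"a", "b"}, "y": {"a", "b"}})
        assert (acc.raw_total, acc.distinct_count) == (4, 2)
        assert set(acc.duplicates) == {"a", "b"}

    def test_raw_equals_distinct_plus_multiplicity_excess(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(50)]
        sets = {
            f"s{j}": set(rng.choice(pool, size=rng.integers(5, 30), replace=False))
            for j in range(4)
        }
        acc = lp.nonredundant_union(sets)
        excess = sum(len(names) - 1 for names in acc.duplicates.values())
        assert acc.raw_total == acc.distinct_count + excess

    def test_overlap_examples(self):
        assert lp.overlap_genes({"g1", "g2", "g3"}, {"g2", "g3", "g4"}) == {"g2", "g3"}
        assert lp.overlap_genes({"g1"}, set()) == frozenset()

    @given(
        a=st.frozensets(st.integers(0, 30)),
        b=st.frozensets(st.integers(0, 30)),
        c=st.frozensets(st.integers(0, 30)),
    )
    @settings(max_examples=50, deadline=None)
    def test_overlap_is_commutative_associative_and_bounded(self, a, b, c):
        abc = lp.overlap_genes(a, b, c)
        assert abc == lp.overlap_genes(c, a, b)
        assert abc == lp.overlap_genes(lp.overlap_genes(a, b), c)
        assert len(lp.overlap_genes(a, b)) <= min(len(a), len(b))


class TestPartitionIdentity:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_categories_partition_the_lowp_degs(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        genes = [f"g{i}" for i in range(n)]
        low = make_contrast_table(
            [
                (
                    g,
                    float(rng.normal(0, 2)),
                    float(rng.uniform(0, 0.2)),
                    int(rng.choice([2, 3])),
                )
                for g in genes
            ]
        )
        norm = make_contrast_table(
            [
                (
                    g,
                    float(rng.normal(0, 2)),
                    float(rng.uniform(0, 1)),
                    3,
                )
                for g in genes
            ]
        )
        cfg = lp.PipelineConfig()
        pat = lp.classify_patterns(low, norm, cfg, comparison="cmp")
        n_degs = int(low["is_deg"].sum())
        counts = pat["category"].value_counts()
        assert counts.sum() == n_degs
        assert (pat.groupby("gene_id").size() == 1).all()


class TestPrintedTableFixtures:
    def test_two_way_table_category_counts(self, config):
        fixtures = lp.simulate_table2_fixture()
        frames = [
            lp.classify_patterns(low, norm, config, comparison=cmp)
            for cmp, (low, norm) in fixtures.items()
        ]
        pat = pd.concat(frames, ignore_index=True)
        counts = lp.category_counts(pat).set_index(["comparison", "lowP_direction"])
        expect = {
            ("material_roots", "up"): (941, 10, 93, 733, 1777),
            ("material_roots", "down"): (610, 0, 14, 310, 934),
            ("material_leaves", "up"): (2636, 1, 40, 935, 3612),
            ("material_leaves", "down"): (1040, 0, 38, 488, 1566),
            ("tissue_tolerant", "up"): (5137, 1, 97, 1135, 6370),
            ("tissue_tolerant", "down"): (4696, 0, 19, 874, 5589),
            ("tissue_sensitive", "up"): (6149, 0, 63, 1144, 7356),
            ("tissue_sensitive", "down"): (4156, 0, 73, 1002, 5231),
        }
        for key, (conc, opp, resc, drop, total) in expect.items():
            row = counts.loc[key]
            assert (
                row["concordant"],
                row["opposite"],
                row["rescued"],
                row["dropped"],
                row["total"],
            ) == (conc, opp, resc, drop, total)

    def test_marked_deg_counts(self, config):
        fixtures = lp.simulate_table2_fixture()
        frames = [
            lp.classify_patterns(low, norm, config, comparison=cmp)
            for cmp, (low, norm) in fixtures.items()
        ]
        pat = pd.concat(frames, ignore_index=True)
        material = lp.marked_degs(pat[pat["comparison"].str.startswith("material")])
        tissue = lp.marked_degs(pat[pat["comparison"].str.startswith("tissue")])
        assert material.raw_total == 196
        assert material.nonredundant_count == 195
        assert tissue.raw_total == 253
        assert tissue.nonredundant_count == 253

    def test_treatment_union_accounting(self):
        sets = lp.simulate_table1_fixture()
        acc = lp.nonredundant_union(sets)
        assert acc.raw_total == 319
        assert acc.distinct_count == 317
        assert len(acc.duplicates) == 2

    def test_engineered_overlap_cardinalities(self):
        ov = lp.simulate_overlap_fixture()
        assert len(lp.overlap_genes(ov["treatment"], ov["marked_material"])) == 85
        assert len(lp.overlap_genes(ov["treatment"], ov["marked_tissue"])) == 68
        assert len(lp.overlap_genes(*ov.values())) == 42
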