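import statistics
from itertools import combinations
from math import sqrt

import numpy as np
import pandas as pd
import pytest

import lowphos as lp
from lowphos import detest
from lowphos.io import ExpressionMatrix


def toy_matrix(seed=0, genes=8, samples=6):
    rng = np.random.default_rng(seed)
    vals = rng.normal(8, 1, size=(genes, samples))
    vals[:3, :3] += 2.5  # a few shifted genes
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(genes)],
            columns=[f"s{j}" for j in range(samples)],
        )
    )


def brute_force_pooled_p(values, s0):
    """Independent oracle: enumerate all C(6,3)=20 balanced relabelings with
    plain-python arithmetic and pool the null across genes."""

    def d_of(vals, exp_idx):
        ctl_idx = [i for i in range(6) if i not in exp_idx]
        x = [vals[i] for i in exp_idx]
        y = [vals[i] for i in ctl_idx]
        diff = statistics.mean(x) - statistics.mean(y)
        ss = sum((v - statistics.mean(x)) ** 2 for v in x) + sum(
            (v - statistics.mean(y)) ** 2 for v in y
        )
        s = sqrt((1 / 3 + 1 / 3) * ss / 4)
        return diff / (s + s0)

    labelings = list(combinations(range(6), 3))
    observed = [d_of(row, (0, 1, 2)) for row in values]
    null = [abs(d_of(row, lab)) for row in values for lab in labelings]
    total = len(null)
    ps = []
    for d in observed:
        exceed = sum(1 for v in null if v >= abs(d))
        ps.append((1 + exceed) / (1 + total))
    return ps


class TestSamD:
    def test_equal_means_give_zero(self):
        assert lp.sam_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=0.5) == pytest.approx(0.0)

    def test_hand_arithmetic_zero_variance_groups(self):
        # pooled s = 0, so d = (2 - 0) / (0 + 1) = 2
        assert lp.sam_d([2.0, 2.0, 2.0], [0.0, 0.0, 0.0], s0=1.0) == pytest.approx(2.0)

    def test_antisymmetric_under_group_swap(self):
        x, y = [4.0, 5.0, 6.0], [1.0, 2.0, 2.5]
        assert lp.sam_d(x, y, 0.3) == pytest.approx(-lp.sam_d(y, x, 0.3))

    def test_shrinks_toward_zero_as_s0_grows(self):
        x, y = [4.0, 5.0, 6.0], [1.0, 2.0, 2.5]
        assert abs(lp.sam_d(x, y, 2.0)) < abs(lp.sam_d(x, y, 0.1))

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError, match="2 values"):
            lp.sam_d([1.0], [2.0, 3.0], 0.1)

    def test_invariant_to_adding_constant_to_all_values(self):
        x, y = np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 2.5])
        assert lp.sam_d(x + 100, y + 100, 0.3) == pytest.approx(lp.sam_d(x, y, 0.3))


class TestChooseS0:
    def test_identical_s_returns_smallest_candidate(self):
        diff = np.array([1.0, -2.0, 0.5, 3.0])
        s = np.full(4, 0.7)
        assert lp.choose_s0(diff, s) == 0.0

    def test_deterministic_on_null_data(self):
        rng = np.random.default_rng(7)
        diff = rng.normal(0, 0.3, 2000)
        s = rng.gamma(4, 0.05, 2000)
        assert lp.choose_s0(diff, s) == lp.choose_s0(diff.copy(), s.copy())

    def test_low_variance_contamination_forces_positive_s0(self):
        rng = np.random.default_rng(8)
        n = 2000
        s = rng.gamma(4, 0.05, n)
        s[: n // 10] = 1e-6  # 10% of genes with near-zero spread
        diff = rng.normal(0, 0.3, n)
        assert lp.choose_s0(diff, s) > 0

    def test_all_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert lp.choose_s0(np.zeros(5), np.zeros(5)) == 0.0


class TestPermutationPValues:
    def test_exhaustive_matches_brute_force_enumeration(self):
        matrix = toy_matrix(seed=1)
        contrast = lp.ContrastSpec("t", ("s0", "s1", "s2"), ("s3", "s4", "s5"))
        params = lp.SamParameters(s0=0.1, n_permutations=20)
        p = lp.permutation_pvalues(matrix, contrast, params)
        expected = brute_force_pooled_p(matrix.values.to_numpy(), s0=0.1)
        np.testing.assert_allclose(p.to_numpy(), expected, rtol=1e-12)

    def test_constant_gene_has_p_one(self):
        matrix = toy_matrix(seed=2)
        vals = matrix.values.copy()
        vals.loc["g0"] = 5.0
        matrix = ExpressionMatrix(vals)
        contrast = lp.ContrastSpec("t", ("s0", "s1", "s2"), ("s3", "s4", "s5"))
        p = lp.permutation_pvalues(matrix, contrast, lp.SamParameters(s0=0.2))
        assert p.loc["g0"] == pytest.approx(1.0)

    def test_subsampled_permutations_reproducible_by_seed(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(30, 10))
        matrix = ExpressionMatrix(
            pd.DataFrame(
                vals,
                index=[f"g{i}" for i in range(30)],
                columns=[f"s{j}" for j in range(10)],
            )
        )
        contrast = lp.ContrastSpec(
            "t", tuple(f"s{j}" for j in range(5)), tuple(f"s{j}" for j in range(5, 10))
        )
        params = lp.SamParameters(s0=0.1, n_permutations=50, rng_seed=42)
        p1 = lp.permutation_pvalues(matrix, contrast, params)
        p2 = lp.permutation_pvalues(matrix, contrast, params)
        pd.testing.assert_series_equal(p1, p2)
        assert ((p1 > 0) & (p1 <= 1)).all()


class TestFdrAdjust:
    def test_step_up_rule_hand_case(self):
        # every p_i * 4 / i equals 0.04, so all q are 0.04
        np.testing.assert_allclose(
            lp.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(lp.fdr_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(lp.fdr_adjust([0.03]), [0.03])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        q = lp.fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lp.fdr_adjust([0.5, 1.5])


class TestSamQValues:
    def test_monotone_nonincreasing_in_abs_d(self):
        rng = np.random.default_rng(10)
        d_obs = rng.normal(size=300)
        d_star = rng.normal(size=(20, 300))
        q = detest.sam_qvalues(d_obs, d_star)
        order = np.argsort(np.abs(d_obs))
        assert (np.diff(q[order]) <= 1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc,q,reps,expected",
        [
            (1.0, 0.01, 3, "up"),  # minimum admissible up fold change, 2.00
            (0.9, 0.001, 3, "none"),  # fails the ratio criterion
            (-2.0, 0.2, 3, "none"),  # fails the FDR criterion
            (-1.5, 0.01, 2, "none"),  # fails the replicate criterion
            (-1.5, 0.01, 3, "down"),
        ],
    )
    def test_three_part_criterion(self, config, lfc, q, reps, expected):
        table = pd.DataFrame(
            {
                "log2_ratio": [lfc],
                "fold_change": [2.0**lfc],
                "q_value": [q],
                "n_complete_replicates": [reps],
            },
            index=["g1"],
        )
        out = lp.call_degs(table, config)
        assert out.loc["g1", "direction"] == expected
        assert out.loc["g1", "is_deg"] == (expected != "none")

    def test_minimum_up_deg_has_fold_change_two(self, config):
        table = pd.DataFrame(
            {
                "log2_ratio": [1.0],
                "fold_change": [2.0],
                "q_value": [0.01],
                "n_complete_replicates": [3],
            },
            index=["g1"],
        )
        out = lp.call_degs(table, config)
        assert out.loc["g1", "fold_change"] == pytest.approx(2.00)
        assert out.loc["g1", "is_deg"]
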