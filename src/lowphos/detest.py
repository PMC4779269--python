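"""Two-group differential expression with a SAM-style permutation test.

For each gene the moderated statistic ``d = (mean_exp - mean_ctl) / (s + s0)``
is computed, where ``s`` is the pooled standard error of the mean difference
and ``s0`` is the exchangeability ("fudge") constant that stabilizes genes
with tiny variance. The null distribution of ``d`` comes from balanced
relabelings of the sample columns, pooled across genes; with 3 vs 3 groups
all C(6,3) = 20 relabelings are enumerated so the null is exact.

Two FDR routes are available:

* ``"sam"`` (default) — SAM's own q-value: at each |d| threshold the number
  of false calls is estimated by the median count of permuted |d*| values
  exceeding the threshold, divided by the observed call count; q-values are
  made monotone by a cumulative minimum from liberal to strict thresholds.
* ``"bh"`` — Benjamini-Hochberg step-up adjustment of the pooled
  permutation p-values.

A gene is a DEG when all three criteria hold: |log2 ratio| >= threshold
(default 1, i.e. 2-fold), FDR-adjusted significance below alpha (default
0.05), and complete replicate measurements in both groups (default 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PipelineConfig


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison: experimental over control sample columns."""

    name: str
    experimental: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.experimental) & set(self.control):
            raise ValueError(f"contrast {self.name}: groups overlap")
        if len(self.experimental) < 2 or len(self.control) < 2:
            raise ValueError(
                f"contrast {self.name}: each group needs >=2 samples"
            )


@dataclass
class SamParameters:
    s0: float | None = None  # None -> choose by the CV rule
    n_permutations: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 is not None and self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


# ---------------------------------------------------------------------------
# the d statistic
# ---------------------------------------------------------------------------


def _diff_and_se(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean difference and pooled standard error for G x n arrays."""
    n1, n2 = X.shape[1], Y.shape[1]
    diff = X.mean(axis=1) - Y.mean(axis=1)
    ss = ((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (Y - Y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return diff, s


def sam_d(
    gene_values_exp: np.ndarray, gene_values_ctl: np.ndarray, s0: float
) -> float:
    """SAM d for one gene: mean difference over (pooled SE + s0).

    Antisymmetric under swapping the groups; shrinks toward 0 as ``s0``
    grows. Each group needs at least two finite values.
    """
    x = np.asarray(gene_values_exp, dtype=float)
    y = np.asarray(gene_values_ctl, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >=2 values (variance undefined)")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    diff, s = _diff_and_se(x[None, :], y[None, :])
    denom = s[0] + s0
    if denom == 0:
        return 0.0 if diff[0] == 0 else np.sign(diff[0]) * np.inf
    return float(diff[0] / denom)


def choose_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """The SAM fudge factor: the candidate minimizing the coefficient of
    variation of the spread of d across bins of s.

    Candidates are 0 and the 0th..100th percentiles (step 5) of ``s``. For
    each candidate the genes are cut into up to 100 quantile bins of ``s``;
    within each bin the median absolute deviation of ``d = diff / (s + s0)``
    is taken, and the candidate minimizing the CV of those MADs wins. Ties
    (including fully degenerate inputs) resolve to the smallest candidate.
    """
    diff = np.asarray(diff, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.all(s == 0):
        warnings.warn("all genes have zero variance; s0 set to 0")
        return 0.0
    candidates = np.unique(
        np.concatenate([[0.0], np.percentile(s, np.arange(0, 101, 5))])
    )
    edges = np.unique(np.quantile(s, np.linspace(0, 1, 101)))
    # digitize into quantile bins of s (at most 100 bins)
    bin_idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2) \
        if len(edges) > 1 else np.zeros(len(s), dtype=int)

    best_alpha, best_cv = None, np.inf
    for alpha in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = diff / (s + alpha)
        if not np.isfinite(d).all():
            continue
        mads = []
        for b in np.unique(bin_idx):
            db = d[bin_idx == b]
            mads.append(1.4826 * np.median(np.abs(db - np.median(db))))
        mads = np.asarray(mads)
        mean = mads.mean()
        cv = 0.0 if mean == 0 else mads.std() / mean
        if not np.isfinite(cv):
            continue
        if cv < best_cv - 1e-12:  # strict improvement; ties keep smaller alpha
            best_alpha, best_cv = float(alpha), cv
    if best_alpha is None:
        warnings.warn("degenerate d distribution; s0 set to 0")
        return 0.0
    return best_alpha


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def balanced_relabelings(n_exp: int, n_ctl: int) -> list[tuple[int, ...]]:
    """All ways to choose ``n_exp`` of the pooled columns as 'experimental'.

    The original labeling is element 0. With 3 vs 3 there are C(6,3) = 20.
    """
    return list(combinations(range(n_exp + n_ctl), n_exp))


def permutation_d(
    X: np.ndarray, Y: np.ndarray, params: SamParameters, s0: float
) -> np.ndarray:
    """d statistics for every (relabeling, gene): a B x G array.

    When the requested number of permutations is at least the exhaustive
    count, all balanced relabelings are used; otherwise a seeded random
    subsample without replacement.
    """
    n1, n2 = X.shape[1], Y.shape[1]
    total = comb(n1 + n2, n1)
    if total < 2:
        raise ValueError("fewer than 2 distinct relabelings possible")
    labelings = balanced_relabelings(n1, n2)
    if params.n_permutations < total:
        rng = np.random.default_rng(params.rng_seed)
        pick = rng.choice(total, size=params.n_permutations, replace=False)
        labelings = [labelings[i] for i in sorted(pick)]
    pooled = np.hstack([X, Y])
    d_star = np.empty((len(labelings), X.shape[0]))
    for b, exp_idx in enumerate(labelings):
        ctl_idx = tuple(i for i in range(n1 + n2) if i not in exp_idx)
        diff, s = _diff_and_se(pooled[:, exp_idx], pooled[:, ctl_idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            d_star[b] = np.where(s + s0 == 0, 0.0, diff / (s + s0))
    return d_star


def pooled_permutation_pvalues(d_obs: np.ndarray, d_star: np.ndarray) -> np.ndarray:
    """p = (1 + #{(b, g'): |d*| >= |d_obs|}) / (1 + B*G), pooled across genes."""
    flat = np.sort(np.abs(d_star).ravel())
    total = flat.size
    exceed = total - np.searchsorted(flat, np.abs(d_obs), side="left")
    return (1.0 + exceed) / (1.0 + total)


def sam_qvalues(
    d_obs: np.ndarray, d_star: np.ndarray, pi0: float = 1.0
) -> np.ndarray:
    """SAM q-values from the permutation null.

    At threshold t = |d| of each gene, the estimated false-call count is the
    median over relabelings of the number of permuted |d*| >= t; dividing by
    the observed call count gives the FDR at t. Each gene's q is the
    smallest FDR over all thresholds liberal enough to include it, so q is
    monotone nonincreasing in |d| and capped at 1.
    """
    abs_d = np.abs(d_obs)
    thresholds = abs_d
    sorted_rows = np.sort(np.abs(d_star), axis=1)
    counts = sorted_rows.shape[1] - np.vstack(
        [np.searchsorted(row, thresholds, side="left") for row in sorted_rows]
    )
    v = np.median(counts, axis=0)
    sorted_obs = np.sort(abs_d)
    r = abs_d.size - np.searchsorted(sorted_obs, thresholds, side="left")
    raw = np.minimum(1.0, pi0 * v / np.maximum(r, 1))
    order = np.argsort(abs_d, kind="stable")  # liberal -> strict
    q = raw.copy()
    q[order] = np.minimum.accumulate(raw[order])
    return q


def permutation_pvalues(
    matrix: ExpressionMatrix, contrast: ContrastSpec, params: SamParameters
) -> pd.Series:
    """Pooled permutation p-values for every gene of ``matrix``."""
    X = matrix.values[list(contrast.experimental)].to_numpy(dtype=float)
    Y = matrix.values[list(contrast.control)].to_numpy(dtype=float)
    diff, s = _diff_and_se(X, Y)
    s0 = choose_s0(diff, s) if params.s0 is None else params.s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d_obs = np.where(s + s0 == 0, 0.0, diff / (s + s0))
    d_star = permutation_d(X, Y, params, s0)
    p = pooled_permutation_pvalues(d_obs, d_star)
    return pd.Series(p, index=matrix.values.index, name="p_value")


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full contrast table and DEG calling
# ---------------------------------------------------------------------------


def test_contrast(
    matrix: ExpressionMatrix,
    contrast: ContrastSpec,
    config: PipelineConfig,
    params: SamParameters | None = None,
) -> pd.DataFrame:
    """Per-gene statistics for one contrast, with the DEG call applied.

    Columns: gene_id (index), mean_experimental, mean_control, log2_ratio,
    fold_change, d_statistic, p_value, q_value, n_complete_replicates,
    is_deg, direction.
    """
    if params is None:
        params = SamParameters(
            s0=config.s0,
            n_permutations=config.permutations,
            rng_seed=config.rng_seed,
        )
    missing = [
        c
        for c in (*contrast.experimental, *contrast.control)
        if c not in matrix.values.columns
    ]
    if missing:
        raise ValueError(f"contrast {contrast.name}: samples not in matrix: {missing}")
    X = matrix.values[list(contrast.experimental)].to_numpy(dtype=float)
    Y = matrix.values[list(contrast.control)].to_numpy(dtype=float)
    diff, s = _diff_and_se(X, Y)
    s0 = choose_s0(diff, s) if params.s0 is None else params.s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d_obs = np.where(s + s0 == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), diff / (s + s0))
    d_star = permutation_d(X, Y, SamParameters(s0=s0, n_permutations=params.n_permutations, rng_seed=params.rng_seed), s0)
    p = pooled_permutation_pvalues(d_obs, d_star)
    if config.fdr_method == "sam":
        q = sam_qvalues(d_obs, d_star)
    else:
        q = fdr_adjust(p)
    n_complete = np.minimum(
        np.isfinite(X).sum(axis=1), np.isfinite(Y).sum(axis=1)
    )
    result = pd.DataFrame(
        {
            "mean_experimental": X.mean(axis=1),
            "mean_control": Y.mean(axis=1),
            "log2_ratio": diff,
            "fold_change": np.exp2(diff),
            "d_statistic": d_obs,
            "p_value": p,
            "q_value": q,
            "n_complete_replicates": n_complete,
        },
        index=matrix.values.index,
    )
    result.index.name = "gene_id"
    result.attrs["contrast"] = contrast.name
    result.attrs["s0"] = s0
    return call_degs(result, config)


def call_degs(results: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply the three-part DEG criterion and set direction.

    A gene is a DEG iff |log2 ratio| >= threshold, q < alpha and complete
    replicates exist in both groups.
    """
    out = results.copy()
    is_deg = (
        (out["log2_ratio"].abs() >= config.log2_ratio_threshold)
        & (out["q_value"] < config.fdr_alpha)
        & (out["n_complete_replicates"] >= config.min_replicates)
    )
    out["is_deg"] = is_deg
    out["direction"] = np.where(
        ~is_deg, "none", np.where(out["log2_ratio"] > 0, "up", "down")
    )
    return out


def deg_sets(results: pd.DataFrame) -> dict[str, frozenset[str]]:
    """The up and down DEG id sets of one contrast table."""
    up = frozenset(results.index[results["direction"] == "up"])
    down = frozenset(results.index[results["direction"] == "down"])
    return {"up": up, "down": down}
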