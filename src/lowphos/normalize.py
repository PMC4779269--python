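"""Between-array normalization and probe-to-gene summarization.

Two of the three RMA components are provided: quantile normalization
(forcing every array onto one shared empirical intensity distribution) and
Tukey median polish (the robust two-way fit RMA uses to summarize a gene's
probe block into one value per array). Probe-level background correction is
out of scope; the pipeline accepts matrices already summarized to one row
per transcript.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FormatError


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the shared rank-mean distribution.

    The reference distribution is the across-column mean of the sorted
    values at each rank. Tied values within a column receive the mean of
    the reference values over their rank span (same convention as limma's
    ``normalizeQuantiles``), which makes the result independent of input
    row order.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite values")

    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    from scipy.stats import rankdata

    for j in range(n_samples):
        ranks = rankdata(X[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, normalized=True)


def median_polish(
    block: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's two-way median polish of a probes-x-samples block.

    Returns ``(overall, row_effects, col_effects, residuals)`` with
    ``block ~= overall + row_effects[:, None] + col_effects[None, :] +
    residuals``. Iterates until the largest absolute change in the
    residuals falls below ``tol`` or ``max_iter`` sweeps have run.
    """
    z = np.asarray(block, dtype=float).copy()
    if z.ndim != 2:
        raise ValueError("median_polish expects a 2-d array")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        previous = z.copy()
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta
        if np.max(np.abs(z - previous)) < tol:
            break
    return overall, row, col, z


def median_polish_summarize(
    probe_values: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    tol: float = 1e-6,
    max_iter: int = 20,
) -> ExpressionMatrix:
    """Summarize a probes-x-samples matrix to one row per gene.

    Each gene's probe block gets a median-polish fit; the gene's value on
    each array is ``overall + column effect`` (the chip effect of the
    additive decomposition). Every probe must map to exactly one gene.
    """
    unmapped = [p for p in probe_values.index if p not in probe_to_gene]
    if unmapped:
        raise FormatError(f"probes without a gene mapping: {unmapped}")
    genes: dict[str, list[str]] = {}
    for probe in probe_values.index:
        genes.setdefault(probe_to_gene[probe], []).append(probe)
    rows = {}
    for gene in genes:
        block = probe_values.loc[genes[gene]].to_numpy(dtype=float)
        overall, _, col, _ = median_polish(block, tol=tol, max_iter=max_iter)
        rows[gene] = overall + col
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=probe_values.columns)
    return ExpressionMatrix(frame)
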