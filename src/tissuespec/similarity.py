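"""Pairwise Spearman correlation QC between samples or tissue profiles.

Spearman's rank correlation is invariant under monotone transforms, so the
matrix is identical whether computed on raw FPKM or on log2(FPKM + 1).
Two gene-selection modes are supported: the full gene set, or per pair the
genes detected (FPKM >= cutoff) in at least one of the two columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def spearman_matrix(
    matrix: pd.DataFrame,
    gene_filter: str = "all",
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Spearman correlations between columns.

    Ties receive average ranks. A pair whose selected values are constant
    in either column gets ``nan`` (correlation undefined).

    Parameters
    ----------
    matrix
        Genes-by-samples FPKM table (>= 3 genes, >= 2 columns).
    gene_filter
        ``"all"`` uses every gene for every pair; ``"detected_in_either"``
        restricts each pair to genes at or above ``cutoff`` in at least
        one of its two columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    if matrix.shape[0] < 3:
        raise ValueError("need at least three genes")
    if gene_filter not in ("all", "detected_in_either"):
        raise ValueError(f"unknown gene_filter {gene_filter!r}")

    ids = list(matrix.columns)
    n = len(ids)
    values = matrix.to_numpy(dtype=float)
    out = np.eye(n)
    if gene_filter == "all":
        with warnings.catch_warnings():
            # constant columns get the NaN sentinel by design
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(values).statistic
        if n == 2:  # scipy returns a scalar for two columns
            rho = np.array([[1.0, rho], [rho, 1.0]])
        out = np.asarray(rho, dtype=float)
        np.fill_diagonal(out, 1.0)
    else:
        detected = values >= cutoff
        for i in range(n):
            for j in range(i + 1, n):
                keep = detected[:, i] | detected[:, j]
                if keep.sum() < 3:
                    rho = np.nan
                else:
                    rho = stats.spearmanr(
                        values[keep, i], values[keep, j]).statistic
                out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=ids, columns=ids)
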