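"""Bulk two-group differential expression with a threshold decision rule.

Counts are normalized by median-of-ratios size factors, log2(x+1)
transformed, and tested per gene with a two-sided Welch t-test.  A gene
is differentially expressed when p < alpha and |log2 fold change| >= the
cutoff (boundary inclusive).  A BH-adjusted p column is emitted for
transparency but does not enter the call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, the factor is the median over genes (with a
    positive geometric mean across samples) of count_gj / geomean_g.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be genes x samples")
    if x.shape[1] == 1:
        return np.ones(1)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    log_geomean = logx.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has a nonzero count in every sample")
    ratios = logx[usable] - log_geomean[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.log(factors).mean())
    return factors


def _welch(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values per row; degenerate rows resolved.

    Rows where both groups have zero variance get p = 1 when the means
    are equal and p = 0 otherwise (rather than NaN).
    """
    res = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(xb.mean(axis=1), xa.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def de_test(
    counts: pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DE table between the two groups of ``groups``.

    log2fc is mean(log2(norm+1)) in group B minus group A, where group A
    is the alphabetically first label.  Returns a frame indexed by gene
    with ``log2fc``, ``p``, ``p_adj_bh`` and ``is_deg``.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    lab_a, lab_b = labels
    cols_a = [c for c in counts.columns if groups.get(c) == lab_a]
    cols_b = [c for c in counts.columns if groups.get(c) == lab_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    sub = counts[cols_a + cols_b]
    factors = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / factors
    x = np.log2(norm + 1.0)
    xa, xb = x[:, : len(cols_a)], x[:, len(cols_a):]
    log2fc = xb.mean(axis=1) - xa.mean(axis=1)
    p = _welch(xa, xb)
    p_adj = stats.false_discovery_control(p, method="bh")
    is_deg = (p < alpha) & (np.abs(log2fc) >= min_abs_lfc)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj_bh": p_adj, "is_deg": is_deg},
        index=counts.index,
    )


def overlap_counts(
    deg_sets_by_tissue: dict[str, set[str]],
    sv_gene_list: set[str],
) -> pd.DataFrame:
    """Per-tissue |DEG ∩ SV-gene-list| counts as a tidy table."""
    rows = [
        {"tissue": t, "n_deg": len(degs), "n_overlap": len(degs & sv_gene_list)}
        for t, degs in deg_sets_by_tissue.items()
    ]
    return pd.DataFrame(rows, columns=["tissue", "n_deg", "n_overlap"])
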