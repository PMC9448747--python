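"""Association and enrichment statistics linking SV gene lists, DEGs and
single-cell cluster markers.

Covers the chi-square DEG/SV-gene association over a gene universe, the
seven-region three-list Venn decomposition, per-cluster marker-set
enrichment (overlap ratio, within-list z-score normalization, two-sided
Fisher's exact test) and a one-vs-rest two-sided Welch t-test on
membership indicators with a two-proportion z cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    chi2: float
    df: int
    p: float
    table: np.ndarray  # 2x2: (DE yes/no) x (SV yes/no)


def chi_square_association(
    universe: set[str],
    degs: set[str],
    sv_genes: set[str],
    continuity_correction: bool = False,
) -> AssociationResult:
    """Pearson chi-square (df=1) for DE status vs SV-carrier status."""
    if not degs <= universe or not sv_genes <= universe:
        raise ValueError("degs and sv_genes must be subsets of the universe")
    both = len(degs & sv_genes)
    de_only = len(degs) - both
    sv_only = len(sv_genes) - both
    neither = len(universe) - both - de_only - sv_only
    table = np.array([[both, de_only], [sv_only, neither]])
    for axis, name in ((0, "column"), (1, "row")):
        margins = table.sum(axis=axis)
        if (margins == 0).any():
            raise ValueError(f"degenerate 2x2 table: zero {name} margin {margins.tolist()}")
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return AssociationResult(float(res.statistic), int(res.dof), float(res.pvalue), table)


def venn_counts(list1, list2, list3) -> dict[str, int]:
    """Counts of the 7 disjoint regions of a three-set Venn diagram.

    Keys are membership masks over (list1, list2, list3), e.g. ``"110"``
    = in lists 1 and 2 only.
    """
    s1, s2, s3 = set(list1), set(list2), set(list3)
    out = {f"{a}{b}{c}": 0 for a in "01" for b in "01" for c in "01" if a + b + c != "000"}
    for g in s1 | s2 | s3:
        key = f"{int(g in s1)}{int(g in s2)}{int(g in s3)}"
        out[key] += 1
    return out


def marker_enrichment(
    marker_table: pd.DataFrame,
    gene_lists: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Per-(cluster, gene list) marker-set enrichment table.

    For each cluster's marker set M and list L: ``ratio = |M ∩ L| / |M|``;
    two-sided Fisher's exact test on the 2x2 table
    ``[[|M∩L|, |M\\L|], [|L\\M|, |universe \\ (M∪L)|]]``; and a
    ``normalized_ratio`` z-scored across clusters within each list.
    Clusters without markers yield undefined ratios with a warning.
    """
    clusters = sorted(marker_table["cluster_id"].unique())
    markers = {
        cl: set(marker_table.loc[marker_table["cluster_id"] == cl, "gene_id"]) & universe
        for cl in clusters
    }
    rows = []
    for list_name in sorted(gene_lists):
        L = gene_lists[list_name] & universe
        for cl in clusters:
            M = markers[cl]
            if not M:
                warnings.warn(f"cluster {cl} has zero markers in the universe")
                rows.append((cl, list_name, 0, 0, np.nan, np.nan, np.nan, np.nan))
                continue
            overlap = len(M & L)
            table = [
                [overlap, len(M) - overlap],
                [len(L) - overlap, len(universe) - len(M | L)],
            ]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append((cl, list_name, len(M), overlap, overlap / len(M),
                         np.nan, float(odds), float(p)))
    df = pd.DataFrame(
        rows,
        columns=["cluster_id", "list", "marker_count", "overlap",
                 "ratio", "normalized_ratio", "fisher_odds", "fisher_p"],
    )
    for list_name, grp in df.groupby("list"):
        r = grp["ratio"].to_numpy(dtype=float)
        ok = np.isfinite(r)
        if ok.sum() >= 2 and np.nanstd(r[ok], ddof=0) > 0:
            z = (r - np.nanmean(r[ok])) / np.nanstd(r[ok], ddof=0)
        else:
            z = np.where(ok, 0.0, np.nan)
        df.loc[grp.index, "normalized_ratio"] = z
    return df


@dataclass
class RatioTestResult:
    t: float
    df: float
    p: float
    z: float
    z_p: float
    rate_cluster: float
    rate_rest: float


def one_vs_rest_ratio_test(
    marker_table: pd.DataFrame,
    gene_list: set[str],
    cluster_id,
) -> RatioTestResult:
    """Two-sided Welch t-test on list-membership indicators of one
    cluster's markers vs the pooled markers of all other clusters,
    with an equivalent two-proportion z-test alongside."""
    in_cl = marker_table["cluster_id"] == cluster_id
    genes_cl = marker_table.loc[in_cl, "gene_id"].tolist()
    genes_rest = marker_table.loc[~in_cl, "gene_id"].tolist()
    if len(genes_cl) < 2 or len(genes_rest) < 2:
        raise ValueError("need >= 2 markers in the cluster and in the rest")
    x = np.array([g in gene_list for g in genes_cl], dtype=float)
    y = np.array([g in gene_list for g in genes_rest], dtype=float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if v1 == 0 and v2 == 0:
        t = 0.0 if diff == 0 else math.inf * np.sign(diff)
        dof = float(n1 + n2 - 2)
        p = 1.0 if diff == 0 else 0.0
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        t = diff / se
        dof = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p = 2 * stats.t.sf(abs(t), dof)
    pooled = (x.sum() + y.sum()) / (n1 + n2)
    if pooled in (0.0, 1.0):
        z, z_p = 0.0, 1.0
    else:
        se_z = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = diff / se_z
        z_p = 2 * stats.norm.sf(abs(z))
    return RatioTestResult(float(t), float(dof), float(p), float(z), float(z_p),
                           float(x.mean()), float(y.mean()))
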