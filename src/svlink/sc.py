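"""Minimal single-cell processing: QC, log-normalization, graph
clustering, marker detection, cross-species cluster correlation and
simplified joint clustering.

Clustering follows the common toolkit recipe: per-gene scaling (clipped
at ±10), PCA, a shared-nearest-neighbor graph (k=20, Jaccard weights,
pruned at 1/15) and Louvain community detection with a fixed seed.
Marker statistics use a two-sided Wilcoxon rank-sum test with BH
adjustment within each cluster; avg_log_fc is the difference of mean
log-normalized (natural log) values.  Cross-species integration is a
deliberate simplification: each species is scaled independently on
shared orthologs and the cell matrices concatenated before joint PCA.
"""

from __future__ import annotations

import logging
import random as _random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class CellMatrix:
    """Genes x cells integer count matrix with mitochondrial gene flags."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    mito_flags: np.ndarray
    species_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape inconsistent with gene/cell ids")
        if len(self.mito_flags) != len(self.gene_ids):
            raise ValueError("mito_flags length != number of genes")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    # -- I/O ---------------------------------------------------------------
    def to_mtx_dir(self, outdir) -> None:
        """Write MatrixMarket triplet + gene/barcode lists (text files)."""
        import os
        from scipy.io import mmwrite

        os.makedirs(outdir, exist_ok=True)
        mmwrite(os.path.join(outdir, "matrix.mtx"), sparse.coo_matrix(self.counts))
        with open(os.path.join(outdir, "genes.txt"), "w") as fh:
            fh.write("\n".join(self.gene_ids) + "\n")
        with open(os.path.join(outdir, "barcodes.txt"), "w") as fh:
            fh.write("\n".join(self.cell_ids) + "\n")

    @classmethod
    def from_mtx_dir(cls, indir, species_label: str = "", mito_prefix: str = "MT-") -> "CellMatrix":
        import os
        from scipy.io import mmread

        counts = np.asarray(mmread(os.path.join(indir, "matrix.mtx")).todense())
        with open(os.path.join(indir, "genes.txt")) as fh:
            genes = [l.strip() for l in fh if l.strip()]
        with open(os.path.join(indir, "barcodes.txt")) as fh:
            cells = [l.strip() for l in fh if l.strip()]
        mito = np.array([g.startswith(mito_prefix) for g in genes])
        return cls(counts.astype(np.int64), genes, cells, mito, species_label)

    @classmethod
    def from_tsv(cls, path, species_label: str = "", mito_prefix: str = "MT-") -> "CellMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = list(df.index.astype(str))
        mito = np.array([g.startswith(mito_prefix) for g in genes])
        return cls(df.to_numpy(dtype=np.int64), genes, list(df.columns.astype(str)), mito, species_label)


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of log-normalized values."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    species_label: str = ""


def qc_filter(matrix: CellMatrix, min_genes: int, max_mito: float = 0.20) -> CellMatrix:
    """Drop low-quality cells.

    Removes cells with fewer than ``min_genes`` detected (count > 0)
    genes or with a mitochondrial count fraction strictly above
    ``max_mito``; cells exactly at either boundary are kept.
    """
    detected = (matrix.counts > 0).sum(axis=0)
    totals = matrix.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, matrix.counts[matrix.mito_flags].sum(axis=0) / np.maximum(totals, 1), 1.0
        )
    keep = (detected >= min_genes) & (mito_frac <= max_mito)
    if not keep.any():
        raise ValueError(
            f"qc_filter removed all {matrix.n_cells} cells "
            f"(median detected genes {np.median(detected):.0f}, "
            f"median mito fraction {np.median(mito_frac):.3f})"
        )
    return CellMatrix(
        matrix.counts[:, keep],
        list(matrix.gene_ids),
        [c for c, k in zip(matrix.cell_ids, keep) if k],
        matrix.mito_flags,
        matrix.species_label,
    )


def lognormalize(matrix: CellMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """Per-cell total-count scaling to ``scale`` followed by ln(1 + x)."""
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter first")
    values = np.log1p(matrix.counts / totals * scale)
    return ExpressionMatrix(values, list(matrix.gene_ids), list(matrix.cell_ids), matrix.species_label)


def _scale_genes(values: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Per-gene z-scores (rows), clipped; constant genes become zero rows."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[~np.isfinite(z)] = 0.0
    return np.clip(z, -clip, clip)


def _snn_louvain(pcs: np.ndarray, k_neighbors: int, resolution: float, seed: int,
                 prune: float = 1.0 / 15.0) -> np.ndarray:
    """Shared-nearest-neighbor graph + seeded Louvain labels."""
    n = pcs.shape[0]
    if n < k_neighbors:
        raise ValueError(f"{n} cells < k={k_neighbors} neighbors")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (adj @ adj.T).tocoo()
    jac = shared.data / (2 * k_neighbors - shared.data)
    keep = (jac >= prune) & (shared.row < shared.col)
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    weights = jac[keep].tolist()
    g = igraph.Graph(n=n, edges=edges)
    igraph.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.array(part.membership)


def cluster_cells(
    normalized: ExpressionMatrix,
    n_pcs: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
    k_neighbors: int = 20,
    clip: float = 10.0,
) -> np.ndarray:
    """Louvain cluster labels from scaled data via PCA and an SNN graph."""
    z = _scale_genes(normalized.values, clip=clip)
    nonconstant = (z != 0).any(axis=1)
    if nonconstant.sum() < n_pcs:
        raise ValueError(f"need >= {n_pcs} non-constant genes, have {nonconstant.sum()}")
    n_comp = min(n_pcs, z.shape[1] - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(z[nonconstant].T)
    return _snn_louvain(pcs, k_neighbors, resolution, seed)


def find_markers(
    normalized: ExpressionMatrix,
    labels: np.ndarray,
    min_avg_log_fc: float = 1.0,
    max_p_adj: float = 0.05,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """Per-cluster positive marker genes (one cluster vs all other cells).

    Two-sided Wilcoxon rank-sum per gene with BH adjustment across genes
    within the cluster; retained rows satisfy ``p_adj < max_p_adj``,
    ``avg_log_fc > min_avg_log_fc`` (natural-log mean difference) and an
    in-cluster detection fraction of at least ``min_pct``.
    """
    labels = np.asarray(labels)
    values = normalized.values
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("find_markers requires >= 2 clusters")
    rows = []
    for cl in clusters:
        in_cl = labels == cl
        if in_cl.sum() < 2:
            warnings.warn(f"cluster {cl} has fewer than 2 cells; skipped")
            continue
        x, y = values[:, in_cl], values[:, ~in_cl]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0  # fully tied genes
        p_adj = stats.false_discovery_control(p, method="bh")
        lfc = x.mean(axis=1) - y.mean(axis=1)
        pct_in = (x > 0).mean(axis=1)
        pct_out = (y > 0).mean(axis=1)
        keep = (p_adj < max_p_adj) & (lfc > min_avg_log_fc) & (pct_in >= min_pct)
        for i in np.flatnonzero(keep):
            rows.append((int(cl), normalized.gene_ids[i], float(lfc[i]),
                         float(pct_in[i]), float(pct_out[i]), float(p[i]), float(p_adj[i])))
    return pd.DataFrame(
        rows, columns=["cluster_id", "gene_id", "avg_log_fc", "pct_in", "pct_out", "p", "p_adj"]
    )


def cluster_profiles(normalized: ExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Mean log-normalized profile per cluster (genes x clusters)."""
    labels = np.asarray(labels)
    cols = {}
    for cl in np.unique(labels):
        cols[cl] = normalized.values[:, labels == cl].mean(axis=1)
    return pd.DataFrame(cols, index=normalized.gene_ids)


def cross_species_correlation(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    novel_r_threshold: float = 0.31,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between cluster profiles across species.

    Profiles are restricted to ortholog pairs present in both frames.  A
    cluster of species A is flagged novel iff its maximum correlation
    over all B clusters is strictly below ``novel_r_threshold``.
    Returns (correlation matrix A x B, per-A-cluster novelty report).
    """
    pairs = ortholog_map[
        ortholog_map["gene_a"].isin(profiles_a.index)
        & ortholog_map["gene_b"].isin(profiles_b.index)
    ]
    if len(pairs) < 2:
        raise ValueError("fewer than 2 usable ortholog pairs")
    pa = profiles_a.loc[pairs["gene_a"]].to_numpy()
    pb = profiles_b.loc[pairs["gene_b"]].to_numpy()
    if (pa.std(axis=0) == 0).any() or (pb.std(axis=0) == 0).any():
        raise ValueError("a cluster profile has zero variance over the orthologs")
    n_a, n_b = pa.shape[1], pb.shape[1]
    r = np.corrcoef(pa.T, pb.T)[:n_a, n_a:]
    rmat = pd.DataFrame(r, index=profiles_a.columns, columns=profiles_b.columns)
    report = pd.DataFrame(
        {
            "cluster": rmat.index,
            "best_match": rmat.idxmax(axis=1).to_numpy(),
            "max_r": rmat.max(axis=1).to_numpy(),
        }
    )
    report["novel"] = report["max_r"] < novel_r_threshold
    return rmat, report


@dataclass
class JointClustering:
    labels: pd.Series  # cell id -> joint cluster label
    species: pd.Series  # cell id -> species label
    composition: pd.DataFrame  # clusters x species fractions (rows sum to 1)


def joint_cluster(
    matrix_a: CellMatrix,
    matrix_b: CellMatrix,
    ortholog_map: pd.DataFrame,
    n_pcs: int = 30,
    resolution: float = 0.1,
    seed: int = 0,
    k_neighbors: int = 20,
    scale_factor: float = 10000.0,
) -> JointClustering:
    """Joint Louvain clustering of two species on shared orthologs.

    Both matrices are restricted to the ortholog pairs, renamed to the
    species-A namespace, log-normalized and gene-scaled independently
    per species, then concatenated for joint PCA and SNN/Louvain
    clustering.  The composition table gives per-cluster species
    fractions (rows sum to 1).
    """
    if len(ortholog_map) == 0:
        raise ValueError("empty ortholog map")
    ia = {g: i for i, g in enumerate(matrix_a.gene_ids)}
    ib = {g: i for i, g in enumerate(matrix_b.gene_ids)}
    pairs = ortholog_map[
        ortholog_map["gene_a"].isin(ia) & ortholog_map["gene_b"].isin(ib)
    ]
    if len(pairs) == 0:
        raise ValueError("no ortholog pair present in both matrices")
    rows_a = [ia[g] for g in pairs["gene_a"]]
    rows_b = [ib[g] for g in pairs["gene_b"]]

    def _prep(matrix: CellMatrix, rows: list[int]) -> np.ndarray:
        counts = matrix.counts[rows]
        totals = matrix.counts.sum(axis=0).astype(float)  # full-cell totals
        if (totals == 0).any():
            raise ValueError("cell with zero total counts; run qc_filter first")
        values = np.log1p(counts / totals * scale_factor)
        return _scale_genes(values)

    za = _prep(matrix_a, rows_a)
    zb = _prep(matrix_b, rows_b)
    z = np.hstack([za, zb])
    n_comp = min(n_pcs, z.shape[0], z.shape[1] - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(z.T)
    labels = _snn_louvain(pcs, k_neighbors, resolution, seed)

    cell_ids = list(matrix_a.cell_ids) + list(matrix_b.cell_ids)
    species = [matrix_a.species_label] * matrix_a.n_cells + [matrix_b.species_label] * matrix_b.n_cells
    lab = pd.Series(labels, index=cell_ids, name="cluster")
    sp = pd.Series(species, index=cell_ids, name="species")
    comp = pd.crosstab(lab, sp, normalize="index")
    return JointClustering(lab, sp, comp)
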