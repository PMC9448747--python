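"""Synthetic inputs with known truth for every pipeline stage.

Generates gene models, a two-population SV cohort (per-sample call sets
plus the true multi-sample genotype matrix), bulk RNA count matrices
with seeded fold changes, clustered single-cell count matrices with
seeded markers and mitochondrial fractions, and an ortholog table —
everything the downstream stages consume, with truth tables recording
what was planted.

All generators are deterministic functions of :class:`SimConfig` (seed
included); distinct stages use disjoint seed streams so that, e.g.,
changing the number of cells never perturbs the SV cohort.
"""

from __future__ import annotations

import json
import logging
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from types import SimpleNamespace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, GeneModelSet, classify_sv
from .sv_io import MISSING, GenotypeMatrix, SVRecord, to_genotype_matrix

logger = logging.getLogger(__name__)

# seed-stream tags so stages draw from independent generators
_TAG_GENES, _TAG_SV, _TAG_BULK, _TAG_SC_SHARED, _TAG_SC_CELLS, _TAG_ORTHO = 11, 13, 17, 23, 29, 31

DEFAULT_CATEGORY_PROBS = {
    "intronic": 0.30,
    "intergenic": 0.25,
    "exonic": 0.10,
    "UTR": 0.05,
    "promoter": 0.10,
    "upstream": 0.10,
    "downstream": 0.10,
}

SVTYPE_PROBS = {"DEL": 0.45, "INS": 0.40, "DUP": 0.10, "INV": 0.05}


@dataclass
class SimConfig:
    """Knobs for the synthetic cohort; all generators take one of these."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 200
    n_samples_pop_a: int = 3
    n_samples_pop_b: int = 26
    n_sv: int = 2000
    n_divergent_sv: int = 20
    divergence_delta: float = 1.0
    n_de_genes: int = 50
    de_log2fc: float = 3.0
    n_clusters: int = 4
    cells_per_cluster: int = 150
    markers_per_cluster: int = 10
    mito_gene_fraction: float = 0.02
    species_specific_cluster: bool = True

    def validate(self) -> None:
        counts = (
            self.n_chroms, self.chrom_length_bp, self.n_genes,
            self.n_samples_pop_a, self.n_samples_pop_b, self.n_sv,
            self.n_divergent_sv, self.n_de_genes, self.n_clusters,
            self.cells_per_cluster, self.markers_per_cluster,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0 <= self.divergence_delta <= 1:
            raise ValueError("divergence_delta must be in [0, 1]")
        if self.n_divergent_sv > self.n_sv:
            raise ValueError("n_divergent_sv exceeds n_sv")
        if not 0 <= self.mito_gene_fraction < 1:
            raise ValueError("mito_gene_fraction must be in [0, 1)")


@dataclass
class TruthTables:
    """What the generators planted, keyed by artifact ids."""

    divergent_sv_ids: set[str] = field(default_factory=set)
    sv_placement: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    de_gene_ids: dict[str, float] = field(default_factory=dict)
    marker_assignment: dict[str, list[str]] = field(default_factory=dict)
    species_specific_cluster_id: str | None = None

    def to_json(self, path: str) -> None:
        payload = {
            "divergent_sv_ids": sorted(self.divergent_sv_ids),
            "sv_placement": {k: list(v) for k, v in sorted(self.sv_placement.items())},
            "de_gene_ids": dict(sorted(self.de_gene_ids.items())),
            "marker_assignment": {k: sorted(v) for k, v in sorted(self.marker_assignment.items())},
            "species_specific_cluster_id": self.species_specific_cluster_id,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _rng(config: SimConfig, tag: int, extra: Sequence[int] = ()) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag, *extra])


# ---------------------------------------------------------------------------
# gene models

def _exonic_slice(exons: list[tuple[int, int]], a: int, b: int) -> tuple[tuple[int, int], ...]:
    """Genomic intervals covering exonic offsets [a, b) (0-based, genomic order)."""
    out = []
    off = 0
    for s, e in exons:
        n = e - s + 1
        lo, hi = max(a, off), min(b, off + n)
        if lo < hi:
            out.append((s + lo - off, s + hi - 1 - off))
        off += n
    return tuple(out)


def _gene_structure(rng: np.random.Generator, s: int, e: int, strand: str):
    length = e - s + 1
    n_ex = int(rng.integers(2, 5))
    min_exon, min_intron = 150, 60
    while n_ex > 1 and n_ex * min_exon + (n_ex - 1) * min_intron > length:
        n_ex -= 1
    n_parts = 2 * n_ex - 1
    mins = [min_exon if i % 2 == 0 else min_intron for i in range(n_parts)]
    slack = length - sum(mins)
    extra = rng.multinomial(slack, np.full(n_parts, 1.0 / n_parts))
    sizes = [m + int(x) for m, x in zip(mins, extra)]
    exons = []
    pos = s
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + size - 1))
        pos += size
    exonic_total = sum(e2 - s2 + 1 for s2, e2 in exons)
    u5 = int(rng.integers(60, 121))
    u3 = int(rng.integers(60, 121))
    if strand == "+":
        utr5 = _exonic_slice(exons, 0, u5)
        cds = _exonic_slice(exons, u5, exonic_total - u3)
        utr3 = _exonic_slice(exons, exonic_total - u3, exonic_total)
    else:
        utr3 = _exonic_slice(exons, 0, u3)
        cds = _exonic_slice(exons, u3, exonic_total - u5)
        utr5 = _exonic_slice(exons, exonic_total - u5, exonic_total)
    return tuple(exons), cds, utr5, utr3


def make_gene_models(config: SimConfig, prefix: str = "G") -> GeneModelSet:
    """Place non-overlapping strand-assigned gene models on each chromosome.

    Every gene has >= 1 CDS interval plus 5'/3' UTR intervals inside the
    transcript span, genes are separated by >= 300 bp, and a fraction of
    gene ids carry the reserved mitochondrial prefix ``MT-``.
    """
    config.validate()
    rng = _rng(config, _TAG_GENES)
    if config.n_genes == 0:
        return GeneModelSet([])
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    mito_idx = set(rng.choice(config.n_genes, size=n_mito, replace=False).tolist())

    genes: list[GeneModel] = []
    gidx = 0
    min_gap = 300
    for c, n in enumerate(per_chrom):
        if n == 0:
            continue
        chrom = f"chr{c + 1}"
        lengths = rng.integers(1200, 4501, size=n)
        needed = int(lengths.sum()) + (n + 1) * min_gap
        if needed > config.chrom_length_bp:
            raise ValueError(
                f"cannot place {n} genes on {chrom}: need {needed} bp, "
                f"have {config.chrom_length_bp}"
            )
        gaps = rng.multinomial(config.chrom_length_bp - needed, np.full(n + 1, 1.0 / (n + 1)))
        pos = 1
        for j in range(n):
            pos += min_gap + int(gaps[j])
            s, e = pos, pos + int(lengths[j]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons, cds, utr5, utr3 = _gene_structure(rng, s, e, strand)
            name = f"{prefix}{gidx:05d}"
            if gidx in mito_idx:
                name = f"MT-{name}"
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand,
                    tx_start=s, tx_end=e,
                    exons=exons, cds=cds, utr5=utr5, utr3=utr3,
                )
            )
            pos = e + 1
            gidx += 1
    return GeneModelSet(genes)


# ---------------------------------------------------------------------------
# SV cohort

@dataclass
class SVCohort:
    """Truth sites, per-sample call sets, genotype matrix and truth tables."""

    sites: list[SVRecord]
    callsets: dict[str, list[SVRecord]]
    matrix: GenotypeMatrix
    popmap: dict[str, str]
    truth: TruthTables


def _rand_span(rng, lo: int, hi: int, svtype: str, chrom_len: int):
    """Random SV span inside the closed window [lo, hi]; None if infeasible."""
    lo, hi = max(1, lo), min(chrom_len, hi)
    if hi < lo:
        return None
    length = int(rng.integers(50, 401))
    if svtype == "INS":
        start = int(rng.integers(lo, hi + 1))
        return start, start, length
    width = hi - lo + 1
    if width < 50:
        return None
    length = min(length, width)
    start = int(rng.integers(lo, hi - length + 2))
    return start, start + length - 1, length


def _category_window(rng, gene: GeneModel, category: str):
    if category == "exonic":
        pools = gene.cds
    elif category == "UTR":
        pools = gene.utrs
    elif category == "intronic":
        pools = gene.introns
    elif category == "promoter":
        pools = (gene.promoter_window(),)
    elif category == "upstream":
        pools = (gene.upstream_window(),)
    elif category == "downstream":
        pools = (gene.downstream_window(),)
    else:
        raise ValueError(category)
    if not pools:
        return None
    return pools[int(rng.integers(0, len(pools)))]


def _place_sv(rng, svtype, category, models, config, gene=None, max_tries=100):
    """Draw a span realizing ``category``; verified against the classifier."""
    chroms = sorted({g.chrom for g in models}) or [f"chr{i+1}" for i in range(config.n_chroms)]
    for _ in range(max_tries):
        if category == "intergenic":
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            span = _rand_span(rng, 1, config.chrom_length_bp, svtype, config.chrom_length_bp)
            g = None
        else:
            g = gene if gene is not None else models.genes[int(rng.integers(0, len(models)))]
            chrom = g.chrom
            window = _category_window(rng, g, category)
            if window is None:
                g = None if gene is None else gene
                continue
            span = _rand_span(rng, window[0], window[1], svtype, config.chrom_length_bp)
        if span is None:
            continue
        start, end, length = span
        probe = SimpleNamespace(id="probe", chrom=chrom, start=start, end=end, svtype=svtype)
        ann = classify_sv(probe, models)
        if ann.category == category:
            return chrom, start, end, length, (g.gene_id if g is not None else None)
    raise RuntimeError(f"could not place SV with category {category!r}")


def simulate_sv_cohort(
    models: GeneModelSet,
    config: SimConfig,
    category_probs: dict[str, float] | None = None,
    favored_gene_ids: Sequence[str] = (),
    favored_fraction: float = 0.6,
    jitter_bp: int = 10,
    missing_rate: float = 0.03,
) -> SVCohort:
    """Two-population SV cohort with divergent sites at |pA - pB| = delta.

    Background SVs share one Beta(0.8, 0.8) allele frequency across
    populations; divergent SVs get frequencies differing by exactly
    ``divergence_delta`` (delta 1 = fixed alternate in one population,
    absent in the other).  Genotypes are drawn per diploid sample under
    Hardy-Weinberg.  Each carrier sample contributes a jittered call to
    its per-sample call set; the true multi-sample matrix is returned
    alongside.  ``favored_gene_ids`` biases divergent-SV placement into
    the given genes (genic categories), seeding downstream enrichment.
    """
    config.validate()
    if config.divergence_delta > 1:
        raise ValueError("divergence_delta > 1")
    probs = dict(DEFAULT_CATEGORY_PROBS if category_probs is None else category_probs)
    if len(models) == 0:
        genic = {k for k in probs if k != "intergenic"}
        if any(probs[k] > 0 for k in genic):
            probs = {"intergenic": 1.0}
    cats = sorted(probs)
    cat_p = np.array([probs[c] for c in cats], dtype=float)
    cat_p /= cat_p.sum()
    types = sorted(SVTYPE_PROBS)
    type_p = np.array([SVTYPE_PROBS[t] for t in types], dtype=float)
    type_p /= type_p.sum()

    rng = _rng(config, _TAG_SV)
    n_a, n_b = config.n_samples_pop_a, config.n_samples_pop_b
    samples_a = [f"A{i+1:02d}" for i in range(n_a)]
    samples_b = [f"B{i+1:02d}" for i in range(n_b)]
    samples = samples_a + samples_b
    popmap = {s: "popA" for s in samples_a} | {s: "popB" for s in samples_b}

    div_idx = set(rng.choice(config.n_sv, size=config.n_divergent_sv, replace=False).tolist()) \
        if config.n_sv else set()
    favored = [models.get(g) if isinstance(g, str) else g for g in favored_gene_ids]

    truth = TruthTables()
    sites: list[SVRecord] = []
    callsets: dict[str, list[SVRecord]] = {s: [] for s in samples}
    # same-type truth sites must stay farther apart than the merge
    # distance plus twice the jitter, or they would collapse on merging
    min_sep = 50 + 2 * jitter_bp + 1
    placed_starts: dict[tuple[str, str], list[int]] = {}
    for i in range(config.n_sv):
        sv_id = f"sv{i:05d}"
        svtype = types[int(rng.choice(len(types), p=type_p))]
        divergent = i in div_idx
        gene = None
        if divergent and favored and rng.random() < favored_fraction:
            gene = favored[int(rng.integers(0, len(favored)))]
            genic = [c for c in ("exonic", "promoter", "intronic") if _category_window(rng, gene, c)]
            category = genic[int(rng.integers(0, len(genic)))]
        else:
            category = cats[int(rng.choice(len(cats), p=cat_p))]
        for attempt in range(300):
            if attempt == 30:
                gene = None  # loosen the favored-gene constraint if crowded
            if attempt >= 30 and attempt % 30 == 0:
                category = cats[int(rng.choice(len(cats), p=cat_p))]
            try:
                chrom, start, end, length, gene_id = _place_sv(
                    rng, svtype, category, models, config, gene=gene
                )
            except RuntimeError:
                if gene is None:
                    raise
                continue
            nearby = placed_starts.setdefault((chrom, svtype), [])
            j = bisect_left(nearby, start)
            if (j == 0 or start - nearby[j - 1] >= min_sep) and (
                j == len(nearby) or nearby[j] - start >= min_sep
            ):
                break
        else:
            raise RuntimeError(f"could not place SV {sv_id} with adequate spacing")
        insort(placed_starts[(chrom, svtype)], start)

        if divergent:
            delta = config.divergence_delta
            c = 0.5 if delta == 1 else float(rng.uniform(delta / 2, 1 - delta / 2))
            p_a, p_b = c + delta / 2, c - delta / 2
            if rng.random() < 0.5:
                p_a, p_b = p_b, p_a
            qual = float(rng.uniform(40, 90))
            truth.divergent_sv_ids.add(sv_id)
        else:
            p_a = p_b = float(rng.beta(0.8, 0.8))
            qual = float(rng.uniform(15, 90))
        codes = np.concatenate([
            rng.binomial(2, p_a, size=n_a),
            rng.binomial(2, p_b, size=n_b),
        ]).astype(int)
        if not divergent and missing_rate > 0:
            codes[rng.random(len(samples)) < missing_rate] = MISSING

        genotypes = dict(zip(samples, (int(c) for c in codes)))
        sites.append(SVRecord(sv_id, chrom, start, end, svtype, length, qual, genotypes))
        truth.sv_placement[sv_id] = (category, gene_id)

        for s, code in genotypes.items():
            if code in (1, 2):
                shift = int(rng.integers(-jitter_bp, jitter_bp + 1))
                js = max(1, start + shift)
                je = js if svtype == "INS" else js + length - 1
                callsets[s].append(
                    SVRecord(sv_id, chrom, js, je, svtype, length, qual, {s: code})
                )

    codes = np.array([[r.genotypes[s] for s in samples] for r in sites], dtype=np.int8) \
        if sites else np.zeros((0, len(samples)), dtype=np.int8)
    matrix = GenotypeMatrix(
        [r.id for r in sites], samples, codes,
        np.array([r.qual for r in sites], dtype=float), records=list(sites),
    )
    return SVCohort(sites, callsets, matrix, popmap, truth)


# ---------------------------------------------------------------------------
# bulk counts

@dataclass
class BulkSim:
    counts: pd.DataFrame  # genes x samples
    groups: dict[str, str]
    truth_de: dict[str, float]  # gene -> signed log2 fold change (B vs A)


def simulate_bulk_counts(
    models: GeneModelSet,
    config: SimConfig,
    n_a: int = 5,
    n_b: int = 5,
    dispersion: float = 0.1,
) -> BulkSim:
    """Gamma-Poisson bulk counts with seeded group-B log2 fold changes.

    Per-sample library-size factors are lognormal; seeded DE genes have
    their group-B mean scaled by ``2 ** (±de_log2fc)`` (sign random per
    gene).  Dispersion is gene-level and constant.
    """
    config.validate()
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per group")
    rng = _rng(config, _TAG_BULK)
    gene_ids = models.gene_ids
    n_genes = len(gene_ids)
    if config.n_de_genes > n_genes:
        raise ValueError("n_de_genes exceeds number of genes")
    mu = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    de_idx = rng.choice(n_genes, size=config.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    truth_de = {gene_ids[int(i)]: float(s * config.de_log2fc) for i, s in zip(de_idx, signs)}

    samples = [f"bulkA{i+1:02d}" for i in range(n_a)] + [f"bulkB{i+1:02d}" for i in range(n_b)]
    groups = {s: ("groupA" if s.startswith("bulkA") else "groupB") for s in samples}
    size_f = rng.lognormal(mean=0.0, sigma=0.25, size=n_a + n_b)

    shape = 1.0 / dispersion
    counts = np.empty((n_genes, n_a + n_b), dtype=np.int64)
    mu_b = mu.copy()
    for i, s in zip(de_idx, signs):
        mu_b[int(i)] *= 2.0 ** (s * config.de_log2fc)
    for j in range(n_a + n_b):
        m = mu if j < n_a else mu_b
        lam = size_f[j] * rng.gamma(shape, m / shape)
        counts[:, j] = rng.poisson(lam)
    return BulkSim(pd.DataFrame(counts, index=gene_ids, columns=samples), groups, truth_de)


# ---------------------------------------------------------------------------
# single-cell counts

@dataclass
class ScSim:
    matrix: "object"  # svlink.sc.CellMatrix
    labels: np.ndarray  # true cluster label per (pre-QC) cell
    marker_assignment: dict[int, list[str]]
    species_specific_cluster_id: int | None


def simulate_sc_counts(
    models: GeneModelSet,
    config: SimConfig,
    species_label: str,
    add_specific_cluster: bool | None = None,
    marker_boost: float = 8.0,
    mito_fail_rate: float = 0.04,
    depth_fail_rate: float = 0.03,
    mean_library_size: float = 2000.0,
) -> ScSim:
    """Clustered Poisson single-cell counts with seeded markers.

    Cluster mean profiles (and marker gene indices) are drawn from a
    species-shared stream so orthologous clusters correspond across
    species; per-cell sampling uses a species-specific stream.  Marker
    genes are elevated ``marker_boost``-fold (> e) in their home
    cluster.  Mitochondrial genes (``MT-`` prefix) contribute about
    ``mito_gene_fraction`` of each cell's counts, except for a failing
    minority with heavy-tailed elevated fractions.  When
    ``add_specific_cluster`` resolves true, one extra cluster with an
    independent profile and unique markers is appended.
    """
    from .sc import CellMatrix

    config.validate()
    if config.n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if add_specific_cluster is None:
        add_specific_cluster = config.species_specific_cluster
    gene_ids = models.gene_ids
    n_genes = len(gene_ids)
    mito = np.array([g.startswith("MT-") for g in gene_ids])
    n_mito = int(mito.sum())
    n_shared = config.n_clusters
    n_marker_total = (n_shared + 1) * config.markers_per_cluster
    if n_marker_total > n_genes - n_mito:
        raise ValueError("markers_per_cluster x n_clusters exceeds available genes")

    rng_shared = _rng(config, _TAG_SC_SHARED)
    rng_sp = _rng(config, _TAG_SC_CELLS, list(species_label.encode()))

    base = rng_shared.gamma(2.0, 0.5, size=n_genes) + 0.05
    pool = rng_shared.permutation(np.flatnonzero(~mito))
    marker_idx = [
        pool[k * config.markers_per_cluster:(k + 1) * config.markers_per_cluster]
        for k in range(n_shared + 1)  # last block reserved for the specific cluster
    ]
    f = config.mito_gene_fraction
    mito_w = rng_shared.random(n_mito) + 0.1 if n_mito else np.empty(0)

    def _with_mito(prof: np.ndarray) -> np.ndarray:
        prof = prof.copy()
        if n_mito and f > 0:
            nonmito_sum = prof[~mito].sum()
            prof[mito] = (mito_w / mito_w.sum()) * (f / (1 - f)) * nonmito_sum
        return prof

    profiles = []
    for k in range(n_shared):
        prof = base.copy()
        prof[marker_idx[k]] *= marker_boost
        profiles.append(_with_mito(prof))
    specific_id = None
    marker_assignment = {
        k: [gene_ids[int(i)] for i in marker_idx[k]] for k in range(n_shared)
    }
    if add_specific_cluster:
        specific_id = n_shared
        prof = rng_sp.gamma(2.0, 0.5, size=n_genes) + 0.05
        prof[marker_idx[n_shared]] *= marker_boost
        profiles.append(_with_mito(prof))
        marker_assignment[specific_id] = [gene_ids[int(i)] for i in marker_idx[n_shared]]

    n_clusters_total = len(profiles)
    labels = np.repeat(np.arange(n_clusters_total), config.cells_per_cluster)
    n_cells = len(labels)
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for c in range(n_cells):
        prof = profiles[labels[c]]
        p = prof / prof.sum()
        lib = float(rng_sp.lognormal(mean=math.log(mean_library_size), sigma=0.3))
        if rng_sp.random() < depth_fail_rate:
            lib = float(rng_sp.integers(30, 80))
        if n_mito and rng_sp.random() < mito_fail_rate:
            target = min(0.9, 0.25 + float(rng_sp.exponential(0.2)))
            p = p.copy()
            cur = p[mito].sum()
            if 0 < cur < 1:
                p[mito] *= target / cur
                p[~mito] *= (1 - target) / (1 - cur)
        counts[:, c] = rng_sp.poisson(lib * p)
    cell_ids = [f"{species_label}_c{i:04d}" for i in range(n_cells)]
    matrix = CellMatrix(
        counts=counts, gene_ids=list(gene_ids), cell_ids=cell_ids,
        mito_flags=mito, species_label=species_label,
    )
    return ScSim(matrix, labels, marker_assignment, specific_id)


# ---------------------------------------------------------------------------
# orthologs

def make_ortholog_map(
    models_a: GeneModelSet,
    models_b: GeneModelSet,
    fraction_shared: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One-to-one, order-preserving ortholog pairs over a random index subset.

    Covers ``fraction_shared`` of the smaller gene set; pairing is by
    gene rank so species-shared expression profiles drawn by gene index
    stay aligned.  Columns: ``gene_a``, ``gene_b``.
    """
    if not 0 <= fraction_shared <= 1:
        raise ValueError("fraction_shared must be in [0, 1]")
    genes_a, genes_b = models_a.gene_ids, models_b.gene_ids
    n = min(len(genes_a), len(genes_b))
    k = int(math.floor(fraction_shared * n))
    rng = np.random.default_rng([seed, _TAG_ORTHO])
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return pd.DataFrame(
        {"gene_a": [genes_a[i] for i in idx], "gene_b": [genes_b[i] for i in idx]}
    )


# ---------------------------------------------------------------------------
# serialization helpers

def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_group_map(groups: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def write_ortholog_tsv(orthologs: pd.DataFrame, path: str) -> None:
    orthologs.to_csv(path, sep="\t", index=False)


def read_ortholog_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene_a", "gene_b"]
    return df
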