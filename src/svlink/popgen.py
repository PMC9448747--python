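"""Per-SV two-population differentiation (FST) and candidate selection.

The default estimator is the per-site Weir & Cockerham (1984) theta-hat,
built from the among-population (a), between-individual (b) and
within-individual (c) variance components computed from genotype counts
(observed heterozygosity enters through c).  A Hudson-style estimator is
available as an alternative.  Sites that are monomorphic across both
populations, have a zero variance-component denominator, or lack called
genotypes in a population are reported as undefined.  Negative
estimates are reported unclamped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sv_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Per-SV differentiation estimate with population allele frequencies."""

    sv_id: str
    fst: float | None
    p_hat_a: float | None
    p_hat_b: float | None
    n_called_a: int
    n_called_b: int

    @property
    def defined(self) -> bool:
        return self.fst is not None


def _pop_indices(matrix: GenotypeMatrix, popmap: dict[str, str]) -> tuple[str, str, np.ndarray, np.ndarray]:
    missing = [s for s in matrix.sample_ids if s not in popmap]
    if missing:
        raise ValueError(f"samples missing from population map: {missing}")
    labels = sorted({popmap[s] for s in matrix.sample_ids})
    if len(labels) != 2:
        raise ValueError(f"exactly two population labels required, got {labels}")
    lab_a, lab_b = labels
    idx_a = np.array([j for j, s in enumerate(matrix.sample_ids) if popmap[s] == lab_a])
    idx_b = np.array([j for j, s in enumerate(matrix.sample_ids) if popmap[s] == lab_b])
    return lab_a, lab_b, idx_a, idx_b


def _pop_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Called-diploid count, alt-allele frequency and het frequency per site."""
    called = codes != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, codes, 0).sum(axis=1).astype(float)
    het = np.where(called, codes == 1, False).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def allele_frequency(matrix: GenotypeMatrix, popmap: dict[str, str], population: str) -> pd.DataFrame:
    """Alternate-allele frequency per SV within one population.

    Missing genotypes are excluded; sites with zero called genotypes get
    NaN.  Returns a frame with ``sv_id``, ``p_hat`` and ``n_called``.
    """
    idx = np.array([j for j, s in enumerate(matrix.sample_ids) if popmap.get(s) == population])
    if idx.size == 0:
        raise ValueError(f"population {population!r} not present in population map")
    n, p, _ = _pop_stats(matrix.codes[:, idx])
    return pd.DataFrame({"sv_id": matrix.sv_ids, "p_hat": p, "n_called": n.astype(int)})


def _weir_cockerham(n1, p1, h1, n2, p2, h2):
    """Vectorized per-site W&C (1984) a, b, c components for two populations."""
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a_corr = inner - hbar / 4
        b_brak = inner - (2 * nbar - 1) / (4 * nbar) * hbar
        with_nbar1 = nbar <= 1
        safe = np.where(with_nbar1, np.inf, nbar - 1)
        a = nbar / nc * (s2 - a_corr / safe)
        b = nbar / safe * b_brak
        # nbar == 1: the 1/(nbar-1) corrections are only defined when their
        # brackets vanish (e.g. a fixed difference between two singletons)
        a = np.where(with_nbar1 & (a_corr != 0), np.nan, a)
        b = np.where(with_nbar1 & (b_brak != 0), np.nan, b)
        c = hbar / 2
    return a, b, c


def _hudson(n1, p1, n2, p2):
    """Hudson FST (Bhatia et al. 2013 estimator), allele sample sizes 2n."""
    m1, m2 = 2 * n1, 2 * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    fst = np.where((m1 < 2) | (m2 < 2) | (den == 0), np.nan, fst)
    return fst


def fst_per_sv(
    matrix: GenotypeMatrix,
    popmap: dict[str, str],
    estimator: str = "weir_cockerham",
) -> list[FstResult]:
    """Per-SV FST between the two populations of ``popmap``.

    Population "a" is the alphabetically first label.  Undefined sites
    (monomorphic across both populations, zero denominator, or a
    population with no called genotypes) carry ``fst=None``.
    """
    if estimator not in ("weir_cockerham", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    _, _, idx_a, idx_b = _pop_indices(matrix, popmap)
    n1, p1, h1 = _pop_stats(matrix.codes[:, idx_a])
    n2, p2, h2 = _pop_stats(matrix.codes[:, idx_b])

    if estimator == "weir_cockerham":
        a, b, c = _weir_cockerham(n1, p1, h1, n2, p2, h2)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = a + b + c
            fst = a / denom
        undef = (n1 == 0) | (n2 == 0) | ~np.isfinite(denom) | (denom == 0)
        # a fixed difference gives theta = 1 exactly (b = c = 0); evaluate
        # it as such rather than through the cancellation-prone formula
        fixed = (h1 == 0) & (h2 == 0) & (
            ((p1 == 1) & (p2 == 0)) | ((p1 == 0) & (p2 == 1))
        )
        fst = np.where(fixed, 1.0, fst)
    else:
        fst = _hudson(n1, p1, n2, p2)
        undef = (n1 == 0) | (n2 == 0) | ~np.isfinite(fst)
    undef |= ~np.isfinite(fst)

    results = []
    for i, sv_id in enumerate(matrix.sv_ids):
        results.append(
            FstResult(
                sv_id=sv_id,
                fst=None if undef[i] else float(fst[i]),
                p_hat_a=None if n1[i] == 0 else float(p1[i]),
                p_hat_b=None if n2[i] == 0 else float(p2[i]),
                n_called_a=int(n1[i]),
                n_called_b=int(n2[i]),
            )
        )
    return results


def select_top_fraction(fst_results: list[FstResult], fraction: float = 0.005) -> set[str]:
    """IDs of SVs in the top ``fraction`` of defined FST values.

    ``k = ceil(fraction * n_defined)`` largest values are selected, and
    every site tied with the k-th value is included, so the result may
    exceed ``k``.  Undefined values are excluded from both numerator and
    denominator.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    defined = [(r.fst, r.sv_id) for r in fst_results if r.defined]
    if not defined:
        warnings.warn("select_top_fraction: no defined FST values; empty selection")
        return set()
    k = math.ceil(fraction * len(defined))
    values = sorted((v for v, _ in defined), reverse=True)
    threshold = values[k - 1]
    return {sv_id for v, sv_id in defined if v >= threshold}


def fst_table(
    matrix: GenotypeMatrix,
    results: list[FstResult],
    selected: set[str],
) -> pd.DataFrame:
    """Tidy per-SV FST table (with coordinates when records are attached)."""
    recs = {r.id: r for r in matrix.records} if matrix.records else {}
    rows = []
    for res in results:
        rec = recs.get(res.sv_id)
        rows.append(
            {
                "sv_id": res.sv_id,
                "chrom": rec.chrom if rec else "",
                "start": rec.start if rec else -1,
                "end": rec.end if rec else -1,
                "svtype": rec.svtype if rec else "",
                "p_hat_a": res.p_hat_a,
                "p_hat_b": res.p_hat_b,
                "fst": res.fst,
                "selected": res.sv_id in selected,
            }
        )
    return pd.DataFrame(rows)
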