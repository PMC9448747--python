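"""Structural-variant call-set I/O, merging and filtering.

Reads and writes a cuteSV-style VCF 4.2 dialect (symbolic ALT alleles,
``SVTYPE``/``SVLEN``/``END`` in INFO, ``GT`` in FORMAT), merges per-sample
call sets by a distance-and-type rule into a multi-sample set, and
filters the resulting genotype matrix with vcftools-style thresholds
(call rate, minor allele count, site quality).

Genotype codes count alternate alleles: 0 (hom ref), 1 (het),
2 (hom alt) and -1 (missing).  Translocation-like records (BND/TRA) are
skipped on read.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV")

MISSING = -1

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class SVRecord:
    """One structural-variant site with per-sample genotype codes."""

    id: str
    chrom: str
    start: int  # 1-based POS
    end: int    # 1-based inclusive; == start for INS
    svtype: str
    length_bp: int
    qual: float = 0.0
    genotypes: dict[str, int] = field(default_factory=dict)
    support: int = 1
    members: tuple["SVRecord", ...] = ()

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unsupported SVTYPE {self.svtype!r} on {self.id}")
        if self.length_bp <= 0:
            raise ValueError(f"non-positive SVLEN on {self.id}")
        if self.end < self.start:
            raise ValueError(f"END < POS on {self.id}")


@dataclass
class CallSet:
    """Records read from one VCF plus bookkeeping about skipped lines."""

    records: list[SVRecord]
    sample_ids: list[str]
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class GenotypeMatrix:
    """Multi-sample alternate-allele-count matrix over merged SV sites."""

    sv_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray  # (n_sv, n_samples) int8, -1 = missing
    site_qual: np.ndarray  # (n_sv,)
    records: list[SVRecord] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.site_qual = np.asarray(self.site_qual, dtype=float)
        if self.codes.shape != (len(self.sv_ids), len(self.sample_ids)):
            raise ValueError("codes shape inconsistent with sv/sample ids")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")

    @property
    def n_sv(self) -> int:
        return len(self.sv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        return GenotypeMatrix(
            [self.sv_ids[i] for i in idx],
            list(self.sample_ids),
            self.codes[idx],
            self.site_qual[idx],
            [self.records[i] for i in idx] if self.records is not None else None,
        )


# ---------------------------------------------------------------------------
# population map

def read_population_map(path: str) -> dict[str, str]:
    """Two-column sample<TAB>population TSV -> mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out


def write_population_map(popmap: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF I/O

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=svlink
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">
##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of contributing samples">
##INFO=<ID=MEMBERS,Number=.,Type=String,Description="IDs of member calls">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_sv_vcf(records: list[SVRecord], path: str, sample_ids: list[str] | None = None,
                 absent_code: int = 0) -> None:
    """Write records as uncompressed VCF 4.2.

    ``sample_ids`` fixes the column order; samples without a genotype on
    a record receive ``absent_code`` (default hom ref).  Deletions are
    written with negative SVLEN, per common caller convention.
    """
    if sample_ids is None:
        seen: dict[str, None] = {}
        for rec in records:
            for s in rec.genotypes:
                seen.setdefault(s)
        sample_ids = list(seen)
    contigs: dict[str, int] = {}
    for rec in records:
        contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.end + 1)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.id)):
            svlen = -rec.length_bp if rec.svtype == "DEL" else rec.length_bp
            info = f"SVTYPE={rec.svtype};SVLEN={svlen};END={rec.end}"
            if rec.support > 1 or rec.members:
                info += f";SUPP={rec.support}"
            if rec.members:
                info += ";MEMBERS=" + ",".join(m.id for m in rec.members)
            gts = "\t".join(
                _GT_STR[rec.genotypes.get(s, absent_code)] for s in sample_ids
            )
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.id}\tN\t<{rec.svtype}>\t"
                f"{rec.qual:g}\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_sv_vcf(path: str) -> CallSet:
    """Parse a VCF into a :class:`CallSet`.

    SVTYPE/SVLEN/END come from INFO, genotypes from GT.  Records whose
    SVTYPE is outside ``{DEL, INS, DUP, INV}`` (e.g. BND/TRA) are
    skipped and counted.  A retained record without SVTYPE is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records: list[SVRecord] = []
    n_skipped = 0
    for var in vcf:
        svtype = var.INFO.get("SVTYPE")
        if svtype is None:
            alt = var.ALT[0] if var.ALT else ""
            if alt.startswith("<") or "[" in alt or "]" in alt:
                svtype = alt.strip("<>")
            else:
                raise ValueError(
                    f"missing SVTYPE at {var.CHROM}:{var.POS} ({var.ID})"
                )
        if svtype not in SV_TYPES:
            n_skipped += 1
            continue
        start = var.POS
        svlen = var.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        end = var.INFO.get("END")
        if svtype == "INS":
            end = start
        elif end is None:
            end = start + abs(int(svlen)) if svlen is not None else var.end
        length = abs(int(svlen)) if svlen is not None else max(1, int(end) - start)
        gt = var.gt_types  # 0 hom_ref, 1 het, 2 hom_alt, 3 unknown (gts012)
        genotypes = {
            s: (MISSING if g == 3 else int(g)) for s, g in zip(samples, gt)
        }
        supp = var.INFO.get("SUPP")
        records.append(
            SVRecord(
                id=var.ID or f"{var.CHROM}_{start}_{svtype}",
                chrom=var.CHROM,
                start=start,
                end=int(end),
                svtype=svtype,
                length_bp=int(length),
                qual=float(var.QUAL) if var.QUAL is not None else 0.0,
                genotypes=genotypes,
                support=int(supp) if supp is not None else 1,
            )
        )
    if n_skipped:
        logger.info("read_sv_vcf(%s): skipped %d non-{DEL,INS,DUP,INV} records", path, n_skipped)
    return CallSet(records, samples, n_skipped)


# ---------------------------------------------------------------------------
# merging

def merge_callsets(
    callsets: list[CallSet | list[SVRecord]],
    max_dist_bp: int = 50,
    require_type_match: bool = True,
    min_support: int = 1,
) -> list[SVRecord]:
    """Merge call sets by breakpoint proximity (SURVIVOR-style contract).

    Calls on the same chromosome, of the same type (when required), with
    start — and for non-insertions end — within ``max_dist_bp`` of a
    chain seed are merged transitively and greedily in coordinate-sorted
    order; within one pass every member lies within ``max_dist_bp`` of
    its chain's leftmost member.  Passes repeat until the record count
    is stable, which makes the operation idempotent.  The representative
    start/end is the per-coordinate median over all original member
    calls; ``support`` counts distinct contributing samples.  Chains
    with support below ``min_support`` are dropped.  Output is sorted by
    (chrom, start).
    """
    if not callsets:
        raise ValueError("merge_callsets: empty input list")
    records: list[SVRecord] = []
    for cs in callsets:
        records.extend(cs.records if isinstance(cs, CallSet) else cs)
    while True:
        merged = _merge_pass(records, max_dist_bp, require_type_match)
        if len(merged) == len(records):
            break
        records = merged
    merged = [r for r in merged if r.support >= min_support]
    merged.sort(key=lambda r: (r.chrom, r.start, r.id))
    return merged


def _merge_pass(
    records: list[SVRecord],
    max_dist_bp: int,
    require_type_match: bool,
) -> list[SVRecord]:
    calls = sorted(
        enumerate(records), key=lambda t: (t[1].chrom, t[1].start, t[1].end, t[0])
    )
    chains: list[list[SVRecord]] = []
    open_chains: list[list[SVRecord]] = []
    cur_chrom = None
    for _, rec in calls:
        if rec.chrom != cur_chrom:
            chains.extend(open_chains)
            open_chains = []
            cur_chrom = rec.chrom
        # close chains whose seed can no longer match anything downstream
        still_open = []
        for ch in open_chains:
            if rec.start - ch[0].start > max_dist_bp:
                chains.append(ch)
            else:
                still_open.append(ch)
        open_chains = still_open
        placed = False
        for ch in open_chains:
            seed = ch[0]
            if require_type_match and seed.svtype != rec.svtype:
                continue
            if abs(rec.start - seed.start) > max_dist_bp:
                continue
            if rec.svtype != "INS" and abs(rec.end - seed.end) > max_dist_bp:
                continue
            ch.append(rec)
            placed = True
            break
        if not placed:
            open_chains.append([rec])
    chains.extend(open_chains)

    merged: list[SVRecord] = []
    for ch in chains:
        if len(ch) == 1:
            merged.append(ch[0])  # untouched chains keep their record verbatim
            continue
        genotypes: dict[str, int] = {}
        for m in ch:
            for s, g in m.genotypes.items():
                genotypes.setdefault(s, g)
        support = len({s for m in ch for s in m.genotypes})
        members = tuple(
            orig for m in ch for orig in (m.members if m.members else (m,))
        )
        start = int(statistics.median_low(sorted(m.start for m in members)))
        seed = ch[0]
        if seed.svtype == "INS":
            end = start
            length = int(statistics.median_low(sorted(m.length_bp for m in members)))
        else:
            end = int(statistics.median_low(sorted(m.end for m in members)))
            length = max(1, end - start)
        merged.append(
            SVRecord(
                id=seed.id,
                chrom=seed.chrom,
                start=start,
                end=end,
                svtype=seed.svtype,
                length_bp=length,
                qual=max(m.qual for m in ch),
                genotypes=genotypes,
                support=support,
                members=members,
            )
        )
    return merged


def to_genotype_matrix(
    merged: list[SVRecord],
    sample_ids: list[str],
    absent: str = "hom_ref",
) -> GenotypeMatrix:
    """Build a genotype matrix from merged records.

    Samples without a member call receive the ``absent`` policy genotype
    (``"hom_ref"``, mirroring re-genotyping at merged breakpoints, or
    ``"missing"``).
    """
    if absent not in ("hom_ref", "missing"):
        raise ValueError("absent policy must be 'hom_ref' or 'missing'")
    fill = 0 if absent == "hom_ref" else MISSING
    ids = [r.id for r in merged]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate SV ids in merged call set")
    known = set(sample_ids)
    for rec in merged:
        extra = set(rec.genotypes) - known
        if extra:
            raise ValueError(f"samples {sorted(extra)} on {rec.id} not in sample_ids")
    codes = np.full((len(merged), len(sample_ids)), fill, dtype=np.int8)
    for i, rec in enumerate(merged):
        for j, s in enumerate(sample_ids):
            if s in rec.genotypes:
                codes[i, j] = rec.genotypes[s]
    qual = np.array([r.qual for r in merged], dtype=float)
    return GenotypeMatrix(ids, list(sample_ids), codes, qual, records=list(merged))


# ---------------------------------------------------------------------------
# filtering

def filter_callset(
    matrix: GenotypeMatrix,
    max_missing: float = 0.5,
    mac: int = 3,
    min_qual: float = 30.0,
) -> GenotypeMatrix:
    """vcftools-style site filter.

    ``max_missing`` follows the vcftools flag convention: the minimum
    fraction of called genotypes (1 = no missing data allowed).  ``mac``
    is the minimum minor allele count over called genotypes; ``min_qual``
    the minimum site quality.  All boundaries are inclusive.
    """
    codes = matrix.codes
    called = codes != MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / max(1, matrix.n_samples)
    alt = np.where(called, codes, 0).sum(axis=1)
    ref = 2 * n_called - alt
    minor = np.minimum(alt, ref)
    keep = (call_rate >= max_missing) & (minor >= mac) & (matrix.site_qual >= min_qual)
    return matrix.subset(keep)
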