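"""Genomic-region classification of structural variants against gene models.

Each SV is assigned exactly one region category by a fixed severity
priority (``exonic > UTR > intronic > promoter > upstream > downstream >
intergenic``) evaluated over every gene whose extended footprint (gene
span plus promoter window plus immediate flanks) the SV overlaps.
Deletions overlapping coding sequence additionally receive a
frameshift/in-frame call from the deleted CDS base count modulo 3.

Coordinates are 1-based closed throughout this module, matching GFF3.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: region categories in decreasing priority
CATEGORY_PRIORITY = (
    "exonic",
    "UTR",
    "intronic",
    "promoter",
    "upstream",
    "downstream",
    "intergenic",
)

_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}

Interval = tuple[int, int]


def _overlaps(a1: int, a2: int, b1: int, b2: int) -> bool:
    """Closed-interval overlap test."""
    return a1 <= b2 and b1 <= a2


def _any_overlap(start: int, end: int, intervals: Sequence[Interval]) -> bool:
    return any(_overlaps(start, end, s, e) for s, e in intervals)


def _overlap_len(start: int, end: int, intervals: Sequence[Interval]) -> int:
    total = 0
    for s, e in intervals:
        lo, hi = max(start, s), min(end, e)
        if lo <= hi:
            total += hi - lo + 1
    return total


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware single-transcript gene structure.

    Intervals are 1-based closed, sorted, non-overlapping within each
    list; ``cds`` and the UTR lists partition the exonic bases.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.tx_end < self.tx_start:
            raise ValueError(f"tx_end < tx_start for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def utrs(self) -> tuple[Interval, ...]:
        return self.utr5 + self.utr3

    @property
    def introns(self) -> tuple[Interval, ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def promoter_window(self, promoter_bp: int = 2000, flank_bp: int = 150) -> Interval:
        """Promoter interval, excluding the immediate ``flank_bp`` upstream flank."""
        if self.strand == "+":
            return (max(1, self.tss - promoter_bp), self.tss - flank_bp - 1)
        return (self.tss + flank_bp + 1, self.tss + promoter_bp)

    def upstream_window(self, flank_bp: int = 150) -> Interval:
        if self.strand == "+":
            return (max(1, self.tss - flank_bp), self.tss - 1)
        return (self.tss + 1, self.tss + flank_bp)

    def downstream_window(self, flank_bp: int = 150) -> Interval:
        if self.strand == "+":
            return (self.tx_end + 1, self.tx_end + flank_bp)
        return (max(1, self.tx_start - flank_bp), self.tx_start - 1)

    def extended_footprint(self, promoter_bp: int = 2000, flank_bp: int = 150) -> Interval:
        """Union span of gene body, promoter, upstream and downstream windows."""
        if self.strand == "+":
            return (max(1, self.tx_start - promoter_bp), self.tx_end + flank_bp)
        return (max(1, self.tx_start - flank_bp), self.tx_end + promoter_bp)


class GeneModelSet:
    """Ordered collection of gene models with a per-chromosome lookup index."""

    def __init__(self, genes: Iterable[GeneModel], promoter_bp: int = 2000, flank_bp: int = 150):
        self.genes: list[GeneModel] = list(genes)
        self.promoter_bp = promoter_bp
        self.flank_bp = flank_bp
        self._by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in self.genes:
            s, e = g.extended_footprint(promoter_bp, flank_bp)
            self._by_chrom.setdefault(g.chrom, []).append((s, e, g))
        for entries in self._by_chrom.values():
            entries.sort(key=lambda t: (t[0], t[1]))
        # max footprint width per chrom bounds how far left a hit can start
        self._max_width = {
            c: max((e - s + 1) for s, e, _ in v) for c, v in self._by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def get(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose extended footprint overlaps ``[start, end]``."""
        entries = self._by_chrom.get(chrom)
        if not entries:
            return []
        starts = [s for s, _, _ in entries]
        hi = bisect_right(starts, end)
        lo_bound = start - self._max_width[chrom]
        hits = []
        for s, e, g in entries[:hi]:
            if s < lo_bound:
                continue
            if e >= start:
                hits.append(g)
        return hits


@dataclass
class SVAnnotation:
    """Single-category annotation for one SV."""

    sv_id: str
    category: str
    gene_ids: tuple[str, ...] = ()
    coding_effect: str = "none"


def _gene_category(start: int, end: int, gene: GeneModel, promoter_bp: int, flank_bp: int) -> str | None:
    """Highest-priority category of ``[start, end]`` with respect to one gene."""
    if _any_overlap(start, end, gene.cds):
        return "exonic"
    if _any_overlap(start, end, gene.utrs):
        return "UTR"
    if _overlaps(start, end, gene.tx_start, gene.tx_end):
        return "intronic"
    if _overlaps(start, end, *gene.promoter_window(promoter_bp, flank_bp)):
        return "promoter"
    if _overlaps(start, end, *gene.upstream_window(flank_bp)):
        return "upstream"
    if _overlaps(start, end, *gene.downstream_window(flank_bp)):
        return "downstream"
    return None


def coding_effect(sv, model: GeneModel) -> str:
    """Frameshift/in-frame call for a deletion against one gene's CDS.

    Non-deletions return ``"none"``.  The deleted coding base count is
    the total overlap between the deletion span and the CDS intervals;
    a nonzero count not divisible by 3 is a frameshift.
    """
    if sv.svtype != "DEL":
        return "none"
    deleted = _overlap_len(sv.start, sv.end, model.cds)
    if deleted == 0:
        return "none"
    return "inframe" if deleted % 3 == 0 else "frameshift"


def classify_sv(
    sv,
    models: GeneModelSet,
    promoter_bp: int = 2000,
    flank_bp: int = 150,
    unknown_chrom: str = "warn",
) -> SVAnnotation:
    """Assign one region category (and coding effect) to an SV.

    Insertions are evaluated at their insertion point; all other types
    as their full ``[start, end]`` span.  ``unknown_chrom`` controls
    behaviour for chromosomes absent from the models: ``"warn"`` yields
    intergenic with a warning, ``"error"`` raises.
    """
    start, end = sv.start, sv.end
    if sv.svtype == "INS":
        end = start
    if sv.chrom not in models._by_chrom:
        if unknown_chrom == "error":
            raise ValueError(f"unknown chromosome {sv.chrom!r} for SV {sv.id}")
        warnings.warn(f"SV {sv.id}: chromosome {sv.chrom!r} not in gene models; intergenic")
        return SVAnnotation(sv.id, "intergenic")

    hits = models.overlapping(sv.chrom, start, end)
    if not hits:
        return SVAnnotation(sv.id, "intergenic")

    best = "intergenic"
    effect = "none"
    for gene in hits:
        cat = _gene_category(start, end, gene, promoter_bp, flank_bp)
        if cat is not None and _RANK[cat] < _RANK[best]:
            best = cat
        ce = coding_effect(sv, gene)
        if ce == "frameshift" or (ce == "inframe" and effect == "none"):
            effect = ce
    if best == "intergenic":
        # footprint overlap was at a clamped/degenerate window only
        return SVAnnotation(sv.id, "intergenic")
    return SVAnnotation(sv.id, best, tuple(sorted(g.gene_id for g in hits)), effect)


def classify_all(svs, models: GeneModelSet, promoter_bp: int = 2000, flank_bp: int = 150) -> list[SVAnnotation]:
    return [classify_sv(sv, models, promoter_bp, flank_bp) for sv in svs]


def gene_category_lists(annotations: Iterable[SVAnnotation], high_fst_ids: set[str]) -> dict[str, set[str]]:
    """Gene lists backed by high-FST SVs.

    ``list1``: genes hit by at least one high-FST SV in any
    non-intergenic category; ``list2``: genes hit by at least one
    high-FST SV classified exonic or promoter.  ``list2 ⊆ list1``.
    """
    list1: set[str] = set()
    list2: set[str] = set()
    for ann in annotations:
        if ann.sv_id not in high_fst_ids or ann.category == "intergenic":
            continue
        list1.update(ann.gene_ids)
        if ann.category in ("exonic", "promoter"):
            list2.update(ann.gene_ids)
    return {"list1": list1, "list2": list2}


def annotations_to_frame(annotations: Iterable[SVAnnotation]) -> pd.DataFrame:
    rows = [
        (a.sv_id, a.category, ",".join(a.gene_ids), a.coding_effect)
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=["sv_id", "category", "gene_ids", "coding_effect"])


# ---------------------------------------------------------------------------
# GFF3 I/O

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def write_gff3(models: Iterable[GeneModel], path: str) -> None:
    """Serialize gene models as minimal GFF3 (gene/mRNA/exon/CDS/UTR)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            base = f"{g.chrom}\tsvlink\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{g.tx_start}\t{g.tx_end}{tail}.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{g.tx_start}\t{g.tx_end}{tail}.\tID={mrna};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tID={mrna}.exon{i};Parent={mrna}\n")
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(f"{base}CDS\t{s}\t{e}{tail}0\tID={mrna}.cds{i};Parent={mrna}\n")
            for i, (s, e) in enumerate(g.utr5, 1):
                fh.write(f"{base}five_prime_UTR\t{s}\t{e}{tail}.\tID={mrna}.u5.{i};Parent={mrna}\n")
            for i, (s, e) in enumerate(g.utr3, 1):
                fh.write(f"{base}three_prime_UTR\t{s}\t{e}{tail}.\tID={mrna}.u3.{i};Parent={mrna}\n")


def read_gff3(path: str, promoter_bp: int = 2000, flank_bp: int = 150) -> GeneModelSet:
    """Load gene models from GFF3 via :mod:`gffutils` (one transcript per gene)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        def ivals(ft):
            return tuple(sorted((f.start, f.end) for f in db.children(parent, featuretype=ft)))
        exons = ivals("exon")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=gene.start,
                tx_end=gene.end,
                exons=exons if exons else ((gene.start, gene.end),),
                cds=ivals("CDS"),
                utr5=ivals("five_prime_UTR"),
                utr3=ivals("three_prime_UTR"),
            )
        )
    return GeneModelSet(genes, promoter_bp=promoter_bp, flank_bp=flank_bp)
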