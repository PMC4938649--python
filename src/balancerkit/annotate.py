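"""Gene-model annotation of breakpoints and small lesions.

Intersects called junction coordinates with GFF3 gene models to report
which genes are bisected by a breakpoint (with the affected isoforms and
the containing intron/exon per isoform), and classifies deletions
overlapping coding sequence as in-frame or frameshifting.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import pandas as pd

from .errors import InvalidIntervalError

__all__ = [
    "GeneModels",
    "BreakpointAnnotation",
    "IsoformHit",
    "load_gene_models",
    "intersect_breakpoints",
    "classify_deletion",
    "annotation_table",
]


@dataclass(frozen=True)
class IsoformHit:
    transcript: str
    feature: str        # 'exon' | 'intron'
    index: int          # 1-based in transcript (strand-aware) order


@dataclass
class BreakpointAnnotation:
    chrom: str
    pos: int
    status: str                     # 'bisected' | 'boundary' | 'intergenic' | 'deleted'
    genes: list[str]
    isoform_hits: dict[str, list[IsoformHit]]

    @property
    def label(self) -> str:
        if self.status in ("intergenic",):
            return "Intergenic"
        return ",".join(self.genes)


class GeneModels:
    """Thin wrapper over a gffutils database of gene/mRNA/exon/CDS features."""

    def __init__(self, db: gffutils.FeatureDB):
        self.db = db

    def genes(self):
        return self.db.features_of_type("gene")

    def isoforms(self, gene) -> list:
        return list(self.db.children(gene, featuretype=("mRNA", "transcript")))

    def exons(self, transcript) -> list[tuple[int, int]]:
        ex = [(f.start, f.end) for f in
              self.db.children(transcript, featuretype="exon")]
        return sorted(ex)

    def cds(self, transcript) -> list[tuple[int, int]]:
        return sorted((f.start, f.end) for f in
                      self.db.children(transcript, featuretype="CDS"))


def load_gene_models(gff3_path: str) -> GeneModels:
    db = gffutils.create_db(
        str(gff3_path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    return GeneModels(db)


def _locate_in_transcript(exons: list[tuple[int, int]], strand: str,
                          pos: int) -> IsoformHit | None:
    """Exon/intron index (1-based, transcript order) containing ``pos``."""
    if not exons:
        return None
    if strand == "-":
        ordered = list(reversed(exons))
    else:
        ordered = exons
    for i, (a, b) in enumerate(ordered, 1):
        if a <= pos <= b:
            return IsoformHit("", "exon", i)
    # introns lie between consecutive exons in transcript order
    for i in range(len(ordered) - 1):
        a, b = ordered[i], ordered[i + 1]
        lo, hi = (b[1] + 1, a[0] - 1) if strand == "-" else (a[1] + 1, b[0] - 1)
        if lo <= pos <= hi:
            return IsoformHit("", "intron", i + 1)
    return None


def intersect_breakpoints(breakpoints: list[tuple[str, int]],
                          models: GeneModels,
                          deleted_intervals: list[tuple[str, int, int]] | None = None,
                          ) -> list[BreakpointAnnotation]:
    """Annotate each (chrom, pos) breakpoint against the gene models.

    A breakpoint strictly inside a gene span bisects it; exactly at a span
    edge it is reported as 'boundary'; otherwise 'intergenic'.  Overlapping
    genes containing the same breakpoint are all reported, sorted by name.
    For each bisected gene the isoforms whose span contains the breakpoint
    are listed with the containing intron/exon index.
    """
    gene_list = [
        (g.seqid, g.start, g.end, g.attributes.get("Name", [g.id])[0], g)
        for g in models.genes()
    ]
    out = []
    for chrom, pos in breakpoints:
        inside, boundary = [], []
        hits: dict[str, list[IsoformHit]] = {}
        for seqid, s, e, name, g in gene_list:
            if seqid != chrom:
                continue
            if s < pos < e:
                inside.append(name)
                iso_hits = []
                for tr in models.isoforms(g):
                    if tr.start <= pos <= tr.end:
                        loc = _locate_in_transcript(models.exons(tr),
                                                    tr.strand, pos)
                        if loc is not None:
                            iso_hits.append(
                                IsoformHit(tr.id, loc.feature, loc.index))
                hits[name] = iso_hits
            elif pos == s or pos == e:
                boundary.append(name)
        if inside:
            status = "bisected"
            genes = sorted(inside)
        elif boundary:
            status = "boundary"
            genes = sorted(boundary)
        else:
            status = "intergenic"
            genes = []
        out.append(BreakpointAnnotation(chrom, pos, status, genes, hits))

    if deleted_intervals:
        # whole features removed by a junction deletion are reported as such
        for chrom, a, b in deleted_intervals:
            for seqid, s, e, name, g in gene_list:
                if seqid == chrom and a <= s and e <= b:
                    out.append(BreakpointAnnotation(
                        chrom, s, "deleted", [name], {}))
    return out


def classify_deletion(interval: tuple[int, int],
                      cds_intervals: list[tuple[int, int]]) -> dict:
    """Frame classification of a deletion against CDS intervals.

    The deleted coding length L is the total overlap with CDS; the
    deletion is in-frame iff L mod 3 == 0 (then L/3 codons are removed),
    otherwise it causes a frameshift.  A deletion with no CDS overlap is
    noncoding.  Interval coordinates are 1-based inclusive, so the
    deletion length itself is end - start + 1.
    """
    start, end = interval
    if end < start:
        raise InvalidIntervalError(f"bad interval {interval}")
    length = end - start + 1
    L = 0
    for a, b in cds_intervals:
        L += max(0, min(end, b) - max(start, a) + 1)
    if L == 0:
        return {"length": length, "cds_bp": 0, "classification": "noncoding",
                "codons": None}
    if L % 3 == 0:
        return {"length": length, "cds_bp": L, "classification": "in-frame",
                "codons": L // 3}
    return {"length": length, "cds_bp": L, "classification": "frameshift",
            "codons": None}


def annotation_table(annotations: list[BreakpointAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        iso = ";".join(
            f"{h.transcript}:{h.feature}{h.index}"
            for hs in a.isoform_hits.values() for h in hs
        )
        rows.append({
            "chrom": a.chrom, "pos": a.pos, "status": a.status,
            "affected": a.label if a.genes else "Intergenic",
            "n_isoforms_affected": sum(len(v) for v in a.isoform_hits.values()),
            "isoform_detail": iso,
        })
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "status", "affected", "n_isoforms_affected",
        "isoform_detail",
    ])
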