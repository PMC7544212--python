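"""Pairwise TIF overlap typology, the 2-kb downstream-PAS statistic, and
read-through transcript detection.

Overlap between same-strand TIFs whose TSSs lie within 10 kb is summarized
per ordered pair (upstream first, by strand-aware TSS) as the overlap width,
the gap when disjoint, and the overlapped fraction of each TIF's genomic
span (single-exon view: this assay sees boundaries, not splicing).  Pairs
partition into high_overlap (both fractions > 0.9), truncated (exactly one
> 0.9), low_tandem (both < 0.2 with nonzero overlap), disjoint, and other.

Tandem-overlapping upstream transcripts tend to polyadenylate within the
first 2 kb of the downstream unit; ``tandem_pas_statistic`` measures that
fraction.  A read-through TIF starts in (or near) one gene and polyadenylates
in a distinct, same-strand, downstream gene - a putative transcriptional
fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assembly import TIF
from .io import GeneModel

OVERLAP_WINDOW = 10_000
PAS_WINDOW = 2_000
PATTERNS = ("high_overlap", "truncated", "low_tandem", "other", "disjoint")


@dataclass
class OverlapRecord:
    """One ordered same-strand TIF pair; ``tif_a`` is upstream by strand-aware TSS."""

    tif_a: TIF
    tif_b: TIF
    overlap_width: int
    gap: int
    frac_a: float
    frac_b: float
    tss_tss_distance: int
    pattern: str = ""

    @property
    def signed_offset(self) -> int:
        """Overlap width, or minus the gap when disjoint."""
        return self.overlap_width if self.overlap_width > 0 else -self.gap


@dataclass(frozen=True)
class ReadThroughCall:
    tif_id: str
    upstream_gene: str
    downstream_gene: str
    tss_location: str  # inside | near
    pas_location: str


def _strand_tss(tif: TIF) -> int:
    return tif.tss_cluster.dominant_pos


def pairwise_overlap(tifs: list[TIF],
                     max_tss_window: int = OVERLAP_WINDOW) -> list[OverlapRecord]:
    """Overlap records for ordered same-strand TIF pairs originating within
    ``max_tss_window`` of each other."""
    grouped: dict[tuple[str, str], list[TIF]] = {}
    for t in tifs:
        grouped.setdefault((t.chrom, t.strand), []).append(t)
    records = []
    for (chrom, strand), group in sorted(grouped.items()):
        # transcription order: upstream = smaller TSS on +, larger on -
        group.sort(key=lambda t: _strand_tss(t) if strand == "+" else -_strand_tss(t))
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                dist = abs(_strand_tss(b) - _strand_tss(a))
                if dist > max_tss_window:
                    break
                records.append(_overlap_record(a, b, dist))
    for rec in records:
        rec.pattern = classify_pattern(rec)
    return records


def _overlap_record(a: TIF, b: TIF, tss_dist: int) -> OverlapRecord:
    (a0, a1), (b0, b1) = a.span, b.span
    ov = max(0, min(a1, b1) - max(a0, b0))
    gap = 0 if ov > 0 else max(b0 - a1, a0 - b1, 0)
    return OverlapRecord(
        tif_a=a, tif_b=b, overlap_width=ov, gap=gap,
        frac_a=ov / (a1 - a0), frac_b=ov / (b1 - b0),
        tss_tss_distance=tss_dist,
    )


def classify_pattern(record: OverlapRecord) -> str:
    """Partition an overlap record into one of the five patterns."""
    if record.overlap_width == 0:
        return "disjoint"
    hi_a, hi_b = record.frac_a > 0.9, record.frac_b > 0.9
    if hi_a and hi_b:
        return "high_overlap"
    if hi_a or hi_b:
        return "truncated"
    if record.frac_a < 0.2 and record.frac_b < 0.2:
        return "low_tandem"
    return "other"


def tandem_pas_statistic(records: list[OverlapRecord],
                         window: int = PAS_WINDOW):
    """Fraction of overlapping pairs whose upstream PAS lies within ``window``
    downstream of the downstream TIF's TSS.

    Only overlapping records are considered; the strand-aware offset
    (upstream PAS - downstream TSS) must fall in [0, window].  Returns
    ``(fraction, flags)``; the fraction is None when no overlapping pair
    exists.
    """
    flags = []
    for rec in records:
        if rec.overlap_width == 0:
            continue
        a_pas = rec.tif_a.pas_cluster.dominant_pos
        b_tss = rec.tif_b.tss_cluster.dominant_pos
        offset = a_pas - b_tss if rec.tif_a.strand == "+" else b_tss - a_pas
        flags.append((rec, 0 <= offset <= window))
    if not flags:
        return None, []
    fraction = sum(hit for _, hit in flags) / len(flags)
    return fraction, flags


def detect_read_through(tifs: list[TIF], genes: list[GeneModel], tol: int = 200,
                        allow_skipped_genes: bool = False) -> list[ReadThroughCall]:
    """Call TIFs bridging two distinct neighbouring same-strand genes.

    A TIF is a read-through iff its TSS lies within (or within ``tol`` of)
    gene A's span and its PAS within (or within ``tol`` of) gene B's span,
    with A != B on the TIF's strand and B strand-aware downstream of A.
    Genes overlapping another same-strand gene are ambiguous and excluded
    from candidacy.  Unless ``allow_skipped_genes``, a third same-strand gene
    lying wholly inside the TIF span disqualifies the call.
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    unambiguous: dict[tuple[str, str], list[GeneModel]] = {}
    for key, group in by_key.items():
        group.sort(key=lambda g: g.start)
        keep = []
        for i, g in enumerate(group):
            ov = any(h.start < g.end and g.start < h.end
                     for j, h in enumerate(group) if j != i)
            if not ov:
                keep.append(g)
        unambiguous[key] = keep

    calls = []
    for tif in sorted(tifs, key=lambda t: (t.chrom, t.span, t.id)):
        group = unambiguous.get((tif.chrom, tif.strand), [])
        tss = tif.tss_cluster.dominant_pos
        pas = tif.pas_cluster.dominant_pos
        gene_a, loc_a = _locate(group, tss, tol)
        gene_b, loc_b = _locate(group, pas, tol)
        if gene_a is None or gene_b is None or gene_a.gene_id == gene_b.gene_id:
            continue
        downstream_ok = (gene_b.start >= gene_a.end if tif.strand == "+"
                         else gene_b.end <= gene_a.start)
        if not downstream_ok:
            continue
        if not allow_skipped_genes:
            lo, hi = min(tss, pas), max(tss, pas)
            skipped = [g for g in group
                       if g.gene_id not in (gene_a.gene_id, gene_b.gene_id)
                       and lo < g.start and g.end <= hi + 1]
            if skipped:
                continue
        calls.append(ReadThroughCall(tif.id, gene_a.gene_id, gene_b.gene_id,
                                     loc_a, loc_b))
    return calls


def _locate(genes: list[GeneModel], pos: int, tol: int):
    """Nearest gene containing ``pos`` or within ``tol`` of its span."""
    best = None
    for g in genes:
        if g.start <= pos < g.end:
            return g, "inside"
        dist = g.start - pos if pos < g.start else pos - (g.end - 1)
        if dist <= tol and (best is None or dist < best[1]):
            best = (g, dist)
    return (best[0], "near") if best else (None, None)


def overlap_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tif_a": r.tif_a.id, "tif_b": r.tif_b.id,
          "overlap_width": r.overlap_width, "gap": r.gap,
          "frac_a": r.frac_a, "frac_b": r.frac_b,
          "tss_tss_distance": r.tss_tss_distance,
          "signed_offset": r.signed_offset, "pattern": r.pattern}
         for r in records],
        columns=["tif_a", "tif_b", "overlap_width", "gap", "frac_a", "frac_b",
                 "tss_tss_distance", "signed_offset", "pattern"],
    )


def read_through_frame(calls: list[ReadThroughCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tif_id": c.tif_id, "upstream_gene": c.upstream_gene,
          "downstream_gene": c.downstream_gene,
          "tss_location": c.tss_location, "pas_location": c.pas_location}
         for c in calls],
        columns=["tif_id", "upstream_gene", "downstream_gene",
                 "tss_location", "pas_location"],
    )
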