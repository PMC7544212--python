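"""Assignment of TIFs to annotated transcripts and five-way classification.

Each TIF is compared with same-strand annotated transcripts whose spans
overlap its own.  d1 is the distance between the TIF's TSS-side boundary and
the transcript's 5' end, d2 between the PAS-side boundary and the 3' end
(strand-aware); the TIF is assigned to the overlapping transcript minimizing
d1 + d2 and inherits that transcript's gene.  With a 200 bp tolerance the
categories are: annotated (both within), new_tss, new_pas, new_boundaries,
and intergenic (no same-strand overlap).  Distances are measured from the
cluster dominant positions by default (the best single-nucleotide boundary
estimate); cluster edges are available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .assembly import TIF
from .io import GeneModel, TranscriptModel

ANNOT_TOL = 200
CATEGORIES = ("annotated", "new_tss", "new_pas", "new_boundaries", "intergenic")


@dataclass
class TIFAssignment:
    tif_id: str
    transcript_id: str | None
    gene_id: str | None
    d1: int | None  # TSS distance, bp
    d2: int | None  # PAS distance, bp
    category: str | None = None


@dataclass
class UnannotatedGene:
    """A merged non-overlapping transcribed region built from intergenic TIFs."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    tif_ids: list[str]


def _tif_boundaries(tif: TIF, use_edges: bool = False) -> tuple[int, int]:
    """(TSS-side, PAS-side) boundary positions of a TIF."""
    if not use_edges:
        return tif.tss_cluster.dominant_pos, tif.pas_cluster.dominant_pos
    if tif.strand == "+":
        return tif.tss_cluster.start, tif.pas_cluster.end - 1
    return tif.tss_cluster.end - 1, tif.pas_cluster.start


def build_transcript_index(transcripts: list[TranscriptModel]) -> dict:
    index: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        index.setdefault((t.chrom, t.strand), IntervalTree()).addi(t.start, t.end, t)
    return index


def assign_tif(tif: TIF, transcript_index: dict, use_edges: bool = False) -> TIFAssignment:
    """Assign a TIF to the same-strand overlapping transcript with least d1+d2.

    Ties break on smaller d1, then lexicographically smallest transcript_id;
    with no same-strand overlapping transcript the TIF stays unassigned.
    """
    tree = transcript_index.get((tif.chrom, tif.strand))
    start, end = tif.span
    candidates = [iv.data for iv in tree.overlap(start, end)] if tree else []
    if not candidates:
        return TIFAssignment(tif.id, None, None, None, None)
    tss_b, pas_b = _tif_boundaries(tif, use_edges)
    best = None
    for t in candidates:
        d1 = abs(tss_b - t.five_prime)
        d2 = abs(pas_b - t.three_prime)
        key = (d1 + d2, d1, t.transcript_id)
        if best is None or key < best[0]:
            best = (key, t, d1, d2)
    _, t, d1, d2 = best
    return TIFAssignment(tif.id, t.transcript_id, t.gene_id, d1, d2)


def classify_tif(assignment: TIFAssignment, tol: int = ANNOT_TOL) -> str:
    """Five-way category from (d1, d2) at the given tolerance (inclusive)."""
    if assignment.transcript_id is None:
        return "intergenic"
    near_tss = assignment.d1 <= tol
    near_pas = assignment.d2 <= tol
    if near_tss and near_pas:
        return "annotated"
    if not near_tss and near_pas:
        return "new_tss"
    if near_tss and not near_pas:
        return "new_pas"
    return "new_boundaries"


def assign_and_classify(tifs: list[TIF], transcripts: list[TranscriptModel],
                        tol: int = ANNOT_TOL, use_edges: bool = False) -> list[TIFAssignment]:
    index = build_transcript_index(transcripts)
    assignments = []
    for tif in tifs:
        a = assign_tif(tif, index, use_edges=use_edges)
        a.category = classify_tif(a, tol=tol)
        assignments.append(a)
    return assignments


def define_unannotated_genes(tifs: list[TIF], assignments: list[TIFAssignment],
                             genes: list[GeneModel]) -> list[UnannotatedGene]:
    """Merge intergenic TIFs into unannotated transcribed regions.

    Intergenic TIFs on one chrom/strand merge transitively when their spans
    overlap.  A region touching an annotated same-strand gene should not
    exist if classification was correct; such regions are discarded (and
    asserted against).
    """
    by_id = {t.id: t for t in tifs}
    intergenic = [by_id[a.tif_id] for a in assignments if a.category == "intergenic"]
    gene_trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(g.start, g.end, g)

    grouped: dict[tuple[str, str], list[TIF]] = {}
    for t in intergenic:
        grouped.setdefault((t.chrom, t.strand), []).append(t)

    regions: list[UnannotatedGene] = []
    for (chrom, strand), members in sorted(grouped.items()):
        members.sort(key=lambda t: t.span)
        current: list[TIF] = []
        cur_end = None
        for t in members + [None]:
            if t is None or (current and t.span[0] >= cur_end):
                start = min(m.span[0] for m in current)
                end = max(m.span[1] for m in current)
                tree = gene_trees.get((chrom, strand))
                overlapping = tree.overlap(start, end) if tree else set()
                assert not overlapping, (
                    f"intergenic region {chrom}:{start}-{end} overlaps an "
                    f"annotated same-strand gene; classification inconsistent")
                regions.append(UnannotatedGene(
                    id="", chrom=chrom, strand=strand, start=start, end=end,
                    tif_ids=sorted(m.id for m in current)))
                current = []
                cur_end = None
            if t is not None:
                current.append(t)
                cur_end = t.span[1] if cur_end is None else max(cur_end, t.span[1])
    regions.sort(key=lambda r: (r.chrom, r.start, r.strand))
    for i, r in enumerate(regions):
        r.id = f"UG{i + 1:04d}"
    return regions


def assignments_frame(assignments: list[TIFAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tif_id": a.tif_id, "transcript_id": a.transcript_id,
          "gene_id": a.gene_id, "d1": a.d1, "d2": a.d2, "category": a.category}
         for a in assignments],
        columns=["tif_id", "transcript_id", "gene_id", "d1", "d2", "category"],
    )
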