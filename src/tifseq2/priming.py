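"""Internal-priming artifact filtering of poly(A)-site tags.

Oligo-dT primers can anneal to genomic A-rich tracts instead of the poly(A)
tail, producing artifactual 3' ends.  A PAS tag whose downstream 10 genomic
nucleotides (on the transcript strand, starting at the base immediately after
the PAS base) contain at least 7 adenines is flagged as internal priming and
excluded from all downstream clustering.  The hexamer QC quantifies the
poly(A)-signal motif A[AT]TAAA at 15-30 nt upstream of kept versus flagged
sites; it is diagnostic only and never filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GenomeSequence, revcomp

HEXAMERS = ("AATAAA", "ATTAAA")
QC_WINDOW = (15, 30)  # hexamer start offsets, nt upstream of the PAS base
DOWNSTREAM_LEN = 10


@dataclass(frozen=True)
class PasContext:
    """Genomic context of one PAS tag on the transcript strand.

    ``downstream10`` starts at the base after the PAS base; ``upstream_window``
    covers offsets 15-30 counted from the base before the PAS.  Windows are
    reverse-complemented on the minus strand and truncated at contig edges
    (``a_count`` is then computed over the available bases; N never counts).
    """

    pas_pos: int
    strand: str
    downstream10: str
    upstream_window: str
    a_count: int


def downstream_sequence(genome: GenomeSequence, chrom: str, strand: str,
                        pas_pos: int, length: int = DOWNSTREAM_LEN) -> str:
    """Transcript-strand bases immediately 3' of the PAS base."""
    if strand == "+":
        return genome.fetch(chrom, pas_pos + 1, pas_pos + 1 + length, truncate=True)
    return revcomp(genome.fetch(chrom, pas_pos - length, pas_pos, truncate=True))


def upstream_sequence(genome: GenomeSequence, chrom: str, strand: str,
                      pas_pos: int, length: int) -> str:
    """Transcript-strand bases 5' of the PAS base, 5'->3'.

    The returned string ends at upstream offset 1 (the base before the PAS);
    near a contig edge it is shorter than ``length``.
    """
    if strand == "+":
        return genome.fetch(chrom, pas_pos - length, pas_pos, truncate=True)
    return revcomp(genome.fetch(chrom, pas_pos + 1, pas_pos + 1 + length, truncate=True))


def pas_context(genome: GenomeSequence, chrom: str, strand: str, pas_pos: int) -> PasContext:
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not 0 <= pas_pos < genome.lengths[chrom]:
        raise IndexError(f"PAS position {pas_pos} outside chromosome {chrom}")
    down = downstream_sequence(genome, chrom, strand, pas_pos)
    up = upstream_sequence(genome, chrom, strand, pas_pos, QC_WINDOW[1])
    # keep offsets 15..30: drop the 14 bases closest to the PAS
    window = up[: max(0, len(up) - (QC_WINDOW[0] - 1))]
    return PasContext(pas_pos, strand, down, window, down.count("A"))


def flag_internal_priming(ctx: PasContext, threshold: int = 7) -> bool:
    """True iff the downstream A-count reaches the internal-priming threshold."""
    if not 0 <= threshold <= DOWNSTREAM_LEN:
        raise ValueError(f"threshold must be within [0,{DOWNSTREAM_LEN}]")
    return ctx.a_count >= threshold


def filter_internal_priming(tags: pd.DataFrame, genome: GenomeSequence,
                            threshold: int = 7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition deduplicated tags into (kept, flagged) by the priming rule."""
    if tags.empty:
        return tags.copy(), tags.copy()
    flags = [
        flag_internal_priming(
            pas_context(genome, row.chrom, row.strand, row.pas_pos), threshold)
        for row in tags.itertuples()
    ]
    mask = pd.Series(flags, index=tags.index)
    return tags[~mask].reset_index(drop=True), tags[mask].reset_index(drop=True)


@dataclass
class HexamerQC:
    """Per-offset motif frequency table plus the 15-30 nt window summary."""

    table: pd.DataFrame      # columns: partition, offset, fraction
    summary: dict[str, float]  # partition -> fraction with >=1 match in 15-30


def hexamer_qc(partitions: dict[str, pd.DataFrame], genome: GenomeSequence,
               max_offset: int = 40) -> HexamerQC:
    """Poly(A)-signal motif frequencies upstream of kept vs flagged PAS tags.

    For each partition and each upstream start offset o (the hexamer occupies
    offsets o..o-5, read toward the PAS), the fraction of tags matching
    AATAAA or ATTAAA; the summary is the fraction of tags with at least one
    match starting anywhere in offsets 15-30.
    """
    rows = []
    summary = {}
    for name, tags in partitions.items():
        if tags.empty:
            continue
        seqs = [
            upstream_sequence(genome, r.chrom, r.strand, r.pas_pos, max_offset)
            for r in tags.itertuples()
        ]
        n = len(seqs)
        window_hit = 0
        frac_by_offset = {}
        for o in range(6, max_offset + 1):
            hits = sum(1 for s in seqs if _hexamer_at(s, o) in HEXAMERS)
            frac_by_offset[o] = hits / n
        for s in seqs:
            if any(_hexamer_at(s, o) in HEXAMERS
                   for o in range(QC_WINDOW[0], QC_WINDOW[1] + 1)):
                window_hit += 1
        summary[name] = window_hit / n
        rows.extend({"partition": name, "offset": o, "fraction": f}
                    for o, f in sorted(frac_by_offset.items()))
    table = pd.DataFrame(rows, columns=["partition", "offset", "fraction"])
    return HexamerQC(table, summary)


def _hexamer_at(upstream: str, offset: int) -> str:
    """Hexamer starting ``offset`` nt upstream, read in transcript direction.

    ``upstream`` ends at offset 1; a hexamer starting at offset o covers
    offsets o..o-5, i.e. slice [L-o, L-o+6).  Returns '' if out of range.
    """
    start = len(upstream) - offset
    if start < 0 or offset < 6:
        return ""
    return upstream[start:start + 6]
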