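"""TIF assembly: link TSS and PAS consensus clusters through supporting pairs.

A transcript isoform boundary (TIF) is a unique combination of one TSS
consensus cluster and one PAS consensus cluster supported by at least four
deduplicated read pairs summed across all samples.  Supporting pairs must
span between 300 bp and 2 Mb (inclusive base span |pas - tss| + 1).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .clustering import ConsensusCluster

MIN_SPAN = 300
MAX_SPAN = 2_000_000
MIN_SUPPORT = 4


@dataclass
class TIF:
    """A called transcript isoform boundary with per-sample pair support."""

    id: str
    chrom: str
    strand: str
    tss_cluster: ConsensusCluster
    pas_cluster: ConsensusCluster
    support: dict[str, int] = field(default_factory=dict)
    norm_support: dict[str, float] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tss_cluster.start, self.pas_cluster.start),
                max(self.tss_cluster.end, self.pas_cluster.end))

    @property
    def total_support(self) -> int:
        return sum(self.support.values())

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def tss_pos(self) -> int:
        return self.tss_cluster.dominant_pos

    @property
    def pas_pos(self) -> int:
        return self.pas_cluster.dominant_pos


def span_filter(tags: pd.DataFrame, min_span: int = MIN_SPAN,
                max_span: int = MAX_SPAN) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop pairs with extreme mate distances.

    Distance is the inclusive base span |pas_pos - tss_pos| + 1 (the molecule
    length implied by the boundaries); a pair is dropped iff it is shorter
    than ``min_span`` or longer than ``max_span``.
    """
    dist = (tags["pas_pos"] - tags["tss_pos"]).abs() + 1
    keep = (dist >= min_span) & (dist <= max_span)
    return (tags[keep].reset_index(drop=True),
            tags[~keep].reset_index(drop=True))


class _IntervalIndex:
    """Point lookup into non-overlapping sorted intervals of one chrom/strand."""

    def __init__(self, clusters: list[ConsensusCluster]) -> None:
        self.by_key: dict[tuple[str, str], tuple[list[int], list[int], list[ConsensusCluster]]] = {}
        grouped: dict[tuple[str, str], list[ConsensusCluster]] = {}
        for c in clusters:
            grouped.setdefault((c.chrom, c.strand), []).append(c)
        for key, grp in grouped.items():
            grp.sort(key=lambda c: c.start)
            self.by_key[key] = ([c.start for c in grp], [c.end for c in grp], grp)

    def lookup(self, chrom: str, strand: str, pos: int) -> ConsensusCluster | None:
        entry = self.by_key.get((chrom, strand))
        if entry is None:
            return None
        starts, ends, grp = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return grp[i]
        return None


def link_pairs(tags: pd.DataFrame, tss_clusters: list[ConsensusCluster],
               pas_clusters: list[ConsensusCluster]):
    """Assign each pair's boundaries to consensus clusters.

    A pair supports (tss_id, pas_id) iff its tss_pos lies inside that TSS
    consensus interval and its pas_pos inside that PAS interval on the same
    strand.  Returns ``(support, n_unassigned)`` where support maps
    (tss_id, pas_id) -> {sample: pair count}.
    """
    tss_index = _IntervalIndex(tss_clusters)
    pas_index = _IntervalIndex(pas_clusters)
    support: dict[tuple[str, str], dict[str, int]] = {}
    n_unassigned = 0
    for row in tags.itertuples():
        tss_c = tss_index.lookup(row.chrom, row.strand, row.tss_pos)
        pas_c = pas_index.lookup(row.chrom, row.strand, row.pas_pos)
        if tss_c is None or pas_c is None:
            n_unassigned += 1
            continue
        per_sample = support.setdefault((tss_c.id, pas_c.id), {})
        per_sample[row.sample] = per_sample.get(row.sample, 0) + 1
    return support, n_unassigned


def call_tifs(support: dict, tss_clusters: list[ConsensusCluster],
              pas_clusters: list[ConsensusCluster], samples: list[str] | None = None,
              min_support: int = MIN_SUPPORT,
              per_sample_min: int = 0) -> tuple[list[TIF], pd.DataFrame]:
    """Call TIFs from the support table and build the counts matrix.

    A (TSS, PAS) cluster combination becomes a TIF iff its summed support
    across all samples reaches ``min_support`` (set ``per_sample_min`` to
    additionally require that many pairs in at least one sample).  TIF ids
    are deterministic by (chrom, span start, span end); the counts matrix has
    one row per TIF id and one column per sample.
    """
    tss_by_id = {c.id: c for c in tss_clusters}
    pas_by_id = {c.id: c for c in pas_clusters}
    called = []
    for (tss_id, pas_id), per_sample in support.items():
        total = sum(per_sample.values())
        if total < min_support:
            continue
        if per_sample_min and max(per_sample.values()) < per_sample_min:
            continue
        tss_c, pas_c = tss_by_id[tss_id], pas_by_id[pas_id]
        called.append(TIF(
            id="", chrom=tss_c.chrom, strand=tss_c.strand,
            tss_cluster=tss_c, pas_cluster=pas_c, support=dict(per_sample),
        ))
    called.sort(key=lambda t: (t.chrom, t.span[0], t.span[1], t.strand))
    for i, t in enumerate(called):
        t.id = f"TIF{i + 1:06d}"
    if samples is None:
        samples = sorted({s for t in called for s in t.support})
    matrix = pd.DataFrame(
        [[t.support.get(s, 0) for s in samples] for t in called],
        index=[t.id for t in called], columns=samples, dtype=int,
    )
    return called, matrix
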