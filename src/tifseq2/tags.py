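"""Deduplicated single-nucleotide boundary pairs from raw aligned molecule records.

A raw record carries the two mate intervals of one sequenced molecule; the
boundary pair is the single base of the transcript's first (TSS) and last
(PAS) nucleotide.  PCR duplicates are removed UMI-tools style: unique
molecular identifiers within 1 mismatch, at transcription start sites within
1 bp, collapse into one molecule under the directional count rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TAG_COLUMNS = ["chrom", "strand", "tss_pos", "pas_pos", "umi", "sample", "count"]

REJECT_CROSS_CHROMOSOME = "cross_chromosome"
REJECT_DISCORDANT_STRAND = "discordant_strand"
REJECT_IMPROPER_ORIENTATION = "improper_orientation"


@dataclass(frozen=True)
class PairedTag:
    """One deduplicated molecule boundary pair.

    ``tss_pos``/``pas_pos`` are 0-based indices of the first/last transcribed
    base; on the plus strand tss_pos <= pas_pos, mirrored on the minus strand.
    """

    chrom: str
    strand: str
    tss_pos: int
    pas_pos: int
    umi: str
    sample: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.strand == "+" and self.tss_pos > self.pas_pos:
            raise ValueError("plus-strand tag with tss_pos > pas_pos")
        if self.strand == "-" and self.pas_pos > self.tss_pos:
            raise ValueError("minus-strand tag with pas_pos > tss_pos")


@dataclass(frozen=True)
class ChimeraEstimate:
    """Intermolecular circularization (chimera) rate from sample barcodes.

    Same-sample chimeras are invisible; under equal-mass pooling of k samples
    a chimera crosses barcodes with probability (k-1)/k, hence the correction
    corrected_rate = observed_fraction * k / (k - 1), capped at 1.
    """

    n_pairs_total: int
    n_cross_barcode: int
    k_samples: int
    observed_fraction: float
    corrected_rate: float


def extract_boundary_pairs(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn raw molecule records into single-base boundary pairs.

    Plus strand: tss = 5'-mate start, pas = 3'-mate end - 1 (rightmost base).
    Minus strand: tss = 5'-mate end - 1, pas = 3'-mate start.

    Returns ``(tags, rejected)``; rejected rows carry a ``reason`` column
    (cross-chromosome pairs, discordant mate strands, and pairs whose implied
    boundary ordering violates the strand, as circularization chimeras can
    produce).
    """
    df = raw.copy()
    if "chrom3" not in df.columns:
        df["chrom3"] = df["chrom"]
    if "strand3" not in df.columns:
        df["strand3"] = df["strand"]
    if "sample3" not in df.columns:
        df["sample3"] = df["sample"]

    plus = df["strand"] == "+"
    df["tss_pos"] = np.where(plus, df["mate5_start"], df["mate5_end"] - 1)
    df["pas_pos"] = np.where(plus, df["mate3_end"] - 1, df["mate3_start"])

    reason = pd.Series("", index=df.index, dtype=str)
    bad_orient = (plus & (df["tss_pos"] > df["pas_pos"])) | (
        ~plus & (df["pas_pos"] > df["tss_pos"]))
    reason[bad_orient] = REJECT_IMPROPER_ORIENTATION
    reason[df["strand3"] != df["strand"]] = REJECT_DISCORDANT_STRAND
    reason[df["chrom3"] != df["chrom"]] = REJECT_CROSS_CHROMOSOME

    rejected = df[reason != ""].copy()
    rejected["reason"] = reason[reason != ""]
    kept = df[reason == ""].copy()
    kept["count"] = 1
    tags = kept[TAG_COLUMNS + ["sample3"]].reset_index(drop=True)
    return tags, rejected


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("UMI length mismatch")
    return sum(x != y for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _linkable(count_a: int, count_b: int, method: str) -> bool:
    if method == "cluster":
        return True
    # directional adjacency (UMI-tools): an edge a->b requires
    # count_a >= 2*count_b - 1; components ignore edge direction.
    hi, lo = max(count_a, count_b), min(count_a, count_b)
    return hi >= 2 * lo - 1


def dedup_umis(tags: pd.DataFrame, umi_mismatch: int = 1, tss_shift: int = 1,
               pas_shift: int = 0, method: str = "directional") -> pd.DataFrame:
    """Collapse PCR duplicates of boundary tags.

    Tags are grouped by (sample, chrom, strand, pas window) and linked when
    their TSS positions differ by at most ``tss_shift`` and their UMIs by at
    most ``umi_mismatch``; with the default ``directional`` method an edge
    additionally requires the UMI-tools count rule (larger count >= 2x the
    smaller - 1).  Each connected component collapses to one tag positioned
    at its highest-count member (ties: smaller coordinate, then smaller UMI)
    whose count is the component sum.

    The default window tolerates TSS shifts only; the PAS is held exact
    (``pas_shift=0``), as poly(A)-slippage trimming upstream already
    stabilizes the 3' coordinate.
    """
    if method not in ("directional", "cluster"):
        raise ValueError(f"unknown dedup method {method!r}")
    if tags.empty:
        return tags.reindex(columns=TAG_COLUMNS)
    if tags["umi"].str.len().nunique() != 1:
        raise ValueError("mixed UMI lengths in input")

    if "count" not in tags.columns:
        tags = tags.assign(count=1)
    unique = (
        tags.groupby(["sample", "chrom", "strand", "tss_pos", "pas_pos", "umi"],
                     as_index=False)["count"].sum()
    )
    out_rows = []
    group_keys = ["sample", "chrom", "strand"]
    if pas_shift == 0:
        group_keys.append("pas_pos")
    for _, grp in unique.groupby(group_keys, sort=True):
        out_rows.extend(
            _dedup_group(grp, umi_mismatch, tss_shift, pas_shift, method))
    out = pd.DataFrame(out_rows, columns=TAG_COLUMNS)
    return (out.sort_values(TAG_COLUMNS[:6], kind="mergesort")
               .reset_index(drop=True))


def _dedup_group(grp: pd.DataFrame, umi_mismatch: int, tss_shift: int,
                 pas_shift: int, method: str) -> list[dict]:
    recs = grp.sort_values(["tss_pos", "pas_pos", "umi"]).to_dict("records")
    n = len(recs)
    uf = _UnionFind(n)
    by_tss: dict[int, list[int]] = {}
    for i, r in enumerate(recs):
        by_tss.setdefault(r["tss_pos"], []).append(i)
    for i, r in enumerate(recs):
        for dt in range(-tss_shift, tss_shift + 1):
            for j in by_tss.get(r["tss_pos"] + dt, ()):
                if j <= i:
                    continue
                o = recs[j]
                if pas_shift and abs(o["pas_pos"] - r["pas_pos"]) > pas_shift:
                    continue
                if hamming(r["umi"], o["umi"]) > umi_mismatch:
                    continue
                if _linkable(r["count"], o["count"], method):
                    uf.union(i, j)
    comps: dict[int, list[dict]] = {}
    for i, r in enumerate(recs):
        comps.setdefault(uf.find(i), []).append(r)
    rows = []
    for members in comps.values():
        rep = min(members,
                  key=lambda m: (-m["count"], m["tss_pos"], m["pas_pos"], m["umi"]))
        rows.append({
            "chrom": rep["chrom"], "strand": rep["strand"],
            "tss_pos": rep["tss_pos"], "pas_pos": rep["pas_pos"],
            "umi": rep["umi"], "sample": rep["sample"],
            "count": sum(m["count"] for m in members),
        })
    return rows


def estimate_chimera_rate(sample5, sample3, k_samples: int | None = None) -> ChimeraEstimate:
    """Estimate the intermolecular-circularization rate from barcode mismatches.

    ``sample5``/``sample3`` are the per-pair 5'- and 3'-side sample barcodes.
    Requires k >= 2 pooled samples (cross-barcode detection is undefined for
    a single library) and assumes equal-mass pooling.
    """
    s5 = pd.Series(sample5).reset_index(drop=True)
    s3 = pd.Series(sample3).reset_index(drop=True)
    if len(s5) != len(s3):
        raise ValueError("barcode arrays differ in length")
    if k_samples is None:
        k_samples = pd.concat([s5, s3]).nunique()
    if k_samples < 2:
        raise ValueError("chimera estimation requires at least 2 pooled samples")
    n_total = len(s5)
    n_cross = int((s5 != s3).sum())
    observed = n_cross / n_total if n_total else 0.0
    corrected = min(1.0, observed * k_samples / (k_samples - 1))
    return ChimeraEstimate(n_total, n_cross, k_samples, observed, corrected)


def estimate_duplicate_rate(raw: pd.DataFrame) -> float:
    """PCR duplicate rate from a raw library: extra exact copies per distinct row.

    Duplicates re-emit a molecule with identical coordinates, UMI and sample,
    so the number of rows in excess of the distinct row count estimates the
    per-molecule duplication rate.
    """
    cols = [c for c in raw.columns if c != "count"]
    n_rows = len(raw)
    n_distinct = len(raw.drop_duplicates(subset=cols))
    if n_distinct == 0:
        return 0.0
    return (n_rows - n_distinct) / n_distinct
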