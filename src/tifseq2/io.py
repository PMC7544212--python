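"""Readers and writers for on-disk formats and the in-memory genome/annotation model.

All internal coordinates are 0-based half-open.  GTF/GFF input (1-based,
inclusive) is converted at the boundary; BED output is written natively
0-based.  A transcription *boundary position* (TSS or PAS) is the 0-based
index of the single genomic base that is the transcript's first or last
transcribed nucleotide.

The paired-tag TSV dialect (one sequenced molecule per row, tab-separated,
with a header line) has eight mandatory columns::

    chrom  strand  mate5_start  mate5_end  mate3_start  mate3_end  umi  sample

plus three optional trailing columns ``chrom3``, ``strand3`` and ``sample3``
describing the 3'-side mate when it differs from the 5' side (cross-chromosome
alignments, discordant strands, or chimeric molecules carrying a different
3' sample barcode).  Absent optional columns default to the 5'-side values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PAIR_COLUMNS = [
    "chrom", "strand", "mate5_start", "mate5_end",
    "mate3_start", "mate3_end", "umi", "sample",
]
OPTIONAL_PAIR_COLUMNS = ["chrom3", "strand3", "sample3"]


class AnnotationError(ValueError):
    """Raised when a GTF/GFF file cannot be parsed into transcript models."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def to_zero_based(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Per-chromosome uppercase A/C/G/T/N sequences with bounds checking."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int, truncate: bool = False) -> str:
        """Return genome[start:end) on the forward strand.

        With ``truncate=True`` the window is clipped to the chromosome
        (used for boundary contexts near contig edges); otherwise an
        out-of-bounds lookup is an error.
        """
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if truncate:
            start, end = max(start, 0), min(end, len(seq))
            if start >= end:
                return ""
        elif start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"window [{start},{end}) outside chromosome {chrom} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


def read_fasta(path) -> GenomeSequence:
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open transcript span
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """0-based index of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """0-based index of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # union of member transcript spans
    end: int


def _validate_gxf_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )


def read_annotation(path) -> tuple[list[TranscriptModel], list[GeneModel]]:
    """Parse a GTF (Gencode dialect) or GFF3 file into transcript and gene models.

    Only transcript and gene records are consumed; coordinates are converted
    to 0-based half-open.  Genes absent from the file are synthesized as the
    union of their transcripts' spans.  Ordering is deterministic by
    (chrom, start, transcript_id).
    """
    _validate_gxf_lines(path)
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:
        if "empty" in str(exc).lower() or _file_has_no_records(path):
            warnings.warn(f"annotation file {path} contains no records")
            logger.warning("annotation file %s contains no records", path)
            return [], []
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    transcripts: list[TranscriptModel] = []
    for feat in db.features_of_type("transcript"):
        tid = _single_attr(feat, "transcript_id", "ID", path)
        gid = _single_attr(feat, "gene_id", "Parent", path, required=True,
                           what=f"transcript {tid}")
        start, end = to_zero_based(feat.start, feat.end)
        transcripts.append(TranscriptModel(tid, gid, feat.seqid, feat.strand, start, end))
    if not transcripts:
        warnings.warn(f"annotation file {path} contains no transcript records")
        logger.warning("annotation file %s contains no transcript records", path)
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))

    explicit_genes = {}
    for feat in db.features_of_type("gene"):
        gid = _single_attr(feat, "gene_id", "ID", path)
        start, end = to_zero_based(feat.start, feat.end)
        explicit_genes[gid] = GeneModel(gid, feat.seqid, feat.strand, start, end)

    genes: dict[str, GeneModel] = {}
    for t in transcripts:
        g = genes.get(t.gene_id)
        if g is None:
            g = explicit_genes.get(t.gene_id) or GeneModel(
                t.gene_id, t.chrom, t.strand, t.start, t.end)
        genes[t.gene_id] = GeneModel(
            g.gene_id, g.chrom, g.strand,
            min(g.start, t.start), max(g.end, t.end),
        )
    gene_list = sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))
    return transcripts, gene_list


def _file_has_no_records(path) -> bool:
    with open(path) as fh:
        return all(not ln.strip() or ln.startswith("#") for ln in fh)


def _single_attr(feat, name, alt, path, required=False, what=None):
    vals = feat.attributes.get(name) or feat.attributes.get(alt)
    if not vals:
        if required:
            raise AnnotationError(
                f"{path}: {what or name}: missing required {name!r} attribute")
        raise AnnotationError(f"{path}: record without {name!r} attribute")
    return vals[0]


def write_annotation(transcripts: list[TranscriptModel], path,
                     source: str = "tifseq2") -> None:
    """Write transcript models as Gencode-dialect GTF (1-based inclusive)."""
    lines = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid in sorted(by_gene):
        ts = by_gene[gid]
        start0 = min(t.start for t in ts)
        end0 = max(t.end for t in ts)
        s1, e1 = to_one_based(start0, end0)
        lines.append((ts[0].chrom, start0, 0, (
            f"{ts[0].chrom}\t{source}\tgene\t{s1}\t{e1}\t.\t{ts[0].strand}\t.\t"
            f'gene_id "{gid}";'
        )))
        for t in sorted(ts, key=lambda t: (t.start, t.transcript_id)):
            s1, e1 = to_one_based(t.start, t.end)
            lines.append((t.chrom, t.start, 1, (
                f"{t.chrom}\t{source}\ttranscript\t{s1}\t{e1}\t.\t{t.strand}\t.\t"
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            )))
    lines.sort(key=lambda rec: (rec[0], rec[1], rec[2], rec[3]))
    with open(path, "w") as fh:
        for rec in lines:
            fh.write(rec[3] + "\n")


# ---------------------------------------------------------------------------
# paired-tag ingestion
# ---------------------------------------------------------------------------

def read_paired_tags(path, umi_tag: str = "RX", sample: str | None = None) -> pd.DataFrame:
    """Read raw (pre-dedup) molecule records from TSV or SAM/BAM.

    Returns a DataFrame with columns ``chrom, strand, mate5_start, mate5_end,
    mate3_start, mate3_end, umi, sample, chrom3, strand3, sample3,
    cross_chromosome``.  Cross-chromosome records are retained but flagged;
    they are dropped downstream by boundary extraction.
    """
    path = str(path)
    if path.endswith((".sam", ".bam", ".cram")):
        df = _read_pairs_sam(path, umi_tag=umi_tag, sample=sample)
    else:
        df = _read_pairs_tsv(path)
    df["cross_chromosome"] = df["chrom3"] != df["chrom"]
    return df


def _read_pairs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "strand": str, "umi": str, "sample": str,
               "chrom3": str, "strand3": str, "sample3": str},
    )
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col, default in zip(OPTIONAL_PAIR_COLUMNS, ["chrom", "strand", "sample"]):
        if col not in df.columns:
            df[col] = df[default]
        else:
            df[col] = df[col].fillna(df[default])
    if df["umi"].isna().any() or (df["umi"].astype(str).str.len() == 0).any():
        raise ValueError(f"{path}: rows with missing UMI")
    bad = ~df["strand"].isin(["+", "-"]) | ~df["strand3"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown strand code in rows {df.index[bad].tolist()[:5]}")
    return df[PAIR_COLUMNS + OPTIONAL_PAIR_COLUMNS]


def _umi_from_read(read, umi_tag: str) -> str:
    if read.has_tag(umi_tag):
        return str(read.get_tag(umi_tag))
    name = read.query_name
    if "_" in name:
        return name.rsplit("_", 1)[1]
    raise ValueError(f"read {name}: no UMI in tag {umi_tag!r} or read-name suffix")


def _read_pairs_sam(path, umi_tag: str = "RX", sample: str | None = None) -> pd.DataFrame:
    """Name-paired alignments -> raw molecule records.

    The first-of-pair mate is taken as the 5' read.  Mate strands follow FR
    orientation: the 3' mate of a plus-strand molecule aligns to the reverse
    strand.  Sample comes from the read group, else the file name stem.
    """
    import os

    mode = "rb" if path.endswith(".bam") else "r"
    default_sample = sample or os.path.splitext(os.path.basename(path))[0]
    pending: dict[str, pysam.AlignedSegment] = {}
    rows = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r5, r3 = (read, mate) if read.is_read1 else (mate, read)
            strand5 = "-" if r5.is_reverse else "+"
            # FR orientation: 3' mate reversed relative to the molecule strand
            strand3 = "+" if r3.is_reverse else "-"
            smp = default_sample
            if r5.has_tag("RG"):
                smp = str(r5.get_tag("RG"))
            rows.append({
                "chrom": r5.reference_name, "strand": strand5,
                "mate5_start": r5.reference_start, "mate5_end": r5.reference_end,
                "mate3_start": r3.reference_start, "mate3_end": r3.reference_end,
                "umi": _umi_from_read(r5, umi_tag), "sample": smp,
                "chrom3": r3.reference_name, "strand3": strand3, "sample3": smp,
            })
    if pending:
        logger.warning("%d unpaired reads ignored in %s", len(pending), path)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS + OPTIONAL_PAIR_COLUMNS)


def write_paired_tags(df: pd.DataFrame, path) -> None:
    cols = [c for c in PAIR_COLUMNS + OPTIONAL_PAIR_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------

def _bed_score(norm_count: float) -> int:
    return int(round(norm_count * 10))


def write_bed(records, path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write tags/clusters as BED6 or TIFs as BED12, sorted.

    Cluster-like records need ``id, chrom, strand, start, end`` and a total
    normalized count (score = normalized count x10, rounded).  TIF records
    are written as BED12 with two blocks marking the TSS and PAS clusters.
    """
    lines = []
    for rec in records:
        if hasattr(rec, "tss_cluster") and hasattr(rec, "pas_cluster"):
            lines.append(_bed12_line(rec))
        else:
            norm = getattr(rec, "total_norm", None)
            if norm is None:
                norm = sum(getattr(rec, "norm_counts", {}).values())
            lines.append((rec.chrom, rec.start, rec.end,
                          f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.id}\t"
                          f"{_bed_score(norm)}\t{rec.strand}"))
    if chrom_lengths is not None:
        for chrom, start, end, _ in lines:
            if not (0 <= start < end <= chrom_lengths.get(chrom, end)):
                raise ValueError(
                    f"BED interval {chrom}:{start}-{end} outside chromosome")
    lines.sort(key=lambda rec: (rec[0], rec[1], rec[2], rec[3]))
    with open(path, "w") as fh:
        for rec in lines:
            fh.write(rec[3] + "\n")


def _bed12_line(tif):
    start, end = tif.span
    blocks = sorted([
        (tif.tss_cluster.start, tif.tss_cluster.end),
        (tif.pas_cluster.start, tif.pas_cluster.end),
    ])
    sizes = ",".join(str(e - s) for s, e in blocks)
    starts = ",".join(str(s - start) for s, _ in blocks)
    score = _bed_score(sum(tif.norm_support.values())) if tif.norm_support else \
        min(1000, tif.total_support)
    line = (f"{tif.chrom}\t{start}\t{end}\t{tif.id}\t{score}\t{tif.strand}\t"
            f"{start}\t{end}\t0,0,0\t2\t{sizes}\t{starts}")
    return (tif.chrom, start, end, line)


def write_counts_matrix(matrix: pd.DataFrame, path) -> None:
    """Counts matrix TSV: rows = TIF ids, columns = samples."""
    matrix.to_csv(path, sep="\t", index_label="tif_id")
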