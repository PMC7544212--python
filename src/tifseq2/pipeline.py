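"""End-to-end orchestration: dedup -> priming filter -> clustering -> TIF
calling -> annotation -> overlap/read-through, with a run manifest.

Every run writes its resolved configuration next to the outputs so it can be
reproduced from the output directory alone.  Per-chromosome work is
independent by construction; the worker count changes scheduling only, never
the outputs.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import assembly, clustering, overlap as overlap_mod, priming, tags as tags_mod
from . import io as io_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage thresholds (defaults are the method's printed values) + paths."""

    pairs: str = ""
    genome_fasta: str = ""
    gtf: str = ""
    outdir: str = "tifseq2_out"
    umi_mismatch: int = 1
    tss_shift: int = 1
    pas_shift: int = 0
    dedup_method: str = "directional"
    priming_max_a: int = 7
    cluster_window: int = 10
    alpha_ref: float = 1.25
    T: float = 1e6
    fit_range: tuple = (10.0, 1000.0)
    max_low_samples: int = 1
    min_support: int = 4
    min_span: int = 300
    max_span: int = 2_000_000
    annot_tol: int = 200
    overlap_window: int = 10_000
    pas_window: int = 2_000
    workers: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.fit_range, list):
            cfg.fit_range = tuple(cfg.fit_range)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["fit_range"] = list(self.fit_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    tifs: list
    matrix: pd.DataFrame
    tss_consensus: list
    pas_consensus: list
    assignments: list
    unannotated_genes: list
    overlaps: list
    read_through: list
    chimera: tags_mod.ChimeraEstimate | None
    dedup_tags: pd.DataFrame
    flagged_tags: pd.DataFrame
    tandem_pas_fraction: float | None
    summary: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def _map_ordered(fn, items, workers: int):
    """Apply ``fn`` over items, preserving order regardless of worker count."""
    items = list(items)
    if workers <= 1 or len(items) <= 1:
        return [fn(x) for x in items]
    with ThreadPoolExecutor(max_workers=workers) as ex:
        return list(ex.map(fn, items))


@_stage("normalize")
def _normalized_positions(dedup: pd.DataFrame, kind: str, cfg: RunConfig) -> pd.DataFrame:
    """Per-position per-sample raw and normalized counts for one boundary kind.

    The power-law fit is per sample across the whole genome; positions failing
    the low-coverage rule (normalized < 1 in more than ``max_low_samples``
    samples) are removed.
    """
    pos_col = "tss_pos" if kind == "TSS" else "pas_pos"
    counts = (dedup.groupby(["chrom", "strand", pos_col, "sample"])
              .size().rename("raw").reset_index())
    counts = counts.rename(columns={pos_col: "pos"})
    samples = sorted(dedup["sample"].unique())
    norm_parts = []
    for sample in samples:
        sub = counts[counts["sample"] == sample].copy()
        revcum = clustering.reverse_cumulative(sub["raw"].to_numpy())
        fit = clustering.fit_power_law(revcum, fit_range=tuple(cfg.fit_range))
        sub["norm"] = clustering.normalize_counts(
            sub["raw"].to_numpy(), fit, alpha_ref=cfg.alpha_ref, T=cfg.T)
        norm_parts.append(sub)
        logger.info("%s %s power-law fit: alpha_hat=%.3f over %d points",
                    kind, sample, fit.alpha_hat, fit.n_points)
    norm = pd.concat(norm_parts, ignore_index=True)

    wide = norm.pivot_table(index=["chrom", "strand", "pos"], columns="sample",
                            values="norm", fill_value=0.0)
    kept_index = clustering.filter_low_coverage(wide, cfg.max_low_samples)
    kept_keys = set(kept_index)
    mask = [key in kept_keys
            for key in zip(norm["chrom"], norm["strand"], norm["pos"])]
    return norm[mask].reset_index(drop=True)


@_stage("cluster")
def _cluster_kind(norm: pd.DataFrame, kind: str, cfg: RunConfig) -> list:
    keys = sorted(set(zip(norm["chrom"], norm["strand"], norm["sample"])))

    def one(key):
        chrom, strand, sample = key
        sub = norm[(norm["chrom"] == chrom) & (norm["strand"] == strand)
                   & (norm["sample"] == sample)]
        return clustering.cluster_tags(sub, chrom, strand, kind, sample,
                                       window=cfg.cluster_window)

    per_sample = [c for part in _map_ordered(one, keys, cfg.workers) for c in part]
    return clustering.build_consensus(per_sample, window=cfg.cluster_window)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute all stages in order and (optionally) write the output files."""
    import os

    summary: dict = {"stages": {}}
    if write_outputs:
        os.makedirs(config.outdir, exist_ok=True)
        config.to_yaml(os.path.join(config.outdir, "resolved_config.yaml"))

    try:
        raw = io_mod.read_paired_tags(config.pairs)
    except Exception as exc:
        raise StageError("read_pairs", exc) from exc
    summary["stages"]["input_pairs"] = len(raw)

    boundary_tags, rejected = tags_mod.extract_boundary_pairs(raw)
    summary["stages"]["rejected"] = (
        rejected["reason"].value_counts().to_dict() if len(rejected) else {})

    # chimera estimate from barcode mismatches on all pairs (before any
    # mapping-based rejection: chimeras are enriched among rejected pairs);
    # mismatched pairs are artifacts and are dropped below
    chimera = None
    n_samples = raw["sample"].nunique()
    if n_samples >= 2:
        chimera = tags_mod.estimate_chimera_rate(
            raw["sample"], raw["sample3"], n_samples)
        summary["chimera"] = {
            "observed_fraction": chimera.observed_fraction,
            "corrected_rate": chimera.corrected_rate,
            "k_samples": chimera.k_samples,
        }
    concordant = boundary_tags[
        boundary_tags["sample"] == boundary_tags["sample3"]
    ].drop(columns=["sample3"]).reset_index(drop=True)
    summary["stages"]["barcode_concordant"] = len(concordant)

    try:
        dedup = tags_mod.dedup_umis(
            concordant, umi_mismatch=config.umi_mismatch,
            tss_shift=config.tss_shift, pas_shift=config.pas_shift,
            method=config.dedup_method)
    except Exception as exc:
        raise StageError("dedup", exc) from exc
    summary["stages"]["deduplicated"] = len(dedup)

    try:
        genome = io_mod.read_fasta(config.genome_fasta)
    except Exception as exc:
        raise StageError("priming_filter", exc) from exc
    kept, flagged = priming.filter_internal_priming(
        dedup, genome, threshold=config.priming_max_a)
    summary["stages"]["priming_flagged"] = len(flagged)
    summary["stages"]["priming_kept"] = len(kept)

    spanned, dropped = assembly.span_filter(
        kept, min_span=config.min_span, max_span=config.max_span)
    summary["stages"]["span_filtered_out"] = len(dropped)

    tss_norm = _normalized_positions(spanned, "TSS", config)
    pas_norm = _normalized_positions(spanned, "PAS", config)
    tss_consensus = _cluster_kind(tss_norm, "TSS", config)
    pas_consensus = _cluster_kind(pas_norm, "PAS", config)
    summary["stages"]["tss_clusters"] = len(tss_consensus)
    summary["stages"]["pas_clusters"] = len(pas_consensus)
    summary["cluster_width_p80"] = {
        "TSS": clustering.cluster_width_quantile(tss_consensus),
        "PAS": clustering.cluster_width_quantile(pas_consensus),
    }

    support, n_unassigned = assembly.link_pairs(spanned, tss_consensus, pas_consensus)
    samples = sorted(spanned["sample"].unique())
    tifs, matrix = assembly.call_tifs(
        support, tss_consensus, pas_consensus, samples=samples,
        min_support=config.min_support)
    summary["stages"]["unassigned_pairs"] = n_unassigned
    summary["stages"]["tifs"] = len(tifs)

    assignments: list = []
    unannotated: list = []
    if config.gtf:
        try:
            transcripts, genes = io_mod.read_annotation(config.gtf)
        except Exception as exc:
            raise StageError("annotate", exc) from exc
        assignments = annotate_mod.assign_and_classify(
            tifs, transcripts, tol=config.annot_tol)
        unannotated = annotate_mod.define_unannotated_genes(tifs, assignments, genes)
        tally = pd.Series([a.category for a in assignments]).value_counts().to_dict()
        summary["categories"] = {c: int(tally.get(c, 0))
                                 for c in annotate_mod.CATEGORIES}
        summary["stages"]["unannotated_genes"] = len(unannotated)
    else:
        genes = []

    overlaps = overlap_mod.pairwise_overlap(tifs, max_tss_window=config.overlap_window)
    frac, _flags = overlap_mod.tandem_pas_statistic(overlaps, window=config.pas_window)
    read_through = (overlap_mod.detect_read_through(tifs, genes, tol=config.annot_tol)
                    if genes else [])
    summary["stages"]["overlap_pairs"] = len(overlaps)
    summary["stages"]["read_through"] = len(read_through)
    if frac is not None:
        summary["tandem_pas_fraction"] = frac

    result = PipelineResult(
        tifs=tifs, matrix=matrix, tss_consensus=tss_consensus,
        pas_consensus=pas_consensus, assignments=assignments,
        unannotated_genes=unannotated, overlaps=overlaps,
        read_through=read_through, chimera=chimera, dedup_tags=dedup,
        flagged_tags=flagged, tandem_pas_fraction=frac, summary=summary,
    )
    if write_outputs:
        _write_outputs(result, config, genome)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig, genome) -> None:
    import os

    out = config.outdir
    io_mod.write_paired_tags(result.dedup_tags, os.path.join(out, "dedup.tsv"))
    io_mod.write_bed(result.tss_consensus, os.path.join(out, "tss_clusters.bed"),
                     genome.lengths)
    io_mod.write_bed(result.pas_consensus, os.path.join(out, "pas_clusters.bed"),
                     genome.lengths)
    io_mod.write_bed(result.tifs, os.path.join(out, "tifs.bed"), genome.lengths)
    io_mod.write_counts_matrix(result.matrix, os.path.join(out, "counts.tsv"))
    annotate_mod.assignments_frame(result.assignments).to_csv(
        os.path.join(out, "assignments.tsv"), sep="\t", index=False)
    overlap_mod.overlap_frame(result.overlaps).to_csv(
        os.path.join(out, "overlaps.tsv"), sep="\t", index=False,
        float_format="%.6g")
    overlap_mod.read_through_frame(result.read_through).to_csv(
        os.path.join(out, "read_through.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "unannotated_genes.bed"), "w") as fh:
        for r in result.unannotated_genes:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand}\n")
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
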