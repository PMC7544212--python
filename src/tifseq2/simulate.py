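"""Synthetic genomes, annotations and paired boundary-tag libraries with
known ground truth.

The generator emulates a multi-sample paired 5'/3' boundary-tag library:
isoform abundances follow a discrete Pareto law, molecule boundaries carry
rounded Gaussian jitter, every molecule gets a random 8-mer UMI, PCR
duplicates re-emit exact copies, internal-priming artifacts move the PAS to
a planted genomic A-rich tract, and circularization chimeras swap the
3' side of a molecule with that of another molecule pooled from any sample
(the 3' sample barcode travels with the swapped side).

Reference construction plants, at every true PAS, an A[AT]TAAA hexamer
15-30 nt upstream and guarantees at most 6 adenines in any downstream
10-base window even under jitter; artifact sites carry >= 7 downstream
adenines by construction.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeSequence, TranscriptModel, PAIR_COLUMNS, OPTIONAL_PAIR_COLUMNS

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    The default layout holds 20 genes: 8 isolated single-isoform genes,
    3 genes with two isoforms each, 2 tandem-overlap pairs with designed
    overlap fractions, 2 read-through pairs (each contributing a fusion
    isoform), and 1 unannotated gene.
    """

    seed: int
    n_samples: int = 4
    depth: float = 50.0          # mean molecules per sample at unit abundance
    alpha: float = 1.25          # discrete Pareto exponent of isoform abundance
    max_abundance: int = 10      # cap on Pareto draws (library dynamic range)
    jitter_sd: float = 1.0       # bp, rounded zero-mean noise per boundary
    pcr_dup_rate: float = 0.3
    priming_rate: float = 0.05
    chimera_rate: float = 0.02
    umi_length: int = 8
    n_chroms: int = 2
    chrom_length: int = 120_000
    n_isolated: int = 8
    n_multi: int = 3
    n_tandem_pairs: int = 2
    n_readthrough_pairs: int = 2
    n_unannotated: int = 1
    tandem_overlap_fracs: tuple = ((0.10, 0.15), (0.15, 0.08))
    mate_length: int = 75

    def __post_init__(self) -> None:
        for name in ("pcr_dup_rate", "priming_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0,1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimTruth:
    """Ground truth: isoform table, planted artifact sites, per-molecule labels."""

    isoforms: pd.DataFrame       # iso_id, gene_id, chrom, strand, tss, pas, ...
    artifact_sites: pd.DataFrame  # iso_id, chrom, strand, pos
    molecules: pd.DataFrame | None = None
    config: SimConfig | None = None


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _plant(chrom_arr: np.ndarray, strand: str, genome_positions, seq: str) -> None:
    """Write transcript-strand ``seq`` at the given genome positions."""
    comp = str.maketrans("ACGT", "TGCA")
    if strand == "-":
        seq = seq.translate(comp)
    for pos, base in zip(genome_positions, seq):
        chrom_arr[pos] = base.encode()


def _pas_positions(pas: int, strand: str, offsets) -> list[int]:
    """Genome positions of transcript-strand offsets relative to the PAS base.

    Offset 0 is the PAS base itself, positive offsets run downstream.
    """
    step = 1 if strand == "+" else -1
    return [pas + step * o for o in offsets]


@dataclass
class _Iso:
    iso_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    pas: int
    kind: str
    annotated: bool
    artifact_pos: int


def generate_reference(config: SimConfig) -> tuple[GenomeSequence, list[TranscriptModel], SimTruth]:
    """Random genome + annotation + truth skeleton, deterministic given seed."""
    rng = np.random.default_rng([config.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chroms = {
        name: rng.choice(BASES, size=config.chrom_length).copy()
        for name in chrom_names
    }

    isoforms: list[_Iso] = []
    cursors = {name: 2_000 for name in chrom_names}
    chrom_cycle = 0

    def next_chrom() -> str:
        nonlocal chrom_cycle
        name = chrom_names[chrom_cycle % len(chrom_names)]
        chrom_cycle += 1
        return name

    def place(length: int, chrom: str) -> int:
        start = cursors[chrom] + int(rng.integers(2_500, 5_000))
        cursors[chrom] = start + length
        if cursors[chrom] > config.chrom_length - 2_000:
            raise ValueError(
                "gene layout does not fit the chromosome length; increase "
                "chrom_length or reduce the layout")
        return start

    def make_iso(gene_id, iso_id, chrom, strand, left, right, kind, annotated):
        tss, pas = (left, right) if strand == "+" else (right, left)
        body_mid = left + (right - left) * 3 // 5
        artifact = body_mid
        isoforms.append(_Iso(iso_id, gene_id, chrom, strand, tss, pas, kind,
                             annotated, artifact))

    gi = 0
    for _ in range(config.n_isolated):
        gi += 1
        chrom = next_chrom()
        strand = "+" if gi % 2 else "-"
        length = int(rng.integers(800, 2_500))
        left = place(length, chrom)
        make_iso(f"g{gi:03d}", f"g{gi:03d}.i1", chrom, strand,
                 left, left + length - 1, "isolated", True)

    for _ in range(config.n_multi):
        gi += 1
        chrom = next_chrom()
        strand = "+" if gi % 2 else "-"
        length = int(rng.integers(1_600, 2_800))
        left = place(length + 500, chrom)
        right = left + length - 1
        make_iso(f"g{gi:03d}", f"g{gi:03d}.i1", chrom, strand,
                 left, right, "multi", True)
        # second isoform: inner alternative TSS and PAS, >=60 bp from the first
        make_iso(f"g{gi:03d}", f"g{gi:03d}.i2", chrom, strand,
                 left + 400, right - 320, "multi", True)

    for pair_idx in range(config.n_tandem_pairs):
        gi += 2
        chrom = next_chrom()
        strand = "+" if pair_idx % 2 else "-"
        frac_a, frac_b = config.tandem_overlap_fracs[
            pair_idx % len(config.tandem_overlap_fracs)]
        ov = 300
        len_a = int(round(ov / frac_a))
        len_b = int(round(ov / frac_b))
        left_a = place(len_a + len_b - ov, chrom)
        if strand == "+":
            a0, b0 = left_a, left_a + len_a - ov
        else:  # upstream unit is the rightmost on the minus strand
            b0, a0 = left_a, left_a + len_b - ov
        make_iso(f"g{gi - 1:03d}", f"g{gi - 1:03d}.i1", chrom, strand,
                 a0, a0 + len_a - 1, "tandem_up", True)
        make_iso(f"g{gi:03d}", f"g{gi:03d}.i1", chrom, strand,
                 b0, b0 + len_b - 1, "tandem_down", True)

    for _ in range(config.n_readthrough_pairs):
        gi += 2
        chrom = next_chrom()
        strand = "+" if gi % 2 else "-"
        len_a = int(rng.integers(900, 1_600))
        len_b = int(rng.integers(900, 1_600))
        gap = int(rng.integers(500, 1_200))
        left = place(len_a + gap + len_b, chrom)
        a_left, b_left = left, left + len_a + gap
        if strand == "-":
            # upstream gene A occupies the right block on the minus strand
            a_left, b_left = left + len_b + gap, left
        ga, gb = f"g{gi - 1:03d}", f"g{gi:03d}"
        make_iso(ga, f"{ga}.i1", chrom, strand, a_left, a_left + len_a - 1,
                 "readthrough_a", True)
        make_iso(gb, f"{gb}.i1", chrom, strand, b_left, b_left + len_b - 1,
                 "readthrough_b", True)
        # fusion isoform: gene A's TSS joined to gene B's PAS
        fus_left = min(a_left, b_left)
        fus_right = max(a_left + len_a, b_left + len_b) - 1
        make_iso(ga, f"{ga}-{gb}.fusion", chrom, strand, fus_left, fus_right,
                 "fusion", False)

    for _ in range(config.n_unannotated):
        gi += 1
        chrom = next_chrom()
        strand = "+" if gi % 2 else "-"
        length = int(rng.integers(800, 1_800))
        left = place(length, chrom)
        make_iso(f"u{gi:03d}", f"u{gi:03d}.i1", chrom, strand,
                 left, left + length - 1, "unannotated", False)

    _plant_pas_contexts(chroms, isoforms, rng)

    genome = GenomeSequence({
        name: arr.tobytes().decode() for name, arr in sorted(chroms.items())
    })
    transcripts = [
        TranscriptModel(iso.iso_id, iso.gene_id, iso.chrom, iso.strand,
                        min(iso.tss, iso.pas), max(iso.tss, iso.pas) + 1)
        for iso in isoforms if iso.annotated
    ]
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))

    iso_df = pd.DataFrame([asdict_iso(i) for i in isoforms])
    artifact_df = iso_df[["iso_id", "chrom", "strand", "artifact_pos"]].rename(
        columns={"artifact_pos": "pos"})
    return genome, transcripts, SimTruth(iso_df, artifact_df, config=config)


def asdict_iso(iso: _Iso) -> dict:
    return {
        "iso_id": iso.iso_id, "gene_id": iso.gene_id, "chrom": iso.chrom,
        "strand": iso.strand, "tss": iso.tss, "pas": iso.pas,
        "kind": iso.kind, "annotated": iso.annotated,
        "artifact_pos": iso.artifact_pos,
    }


def _plant_pas_contexts(chroms: dict, isoforms: list[_Iso], rng) -> None:
    """Plant poly(A) signals, A-poor downstream windows and artifact tracts.

    True PAS: hexamer AATAAA/ATTAAA starting 16-28 nt upstream; the last 6
    transcribed bases and the first 20 downstream bases are drawn from C/G/T
    with at most 2 sprinkled As, so any 10-base downstream window under up to
    5 bp of jitter holds at most 6 adenines.  Artifact sites: 12 adenines on
    each side of the site on the transcript strand (>= 7 downstream As for
    any jittered position within 5 bp).
    """
    cgt = np.frombuffer(b"CGT", dtype="S1")
    for iso in isoforms:
        arr = chroms[iso.chrom]
        # upstream motif
        hexamer = "AATAAA" if rng.random() < 0.7 else "ATTAAA"
        start_offset = int(rng.integers(16, 29))  # hexamer start, nt upstream
        offsets = [-(start_offset - k) for k in range(6)]
        _plant(arr, iso.strand, _pas_positions(iso.pas, iso.strand, offsets), hexamer)
        # A-poor window around and after the PAS base
        window = rng.choice(cgt, size=26)
        for k in rng.choice(len(window), size=2, replace=False):
            window[k] = b"A"
        seq = window.tobytes().decode()
        _plant(arr, iso.strand,
               _pas_positions(iso.pas, iso.strand, range(-5, 21)), seq)
        # artifact A-tract centred on the artifact site
        _plant(arr, iso.strand,
               _pas_positions(iso.artifact_pos, iso.strand, range(-12, 13)),
               "A" * 25)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _random_umis(rng, n: int, length: int) -> np.ndarray:
    idx = rng.integers(0, 4, size=(n, length))
    return BASES[idx].view(f"S{length}").ravel().astype(str)


def simulate_library(truth: SimTruth, config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a multi-sample paired-tag library from the truth isoform set.

    Returns ``(pairs, truth)`` where ``pairs`` is the pre-dedup paired-tag
    table in the pipeline's TSV dialect and ``truth.molecules`` labels every
    emitted molecule (duplicate-of, priming artifact, chimera, barcodes).
    """
    rng = np.random.default_rng([config.seed, 1])
    isoforms = truth.isoforms
    samples = [f"s{i + 1}" for i in range(config.n_samples)]

    # discrete Pareto abundances: P(X >= x) = x**-alpha, capped
    u = rng.random(len(isoforms))
    abundance = np.minimum(
        np.floor(u ** (-1.0 / config.alpha)).astype(int), config.max_abundance)
    abundance = np.maximum(abundance, 1)

    recs = []
    mol_id = 0
    for sample in samples:
        for iso_idx, iso in enumerate(isoforms.itertuples()):
            n_mol = int(rng.poisson(config.depth * abundance[iso_idx]))
            if n_mol == 0:
                continue
            if config.jitter_sd > 0:
                jit_t = np.rint(rng.normal(0, config.jitter_sd, n_mol)).astype(int)
                jit_p = np.rint(rng.normal(0, config.jitter_sd, n_mol)).astype(int)
            else:
                jit_t = jit_p = np.zeros(n_mol, dtype=int)
            for j in range(n_mol):
                recs.append({
                    "molecule_id": mol_id, "iso_id": iso.iso_id,
                    "chrom": iso.chrom, "strand": iso.strand,
                    "tss": int(iso.tss + jit_t[j]), "pas": int(iso.pas + jit_p[j]),
                    "chrom3": iso.chrom, "strand3": iso.strand,
                    "sample": sample, "sample3": sample,
                    "is_priming": False, "is_chimera": False,
                    "artifact_pos": iso.artifact_pos,
                })
                mol_id += 1
    mols = pd.DataFrame(recs)

    # internal priming: PAS jumps to the planted genomic A-tract (no jitter:
    # the primer anneals at the tract itself)
    priming_mask = rng.random(len(mols)) < config.priming_rate
    mols.loc[priming_mask, "pas"] = mols.loc[priming_mask, "artifact_pos"]
    mols.loc[priming_mask, "is_priming"] = True

    # circularization chimeras: the 3' side (and its barcode) comes from a
    # uniformly drawn partner molecule across all samples
    chimera_mask = rng.random(len(mols)) < config.chimera_rate
    partners = rng.integers(0, len(mols), size=int(chimera_mask.sum()))
    idx = np.flatnonzero(chimera_mask)
    for col in ("pas", "chrom3", "strand3", "sample3"):
        mols.loc[mols.index[idx], col] = mols[col].to_numpy()[partners]
    mols.loc[mols.index[idx], "is_chimera"] = True

    mols["umi"] = _random_umis(rng, len(mols), config.umi_length)

    # PCR duplicates: one extra exact copy with probability pcr_dup_rate
    dup_mask = rng.random(len(mols)) < config.pcr_dup_rate
    mols["duplicate_of"] = -1
    dups = mols[dup_mask].copy()
    dups["duplicate_of"] = dups["molecule_id"]
    library = pd.concat([mols, dups], ignore_index=True)
    library = library.sample(frac=1.0, random_state=int(rng.integers(2**31))
                             ).reset_index(drop=True)

    pairs = _to_pair_rows(library, config.mate_length)
    truth_out = SimTruth(truth.isoforms, truth.artifact_sites,
                         molecules=library, config=config)
    return pairs, truth_out


def _to_pair_rows(mols: pd.DataFrame, mate_len: int) -> pd.DataFrame:
    plus5 = mols["strand"] == "+"
    plus3 = mols["strand3"] == "+"
    out = pd.DataFrame({
        "chrom": mols["chrom"],
        "strand": mols["strand"],
        "mate5_start": np.where(plus5, mols["tss"], mols["tss"] - mate_len + 1),
        "mate5_end": np.where(plus5, mols["tss"] + mate_len, mols["tss"] + 1),
        "mate3_start": np.where(plus3, mols["pas"] - mate_len + 1, mols["pas"]),
        "mate3_end": np.where(plus3, mols["pas"] + 1, mols["pas"] + mate_len),
        "umi": mols["umi"],
        "sample": mols["sample"],
        "chrom3": mols["chrom3"],
        "strand3": mols["strand3"],
        "sample3": mols["sample3"],
    })
    return out[PAIR_COLUMNS + OPTIONAL_PAIR_COLUMNS]


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    precision: float | None
    recall: float
    n_calls: int
    n_truth: int
    n_matched_calls: int
    n_matched_truth: int
    tss_errors: list[int] = field(default_factory=list)
    pas_errors: list[int] = field(default_factory=list)


def evaluate_recovery(tifs, truth_isoforms: pd.DataFrame) -> RecoveryReport:
    """Match called TIFs against truth isoforms.

    A call matches a truth isoform iff the truth TSS falls inside the call's
    TSS consensus interval and the truth PAS inside its PAS interval (same
    chrom and strand).  Precision is matched calls over calls (None when
    there are no calls), recall matched truths over truths; boundary errors
    are dominant position minus truth position.
    """
    matched_calls = set()
    matched_truth = set()
    tss_err, pas_err = [], []
    for t_idx, iso in enumerate(truth_isoforms.itertuples()):
        for c_idx, tif in enumerate(tifs):
            if tif.chrom != iso.chrom or tif.strand != iso.strand:
                continue
            if (tif.tss_cluster.start <= iso.tss < tif.tss_cluster.end
                    and tif.pas_cluster.start <= iso.pas < tif.pas_cluster.end):
                matched_calls.add(c_idx)
                if t_idx not in matched_truth:
                    tss_err.append(tif.tss_cluster.dominant_pos - iso.tss)
                    pas_err.append(tif.pas_cluster.dominant_pos - iso.pas)
                matched_truth.add(t_idx)
    n_calls, n_truth = len(tifs), len(truth_isoforms)
    return RecoveryReport(
        precision=len(matched_calls) / n_calls if n_calls else None,
        recall=len(matched_truth) / n_truth if n_truth else 0.0,
        n_calls=n_calls, n_truth=n_truth,
        n_matched_calls=len(matched_calls), n_matched_truth=len(matched_truth),
        tss_errors=tss_err, pas_errors=pas_err,
    )
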