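import os

import pytest

from tifseq2 import io as io_mod
from tifseq2.pipeline import RunConfig, run_pipeline
from tifseq2.simulate import SimConfig, generate_reference, simulate_library


def write_sim(cfg: SimConfig, outdir) -> RunConfig:
    """Materialize one simulated library on disk and return a run config."""
    genome, transcripts, truth = generate_reference(cfg)
    pairs, truth = simulate_library(truth, cfg)
    os.makedirs(outdir, exist_ok=True)
    io_mod.write_fasta(genome, os.path.join(outdir, "ref.fa"))
    io_mod.write_annotation(transcripts, os.path.join(outdir, "ref.gtf"))
    io_mod.write_paired_tags(pairs, os.path.join(outdir, "pairs.tsv"))
    rc = RunConfig(
        pairs=os.path.join(outdir, "pairs.tsv"),
        genome_fasta=os.path.join(outdir, "ref.fa"),
        gtf=os.path.join(outdir, "ref.gtf"),
        outdir=os.path.join(outdir, "out"),
    )
    return rc, truth


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default study conditions: 20 genes, 4 samples, depth 50, jitter sd 1,
    dup 0.3, priming 0.05, chimera 0.02 - simulated once per session."""
    cfg = SimConfig(seed=11)
    rc, truth = write_sim(cfg, tmp_path_factory.mktemp("default_sim"))
    result = run_pipeline(rc, write_outputs=True)
    return {"config": cfg, "run_config": rc, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def noiseless_sim(tmp_path_factory):
    """Noise-free variant: jitter 0 and all artifact rates 0."""
    cfg = SimConfig(seed=11, jitter_sd=0.0, pcr_dup_rate=0.0,
                    priming_rate=0.0, chimera_rate=0.0)
    rc, truth = write_sim(cfg, tmp_path_factory.mktemp("noiseless_sim"))
    result = run_pipeline(rc, write_outputs=False)
    return {"config": cfg, "run_config": rc, "truth": truth, "result": result}
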