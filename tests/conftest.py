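import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import decarve as dc


def make_track(values, strand="+", total=1_000_000.0, replicon="chr", normalized=False):
    return dc.CoverageTrack(replicon, strand, np.asarray(values, dtype=float),
                            total, normalized)


@pytest.fixture(scope="session")
def noise_free_study():
    """20-gene noise-free decay experiment with 5 planted decRNAs.

    Hosts of planted segments decay fast enough that every segment gains
    >= 8x in relative abundance over the 9-min course; boost 5 puts the
    segments above the 2x steady-state filter.
    """
    cfg = dc.SimConfig(n_genes=20, genome_len=60_000, noise_model="none",
                       library_size_jitter=0.0, seed=3)
    genome, genes = dc.simulate_annotation(cfg)
    rng = np.random.default_rng(33)
    genes = [
        dc.SimGene(g.id, g.interval, g.strand, g.utr5_len, g.utr3_len,
                   max(g.init_abundance, 50.0), float(rng.uniform(0.3, 0.5)))
        for g in genes
    ]
    segments = dc.plant_segments(genes, 5, seed=13, length_range=(60, 300),
                                 decay_rate_range=(0.02, 0.05), boost=5.0)
    experiment, truth = dc.simulate_decay_experiment(genome, genes, segments, cfg)
    gene_models = [g.to_gene_model(cfg.replicon_id) for g in genes]
    return {
        "config": cfg,
        "genome": genome,
        "sim_genes": genes,
        "genes": gene_models,
        "segments": segments,
        "experiment": experiment,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def noise_free_calls(noise_free_study):
    s = noise_free_study
    return dc.detect_decrnas(s["experiment"], s["genes"], s["genome"])
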