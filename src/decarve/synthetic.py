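"""Synthetic decay time courses with planted stabilized segments.

The generator emulates a rifampicin transcription-shutoff assay: after
shutoff every transcript decays exponentially with its own first-order
rate, sampled at ~1-minute intervals in triplicate.  A planted segment
models a decay-generated ncRNA (decRNA): a subgene interval with a much
slower decay rate and an elevated steady-state abundance (real decRNAs
accumulate relative to their host mRNA because they are continuously
produced by decay of new transcripts).

Defaults reflect the assayed conditions: a 0-9 min grid at 1-min steps,
triplicate libraries, Poisson count noise per nucleotide, and gene decay
rates around ln2/2.5 per minute (E. coli mRNA half-lives of a few
minutes).  Coverage correlation along the genome (read-length smearing)
is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CoverageTrack,
    DecayExperiment,
    GeneModel,
    STRANDS,
    write_bedgraph,
    write_fasta,
    write_gff3,
    write_library_sizes,
)

NOISE_MODELS = ("none", "poisson", "negative_binomial")


class InfeasiblePlacementError(ValueError):
    """Genome too short to place the requested genes without overlap."""


@dataclass(frozen=True)
class SimGene:
    """A simulated transcription unit: CDS flanked by optional UTRs.

    ``interval`` is the full footprint (0-based half-open);
    ``init_abundance`` is the expected steady-state reads/nt and
    ``decay_rate`` the first-order decay constant per minute.
    """

    id: str
    interval: tuple[int, int]
    strand: str
    utr5_len: int
    utr3_len: int
    init_abundance: float
    decay_rate: float

    def __post_init__(self) -> None:
        s, e = self.interval
        if not (0 <= s < e):
            raise ValueError(f"bad interval {self.interval}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError("UTR lengths must be >= 0")
        cds_len = (e - s) - self.utr5_len - self.utr3_len
        if cds_len <= 0:
            raise ValueError(f"gene {self.id}: UTRs do not fit inside interval")
        if cds_len % 3 != 0:
            raise ValueError(f"gene {self.id}: CDS length {cds_len} not divisible by 3")
        if self.init_abundance < 0:
            raise ValueError("init_abundance must be >= 0")
        if not self.decay_rate > 0:
            raise ValueError("decay_rate must be > 0")

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    def to_gene_model(self, replicon_id: str) -> GeneModel:
        s, e = self.interval
        if self.strand == "+":
            utr5 = (s, s + self.utr5_len) if self.utr5_len else None
            utr3 = (e - self.utr3_len, e) if self.utr3_len else None
            cds = (s + self.utr5_len, e - self.utr3_len)
        else:
            utr5 = (e - self.utr5_len, e) if self.utr5_len else None
            utr3 = (s, s + self.utr3_len) if self.utr3_len else None
            cds = (s + self.utr3_len, e - self.utr5_len)
        return GeneModel(self.id, replicon_id, self.strand, cds, utr5, utr3)


@dataclass(frozen=True)
class PlantedSegment:
    """Ground-truth stabilized segment inside a host gene.

    ``offset`` counts nucleotides from the gene's 5' end in gene
    orientation.  ``boost`` is the steady-state abundance multiplier
    (>= 1 for a segment that accumulates); ``decay_rate`` should be well
    below the host's for a recoverable segment.
    """

    host_gene_id: str
    offset: int
    length: int
    decay_rate: float
    boost: float = 1.0

    def __post_init__(self) -> None:
        if self.offset < 0 or self.length <= 0:
            raise ValueError("offset must be >= 0 and length > 0")
        if not self.decay_rate > 0:
            raise ValueError("decay_rate must be > 0")
        if self.boost < 1:
            raise ValueError("boost must be >= 1")

    def genomic_interval(self, gene: SimGene) -> tuple[int, int]:
        """Map (offset, length) from gene orientation onto genomic coordinates."""
        s, e = gene.interval
        if self.offset + self.length > gene.length:
            raise ValueError(
                f"segment does not fit inside host gene {gene.id}"
            )
        if gene.strand == "+":
            return (s + self.offset, s + self.offset + self.length)
        return (e - self.offset - self.length, e - self.offset)


@dataclass
class SimConfig:
    """Study-condition knobs for the simulator."""

    n_genes: int = 50
    genome_len: int = 100_000
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(10))
    n_replicates: int = 3
    noise_model: str = "poisson"
    nb_dispersion: float = 0.1
    library_size_jitter: float = 0.05
    gc_content: float = 0.5
    mean_gene_len: int = 1200
    min_spacer: int = 50
    replicon_id: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tps and tps[0] != 0.0:
            raise ValueError("first timepoint must be 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if not (0 <= self.library_size_jitter < 1):
            raise ValueError("library_size_jitter must be in [0, 1)")
        self.timepoints = tps


# ---------------------------------------------------------------------------
# Annotation / genome
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> tuple[str, list[SimGene]]:
    """Random genome sequence plus non-overlapping genes.

    Gene lengths vary around ``mean_gene_len``; CDS length is forced to
    a multiple of 3; strands, initial abundances (log-normal around ~100
    reads/nt) and decay rates (uniform 0.2-0.5 /min, i.e. half-lives of
    1.4-3.5 min) are sampled per gene.  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    p_gc = config.gc_content / 2
    p_at = (1 - config.gc_content) / 2
    genome = "".join(rng.choice(bases, size=config.genome_len, p=[p_at, p_gc, p_gc, p_at]))

    if config.n_genes == 0:
        return genome, []

    utr5 = rng.integers(20, 81, size=config.n_genes)
    utr3 = rng.integers(20, 81, size=config.n_genes)
    cds_len = np.maximum(
        90, (rng.normal(config.mean_gene_len, 300, size=config.n_genes)).astype(int)
    )
    cds_len -= cds_len % 3
    total_len = utr5 + utr3 + cds_len

    needed = int(total_len.sum()) + config.min_spacer * (config.n_genes + 1)
    if needed > config.genome_len:
        raise InfeasiblePlacementError(
            f"{config.n_genes} genes need >= {needed} nt but genome_len is {config.genome_len}"
        )
    # distribute the slack randomly among the n+1 spacers
    slack = config.genome_len - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=config.n_genes))
    extra = np.diff(np.concatenate(([0], cuts)))

    genes: list[SimGene] = []
    pos = config.min_spacer
    for i in range(config.n_genes):
        pos += int(extra[i])
        start = pos
        end = start + int(total_len[i])
        genes.append(
            SimGene(
                id=f"g{i + 1:03d}",
                interval=(start, end),
                strand="+" if rng.random() < 0.5 else "-",
                utr5_len=int(utr5[i]),
                utr3_len=int(utr3[i]),
                init_abundance=float(rng.lognormal(np.log(100), 0.5)),
                decay_rate=float(rng.uniform(0.2, 0.5)),
            )
        )
        pos = end + config.min_spacer
    return genome, genes


def plant_segments(
    genes: Sequence[SimGene],
    n_segments: int,
    seed: int,
    length_range: tuple[int, int] = (80, 300),
    decay_rate_range: tuple[float, float] = (0.02, 0.08),
    boost: float = 5.0,
    min_offset: int = 110,
) -> list[PlantedSegment]:
    """Plant one stabilized segment in each of ``n_segments`` distinct genes.

    Segment lengths follow the observed decRNA size range (80-300 nt);
    their decay rates give half-lives of tens of minutes versus the
    hosts' few minutes, and the default 5x steady-state boost reflects
    decRNA accumulation relative to the host mRNA.  ``min_offset`` keeps
    segments out of the transcript's first scan window, where the
    trailing-window detection rule is blind by construction.
    """
    rng = np.random.default_rng(seed)
    eligible = [g for g in genes if g.length > length_range[1] + min_offset + 20]
    if len(eligible) < n_segments:
        raise ValueError("not enough sufficiently long genes to plant segments in")
    hosts = rng.choice(len(eligible), size=n_segments, replace=False)
    segments = []
    for gi in hosts:
        gene = eligible[int(gi)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        offset = int(rng.integers(min_offset, gene.length - length - 9))
        segments.append(
            PlantedSegment(
                host_gene_id=gene.id,
                offset=offset,
                length=length,
                decay_rate=float(rng.uniform(*decay_rate_range)),
                boost=boost,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Expected coverage and count sampling
# ---------------------------------------------------------------------------

def expected_coverage(
    gene: SimGene,
    segments: Sequence[PlantedSegment],
    t: float,
) -> np.ndarray:
    """Noise-free expected reads/nt across the gene footprint at time ``t``.

    Outside planted segments the gene decays as A*exp(-k*t); inside a
    planted segment the expectation is boost*A*exp(-k_seg*t).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    s, e = gene.interval
    prof = np.full(gene.length, gene.init_abundance * np.exp(-gene.decay_rate * t))
    for seg in segments:
        if seg.host_gene_id != gene.id:
            continue
        gs, ge = seg.genomic_interval(gene)
        prof[gs - s: ge - s] = seg.boost * gene.init_abundance * np.exp(-seg.decay_rate * t)
    return prof


def _expected_genome_profiles(
    genome_len: int, genes: Sequence[SimGene], segments: Sequence[PlantedSegment], t: float
) -> dict:
    prof = {st: np.zeros(genome_len) for st in STRANDS}
    for gene in genes:
        s, e = gene.interval
        prof[gene.strand][s:e] += expected_coverage(gene, segments, t)
    return prof


def _sample_counts(expected: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "none":
        return expected.copy()
    if config.noise_model == "poisson":
        return rng.poisson(expected).astype(float)
    # negative binomial with mean mu, variance mu + dispersion*mu^2
    mu = expected
    disp = config.nb_dispersion
    out = np.zeros_like(mu)
    pos = mu > 0
    r = 1.0 / disp
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p).astype(float)
    return out


def simulate_decay_experiment(
    genome: str,
    genes: Sequence[SimGene],
    segments: Sequence[PlantedSegment],
    config: SimConfig,
) -> tuple[DecayExperiment, pd.DataFrame]:
    """Sample counts for every (timepoint, replicate) library.

    Each library gets a depth jitter factor drawn uniformly from
    ``1 +/- library_size_jitter``; its recorded ``library_total`` is the
    actual sum of sampled counts over both strands, so normalization is
    exercised non-trivially.  Returns the experiment plus the
    ground-truth table of planted segments (genomic coordinates).
    """
    gene_by_id = {g.id: g for g in genes}
    for seg in segments:
        if seg.host_gene_id not in gene_by_id:
            raise ValueError(f"segment host gene {seg.host_gene_id} not in gene list")
        seg.genomic_interval(gene_by_id[seg.host_gene_id])  # validates fit

    rng = np.random.default_rng(config.seed + 1)
    exp = DecayExperiment(config.replicon_id, config.timepoints, config.n_replicates)
    for ti, t in enumerate(config.timepoints):
        prof = _expected_genome_profiles(len(genome), genes, segments, t)
        for rep in range(config.n_replicates):
            jitter = 1.0 + rng.uniform(-config.library_size_jitter, config.library_size_jitter)
            counts = {st: _sample_counts(prof[st] * jitter, config, rng) for st in STRANDS}
            total = max(float(counts["+"].sum() + counts["-"].sum()), 1.0)
            for st in STRANDS:
                exp.tracks[(ti, rep, st)] = CoverageTrack(
                    config.replicon_id, st, counts[st], total
                )
    truth = pd.DataFrame(
        [
            {
                "chrom": config.replicon_id,
                "start": seg.genomic_interval(gene_by_id[seg.host_gene_id])[0],
                "end": seg.genomic_interval(gene_by_id[seg.host_gene_id])[1],
                "strand": gene_by_id[seg.host_gene_id].strand,
                "host_gene": seg.host_gene_id,
                "k_seg": seg.decay_rate,
                "boost": seg.boost,
            }
            for seg in segments
        ],
        columns=["chrom", "start", "end", "strand", "host_gene", "k_seg", "boost"],
    )
    return exp, truth


def simulate_ip_pair(
    genome_len: int,
    genes: Sequence[SimGene],
    true_targets: Sequence[tuple[tuple[int, int], str, float]],
    config: SimConfig,
    replicon_id: Optional[str] = None,
) -> tuple[dict, dict]:
    """Simulate a co-IP (IP, lysate) pair of strand-specific track dicts.

    The lysate follows the steady-state expectation; the IP multiplies
    the expectation inside each ``((start, end), strand, factor)``
    target by its enrichment factor before count sampling.
    """
    for (_, _), _strand, factor in ((iv, st, f) for iv, st, f in true_targets):
        if not factor > 0:
            raise ValueError("enrichment factors must be > 0")
    replicon_id = replicon_id or config.replicon_id
    rng = np.random.default_rng(config.seed + 2)
    base = _expected_genome_profiles(genome_len, genes, [], 0.0)
    ip_exp = {st: base[st].copy() for st in STRANDS}
    for (s, e), strand, factor in true_targets:
        ip_exp[strand][s:e] *= factor

    def build(profiles: dict) -> dict:
        counts = {st: _sample_counts(profiles[st], config, rng) for st in STRANDS}
        total = max(float(counts["+"].sum() + counts["-"].sum()), 1.0)
        return {
            st: CoverageTrack(replicon_id, st, counts[st], total) for st in STRANDS
        }

    return build(ip_exp), build(base)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

STRAND_TAG = {"+": "fwd", "-": "rev"}


def write_simulation(
    outdir,
    genome: str,
    genes: Sequence[SimGene],
    experiment: DecayExperiment,
    truth: pd.DataFrame,
    config: SimConfig,
) -> None:
    """Write genome FASTA, GFF3, per-library bedGraphs, library sizes and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta({config.replicon_id: genome}, outdir / "genome.fasta")
    write_gff3([g.to_gene_model(config.replicon_id) for g in genes], outdir / "annotation.gff3")
    sizes = {}
    for (ti, rep, st), track in experiment.tracks.items():
        t = experiment.timepoints[ti]
        name = f"t{t:g}_rep{rep}"
        write_bedgraph(track, outdir / f"cov_{name}_{STRAND_TAG[st]}.bedgraph")
        sizes[name] = track.library_total
    write_library_sizes(sizes, outdir / "library_sizes.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_simulated_experiment(
    covdir,
    replicon_id: str,
    replicon_length: int,
    timepoints: Sequence[float],
    n_replicates: int,
) -> DecayExperiment:
    """Load an experiment written by :func:`write_simulation`."""
    from .io_formats import read_bedgraph, read_library_sizes

    covdir = Path(covdir)
    sizes = read_library_sizes(covdir / "library_sizes.tsv")
    exp = DecayExperiment(replicon_id, tuple(timepoints), n_replicates)
    for ti, t in enumerate(exp.timepoints):
        for rep in range(n_replicates):
            name = f"t{t:g}_rep{rep}"
            for st in STRANDS:
                exp.tracks[(ti, rep, st)] = read_bedgraph(
                    covdir / f"cov_{name}_{STRAND_TAG[st]}.bedgraph",
                    replicon_length,
                    st,
                    library_total=sizes[name],
                    replicon_id=replicon_id,
                )
    return exp
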