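"""End-to-end orchestration and run-directory outputs."""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    calls_to_dataframe,
    merge_enrichment,
    summarize_catalog,
    write_catalog_bed,
    write_catalog_tsv,
)
from .detection import DecRnaCall, DetectionConfig, detect_decrnas
from .io_formats import (
    DecayExperiment,
    GeneModel,
    STRANDS,
    read_bedgraph,
    read_end_sites,
    read_fasta,
    read_gff3,
    read_library_sizes,
)
from .rnase_chaperone import EnrichmentConfig
from .structure_stats import StabilityComparisonConfig, compare_stability, get_engine
from .synthetic import SimConfig, plant_segments, simulate_annotation, simulate_decay_experiment, write_simulation

_COV_RE = re.compile(r"cov_t(?P<t>[0-9.]+)_rep(?P<rep>\d+)_(?P<tag>fwd|rev)\.bedgraph$")
_TAG2STRAND = {"fwd": "+", "rev": "-"}


@dataclass
class RunConfig:
    """Top-level configuration for `decarve run`."""

    out_dir: str = "decarve_run"
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    stability: StabilityComparisonConfig = field(default_factory=StabilityComparisonConfig)
    sim: Optional[SimConfig] = None
    paths: dict = field(default_factory=dict)
    n_planted: int = 5
    run_stability: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "detection" in kwargs:
            kwargs["detection"] = DetectionConfig(**kwargs["detection"])
        if "enrichment" in kwargs:
            kwargs["enrichment"] = EnrichmentConfig(**kwargs["enrichment"])
        if "stability" in kwargs:
            kwargs["stability"] = StabilityComparisonConfig(**kwargs["stability"])
        if kwargs.get("sim") is not None:
            sim = dict(kwargs["sim"])
            if "timepoints" in sim:
                sim["timepoints"] = tuple(sim["timepoints"])
            kwargs["sim"] = SimConfig(**sim)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_coverage_dir(
    covdir,
    replicon_id: str,
    replicon_length: int,
) -> DecayExperiment:
    """Build a DecayExperiment from ``cov_t{T}_rep{R}_{fwd,rev}.bedgraph`` files.

    Timepoints and replicate count are inferred from the file names; the
    ``library_sizes.tsv`` sidecar supplies per-library mapped-read totals
    keyed ``t{T}_rep{R}``.
    """
    covdir = Path(covdir)
    if not covdir.is_dir():
        raise FileNotFoundError(f"coverage directory not found: {covdir}")
    found = {}
    for f in covdir.iterdir():
        m = _COV_RE.search(f.name)
        if m:
            found[(float(m["t"]), int(m["rep"]), _TAG2STRAND[m["tag"]])] = f
    if not found:
        raise FileNotFoundError(f"no cov_t*_rep*_{{fwd,rev}}.bedgraph files in {covdir}")
    timepoints = tuple(sorted({k[0] for k in found}))
    reps = sorted({k[1] for k in found})
    sizes = read_library_sizes(covdir / "library_sizes.tsv")
    exp = DecayExperiment(replicon_id, timepoints, len(reps))
    for (t, rep, strand), path in found.items():
        ti = timepoints.index(t)
        exp.tracks[(ti, rep, strand)] = read_bedgraph(
            path, replicon_length, strand,
            library_total=sizes[f"t{t:g}_rep{rep}"], replicon_id=replicon_id,
        )
    missing = [
        (ti, rep, st)
        for ti in range(len(timepoints))
        for rep in range(len(reps))
        for st in STRANDS
        if (ti, rep, st) not in exp.tracks
    ]
    if missing:
        raise FileNotFoundError(f"incomplete coverage grid; missing {missing[:3]}...")
    return exp


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Simulate (or load) inputs, detect decRNAs, score stability, write outputs.

    Produces ``catalog.tsv``, ``calls.bed``, ``summary.json``,
    ``stability.json`` (optional) and ``provenance.json`` under
    ``config.out_dir``; deterministic given config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}

    if config.sim is not None:
        sim = config.sim
        genome, sim_genes = simulate_annotation(sim)
        segments = plant_segments(sim_genes, config.n_planted, seed=sim.seed + 10)
        experiment, truth = simulate_decay_experiment(genome, sim_genes, segments, sim)
        genes = [g.to_gene_model(sim.replicon_id) for g in sim_genes]
        indir = out / "inputs"
        write_simulation(indir, genome, sim_genes, experiment, truth, sim)
        end_sites = None
    else:
        paths = config.paths
        for key in ("genome", "annotation", "coverage_dir"):
            if key not in paths:
                raise FileNotFoundError(f"run config paths missing '{key}'")
            if not Path(paths[key]).exists():
                raise FileNotFoundError(f"{key} path does not exist: {paths[key]}")
        genomes = read_fasta(paths["genome"])
        replicon_id, genome = next(iter(genomes.items()))
        genes = read_gff3(paths["annotation"])
        experiment = load_coverage_dir(paths["coverage_dir"], replicon_id, len(genome))
        end_sites = (
            read_end_sites(paths["end_sites"]) if paths.get("end_sites") else None
        )
        for key in ("genome", "annotation"):
            checksums[key] = _sha256(paths[key])

    calls = detect_decrnas(experiment, genes, genome, config.detection, end_sites)
    engine = get_engine(config.stability.engine)
    catalog = calls_to_dataframe(calls, engine=engine)
    write_catalog_tsv(catalog, out / "catalog.tsv")
    write_catalog_bed(calls, out / "calls.bed")

    summary = summarize_catalog(catalog)
    if config.run_stability and calls:
        stab_cfg = StabilityComparisonConfig(
            n_random=config.stability.n_random,
            seed=config.seed,
            engine=config.stability.engine,
        )
        known = []
        if config.paths.get("known_ncrnas"):
            known = list(read_fasta(config.paths["known_ncrnas"]).values())
        comp = compare_stability(
            list(catalog["sequence"]), known, genome, stab_cfg, engine
        )
        with open(out / "stability.json", "w") as fh:
            json.dump(comp.summary(), fh, indent=2)
        summary["p_decrna_vs_random"] = comp.p_decrna_vs_random

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    effective = config.to_dict()
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(effective, fh, sort_keys=True)
    provenance = {
        "tool": "decarve",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(effective, sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": checksums,
        "n_calls": len(calls),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return out


def export_coverage_views(
    experiment: DecayExperiment,
    region: tuple[int, int],
    strand: str = "+",
    calls: Optional[Sequence[DecRnaCall]] = None,
) -> pd.DataFrame:
    """Long-format normalized coverage over a region, for plotting.

    One row per (position, timepoint, replicate); ``in_call`` marks
    positions covered by a supplied decRNA call (annotation only).
    """
    a, b = region
    norm = experiment.normalized()
    some = norm.track(0, 0, strand)
    if not (0 <= a < b <= len(some)):
        raise ValueError(f"region {region} outside replicon of length {len(some)}")
    in_call = set()
    for c in calls or []:
        if c.strand == strand:
            in_call.update(range(max(a, c.interval[0]), min(b, c.interval[1])))
    rows = []
    for ti, t in enumerate(experiment.timepoints):
        for rep in range(experiment.n_replicates):
            v = norm.track(ti, rep, strand).values[a:b]
            for off, val in enumerate(v):
                pos = a + off
                rows.append(
                    {
                        "position": pos,
                        "timepoint": t,
                        "replicate": rep,
                        "coverage": float(val),
                        "in_call": pos in in_call,
                    }
                )
    return pd.DataFrame(rows)
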