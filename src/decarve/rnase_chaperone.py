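"""RNase-E dependence scoring and Hfq/ProQ co-IP enrichment calling.

decRNA biogenesis depends on RNase E: in a temperature-sensitive RNase E
mutant held at the restrictive temperature, decRNAs fail to accumulate.
The dependence score for one decRNA is the ratio of its mean coverage to
the host gene's median coverage; distributions of that ratio in the
wild-type versus the mutant are compared with a two-sided Wilcoxon
rank-sum test.

Chaperone interaction calling follows two published rules:

* Hfq — a putative interaction when the mean raw IP coverage over the
  decRNA exceeds 30 reads/nt (an absolute cut, applied unnormalized).
* ProQ — IP/lysate ratios are computed on library-size-normalized
  tracks for the ProQ-3xFLAG and untagged-WT experiments separately;
  the enrichment is the ratio of those ratios, called when it exceeds
  2-fold and the FLAG IP mean raw coverage exceeds 20 reads/nt.

A small pseudocount keeps ProQ ratios finite when a lysate mean is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detection import DecRnaCall, gene_median_coverage
from .io_formats import CoverageTrack, GeneModel, RPM_SCALE
from .structure_stats import wilcoxon_rank_sum


@dataclass
class EnrichmentConfig:
    hfq_min_mean_coverage: float = 30.0   # reads/nt, raw IP track (strict >)
    proq_min_mean_coverage: float = 20.0  # reads/nt, raw FLAG IP track (strict >)
    proq_min_enrichment: float = 2.0      # fold (strict >)
    pseudocount: float = 0.1              # added to normalized means in ProQ ratios

    def __post_init__(self) -> None:
        for name in (
            "hfq_min_mean_coverage", "proq_min_mean_coverage",
            "proq_min_enrichment", "pseudocount",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RatioRecord:
    """decRNA expression relative to its host gene in one condition."""

    decrna_id: str
    ratio: float
    condition: str  # "wt" | "mutant"


@dataclass
class EnrichmentResult:
    decrna_id: str
    hfq_mean_coverage: Optional[float] = None
    hfq_call: Optional[bool] = None
    proq_mean_coverage: Optional[float] = None
    proq_enrichment: Optional[float] = None
    proq_call: Optional[bool] = None


def _interval_mean(track: CoverageTrack, interval: tuple[int, int]) -> float:
    a, b = interval
    if not (0 <= a < b <= len(track)):
        raise ValueError(f"interval {interval} outside track")
    return float(np.mean(track.values[a:b]))


def decrna_host_ratio(
    track: CoverageTrack, call: DecRnaCall, gene: GeneModel, condition: str = "wt"
) -> RatioRecord:
    """Segment mean coverage over host-gene median coverage (one library)."""
    med = gene_median_coverage(track, gene)
    if med <= 0:
        raise ValueError(
            f"host gene {gene.id} has zero median coverage; ratio undefined"
        )
    return RatioRecord(call.id, _interval_mean(track, call.interval) / med, condition)


def compare_rnase_dependence(
    wt_ratios: Sequence[RatioRecord],
    mutant_ratios: Sequence[RatioRecord],
) -> tuple[float, dict]:
    """Two-sided Wilcoxon rank-sum between WT and mutant ratio distributions.

    A decRNA whose segment/host ratio collapses in the RNase E mutant is
    RNase-E dependent; the test asks whether that collapse holds across
    the whole catalog.  The comparison is unpaired (distribution level),
    matching how the published distributions were compared.
    """
    if len(wt_ratios) < 2 or len(mutant_ratios) < 2:
        raise ValueError("need at least 2 ratio records per condition")
    wt = np.array([r.ratio for r in wt_ratios])
    mut = np.array([r.ratio for r in mutant_ratios])
    res = wilcoxon_rank_sum(wt, mut)
    summary = {
        "n_wt": int(wt.size),
        "n_mutant": int(mut.size),
        "median_wt": float(np.median(wt)),
        "median_mutant": float(np.median(mut)),
        "statistic": res.statistic,
    }
    return res.pvalue, summary


def hfq_call(
    ip_track: CoverageTrack, call: DecRnaCall, config: Optional[EnrichmentConfig] = None
) -> tuple[float, bool]:
    """Mean raw IP coverage over the call and the strict >threshold decision."""
    config = config or EnrichmentConfig()
    if ip_track.normalized:
        raise ValueError("Hfq rule is an absolute reads/nt cut; pass the raw IP track")
    mean = _interval_mean(ip_track, call.interval)
    return mean, mean > config.hfq_min_mean_coverage


def _norm_mean(track: CoverageTrack, interval: tuple[int, int]) -> float:
    m = _interval_mean(track, interval)
    if track.normalized:
        return m
    return m * RPM_SCALE / track.library_total


def proq_enrichment(
    ip_flag: CoverageTrack,
    lysate_flag: CoverageTrack,
    ip_wt: CoverageTrack,
    lysate_wt: CoverageTrack,
    call: DecRnaCall,
    config: Optional[EnrichmentConfig] = None,
) -> EnrichmentResult:
    """Double-ratio ProQ enrichment for one decRNA.

    enrichment = (IP/lysate)_FLAG / (IP/lysate)_WT on normalized means,
    each mean offset by the pseudocount.  The coverage gate uses the raw
    FLAG IP mean.
    """
    config = config or EnrichmentConfig()
    pc = config.pseudocount
    ratio_flag = (_norm_mean(ip_flag, call.interval) + pc) / (
        _norm_mean(lysate_flag, call.interval) + pc
    )
    ratio_wt = (_norm_mean(ip_wt, call.interval) + pc) / (
        _norm_mean(lysate_wt, call.interval) + pc
    )
    enrichment = ratio_flag / ratio_wt
    raw_mean = _interval_mean(ip_flag, call.interval)
    if ip_flag.normalized:
        raise ValueError("pass the raw FLAG IP track (coverage gate is absolute)")
    return EnrichmentResult(
        decrna_id=call.id,
        proq_mean_coverage=raw_mean,
        proq_enrichment=enrichment,
        proq_call=(raw_mean > config.proq_min_mean_coverage)
        and (enrichment > config.proq_min_enrichment),
    )


def annotate_enrichment(
    calls: Sequence[DecRnaCall],
    hfq_ip: Optional[dict] = None,
    proq_tracks: Optional[dict] = None,
    config: Optional[EnrichmentConfig] = None,
) -> list[EnrichmentResult]:
    """Score every decRNA call against the supplied chaperone assays.

    ``hfq_ip`` maps strand -> raw IP CoverageTrack; ``proq_tracks`` maps
    strand -> (ip_flag, lysate_flag, ip_wt, lysate_wt).  Missing assays
    leave the corresponding fields None (never a false call).
    """
    if hfq_ip is None and proq_tracks is None:
        raise ValueError("no enrichment data supplied")
    config = config or EnrichmentConfig()
    out = []
    for call in calls:
        res = EnrichmentResult(decrna_id=call.id)
        if hfq_ip is not None:
            mean, flag = hfq_call(hfq_ip[call.strand], call, config)
            res.hfq_mean_coverage = mean
            res.hfq_call = flag
        if proq_tracks is not None:
            pr = proq_enrichment(*proq_tracks[call.strand], call, config)
            res.proq_mean_coverage = pr.proq_mean_coverage
            res.proq_enrichment = pr.proq_enrichment
            res.proq_call = pr.proq_call
        out.append(res)
    return out
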