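"""Detection of decay-generated ncRNAs from decay time-course coverage.

A decRNA shows up in a transcription-shutoff time course as a subgene
interval whose coverage decays much more slowly than the rest of its
host transcript.  Detection proceeds per replicate:

1. genes with a raw t0 median below ``min_gene_median_t0`` are dropped;
2. a sliding window scans each expressed gene in 5'->3' gene
   orientation: a run starts at a nucleotide whose coverage exceeds the
   mean of the ``window`` nucleotides immediately 5' of it by more than
   ``sd_threshold`` standard deviations (SD floored at ``sd_floor``),
   and extends while coverage stays above the same frozen pre-run
   window statistics; runs longer than ``min_segment_len`` become
   candidate segments;
3. candidates must exceed ``min_t0_fold`` over the gene median at t0
   and gain at least ``min_stabilization_fold`` in relative abundance
   (segment mean / gene median, library-normalized) over the course;
4. candidates supported by >= ``min_replicate_support`` replicates are
   intersected into consensus calls, optionally snapped to mapped
   transcript termini, and classified by CDS overlap.

Absolute-unit rules (the t0 expression filter and the scan's SD floor)
operate on raw reads/nt; ratio-based rules use library-size-normalized
tracks so cross-timepoint comparisons are depth-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import CoverageTrack, DecayExperiment, EndSite, GeneModel

CATEGORIES = ("within_cds", "cds_majority", "utr_majority")


@dataclass
class DetectionConfig:
    """Thresholds of the decRNA detection procedure (defaults as published)."""

    min_gene_median_t0: float = 5.0      # reads/nt, raw
    window: int = 100                    # nt
    step: int = 1                        # nt (window is moved 1 nt at a time)
    sd_threshold: float = 4.0            # multiples of SD
    min_segment_len: int = 40            # nt, exclusive (segments must exceed it)
    min_t0_fold: float = 2.0             # fold over gene median at t0 (strict >)
    min_stabilization_fold: float = 3.0  # fold gain in relative abundance (>=)
    min_replicate_support: int = 2
    sd_floor: float = 1.0                # reads/nt, lower bound on window SD
    expressed_rule: str = "all"          # all | any | mean over replicates
    max_end_distance: int = 20           # nt, boundary-correction search radius

    def __post_init__(self) -> None:
        for name in (
            "min_gene_median_t0", "window", "step", "sd_threshold",
            "min_segment_len", "min_t0_fold", "min_stabilization_fold",
            "min_replicate_support", "sd_floor",
        ):
            if getattr(self, name) <= 0 and name != "min_gene_median_t0":
                raise ValueError(f"{name} must be > 0")
        if self.min_gene_median_t0 < 0:
            raise ValueError("min_gene_median_t0 must be >= 0")
        if self.expressed_rule not in ("all", "any", "mean"):
            raise ValueError("expressed_rule must be all|any|mean")
        if self.window <= self.min_segment_len:
            warnings.warn(
                "window <= min_segment_len; short stabilized segments may be missed",
                stacklevel=2,
            )


@dataclass
class SegmentCandidate:
    """A per-replicate stabilized-segment candidate that passed the fold filters."""

    interval: tuple[int, int]
    host_gene_id: str
    replicate: int
    mean_t0: float
    t0_fold: float
    stabilization_fold: float


@dataclass
class DecRnaCall:
    """One consensus decRNA call."""

    interval: tuple[int, int]
    host_gene_id: str
    replicon_id: str
    strand: str
    n_replicates_support: int
    supporting_replicates: tuple[int, ...]
    cds_overlap_fraction: float
    category: str
    sequence: str
    boundary_corrected: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def id(self) -> str:
        return f"{self.host_gene_id}-decRNA"


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def _footprint_values(track: CoverageTrack, gene: GeneModel) -> np.ndarray:
    s, e = gene.footprint
    if e > len(track):
        raise ValueError(f"gene {gene.id} footprint extends past track end")
    return track.values[s:e]


def gene_median_coverage(track: CoverageTrack, gene: GeneModel) -> float:
    """Median reads/nt over the full gene footprint, UTRs included."""
    v = _footprint_values(track, gene)
    if v.size == 0:
        raise ValueError(f"gene {gene.id} has a zero-length footprint")
    return float(np.median(v))


def filter_expressed(
    t0_tracks: Sequence[dict],
    genes: Sequence[GeneModel],
    config: DetectionConfig,
) -> list[GeneModel]:
    """Keep genes whose raw t0 median meets the expression threshold.

    ``t0_tracks`` is one ``{strand: CoverageTrack}`` dict per replicate.
    The default rule requires the threshold in every replicate
    (configurable to ``any`` or ``mean``).
    """
    kept = []
    for gene in genes:
        medians = [gene_median_coverage(rep[gene.strand], gene) for rep in t0_tracks]
        if config.expressed_rule == "all":
            ok = all(m >= config.min_gene_median_t0 for m in medians)
        elif config.expressed_rule == "any":
            ok = any(m >= config.min_gene_median_t0 for m in medians)
        else:
            ok = float(np.mean(medians)) >= config.min_gene_median_t0
        if ok:
            kept.append(gene)
    return kept


def _rolling_mean_sd(v: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD (ddof=0) of windows [i-w, i) for i = w .. n-1, vectorized."""
    c1 = np.concatenate(([0.0], np.cumsum(v)))
    c2 = np.concatenate(([0.0], np.cumsum(v * v)))
    n = v.size
    idx = np.arange(w, n)
    s1 = c1[idx] - c1[idx - w]
    s2 = c2[idx] - c2[idx - w]
    mean = s1 / w
    var = np.maximum(s2 / w - mean * mean, 0.0)
    return mean, np.sqrt(var)


def scan_gene(
    track: CoverageTrack,
    gene: GeneModel,
    config: DetectionConfig,
) -> list[tuple[int, int]]:
    """Sliding-window scan for locally elevated runs within one gene.

    Works in gene orientation (minus-strand footprints are reversed so
    the window always trails on the transcript's 5' side).  Returns
    genomic half-open intervals of maximal elevated runs strictly longer
    than ``min_segment_len``.  Positions without a full 5' window are
    never flagged.
    """
    s, e = gene.footprint
    v = _footprint_values(track, gene)
    if gene.strand == "-":
        v = v[::-1]
    n = v.size
    w = config.window
    if n <= w:
        warnings.warn(f"gene {gene.id} footprint ({n} nt) <= window ({w} nt); skipped",
                      stacklevel=2)
        return []

    means, sds = _rolling_mean_sd(v, w)
    floor_sds = np.maximum(sds, config.sd_floor)
    start_flag = v[w:] > means + config.sd_threshold * floor_sds

    runs: list[tuple[int, int]] = []
    i = w
    while i < n:
        if not start_flag[i - w]:
            i += 1
            continue
        # freeze the statistics of the last fully pre-run window [i-w, i)
        thr = means[i - w] + config.sd_threshold * floor_sds[i - w]
        j = i
        while j < n and v[j] > thr:
            j += 1
        if j - i > config.min_segment_len:
            runs.append((i, j))
        i = j if j > i else i + 1

    out = []
    for a, b in runs:
        if gene.strand == "+":
            out.append((s + a, s + b))
        else:
            out.append((e - b, e - a))
    out.sort()
    return out


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping/adjacent-by-overlap (>=1 nt) intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def filter_candidates(
    intervals: Sequence[tuple[int, int]],
    norm_experiment: DecayExperiment,
    gene: GeneModel,
    replicate: int,
    config: DetectionConfig,
) -> list[SegmentCandidate]:
    """Apply the t0-fold and stabilization-fold filters to raw scan intervals.

    Relative abundance at time t is the segment's mean coverage divided
    by the gene median, on normalized tracks; the stabilization fold is
    the maximum over post-t0 timepoints of that ratio versus its t0
    value.  Timepoints where the gene median is 0 are skipped; a zero
    gene median at t0 rejects the candidate.
    """
    out = []
    strand = gene.strand
    n_t = len(norm_experiment.timepoints)
    tracks = [norm_experiment.track(ti, replicate, strand) for ti in range(n_t)]
    gene_med = [gene_median_coverage(tr, gene) for tr in tracks]
    for (a, b) in intervals:
        seg_mean = [float(np.mean(tr.values[a:b])) for tr in tracks]
        if gene_med[0] <= 0:
            continue  # reject: relative abundance undefined at t0
        t0_fold = seg_mean[0] / gene_med[0]
        ra0 = t0_fold
        stab = 0.0
        for ti in range(1, n_t):
            if gene_med[ti] <= 0:
                continue
            stab = max(stab, (seg_mean[ti] / gene_med[ti]) / ra0) if ra0 > 0 else stab
        if t0_fold > config.min_t0_fold and stab >= config.min_stabilization_fold:
            out.append(
                SegmentCandidate(
                    interval=(a, b),
                    host_gene_id=gene.id,
                    replicate=replicate,
                    mean_t0=seg_mean[0],
                    t0_fold=t0_fold,
                    stabilization_fold=stab,
                )
            )
    return out


def intersect_replicates(
    per_replicate: Sequence[Sequence[SegmentCandidate]],
    config: DetectionConfig,
) -> list[tuple[tuple[int, int], tuple[int, ...], list[SegmentCandidate]]]:
    """Replicate-consistent consensus intervals.

    Candidates from all replicates are grouped per host gene by
    single-linkage genomic overlap (>= 1 nt).  A group drawing on at
    least ``min_replicate_support`` distinct replicates yields one
    consensus interval: the intersection of its members, which must
    still exceed ``min_segment_len``.  Returns
    ``(interval, sorted replicate ids, member candidates)`` triples.
    """
    if len(per_replicate) < config.min_replicate_support:
        raise ValueError(
            f"need >= {config.min_replicate_support} replicate candidate sets"
        )
    all_cands = [c for reps in per_replicate for c in reps]
    by_gene: dict[str, list[SegmentCandidate]] = {}
    for c in all_cands:
        by_gene.setdefault(c.host_gene_id, []).append(c)

    out = []
    for gene_id, cands in by_gene.items():
        cands.sort(key=lambda c: c.interval)
        groups: list[list[SegmentCandidate]] = []
        cur: list[SegmentCandidate] = []
        cur_end = -1
        for c in cands:
            if cur and c.interval[0] < cur_end:
                cur.append(c)
                cur_end = max(cur_end, c.interval[1])
            else:
                if cur:
                    groups.append(cur)
                cur = [c]
                cur_end = c.interval[1]
        if cur:
            groups.append(cur)
        for grp in groups:
            reps = sorted({c.replicate for c in grp})
            if len(reps) < config.min_replicate_support:
                continue
            start = max(c.interval[0] for c in grp)
            end = min(c.interval[1] for c in grp)
            if end - start <= config.min_segment_len:
                continue
            out.append(((start, end), tuple(reps), grp))
    out.sort(key=lambda x: x[0])
    return out


def correct_boundaries(
    call: DecRnaCall,
    end_sites: Sequence[EndSite],
    max_distance: int,
    min_segment_len: int = 40,
) -> DecRnaCall:
    """Snap call boundaries to the nearest mapped termini within range.

    In gene orientation the segment start snaps to a 5'-end site and the
    segment end to a 3'-end site.  A snap that would invert the interval
    or shrink it to ``min_segment_len`` or less is refused.
    """
    sites = [
        s for s in end_sites
        if s.strand == call.strand and s.replicon_id == call.replicon_id
    ]
    if not sites:
        return call
    start, end = call.interval
    # genomic-left boundary corresponds to the 5' end on '+', 3' end on '-'
    left_kind = "five_prime" if call.strand == "+" else "three_prime"
    right_kind = "three_prime" if call.strand == "+" else "five_prime"

    def nearest(target: int, kind: str) -> Optional[int]:
        best, bestd = None, max_distance + 1
        for s in sites:
            if s.kind != kind:
                continue
            d = abs(s.position - target)
            if d < bestd:
                best, bestd = s.position, d
        return best

    new_start, new_end = start, end
    snapped = False
    ls = nearest(start, left_kind)
    if ls is not None:
        new_start = ls
        snapped = True
    # the right boundary is half-open: site position p means the interval ends at p+1
    rs = nearest(end - 1, right_kind)
    if rs is not None:
        new_end = rs + 1
        snapped = True
    if not snapped:
        return call
    if new_end - new_start <= min_segment_len:
        warnings.warn(
            f"boundary correction of {call.id} refused (would shrink below "
            f"{min_segment_len} nt)", stacklevel=2,
        )
        return call
    from dataclasses import replace

    return replace(call, interval=(new_start, new_end), boundary_corrected=True)


def classify_overlap(
    interval: tuple[int, int], gene: GeneModel
) -> tuple[float, str]:
    """CDS-overlap fraction and category of a call interval.

    fraction 1.0 -> ``within_cds``; > 0.5 -> ``cds_majority``;
    otherwise ``utr_majority``.
    """
    a, b = interval
    cs, ce = gene.cds
    ov = max(0, min(b, ce) - max(a, cs))
    frac = ov / (b - a)
    if frac == 1.0:
        cat = "within_cds"
    elif frac > 0.5:
        cat = "cds_majority"
    else:
        cat = "utr_majority"
    return frac, cat


def _extract_rna(genome: str, interval: tuple[int, int], strand: str) -> str:
    from Bio.Seq import Seq

    seq = genome[interval[0]: interval[1]].upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.replace("T", "U")


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def detect_decrnas(
    experiment: DecayExperiment,
    genes: Sequence[GeneModel],
    genome: str,
    config: Optional[DetectionConfig] = None,
    end_sites: Optional[Sequence[EndSite]] = None,
) -> list[DecRnaCall]:
    """Run the full detection pipeline and return sorted consensus calls.

    Scans every timepoint of every replicate (raw tracks), merges
    per-replicate hits, applies the fold filters on normalized tracks,
    intersects across replicates, optionally corrects boundaries to
    mapped termini, and classifies CDS overlap.  Each call records which
    replicates supported it and their filter values.
    """
    config = config or DetectionConfig()
    if not genes:
        return []
    norm = experiment.normalized()
    n_t = len(experiment.timepoints)
    n_rep = experiment.n_replicates

    t0_by_rep = [
        {st: experiment.track(0, rep, st) for st in ("+", "-")}
        for rep in range(n_rep)
    ]
    expressed = filter_expressed(t0_by_rep, genes, config)

    per_rep: list[list[SegmentCandidate]] = []
    for rep in range(n_rep):
        cands: list[SegmentCandidate] = []
        for gene in expressed:
            hits: list[tuple[int, int]] = []
            for ti in range(n_t):
                hits.extend(scan_gene(experiment.track(ti, rep, gene.strand), gene, config))
            if not hits:
                continue
            merged = _merge_intervals(hits)
            cands.extend(filter_candidates(merged, norm, gene, rep, config))
        per_rep.append(cands)

    consensus = intersect_replicates(per_rep, config)

    gene_by_id = {g.id: g for g in genes}
    calls: list[DecRnaCall] = []
    for interval, reps, members in consensus:
        gene = gene_by_id[members[0].host_gene_id]
        call = DecRnaCall(
            interval=interval,
            host_gene_id=gene.id,
            replicon_id=gene.replicon_id,
            strand=gene.strand,
            n_replicates_support=len(reps),
            supporting_replicates=reps,
            cds_overlap_fraction=0.0,
            category="utr_majority",
            sequence="",
            provenance={
                "replicates": list(reps),
                "t0_fold": {c.replicate: round(c.t0_fold, 4) for c in members},
                "stabilization_fold": {
                    c.replicate: round(c.stabilization_fold, 4) for c in members
                },
            },
        )
        if end_sites:
            call = correct_boundaries(
                call, end_sites, config.max_end_distance, config.min_segment_len
            )
        frac, cat = classify_overlap(call.interval, gene)
        from dataclasses import replace

        call = replace(
            call,
            cds_overlap_fraction=frac,
            category=cat,
            sequence=_extract_rna(genome, call.interval, gene.strand),
        )
        calls.append(call)

    # overlapping gene footprints can produce identical-coordinate calls;
    # keep the host with the larger CDS overlap
    dedup: dict[tuple, DecRnaCall] = {}
    for c in calls:
        key = (c.replicon_id, c.strand, c.interval)
        prev = dedup.get(key)
        if prev is None or c.cds_overlap_fraction > prev.cds_overlap_fraction:
            dedup[key] = c
    out = sorted(dedup.values(), key=lambda c: (c.replicon_id, c.interval))
    return out
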