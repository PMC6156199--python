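# Methods

## Model and assumptions

A rifampicin assay blocks transcription initiation at t = 0; from then
on each transcript decays by first-order kinetics, so expected coverage
at a position of gene *g* is *A_g·e^(−k_g t)*. A decRNA is modeled as a
subgene interval with its own decay rate *k_s « k_g* and a steady-state
abundance boost *b ≥ 1* relative to the host transcript (real decRNAs
accumulate because decay of newly made host mRNA keeps producing them;
the most extreme published case sits ~45-fold above its host). Its
relative abundance — segment mean over host-gene median — therefore
grows as *b·e^((k_g − k_s)t)*.

The detector assumes: (i) coverage within one library is comparable in
absolute reads/nt; (ii) cross-timepoint comparisons require library-size
normalization (reads-per-million here; any constant cancels in the
ratios); (iii) genes are independent transcription units (no operon
structure); (iv) the per-gene median is a robust proxy for host-mRNA
level even when a minority of positions belong to a stabilized segment.

## Detection procedure and its numerical choices

Thresholds (all overridable in `DetectionConfig` / YAML): t=0 gene
median ≥ 5 reads/nt; 100-nt window moved in 1-nt steps; 4 SD; segments
> 40 nt; > 2-fold over the gene median at t=0; ≥ 3-fold gain in relative
abundance; support in ≥ 2 replicates.

**Window orientation and run formation.** The window trails on the
transcript's 5′ side of the evaluated nucleotide, so the 5′ boundary of
a stabilized segment registers as an upshift; both strands are scanned
in gene orientation. A literal per-position rule (each nucleotide versus
its own trailing window) cannot produce runs longer than ~window/17 nt
at a sharp step — as segment positions enter the window, the window SD
grows proportionally to the step height, and the inequality
(w−k) > 4·√(k(w−k)) fails for k ≥ w/17. Runs are therefore started by
the rolling rule and extended while coverage stays above the *frozen*
statistics of the last fully pre-run window; this recovers the full
segment body and terminates at the first post-segment position. The test
suite re-derives the same rule position by position as an independent
oracle.

**SD floor.** On noise-free or constant windows the SD is 0 and any
uptick would be infinitely significant; the SD used in the threshold is
floored at 1 read/nt (configurable), which makes the rule well defined
on noise-free synthetic data and harmless on real counts.

**Raw versus normalized tracks.** Rules expressed in absolute reads/nt
(expression filter, SD floor, Hfq > 30, ProQ coverage gate > 20) are
applied to raw tracks; all ratio rules (t=0 fold, stabilization fold,
ProQ enrichment) use normalized tracks. Applying an absolute cut after
rescaling to an arbitrary constant would make its unit meaningless.

**Which timepoint is scanned.** A segment with modest boost only
becomes locally elevated late in the course, so every timepoint of every
replicate is scanned and a replicate's hits are merged (union of
overlapping intervals) before fold filtering.

**Other conventions.** Even-length medians are the mean of the two
central order statistics. The expression filter requires the threshold
in every replicate ("any"/"mean" configurable). Stabilization is the
maximum over post-t0 timepoints of relative abundance versus its t=0
value; a zero gene median at a later timepoint skips that timepoint
rather than producing an infinite ratio, and a zero median at t=0
rejects the candidate. Replicate grouping is single-linkage by ≥ 1 nt
overlap per host gene; the consensus is the interval intersection and
must still exceed the minimum length. Boundary snapping matches the
segment's 5′ edge to 5′-end sites and its 3′ edge to 3′-end sites within
20 nt (default), refusing snaps that would invert or shrink the call
below the minimum length. Identical-coordinate calls from overlapping
gene footprints keep the host with the larger CDS overlap.

## Fold stability

Stability is the predicted minimum free energy divided by sequence
length (kcal/mol/nt). The default engine is the ViennaRNA
nearest-neighbor model at 37 °C; a built-in engine (exact DP under a
simplified energy function: GC −3, AU −2, GU −1 kcal/mol per pair, −1
per stacked pair, minimum hairpin loop 3 nt) keeps the package
self-contained and is verified against exhaustive enumeration of all
pseudoknot-free structures for short sequences. Absolute energies are
engine-dependent; comparative statistics are run under a single engine
and that is what the distribution comparison relies on. Random segments
are drawn genome-wide, uniform in position and strand, lengths resampled
from the pooled known-ncRNA + decRNA length distribution (10,000 by
default).

The Wilcoxon rank-sum test wraps the standard Mann-Whitney
implementation: exact when the combined sample is ≤ 20 and tie-free,
otherwise the normal approximation with tie and continuity corrections;
degenerate zero-variance inputs return p = 1.

## Chaperone and RNase E scoring

ProQ enrichment is the IP/lysate ratio in the tagged (3xFLAG)
experiment divided by the same ratio in the untagged control, computed
on library-normalized means; a pseudocount of 0.1 (normalized units) on
every mean keeps ratios finite at zero lysate coverage. The coverage
gate is applied to the raw FLAG IP track (configurable). Both chaperone
thresholds are strict inequalities. Multiplying any one library's counts
and its mapped-read total by the same constant leaves the enrichment
unchanged. The RNase E comparison is an unpaired rank-sum test between
WT and mutant decRNA/host ratio distributions; a paired variant can be
built from the returned per-id ratios but is not the default.

## Synthetic data: what it does and does not emulate

Defaults mirror the assayed conditions: a 0–9 min grid at 1-min steps,
triplicate libraries, Poisson counts per nucleotide (negative binomial
with configurable dispersion for overdispersion), ±5% library-depth
jitter, gene decay rates uniform on 0.2–0.5 /min (half-lives of
1.4–3.5 min), steady-state abundances log-normal around ~100 reads/nt,
planted segment lengths 80–300 nt with decay rates 0.02–0.08 /min and a
5× steady-state boost. Library totals are the realized sums of sampled
counts, so normalization is exercised non-trivially. Planted segments
are kept at least one window away from the transcript's 5′ end because
the trailing-window rule is blind there by construction (a documented
method limitation, not a simulator artifact).

Not modeled: along-genome coverage correlation (read-length smearing),
fragment-length effects, rRNA depletion artifacts, multi-gene operons,
read-level (FASTQ) output. Passing recovery tests therefore shows the
algorithm implements its rules correctly under the stated kinetic and
counting model — not that real libraries, with correlated errors and
mapping artifacts, will behave as cleanly.

## Problem sizes used in tests and the acceptance script

Recovery checks use 20-gene (noise-free) and 10-gene × 100-seed
(Poisson) simulations with 3–5 planted segments each; enrichment
recovery uses 12-gene co-IP pairs over 100 seeds; the null calibration
uses 10,000 simulated sample pairs (n = 20 per arm); the stability
comparison in the acceptance script uses 58 structured segments, 63
known-ncRNA stand-ins and 2,000 random segments. These sizes were chosen
to estimate each rate or error well while keeping a full run to tens of
seconds on one CPU.

## Known limitations

* Segments starting within the first window of a transcript's 5′ end
  are undetectable (see above); segments shorter than ~41 nt are
  excluded by design.
* A planted segment whose steady-state boost is ≤ 2 fails the t=0 fold
  filter regardless of how slowly it decays — the filter trades
  sensitivity to late-emerging segments for specificity at t=0.
* The built-in folding engine's energies are not thermodynamic; only
  within-engine comparisons are meaningful.
* Detection is gene-footprint-bounded; intergenic stabilized RNAs are
  out of scope.
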