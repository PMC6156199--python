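import numpy as np
import pytest

import decarve as dc
from decarve.detection import DecRnaCall, _merge_intervals
from decarve.io_formats import DecayExperiment
from conftest import make_track

from oracles import naive_scan

CFG = dc.DetectionConfig()


def simple_gene(n, strand="+", cds=None):
    return dc.GeneModel("g", "chr", strand, cds or (0, n))


class TestGeneMedian:
    @pytest.mark.parametrize(
        "values,expected",
        [([7] * 6, 7.0), ([1, 2, 3, 4, 5], 3.0), ([1, 2, 3, 4], 2.5)],
        ids=["constant", "odd-count", "even-count-midpoint"],
    )
    def test_median_conventions(self, values, expected):
        assert dc.gene_median_coverage(make_track(values), simple_gene(len(values))) == expected

    def test_zero_length_footprint_rejected(self):
        with pytest.raises(ValueError):
            dc.GeneModel("g", "chr", "+", (5, 5))


class TestFilterExpressed:
    def tracks(self, medians):
        return [{"+": make_track([m] * 10), "-": make_track([0] * 10)} for m in medians]

    def test_threshold_boundary(self):
        genes = [simple_gene(10)]
        assert dc.filter_expressed(self.tracks([6, 6, 6]), genes, CFG) == genes
        assert dc.filter_expressed(self.tracks([4, 4, 4]), genes, CFG) == []
        # the published cut is "median less than 5": exactly 5 is kept
        assert dc.filter_expressed(self.tracks([5, 5, 5]), genes, CFG) == genes

    def test_zero_threshold_keeps_everything(self):
        cfg = dc.DetectionConfig(min_gene_median_t0=0.0)
        genes = [simple_gene(10)]
        assert dc.filter_expressed(self.tracks([0, 0, 0]), genes, cfg) == genes

    def test_all_rule_requires_every_replicate(self):
        genes = [simple_gene(10)]
        mixed = self.tracks([6, 4, 6])
        assert dc.filter_expressed(mixed, genes, CFG) == []
        any_cfg = dc.DetectionConfig(expressed_rule="any")
        assert dc.filter_expressed(mixed, genes, any_cfg) == genes


class TestScanGene:
    def test_flat_coverage_yields_nothing(self):
        for const in (0.0, 5.0, 1000.0):
            track = make_track([const] * 800)
            assert dc.scan_gene(track, simple_gene(800), CFG) == []

    def test_plateau_recovered_and_matches_oracle(self):
        v = np.array([100.0] * 400 + [1000.0] * 150 + [100.0] * 400)
        got = dc.scan_gene(make_track(v), simple_gene(v.size), CFG)
        assert got == [(400, 550)]
        assert got == naive_scan(v, CFG.window, CFG.sd_threshold,
                                 CFG.min_segment_len, CFG.sd_floor)

    def test_forty_nt_run_is_excluded_by_strict_rule(self):
        v = np.array([100.0] * 300 + [1000.0] * 40 + [100.0] * 300)
        assert dc.scan_gene(make_track(v), simple_gene(v.size), CFG) == []
        v41 = np.array([100.0] * 300 + [1000.0] * 41 + [100.0] * 300)
        assert dc.scan_gene(make_track(v41), simple_gene(v41.size), CFG) == [(300, 341)]

    def test_minus_strand_scans_in_gene_orientation(self):
        v = np.array([100.0] * 400 + [1000.0] * 150 + [100.0] * 400)
        plus = dc.scan_gene(make_track(v), simple_gene(v.size, "+"), CFG)
        minus = dc.scan_gene(make_track(v[::-1].copy(), strand="-"),
                             simple_gene(v.size, "-"), CFG)
        n = v.size
        assert [(n - b, n - a) for a, b in plus] == minus

    def test_footprint_not_longer_than_window_warns_empty(self):
        with pytest.warns(UserWarning, match="window"):
            assert dc.scan_gene(make_track([5.0] * 80), simple_gene(80), CFG) == []

    def test_random_vectors_match_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(150, 900))
            v = rng.poisson(20.0, size=n).astype(float)
            if rng.random() < 0.7:  # plant a step
                a = int(rng.integers(CFG.window, n - 50))
                b = min(n, a + int(rng.integers(10, 200)))
                v[a:b] += rng.uniform(50, 500)
            got = dc.scan_gene(make_track(v), simple_gene(n), CFG)
            assert got == naive_scan(v, CFG.window, CFG.sd_threshold,
                                     CFG.min_segment_len, CFG.sd_floor)


def _norm_experiment(seg_values, med=10.0, n=200, seg=(50, 100)):
    """Normalized experiment: gene median `med` at every t; segment set per t."""
    exp = DecayExperiment("chr", tuple(float(t) for t in range(len(seg_values))), 1)
    for ti, sv in enumerate(seg_values):
        v = np.full(n, med)
        v[seg[0]: seg[1]] = sv
        exp.tracks[(ti, 0, "+")] = make_track(v, normalized=True)
        exp.tracks[(ti, 0, "-")] = make_track(np.zeros(n) + 1, normalized=True)
    return exp


class TestFilterCandidates:
    GENE = dc.GeneModel("g", "chr", "+", (0, 200))

    def run(self, seg_values):
        exp = _norm_experiment(seg_values)
        return dc.filter_candidates([(50, 100)], exp, self.GENE, 0, CFG)

    def test_kept_candidate_records_stabilization(self):
        # t0 fold 2.1; relative-abundance ratios (1, 1.5, 3.5)
        out = self.run([21.0, 31.5, 73.5])
        assert len(out) == 1
        assert out[0].t0_fold == pytest.approx(2.1)
        assert out[0].stabilization_fold == pytest.approx(3.5)

    def test_low_t0_fold_rejected_regardless_of_stabilization(self):
        assert self.run([19.0, 190.0, 1900.0]) == []

    def test_insufficient_stabilization_rejected(self):
        assert self.run([25.0, 30.0, 72.5]) == []  # fold 2.5, max ratio 2.9

    def test_zero_gene_median_at_later_timepoint_skipped(self):
        exp = _norm_experiment([21.0, 31.5, 73.5])
        # zero out the whole gene at t=1 -> that timepoint cannot contribute
        exp.tracks[(1, 0, "+")] = make_track(np.zeros(200), normalized=True)
        out = dc.filter_candidates([(50, 100)], exp, self.GENE, 0, CFG)
        assert len(out) == 1 and out[0].stabilization_fold == pytest.approx(3.5)


def cand(a, b, rep, gene="g"):
    return dc.SegmentCandidate((a, b), gene, rep, 0.0, 3.0, 4.0)


class TestIntersectReplicates:
    def test_identical_interval_full_support(self):
        per_rep = [[cand(100, 260, r)] for r in range(3)]
        out = dc.intersect_replicates(per_rep, CFG)
        assert out == [((100, 260), (0, 1, 2), per_rep[0] + per_rep[1] + per_rep[2])]

    def test_single_replicate_dropped(self):
        out = dc.intersect_replicates([[cand(100, 260, 0)], [], []], CFG)
        assert out == []

    def test_consensus_is_interval_intersection(self):
        out = dc.intersect_replicates([[cand(100, 260, 0)], [cand(120, 280, 1)]], CFG)
        assert len(out) == 1
        interval, reps, _ = out[0]
        assert interval == (120, 260) and reps == (0, 1)

    def test_consensus_shorter_than_min_length_dropped(self):
        out = dc.intersect_replicates([[cand(100, 260, 0)], [cand(230, 400, 1)]], CFG)
        assert out == []


def make_call(a, b, strand="+"):
    return DecRnaCall((a, b), "g", "chr", strand, 2, (0, 1), 1.0, "within_cds", "")


class TestCorrectBoundaries:
    def test_no_end_sites_leaves_call_unchanged(self):
        c = dc.correct_boundaries(make_call(100, 260), [], 20)
        assert c.interval == (100, 260) and not c.boundary_corrected

    def test_nearby_five_prime_site_snaps_start(self):
        sites = [dc.EndSite("chr", "+", 97, "five_prime")]
        c = dc.correct_boundaries(make_call(100, 260), sites, 20)
        assert c.interval == (97, 260) and c.boundary_corrected

    def test_distant_site_ignored(self):
        sites = [dc.EndSite("chr", "+", 50, "five_prime")]
        c = dc.correct_boundaries(make_call(100, 260), sites, 20)
        assert c.interval == (100, 260) and not c.boundary_corrected

    def test_minus_strand_maps_kinds_to_genomic_sides(self):
        # on '-' the genomic right edge is the transcript 5' end
        sites = [dc.EndSite("chr", "-", 262, "five_prime"),
                 dc.EndSite("chr", "-", 103, "three_prime")]
        c = dc.correct_boundaries(make_call(100, 260, "-"), sites, 20)
        assert c.interval == (103, 263) and c.boundary_corrected

    def test_shrinking_snap_refused(self):
        sites = [dc.EndSite("chr", "+", 118, "five_prime"),
                 dc.EndSite("chr", "+", 139, "three_prime")]
        with pytest.warns(UserWarning, match="refused"):
            c = dc.correct_boundaries(make_call(120, 160), sites, 20, min_segment_len=40)
        assert c.interval == (120, 160) and not c.boundary_corrected


class TestClassifyOverlap:
    GENE = dc.GeneModel("g", "chr", "+", (50, 150), utr5=(0, 50), utr3=(150, 250))

    def test_entirely_within_cds(self):
        assert dc.classify_overlap((60, 140), self.GENE) == (1.0, "within_cds")

    def test_majority_overlap_cut_is_half(self):
        frac, cat = dc.classify_overlap((96, 186), self.GENE)  # 54 of 90 nt in CDS
        assert frac == pytest.approx(0.6) and cat == "cds_majority"

    def test_utr_only(self):
        assert dc.classify_overlap((160, 250), self.GENE) == (0.0, "utr_majority")


class TestDetectDecrnas:
    def test_recovers_all_planted_segments_exactly(self, noise_free_study, noise_free_calls):
        truth = noise_free_study["truth"]
        assert len(noise_free_calls) == len(truth)
        by_host = {c.host_gene_id: c for c in noise_free_calls}
        for r in truth.itertuples():
            c = by_host[r.host_gene]
            assert abs(c.interval[0] - r.start) <= 5
            assert abs(c.interval[1] - r.end) <= 5
            assert c.strand == r.strand
            assert c.n_replicates_support == 3

    def test_call_sequence_is_rna_from_gene_strand(self, noise_free_study, noise_free_calls):
        genome = noise_free_study["genome"]
        c = noise_free_calls[0]
        assert set(c.sequence) <= set("ACGU") and len(c.sequence) == c.length
        from Bio.Seq import Seq
        expect = genome[c.interval[0]: c.interval[1]]
        if c.strand == "-":
            expect = str(Seq(expect).reverse_complement())
        assert c.sequence == expect.replace("T", "U")

    def test_uniform_decay_produces_no_calls(self, noise_free_study):
        s = noise_free_study
        exp, _ = dc.simulate_decay_experiment(s["genome"], s["sim_genes"], [], s["config"])
        assert dc.detect_decrnas(exp, s["genes"], s["genome"]) == []

    def test_thirty_nt_planted_segment_below_min_length(self, noise_free_study):
        s = noise_free_study
        host = s["segments"][0]
        short = dc.PlantedSegment(host.host_gene_id, host.offset, 30,
                                  host.decay_rate, host.boost)
        exp, _ = dc.simulate_decay_experiment(s["genome"], s["sim_genes"], [short], s["config"])
        assert dc.detect_decrnas(exp, s["genes"], s["genome"]) == []

    def test_empty_inputs_give_empty_output(self, noise_free_study):
        s = noise_free_study
        assert dc.detect_decrnas(s["experiment"], [], s["genome"]) == []

    def test_stronger_stabilization_never_removes_a_call(self, noise_free_study):
        s = noise_free_study
        seg = s["segments"][0]
        hosts = set()
        for k_seg in (seg.decay_rate, seg.decay_rate / 2):
            mod = dc.PlantedSegment(seg.host_gene_id, seg.offset, seg.length, k_seg, seg.boost)
            exp, _ = dc.simulate_decay_experiment(s["genome"], s["sim_genes"], [mod], s["config"])
            calls = dc.detect_decrnas(exp, s["genes"], s["genome"])
            hosts.add(tuple(c.host_gene_id for c in calls))
        assert hosts == {(seg.host_gene_id,)}

    def test_strand_symmetry_under_genome_reflection(self, noise_free_study, noise_free_calls):
        from Bio.Seq import Seq

        s = noise_free_study
        L = s["config"].genome_len
        mirror_genome = str(Seq(s["genome"]).reverse_complement())
        mirror_genes = [
            dc.GeneModel(
                g.id, g.replicon_id,
                "-" if g.strand == "+" else "+",
                (L - g.cds[1], L - g.cds[0]),
                utr5=(L - g.utr5[1], L - g.utr5[0]) if g.utr5 else None,
                utr3=(L - g.utr3[1], L - g.utr3[0]) if g.utr3 else None,
            )
            for g in s["genes"]
        ]
        src = s["experiment"]
        mirror = DecayExperiment(src.replicon_id, src.timepoints, src.n_replicates)
        for (ti, rep, st), tr in src.tracks.items():
            flip = "-" if st == "+" else "+"
            mirror.tracks[(ti, rep, flip)] = dc.CoverageTrack(
                tr.replicon_id, flip, tr.values[::-1].copy(), tr.library_total
            )
        mirror_calls = dc.detect_decrnas(mirror, mirror_genes, mirror_genome)
        got = sorted((L - c.interval[1], L - c.interval[0]) for c in mirror_calls)
        want = sorted(c.interval for c in noise_free_calls)
        assert got == want
        assert sorted(c.sequence for c in mirror_calls) == sorted(
            c.sequence for c in noise_free_calls
        )


def test_merge_intervals_unions_overlaps():
    assert _merge_intervals([(5, 10), (8, 12), (20, 30), (12, 15)]) == [(5, 12), (12, 15), (20, 30)]
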