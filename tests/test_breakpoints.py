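"""Read-pair classification, window rule, masking, linking and refinement."""

import random
from collections import defaultdict

import pytest

from balancerkit.breakpoints import (
    CandidateWindow,
    ClipObs,
    Event,
    Placement,
    ReadPairRecord,
    Region,
    build_events,
    call_breakpoints,
    classify_pair,
    collect_pairs,
    estimate_insert_bounds,
    load_bed,
    mask_filter,
    merge_windows,
    pair_junctions,
    refine_breakpoint,
    window_scan,
)
from balancerkit.errors import ParseError
from balancerkit.pipeline import match_junctions


def mk_pair(s1, strand1, s2, strand2, lclip1=0, rclip1=0, supp1=False,
            chrom="c", rlen=150):
    p1 = Placement(chrom, s1, s1 + rlen - 1 - lclip1 - rclip1, strand1,
                   lclip1, rclip1, 60)
    p2 = Placement(chrom, s2, s2 + rlen - 1, strand2, 0, 0, 60)
    return ReadPairRecord("q", "pe", p1, p2, supp1, False, [], [])


class TestClassifyPair:
    def test_fr_pair_within_bounds_is_concordant(self):
        pr = mk_pair(1000, "+", 1400, "-")
        assert classify_pair(pr, "fr", (300, 900)) == "concordant"

    def test_same_strand_pair_is_discordant(self):
        # inversion-flank geometry forces same-strand mates
        for strand in "+-":
            pr = mk_pair(1000, strand, 1400, strand)
            assert classify_pair(pr, "fr", (300, 900)) == "discordant"

    def test_rf_pair_is_discordant_under_fr_expectation(self):
        pr = mk_pair(1000, "-", 1400, "+")
        assert classify_pair(pr, "fr", (300, 900)) == "discordant"
        assert classify_pair(pr, "rf", (300, 900)) == "concordant"

    def test_insert_outside_bounds_is_discordant(self):
        pr = mk_pair(1000, "+", 9000, "-")
        assert classify_pair(pr, "fr", (300, 900)) == "discordant"

    def test_soft_clip_with_supplementary_is_split(self):
        pr = mk_pair(1000, "+", 1400, "-", rclip1=40, supp1=True)
        assert classify_pair(pr, "fr", (300, 900), min_clip=20) == "split"
        # split takes precedence over discordant
        pr2 = mk_pair(1000, "+", 1400, "+", rclip1=40, supp1=True)
        assert classify_pair(pr2, "fr", (300, 900)) == "split"

    def test_clip_below_min_clip_is_not_split(self):
        pr = mk_pair(1000, "+", 1400, "-", rclip1=10, supp1=True)
        assert classify_pair(pr, "fr", (300, 900), min_clip=20) == "concordant"

    def test_unmapped_mate_is_unusable(self):
        pr = ReadPairRecord("q", "pe", mk_pair(1, "+", 2, "-").r1, None)
        assert classify_pair(pr) == "unusable"


def random_events(rng, n, span=50_000):
    return [
        Event("c", rng.randint(1, span), rng.choice(["split", "discordant"]),
              f"q{i}", "pe", rng.randint(1, span))
        for i in range(n)
    ]


class TestWindowScan:
    def test_eleven_events_make_a_candidate_ten_do_not(self):
        ev10 = [Event("c", 4500 + i, "discordant", f"q{i}", "pe", 90_000 + i)
                for i in range(10)]
        assert window_scan(ev10, 1000, 10) == []
        ev11 = ev10 + [Event("c", 4600, "split", "q10", "pe", 90_500)]
        wins = window_scan(ev11, 1000, 10)
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end, wins[0].support) == (4000, 5000, 11)

    def test_counts_equal_brute_force_histogram(self):
        rng = random.Random(42)
        for _ in range(20):
            events = random_events(rng, rng.randint(0, 400))
            for wsize in (1000, 2500):
                expect = defaultdict(int)
                for e in events:
                    expect[(e.pos - 1) // wsize] += 1
                got = {w.start // wsize: w.support
                       for w in window_scan(events, wsize, 3)}
                assert got == {k: v for k, v in expect.items() if v > 3}

    def test_raising_min_support_never_adds_windows(self):
        rng = random.Random(7)
        events = random_events(rng, 500)
        prev = None
        for ms in (0, 3, 8, 15):
            wins = {(w.chrom, w.start) for w in window_scan(events, 1000, ms)}
            if prev is not None:
                assert wins <= prev
            prev = wins


class TestMaskFilter:
    def test_empty_mask_is_identity(self):
        rng = random.Random(1)
        events = random_events(rng, 50)
        assert mask_filter(events, {}) == events

    def test_event_anchored_in_mask_removed(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("c\t999\t2000\n")   # 1-based 1000..2000
        mask = load_bed(str(bed))
        events = [Event("c", 1000, "split", "a", "pe", 5),
                  Event("c", 2000, "split", "b", "pe", 5),
                  Event("c", 2001, "split", "c", "pe", 5)]
        kept = mask_filter(events, mask)
        assert [e.qname for e in kept] == ["c"]

    def test_matches_brute_force_point_in_interval_scan(self, tmp_path):
        rng = random.Random(9)
        for rep in range(10):
            ivs = sorted((rng.randint(0, 40_000), rng.randint(1, 10_000))
                         for _ in range(rng.randint(1, 30)))
            bed = tmp_path / f"m{rep}.bed"
            bed.write_text("".join(f"c\t{a}\t{a + l}\n" for a, l in ivs))
            mask = load_bed(str(bed))
            events = random_events(rng, 300)
            kept = mask_filter(events, mask)
            brute = [e for e in events
                     if not any(a < e.pos <= a + l for a, l in ivs)]
            assert kept == brute

    def test_enlarging_mask_never_adds_events(self, tmp_path):
        rng = random.Random(3)
        events = random_events(rng, 300)
        b1 = tmp_path / "m1.bed"
        b1.write_text("c\t1000\t5000\n")
        b2 = tmp_path / "m2.bed"
        b2.write_text("c\t1000\t5000\nc\t20000\t30000\n")
        k1 = {id(e) for e in mask_filter(events, load_bed(str(b1)))}
        k2 = {id(e) for e in mask_filter(events, load_bed(str(b2)))}
        assert k2 <= k1

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("c\t0\t100\nc\txx\t200\n")
        with pytest.raises(ParseError, match="2"):
            load_bed(str(bed))


class TestRefineBreakpoint:
    def test_clean_clip_consensus_gives_base_pair_call(self):
        region = Region("c", 4_000, 6_000, 12, 30)
        clips = [ClipObs("c", 5_000, "right", f"r{i}") for i in range(6)] + \
                [ClipObs("c", 5_091, "left", f"l{i}") for i in range(5)]
        j = refine_breakpoint(region, clips)
        assert (j.five_prime, j.three_prime, j.delta) == (5_000, 5_091, -90)
        assert j.resolution == "base-pair" and not j.ambiguous

    def test_duplication_locus_reports_positive_delta_and_microhomology(self):
        region = Region("c", 4_000, 6_000, 9, 3)
        clips = [ClipObs("c", 5_007, "right", f"r{i}") for i in range(4)] + \
                [ClipObs("c", 5_001, "left", f"l{i}") for i in range(4)]
        j = refine_breakpoint(region, clips)
        assert (j.five_prime, j.three_prime, j.delta) == (5_007, 5_001, 7)
        assert j.microhomology == 7

    def test_no_split_reads_gives_window_level_call(self):
        region = Region("c", 4_001, 5_000, 0, 25)
        j = refine_breakpoint(region, [])
        assert j.resolution == "window-level" and j.delta is None

    def test_equal_weight_modes_flag_ambiguity_toward_smaller_coordinate(self):
        region = Region("c", 4_000, 6_000, 8, 0)
        clips = [ClipObs("c", 5_000, "right", "a"), ClipObs("c", 5_000, "right", "b"),
                 ClipObs("c", 5_400, "right", "x"), ClipObs("c", 5_400, "right", "y"),
                 ClipObs("c", 5_601, "left", "l1"), ClipObs("c", 5_601, "left", "l2")]
        j = refine_breakpoint(region, clips)
        assert j.ambiguous and j.five_prime == 5_000
        assert j.alt_coords[0] == 5_400


class TestPairJunctions:
    def test_no_shared_pairs_means_no_link(self):
        wins = [CandidateWindow("c", 4000, 5000, 12, 0, 12),
                CandidateWindow("c", 90_000, 91_000, 12, 0, 12)]
        links, one_sided = pair_junctions(wins, [], min_link=3)
        assert links == [] and len(one_sided) == 2

    def test_merge_windows_bridges_small_gaps(self):
        wins = [CandidateWindow("c", 4000, 5000, 12, 6, 6),
                CandidateWindow("c", 7000, 8000, 11, 5, 6),
                CandidateWindow("c", 50_000, 51_000, 15, 7, 8)]
        regions = merge_windows(wins, 1000, merge_gap=2)
        assert [(r.start, r.end) for r in regions] == [(4001, 8000), (50_001, 51_000)]


class TestEndToEnd:
    def test_all_junctions_recovered_exactly_on_clean_simulation(self, small_sim):
        res = call_breakpoints(small_sim["sam"])
        truth = small_sim["truth"].junctions
        m = match_junctions(res.junctions, truth, tol=1)
        assert m["recall"] == 1.0 and m["precision"] == 1.0
        called = {(j.five_prime, j.three_prime): j.delta for j in res.junctions}
        expect = {(j.five_prime, j.three_prime): j.delta for j in truth}
        assert called == expect
        assert {-1090, -4, 0, 7} <= set(called.values())
        assert all(j.resolution == "base-pair" for j in res.junctions)

    def test_single_inversion_mp_library_yields_two_links(self, tmp_path):
        from dataclasses import replace

        from balancerkit.rearrangement import Inversion
        from balancerkit.simulate import (
            SimConfig,
            derive_panel,
            make_reference,
            write_stock_sam,
        )
        cfg = SimConfig(seed=4, ref_length=500_000, n_stocks=1, sco_rate=0.0,
                        dco_specs=[], read_stocks=(0,), pe_fraction=0.0,
                        include_homolog=False, coverage=30.0,
                        karyotype=[Inversion("i", (150_000, 150_001),
                                             (400_000, 400_001))])
        ref = make_reference(cfg.ref_length, cfg.seed)
        bmap, truth = derive_panel(ref, cfg)
        sam = tmp_path / "mp.sam"
        write_stock_sam(str(sam), ref, bmap, truth.stocks[0], cfg, 0)
        res = call_breakpoints(str(sam))
        assert len(res.links) == 2
        assert sorted(l.sig for l in res.links) == ["FF", "RR"]
        m = match_junctions(res.junctions, truth.junctions, tol=1)
        assert m["recall"] == 1.0 and m["precision"] == 1.0

    def test_masking_junction_region_suppresses_its_call(self, small_sim, tmp_path):
        cfg = small_sim["cfg"]
        bed = tmp_path / "mask.bed"
        # mask a 30-kb region swallowing the first locus and its anchors
        bed.write_text(f"{cfg.chrom}\t385000\t415000\n")
        res = call_breakpoints(small_sim["sam"], mask_bed=str(bed))
        assert all(abs(j.five_prime - 400_000) > 1000 for j in res.junctions)

    def test_priors_bed_restricts_scan(self, small_sim, tmp_path):
        cfg = small_sim["cfg"]
        bed = tmp_path / "priors.bed"
        bed.write_text(f"{cfg.chrom}\t380000\t420000\n{cfg.chrom}\t880000\t920000\n")
        res = call_breakpoints(small_sim["sam"], priors_bed=str(bed))
        fives = sorted(j.five_prime for j in res.junctions)
        assert fives == [400_000, 900_000]

    def test_insert_bounds_estimated_per_library(self, small_sim):
        pairs, _ = collect_pairs(small_sim["sam"])
        lo_pe, hi_pe = estimate_insert_bounds(pairs, "pe")
        lo_mp, hi_mp = estimate_insert_bounds(pairs, "mp")
        assert 300 < lo_pe < 600 < hi_pe < 900
        assert hi_mp > 12_000 * 0.9
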