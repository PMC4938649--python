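"""Synthetic-data generator: determinism, panel structure, read geometry,
VCF properties."""

import math
import os
from collections import Counter
from dataclasses import replace

import numpy as np
import pysam
import pytest
from cyvcf2 import VCF

from balancerkit.errors import InvalidConfigError
from balancerkit.rearrangement import Inversion
from balancerkit.simulate import (
    DcoSpec,
    SimConfig,
    build_balancer_map,
    derive_panel,
    emit_stock_vcf,
    make_reference,
    sam_to_fastq,
    simulate_all,
    simulate_read_pairs,
    write_stock_sam,
)


def tiny_cfg(**kw):
    base = dict(
        seed=2, ref_length=200_000, n_stocks=3, sco_rate=0.0, dco_specs=[],
        karyotype=[Inversion("i", (80_000, 80_001), (160_000, 160_001))],
        read_stocks=(0,), mask_intervals=((10_000, 11_000),),
    )
    base.update(kw)
    return SimConfig(**base)


class TestReference:
    def test_deterministic_and_seed_sensitive(self):
        a = make_reference(10_000, 7)
        assert a == make_reference(10_000, 7)
        assert a != make_reference(10_000, 8)

    def test_base_composition_uniform_within_binomial_error(self):
        n = 100_000
        seq = make_reference(n, 1)
        counts = Counter(seq)
        assert set(counts) <= set("ACGT")
        sd = math.sqrt(n * 0.25 * 0.75)
        for b in "ACGT":
            assert abs(counts[b] - n / 4) < 4 * sd

    def test_too_short_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_reference(500, 1)


class TestDerivePanel:
    def test_no_crossovers_means_identical_stock_profiles(self):
        cfg = tiny_cfg()
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        s0 = truth.stocks[0]
        for st in truth.stocks[1:]:
            assert np.array_equal(st.snp_pos, s0.snp_pos)
            assert np.array_equal(st.snp_alt, s0.snp_alt)
        assert not truth.tracts

    def test_sco_removes_distal_balancer_snps_from_crossover_point(self):
        cfg = tiny_cfg(sco_rate=1.0, n_stocks=2)
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        cfg0 = tiny_cfg(n_stocks=2)
        _, anc = derive_panel(ref, cfg0)
        anc_pos = set(anc.stocks[0].snp_pos.tolist())
        for st in truth.stocks:
            (tract,) = st.tracts
            assert tract.kind == "SCO" and tract.start == 1
            c = tract.end
            kept = set(st.snp_pos.tolist()) & anc_pos
            distal_kept = [p for p in kept if p <= c]
            # donor positions may collide with ancestral positions by chance
            assert len(distal_kept) <= 0.02 * len(kept) + 3
            donor = set(st.snp_pos.tolist()) - anc_pos
            assert donor and all(p <= c for p in donor)

    def test_dco_replaces_interval_in_target_stock_only(self):
        spec = DcoSpec((100_000, 140_000), stocks=(1,))
        cfg = tiny_cfg(dco_specs=[spec])
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        s0, s1 = truth.stocks[0], truth.stocks[1]
        a, b = spec.interval
        def snps_in(st):
            m = (st.snp_pos >= a) & (st.snp_pos <= b)
            return set(zip(st.snp_pos[m].tolist(), st.snp_alt[m].tolist()))
        in_iv0, in_iv1 = snps_in(s0), snps_in(s1)
        # the donor haplotype replaces the balancer SNPs (chance positional
        # collisions between two haplotypes are rare but possible)
        assert len(in_iv0 & in_iv1) <= 0.02 * len(in_iv0) + 3
        out0 = s0.snp_pos[(s0.snp_pos < a) | (s0.snp_pos > b)]
        out1 = s1.snp_pos[(s1.snp_pos < a) | (s1.snp_pos > b)]
        assert np.array_equal(out0, out1)
        assert s1.tracts[0].kind == "DCO"

    def test_dco_outside_inverted_segment_rejected(self):
        cfg = tiny_cfg(dco_specs=[DcoSpec((10_000, 20_000), stocks=(0,))])
        ref = make_reference(cfg.ref_length, cfg.seed)
        with pytest.raises(InvalidConfigError):
            derive_panel(ref, cfg)

    def test_snp_count_tracks_density(self):
        cfg = tiny_cfg()
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        n = len(truth.stocks[0].snp_pos)
        lam = cfg.ref_length * cfg.snp_density
        assert abs(n - lam) < 4 * math.sqrt(lam)


class TestReadSimulation:
    def test_identity_karyotype_error_free_pe_is_all_concordant(self, tmp_path):
        from balancerkit.breakpoints import (
            build_events,
            collect_pairs,
            estimate_insert_bounds,
        )
        cfg = tiny_cfg(karyotype=[])
        ref = make_reference(cfg.ref_length, cfg.seed)
        bmap, truth = derive_panel(ref, cfg)
        sam = tmp_path / "id.sam"
        cfg2 = replace(cfg, pe_fraction=1.0, include_homolog=False, coverage=10.0)
        write_stock_sam(str(sam), ref, bmap, truth.stocks[0], cfg2, 0)
        pairs, _ = collect_pairs(str(sam))
        bounds = {"pe": estimate_insert_bounds(pairs, "pe", n_sd=4.0)}
        _, _, stats = build_events(pairs, bounds)
        assert stats["split"] == 0
        assert stats["discordant"] == 0

    def test_mp_junction_straddle_count_matches_fragment_geometry(self, tmp_path):
        cfg = tiny_cfg(include_homolog=False, pe_fraction=0.0, coverage=20.0)
        ref = make_reference(cfg.ref_length, cfg.seed)
        bmap, truth = derive_panel(ref, cfg)
        sam = tmp_path / "mp.sam"
        write_stock_sam(str(sam), ref, bmap, truth.stocks[0], cfg, 0)
        # derived positions of the two junctions of the single inversion
        jpos = [80_000, bmap.derived_length - (cfg.ref_length - 160_000)]
        # count fragments straddling each junction from the qname-encoded
        # derived fragment coordinates
        straddle = Counter()
        n_frags = 0
        with pysam.AlignmentFile(str(sam), "r", check_sq=False) as f:
            for rec in f:
                if rec.is_supplementary or not rec.is_read1:
                    continue
                n_frags += 1
                _, _, s, e = rec.query_name.rsplit(":", 3)
                s, e = int(s), int(e)
                for k, j in enumerate(jpos):
                    if s <= j < e:
                        straddle[k] += 1
        L = bmap.derived_length
        lo, hi = cfg.mp_insert_range
        mean_i = (lo + hi) / 2
        p = mean_i / L
        for k in range(2):
            expect = n_frags * p
            sd = math.sqrt(n_frags * p * (1 - p))
            assert abs(straddle[k] - expect) < 3.5 * sd

    def test_split_and_orientation_discordant_fragments_straddle_junctions(
            self, small_sim):
        # every split or same-strand (inversion-signature) discordant pair
        # from the balancer haplotype must straddle a true derived junction;
        # insert-size-only discordants may come from the PE length tail.
        from balancerkit.breakpoints import (
            classify_pair,
            collect_pairs,
            estimate_insert_bounds,
        )
        bmap = small_sim["map"]
        offs, jpos = 0, []
        for seg in bmap.segments[:-1]:
            offs += len(seg)
            jpos.append(offs)
        pairs, _ = collect_pairs(small_sim["sam"])
        bounds = {lib: estimate_insert_bounds(pairs, lib) for lib in ("pe", "mp")}
        bad = 0
        for pr in pairs.values():
            if not pr.qname.startswith("bal.") or not pr.both_mapped:
                continue
            cls = classify_pair(pr, insert_bounds=bounds[pr.library])
            junction_sig = cls == "split" or (
                cls == "discordant" and pr.r1.strand == pr.r2.strand
            )
            if not junction_sig:
                continue
            _, _, s, e = pr.qname.rsplit(":", 3)
            s, e = int(s), int(e)
            if not any(s <= j < e for j in jpos):
                bad += 1
        assert bad == 0

    def test_junction_crossing_reads_become_split_records(self, small_sim):
        with pysam.AlignmentFile(small_sim["sam"], "r", check_sq=False) as f:
            n_supp = sum(1 for rec in f if rec.is_supplementary)
        assert n_supp > 0

    def test_zero_coverage_rejected_and_tiny_coverage_empty(self, tmp_path):
        cfg = tiny_cfg()
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidConfigError):
            simulate_read_pairs(None, "A" * 1000, cfg, "pe", 0.0, rng,
                                open(os.devnull, "w"))
        n = simulate_read_pairs(None, "A" * 1000, cfg, "pe", 1e-9, rng,
                                open(os.devnull, "w"))
        assert n == 0

    def test_fastq_export_round_trip(self, tmp_path, small_sim):
        out1, out2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        n = sam_to_fastq(small_sim["sam"], str(out1), str(out2))
        assert n > 0
        first = out1.read_text().splitlines()[:4]
        assert first[0].startswith("@") and set(first[1]) <= set("ACGTN")


class TestVcfEmission:
    def test_indel_fraction_zero_gives_only_snvs(self, tmp_path):
        cfg = tiny_cfg(indel_fraction=0.0)
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        p = tmp_path / "s.vcf"
        emit_stock_vcf(str(p), truth.stocks[0], ref, cfg, 0)
        for var in VCF(str(p)):
            assert not var.is_indel

    def test_fixed_high_qual_model_passes_downstream_filter(self, tmp_path):
        cfg = tiny_cfg(qual_model=(500.0, 0.0))
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        p = tmp_path / "s.vcf"
        emit_stock_vcf(str(p), truth.stocks[0], ref, cfg, 0)
        assert all(v.QUAL >= 200 for v in VCF(str(p)))

    def test_low_qual_tail_mass_matches_model(self, tmp_path):
        from scipy.stats import norm
        cfg = tiny_cfg(qual_model=(800.0, 300.0))
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        p = tmp_path / "s.vcf"
        emit_stock_vcf(str(p), truth.stocks[0], ref, cfg, 0)
        quals = [v.QUAL for v in VCF(str(p))]
        n = len(quals)
        ptail = norm.cdf((200 - 800) / 300)
        observed = sum(q < 200 for q in quals)
        assert abs(observed - n * ptail) < 3 * math.sqrt(n * ptail * (1 - ptail))

    def test_records_sorted_and_heterozygous(self, tmp_path):
        cfg = tiny_cfg()
        ref = make_reference(cfg.ref_length, cfg.seed)
        _, truth = derive_panel(ref, cfg)
        p = tmp_path / "s.vcf"
        emit_stock_vcf(str(p), truth.stocks[0], ref, cfg, 0)
        pos = [v.POS for v in VCF(str(p))]
        assert pos == sorted(pos)
        assert all(v.gt_types[0] == 1 for v in VCF(str(p)))


class TestDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        cfg = tiny_cfg(n_stocks=2)
        outs = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            simulate_all(cfg, str(d))
            blob = b""
            for root, _, files in sorted(os.walk(d)):
                for f in sorted(files):
                    blob += open(os.path.join(root, f), "rb").read()
            outs.append(blob)
        assert outs[0] == outs[1]

    def test_fixture_files_are_standard_formats(self, tmp_path):
        cfg = tiny_cfg(n_stocks=2)
        out = simulate_all(cfg, str(tmp_path / "o"))
        bed = open(out["mask"]).read().splitlines()
        assert bed and all(len(l.split("\t")) == 3 for l in bed)
        gff = open(out["genes"]).read()
        assert gff.startswith("##gff-version 3")
        with pysam.FastaFile(out["reference"]) as fa:
            assert fa.lengths[0] == cfg.ref_length
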