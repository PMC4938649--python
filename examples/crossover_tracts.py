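"""Detect single and double crossovers across a panel of balancer stocks.

Simulates an 18-stock panel (11 stocks with a single crossover distal to
the distal-most inversion breakpoint, two related stocks sharing a double
crossover inside the inverted segment), emits one heterozygous VCF per
stock, and runs the sharing analysis: SNPs carried by five or fewer
stocks are plotted in 10-kb windows and contiguous runs become crossover
tracts.
"""

import tempfile

from balancerkit.panel import (
    call_tracts,
    load_panel,
    rare_snp_windows,
    share_counts,
    shared_tracts,
)
from balancerkit.rearrangement import Inversion
from balancerkit.simulate import (
    DcoSpec,
    SimConfig,
    derive_panel,
    emit_stock_vcf,
    make_reference,
)

cfg = SimConfig(
    seed=5, ref_length=2_000_000,
    karyotype=[Inversion("inv", (800_000, 800_001), (1_800_000, 1_800_001))],
    n_stocks=18, sco_stocks=tuple(range(2, 13)),
    dco_specs=[DcoSpec((1_000_000, 1_300_000), stocks=(0, 1))],
    read_stocks=(),
)
ref = make_reference(cfg.ref_length, cfg.seed)
bmap, truth = derive_panel(ref, cfg)

with tempfile.TemporaryDirectory() as d:
    vcfs = []
    for i, st in enumerate(truth.stocks):
        p = f"{d}/{st.stock}.vcf"
        emit_stock_vcf(p, st, ref, cfg, i)
        vcfs.append(p)
    panel = load_panel(vcfs, qual_min=200)

k = share_counts(panel)
print(f"panel: {len(panel):,} SNPs x {panel.n_stocks} stocks "
      f"(QUAL<200 removed: {panel.n_dropped_qual:,}; "
      f"indels removed: {panel.n_dropped_indel:,})")
print(f"unique SNPs (k=1): {(k == 1).sum():,}; shared by all 18: "
      f"{(k == 18).sum():,}")

wm = rare_snp_windows(panel, max_share=5, window=10_000,
                      chrom_length=cfg.ref_length)
bps = sorted({c for j in bmap.junctions for c in (j.five_prime, j.three_prime)})
tracts = call_tracts(wm, panel, bps, chrom_length=cfg.ref_length)
print(f"\n{len(tracts)} crossover tracts "
      f"(SCO = distal single crossover, DCO = internal double crossover):")
for t in tracts:
    print(f"  {t.stock}: {t.kind} {t.start:,}..{t.end:,} "
          f"({t.n_rare_snps:,} rare SNPs; {t.span_display_mb})")
rel = shared_tracts(tracts, panel)
flagged = rel[rel.likely_common_origin]
print("\nstock pairs whose tracts share a likely common recombinant origin:")
for r in flagged.itertuples():
    print(f"  {r.stock1} ~ {r.stock2}: reciprocal overlap "
          f"{r.reciprocal_overlap:.2f}, rare-SNP identity {r.identity:.2f}")
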