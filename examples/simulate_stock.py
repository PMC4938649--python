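"""Simulate a balancer stock: derived chromosome, SNPs, reads and VCF.

Builds a 1-Mb reference, superimposes an inversion whose distal junction
deletes 1,090 bp, and emits the aligned read pairs and the heterozygous
VCF a real sequencing run of a balancer/reference heterozygote would
produce.
"""

import os
import tempfile

from balancerkit.rearrangement import Inversion
from balancerkit.simulate import SimConfig, simulate_all

cfg = SimConfig(
    seed=42,
    ref_length=1_000_000,
    karyotype=[Inversion("In(toy)", (400_000, 401_091), (900_000, 900_001))],
    n_stocks=4,
    sco_stocks=(2, 3),          # two stocks carry a distal single crossover
    dco_specs=[],
    coverage=10.0,
    read_stocks=(0,),
    mask_intervals=((100_000, 102_000),),
)

with tempfile.TemporaryDirectory() as outdir:
    out = simulate_all(cfg, outdir)
    bmap, truth = out["map"], out["truth"]
    print(f"reference: {cfg.ref_length:,} bp; derived balancer: "
          f"{bmap.derived_length:,} bp "
          f"(sum of junction deltas = {sum(j.delta for j in bmap.junctions):+d})")
    print("junction loci (reference frame):")
    for j in bmap.junctions:
        print(f"  5'={j.five_prime:,}  3'={j.three_prime:,}  delta={j.delta:+d}")
    for st in truth.stocks:
        tr = ", ".join(f"{t.kind} 1..{t.end:,}" for t in st.tracts) or "none"
        print(f"  {st.stock}: {len(st.snp_pos):,} balancer SNPs; crossovers: {tr}")
    sam = out["sams"][0]
    n_lines = sum(1 for l in open(sam) if not l.startswith("@"))
    print(f"emitted {n_lines:,} aligned read records to {os.path.basename(sam)} "
          f"and {len(out['vcfs'])} stock VCFs")
print("Reads crossing a junction appear as split (soft-clipped) records;")
print("pairs straddling one appear as orientation/insert discordant pairs.")
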