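"""Junction deletion/duplication arithmetic on the bundled breakpoint table.

Every rearrangement junction is described by the last retained reference
base on its 5' side and the first retained base on its 3' side; the signed
delta (bases deleted at the join, or duplicated onto both sides) follows
from those two coordinates alone.
"""

import balancerkit as bk

tbl = bk.breakpoint_table()
print(f"{'balancer':10} {'inversion':12} {'chrom':5} {'5-break':>10} "
      f"{'3-break':>10} {'delta':>6}")
for row in tbl.itertuples():
    delta = bk.junction_delta(row.five_prime, row.three_prime)
    assert delta == row.delta
    print(f"{row.balancer:10} {row.inversion:12} {row.chrom:5} "
          f"{row.five_prime:>10,} {row.three_prime:>10,} {delta:>+6}")

print("\nA negative delta is bases lost at the junction, a positive delta is")
print("bases present on both sides of the join, and 0 is a clean join.")
print("\nSegment spans quoted from bounding coordinates, in Mb (half-up):")
print("  double-crossover tract 9,216,999..10,625,261 ->",
      bk.span_mb(9_216_999, 10_625_261, 1), "Mb")
print("  inverted segment 8,287,181..10,742,076      ->",
      bk.span_mb(8_287_181, 10_742_076, 1), "Mb")
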