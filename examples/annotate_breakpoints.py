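"""Annotate breakpoints against gene models and classify small lesions.

Shows the two annotation operations: which gene a breakpoint bisects
(with the affected isoforms and containing intron), and whether a
deletion overlapping coding sequence is in-frame or frameshifting.
"""

import tempfile

from balancerkit.annotate import (
    classify_deletion,
    intersect_breakpoints,
    load_gene_models,
)

GFF = """##gff-version 3
chrT\ttoy\tgene\t30000\t70000\t.\t-\t.\tID=gene:tsg;Name=tsg
chrT\ttoy\tmRNA\t30000\t70000\t.\t-\t.\tID=tsg.1;Parent=gene:tsg
chrT\ttoy\texon\t69000\t69500\t.\t-\t.\tID=e1;Parent=tsg.1
chrT\ttoy\texon\t66000\t66500\t.\t-\t.\tID=e2;Parent=tsg.1
chrT\ttoy\texon\t63000\t63500\t.\t-\t.\tID=e3;Parent=tsg.1
chrT\ttoy\texon\t60000\t60500\t.\t-\t.\tID=e4;Parent=tsg.1
chrT\ttoy\texon\t57000\t57500\t.\t-\t.\tID=e5;Parent=tsg.1
chrT\ttoy\texon\t31000\t31800\t.\t-\t.\tID=e6;Parent=tsg.1
"""

with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
    fh.write(GFF)
    path = fh.name
models = load_gene_models(path)

for pos in (50_000, 80_000):
    (ann,) = intersect_breakpoints([("chrT", pos)], models)
    if ann.status == "bisected":
        hits = "; ".join(f"{h.transcript}: {h.feature} {h.index}"
                         for h in ann.isoform_hits[ann.genes[0]])
        print(f"breakpoint at {pos:,}: bisects {ann.label} ({hits})")
    else:
        print(f"breakpoint at {pos:,}: {ann.label}")

print("\ndeletion framing against a fully coding interval:")
for iv in ((26_657_089, 26_657_157), (26_656_728, 26_656_742),
           (6_661_619, 6_661_619)):
    res = classify_deletion(iv, [(min(iv) - 10_000, max(iv) + 10_000)])
    codons = f", removing {res['codons']} codons" if res["codons"] else ""
    print(f"  {iv[0]:,}..{iv[1]:,}: {res['length']} bp, "
          f"{res['classification']}{codons}")
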