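# Methods

## The rearrangement model

A derived (balancer) chromosome is an ordered list of reference segments
`(start, end, orientation)`, 1-based inclusive, tiling the derived frame
without gaps. Rearrangements are applied **sequentially**, each expressed
in the *current* derived frame, because balancers were built historically
by superimposing new inversions on already rearranged chromosomes. Two
event types exist:

* a **two-breakpoint inversion** specified by its two junction loci
  `(f1, t1)` and `(f2, t2)`: the new chromosome is
  `D[1..f1] + rc(D[t1..f2]) + D[t2..end]`;
* a **three-breakpoint rearrangement** with loci A < B < C: cutting
  leaves blocks S1..S4 and the derived order is
  `S1 + rc(S3) + rc(S2) + S4` — the proximal interval inverted in place
  and the interval between the two distal cuts relocated beyond it, also
  inverted. The published figures for the relevant three-breakpoint
  events do not state the block order algebraically; this order was
  chosen because it reproduces the drawn topology (a short distal
  segment, bisecting a gene at its internal breakpoint, relocated and
  inverted inside the large inversion) and yields exactly three derived
  junctions. Any block order with the same cuts gives identical
  junction deltas; the order affects only which loci are linked by
  read-pair evidence.

Each locus records the Table-convention junction: `five_prime` (last
retained base, 5′ side, reference frame), `three_prime` (first retained
base, 3′ side) and `delta = −(three−five−1)` or `+(five−three+1)`. The
rule is equivalent to the length change of joining `ref[:five]` to
`ref[three−1:]`, which is the oracle used in the tests. Duplicated bases
appear once on each side of the junction in the derived sequence;
deleted bases are unreachable by liftover (duplicated ones map to the
leftmost derived copy). Derived length always equals reference length
plus the sum of junction deltas; this is asserted structurally by the
segment arithmetic and checked in tests.

`span_mb` reports the difference of two bounding coordinates in Mb,
rounded half-up (`Decimal`, not banker's rounding), matching how tract
and segment sizes are conventionally quoted.

## Synthetic data: what it emulates

The generator reproduces the *structure* of a balancer-stock sequencing
study, at a scale chosen for desk-size compute:

* **Reference**: uniform-random A/C/G/T, default 5 Mb (a stand-in for a
  chromosome arm; the real arms are 25–32 Mb). Default karyotype: one
  inversion whose distal junction deletes 1,090 bp plus one
  three-breakpoint rearrangement (junction deltas −4 and +7), i.e. five
  breakpoint loci with the full variety of junction lesions.
* **Balancer SNPs**: placed uniformly at `snp_density` = 0.0062/bp,
  matching the reported ~43,000 informative SNPs over a ~6.9-Mb distal
  interval (~6.2/kb). All stocks share this ancestral haplotype.
* **Crossovers**: each stock receives a distal SCO with probability
  `sco_rate` (default 11/18, the observed fraction of recombinant
  stocks), at a uniform position in the distal unbalanced region;
  `sco_stocks` fixes the recombinant subset exactly. The distal 10%
  of the region is excluded by default (`sco_telomere_margin`) because
  crossing over is suppressed near telomeres; `sco_exclusion_bp` adds an
  optional keep-out next to the breakpoint (0 by default; ~2 Mb mimics
  the closest observed exchange). Each SCO imports an independent donor
  haplotype (private SNPs at the same density). DCOs are configured
  explicitly (`dco_specs`) as intervals that must lie inside an inverted
  segment; all stocks receiving one spec share a single donor, modelling
  common descent. Truth (junctions, tracts, per-stock SNPs) is recorded
  and serialised.
* **Reads**: 150-bp pairs from fragments drawn uniformly on the derived
  chromosome — paired-end inserts N(600, 60) bp, mate-pair inserts
  uniform on 2–12 kb — at `coverage` fold **per haplotype** (the
  normal-sequence homolog is added at equal depth by default, as in a
  heterozygote; total depth is twice `coverage`). Each read is placed on
  the reference *analytically* through the balancer map: reads crossing
  a derived junction are emitted as primary + supplementary records with
  soft clips whose boundaries are exact, pairs straddling a junction
  become orientation/insert-discordant. This replaces an external
  aligner while preserving exactly the evidence the caller consumes; an
  aligner would additionally smear clip positions within duplicated
  (microhomologous) bases, which the exact emulation does not. An
  optional FASTQ export (`sam_to_fastq`) exists for users who want to
  run a real aligner. Sequencing error is substitution-only
  (`base_error`, default 0) and base qualities are a constant offset.
* **VCFs**: one per stock, heterozygous 0/1 records at the stock's SNP
  positions; QUAL ~ N(800, 300) clipped at 1, placing ~2% of records
  below the 200 cutoff so the quality filter is genuinely exercised;
  indels (1–3 bp) interleaved at `indel_fraction` = 0.05 of emitted
  records, existing only to exercise the drop-indels filter.
* **Fixtures**: a repeat-mask BED (0-based half-open at the I/O
  boundary; the model itself is 1-based inclusive throughout), toy GFF3
  gene models including a four-isoform gene whose intron 5 spans the
  distal junction, and TSV truth tables.

Not emulated: library-prep artifacts (duplicates, chimeras), indel/TE
alleles as detectable events, alignability structure (mapping quality is
constant), and real *Drosophila* sequence composition. Passing tests
therefore demonstrate correctness of the algorithms under clean,
truth-known conditions — not performance on repeat-rich real data, where
masking and the window threshold carry the burden.

## Breakpoint calling

1. **Classification.** A pair is *split* if either read carries a soft
   clip ≥ `min_clip` (20 bp) and has a supplementary placement (or SA
   tag); else *discordant* if the mates are on different chromosomes,
   their orientation violates the library expectation (FR by default;
   mate-pair orientation is a parameter, since post-processing
   conventions vary), or the inferred insert falls outside the bounds;
   else concordant. Insert bounds default to the per-library empirical
   mean ± 3 SD of concordant-orientation spans, estimated from the data
   itself.
2. **Anchoring and windows.** Every split/discordant record — both
   primaries and supplementaries — contributes one event anchored at its
   leftmost aligned base. Events inside the repeat mask are dropped.
   Fixed windows (1 kb) tile from position 1; a window is a candidate
   iff it holds **strictly more than** `min_support` (10) events. With a
   prior-regions BED, only events inside prior regions are scanned;
   otherwise the whole chromosome (the window rule applied within
   optional priors resolves how candidate-region restriction and the
   window rule combine; both PE and MP evidence is pooled, with
   per-library counts available in the stats).
3. **Region linking.** Candidate windows separated by ≤ 2 empty windows
   merge into breakpoint regions (the deleted bases of a lesion are
   unpopulated, so a locus's two flanks often sit in nearby but distinct
   windows). Two-sided observations — a discordant pair's two anchors,
   or a split read's primary/supplementary anchors — link regions under
   a breakend signature: each side points forward (`F`: right clip or
   `+`-strand mate) or reverse (`R`), taken in reference-position order.
   An inversion yields FF and RR links; deletion-like joins FR;
   duplication-like joins RF. Links need ≥ `min_link` (3) supporting
   read names; one derived junction produces exactly one link, and a
   region with no links is still refined as a one-sided candidate.
4. **Refinement.** Within each region (± 2.5 kb pad), right-clip
   boundaries are clustered (single linkage, 10 bp) and the modal
   position — ties broken toward the smaller coordinate — gives
   `five_prime`; left clips give `three_prime`; `junction_delta` gives
   the lesion size, and `max(delta, 0)` is reported as microhomology.
   Two equally supported modes flag the call ambiguous with both
   reported. Without usable clips the call stays window-level (region
   midpoint, no delta). A de novo assembly of junction-spanning reads
   would provide the same junction sequence evidence; the clip consensus
   uses it directly without an assembler.

On clean 30× simulations this recovers every junction locus exactly
(±0 bp observed; ±1 bp tolerated in tests) with exact deltas, and calls
nothing absent from truth.

## Crossover tracts

Panel assembly treats a polymorphism as the triple (chrom, pos, alt);
genotype phase is ignored because every call is heterozygous
balancer/reference by construction. Records below `qual_min` = 200 are
removed (a record at exactly 200 is retained — the filter removes
"< 200"), indels are never considered, and only heterozygous SNVs enter
the matrix. Sharing count *k* is the row sum; *k* = 1 is a unique
polymorphism, *k* = n shared-by-all.

Rare SNPs (*k* ≤ `max_share`, default 5 for an 18-stock panel) are
counted per stock in 10-kb windows tiled from position 1 — the
heatmap-ready matrix. `max_share` is a parameter, not a constant: the
rule only works when the non-recombinant majority exceeds it (with 11 of
18 stocks recombinant the distal ancestral SNPs are still carried by 7),
and the pipeline clamps it to n−1, which for a 3-stock panel degenerates
to "any SNP not shared by all three".

The published analysis plots these windows but never states a tract
rule; the rule here is this package's formalisation and is labelled as
such. A tract is a maximal run of windows with ≥ 1 rare SNP, allowing
`max_gap` empty windows (default 0), with ≥ `min_windows` (2) populated
windows and ≥ `min_snps` (10) rare SNPs. The density requirements
separate genuine tracts — which carry a donor haplotype's full SNP
complement, ~60 per window at default density — from sparse rare SNPs
created by quality-filter dropout in partially shared regions; the
zero-gap default prevents such stragglers from extending a real tract's
boundary. Boundaries are the outermost rare SNPs; each boundary's
confidence interval extends to the nearest flanking shared-by-all SNP,
which by construction brackets the true exchange point whenever the
tract is detected. A tract wholly distal to the distal-most breakpoint
(or reaching the chromosome end beyond the proximal-most one) is an SCO;
a tract strictly between two breakpoints is a DCO; without breakpoints
tracts are emitted unclassified. Distances from each boundary to the
nearest breakpoint are reported, along with exact coordinates plus a
rounded Mb display column (the printed literature values appear rounded;
the rounding rule there is unstated).

Relatedness: every pair of overlapping tracts from different stocks is
scored by reciprocal overlap fraction and by Jaccard identity of rare
SNPs inside the overlap; pairs above both thresholds (0.8, 0.9) are
flagged "likely common origin". With independent ~2% per-stock dropout,
truly identical tracts score ≈ 0.96.

## Numerical and interface choices

* Coordinates are 1-based inclusive everywhere in the model; BED is
  converted to 0-based half-open only at the I/O boundary.
* All randomness flows from `numpy.random.default_rng([seed, stream…])`
  with fixed stream labels per component, so every output is
  byte-identical for a given config and seed; output tables carry the
  package version and a parameter hash (output paths excluded).
* The simulator formats SAM records as text directly for throughput;
  all reading, and all VCF/FASTA handling, goes through pysam/cyvcf2.
* Problem sizes in the test suite: 1-Mb chromosomes for unit-level
  end-to-end checks, the 5-Mb/30×/18-stock configuration for the
  acceptance-level recovery tests.
* Degenerate inputs: an empty panel is valid (with a warning); zero
  drawn fragments is an empty stream, not an error; a breakpoint
  exactly on a gene-span edge is "boundary", distinct from "bisected",
  since the published tables never exhibit that case; genes wholly
  inside a junction deletion are reported "deleted" rather than
  bisected.

## Limitations

* The caller assumes one chromosome-scale sequence per SAM reference
  and intra-chromosomal junctions; inter-chromosomal pairs are counted
  separately but not called.
* The ≤ `max_share` rule cannot see crossovers shared by more than
  `max_share` stocks, and fails entirely when recombinants outnumber
  `n − max_share` — a property of the method, not the implementation.
* Clip-consensus refinement reports exact coordinates under the exact
  alignment emulation; with a real aligner, microhomology at duplicated
  junction bases makes the two clip positions ambiguous within the
  duplicated run (the reported microhomology length bounds that
  ambiguity).
* Pericentric inversions, centromere-proximal heterochromatin and
  unlocalised repeat-mediated breakpoints are out of scope; the mask
  BED is the only concession to alignability structure.
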