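"""Synthetic balancer-stock data generator with full truth records.

Emulates everything the crossover/breakpoint analysis consumes for a panel
of balancer stocks sequenced as balancer/reference heterozygotes:

* a random reference chromosome (FASTA);
* a balancer derived from it by sequentially superimposed inversions
  (including a three-breakpoint rearrangement), each junction carrying a
  configurable deletion/duplication;
* balancer-lineage SNPs shared by the panel, plus per-stock single
  crossovers (SCO) distal to the distal-most breakpoint and double
  crossovers (DCO) inside inverted segments, each importing a donor
  haplotype's private SNPs;
* 150-bp paired-end and large-insert (2-12 kb) mate-pair read pairs,
  placed analytically on the reference through the balancer map so that
  junction-crossing reads become split records and junction-straddling
  pairs become discordant records (SAM);
* per-stock heterozygous VCFs with a QUAL field spanning the quality
  filter boundary and a configurable indel fraction;
* a repeat-mask BED, toy gene models (GFF3), and truth tables (TSV).

All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .errors import InvalidConfigError
from .rearrangement import (
    BalancerMap,
    Inversion,
    Junction,
    Rearrangement,
    ThreeBreakpointRearrangement,
    reverse_complement,
    write_karyotype,
)

__all__ = [
    "SimConfig",
    "DcoSpec",
    "TractTruth",
    "StockTruth",
    "TruthSet",
    "default_karyotype",
    "make_reference",
    "build_balancer_map",
    "derive_panel",
    "simulate_read_pairs",
    "emit_stock_vcf",
    "emit_fixtures",
    "simulate_all",
    "sam_to_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# rng stream labels (kept stable so outputs are reproducible per component)
_S_REF, _S_SNP, _S_STOCK, _S_VCF, _S_READS, _S_DONOR = 0, 1, 2, 3, 4, 5


def default_karyotype() -> list[Rearrangement]:
    """Two superimposed events on a 5-Mb chromosome: a 2-breakpoint
    inversion (one junction with a 1090-bp deletion) and a three-breakpoint
    rearrangement relocating/inverting a 165-kb segment, with a 4-bp
    deletion and a 7-bp duplication at its junctions."""
    return [
        Inversion("In(sim)A", (2_000_000, 2_001_091), (4_500_000, 4_500_001)),
        ThreeBreakpointRearrangement(
            "Tbr(sim)B",
            (2_600_000, 2_600_001),
            (2_765_000, 2_765_005),
            (3_800_000, 3_799_994),
        ),
    ]


@dataclass(frozen=True)
class DcoSpec:
    """A double-crossover specification: ``interval`` (reference frame,
    1-based inclusive) must lie inside an inverted segment; all listed
    stocks that receive it share one donor haplotype (common origin)."""

    interval: tuple[int, int]
    stocks: tuple[int, ...] | None = None  # None = all stocks eligible
    probability: float = 1.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults emulate the sequenced panel: 18 stocks, ~6.2 balancer SNPs
    per kb (~43,000 informative SNPs over the ~6.9-Mb distal interval),
    150-bp paired-end reads plus a 2-12-kb mate-pair library at 30x
    combined coverage, roughly 11/18 stocks carrying a distal SCO, and a
    shared-origin DCO pair inside an inverted segment.
    """

    seed: int = 1
    chrom: str = "chr3S"
    ref_length: int = 5_000_000
    snp_density: float = 0.0062
    karyotype: list[Rearrangement] = field(default_factory=default_karyotype)
    n_stocks: int = 18
    sco_rate: float = 11 / 18
    sco_stocks: tuple[int, ...] | None = None  # explicit override of sco_rate
    sco_exclusion_bp: int = 0       # keep-out distance from the distal breakpoint
    sco_telomere_margin: float = 0.1  # fraction of distal region excluded at tip
    dco_specs: list[DcoSpec] = field(
        default_factory=lambda: [DcoSpec((2_100_000, 2_600_000), stocks=(0, 1))]
    )
    read_length: int = 150
    pe_insert: tuple[float, float] = (600.0, 60.0)   # mean, sd
    mp_insert_range: tuple[int, int] = (2_000, 12_000)
    coverage: float = 30.0          # fold depth of the balancer haplotype
    pe_fraction: float = 2 / 3      # share of coverage from the PE library
    include_homolog: bool = True    # add reads from the normal-sequence homolog
    base_error: float = 0.0
    qual_model: tuple[float, float] = (800.0, 300.0)  # VCF QUAL normal mean/sd
    indel_fraction: float = 0.05
    donor_snp_density: float | None = None  # default: same as snp_density
    read_stocks: tuple[int, ...] = (0,)     # stocks for which SAM is emitted
    mask_intervals: tuple[tuple[int, int], ...] = (
        (500_000, 512_000),
        (4_800_000, 4_810_000),
    )

    def validate(self) -> None:
        for name in ("sco_rate", "pe_fraction", "base_error", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.sco_telomere_margin < 1.0:
            raise InvalidConfigError("sco_telomere_margin must be in [0, 1)")
        if self.ref_length < 1000:
            raise InvalidConfigError("ref_length must be >= 1 kb")
        if self.coverage <= 0:
            raise InvalidConfigError("coverage must be > 0")
        for spec in self.dco_specs:
            a, b = spec.interval
            if not (1 <= a <= b <= self.ref_length):
                raise InvalidConfigError(f"DCO interval {spec.interval} off chromosome")
            if spec.stocks is not None and any(
                not 0 <= s < self.n_stocks for s in spec.stocks
            ):
                raise InvalidConfigError(f"DCO stock index out of range in {spec}")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), *stream])


@dataclass(frozen=True)
class TractTruth:
    stock: str
    start: int
    end: int
    kind: str   # 'SCO' | 'DCO'
    donor: int


@dataclass
class StockTruth:
    stock: str
    snp_pos: np.ndarray   # 1-based reference positions, sorted
    snp_alt: np.ndarray   # alt bases, dtype '<U1'
    tracts: list[TractTruth]


@dataclass
class TruthSet:
    junctions: list[Junction]
    stocks: list[StockTruth]

    @property
    def tracts(self) -> list[TractTruth]:
        return [t for s in self.stocks for t in s.tracts]


def make_reference(ref_length: int, seed: int) -> str:
    """Uniform-random uppercase A/C/G/T sequence, reproducible from seed."""
    if ref_length < 1000:
        raise InvalidConfigError("ref_length must be >= 1 kb")
    rng = np.random.default_rng([seed % (2**31), _S_REF])
    return _BASES[rng.integers(0, 4, ref_length)].tobytes().decode()


def build_balancer_map(config: SimConfig) -> BalancerMap:
    bmap = BalancerMap.identity(config.chrom, config.ref_length)
    for event in config.karyotype:
        bmap = bmap.apply(event)
    return bmap


def _deleted_mask(bmap: BalancerMap, length: int) -> np.ndarray:
    """Boolean mask (1-based index shifted to 0) of reference bases deleted
    at junctions, i.e. present on no derived segment."""
    dele = np.zeros(length, dtype=bool)
    for j in bmap.junctions:
        if j.delta is not None and j.delta < 0:
            dele[j.five_prime: j.three_prime - 1] = True
    return dele


def _draw_snps(rng: np.random.Generator, lo: int, hi: int, density: float,
               ref: str, forbidden: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """SNP positions (uniform at ``density``) and alt bases over [lo, hi]."""
    n = hi - lo + 1
    pos = np.nonzero(rng.random(n) < density)[0] + lo
    if forbidden is not None and len(pos):
        pos = pos[~forbidden[pos - 1]]
    refb = np.frombuffer(ref.encode(), dtype="S1")[pos - 1]
    # alt = ref base shifted by 1..3 in A<C<G<T order: uniform over non-ref
    shift = rng.integers(1, 4, len(pos))
    order = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    idx = np.array([order.get(b, 0) for b in refb], dtype=np.int64)
    alt = _BASES[(idx + shift) % 4].astype("U1")
    return pos.astype(np.int64), alt


def derive_panel(reference: str, config: SimConfig) -> tuple[BalancerMap, TruthSet]:
    """Build the balancer map and the per-stock SNP/tract truth.

    A single ancestral balancer haplotype carries the lineage SNPs; each
    stock inherits it and then (with probability ``sco_rate``, or exactly
    for the stocks named in ``sco_stocks``) receives one crossover at a
    uniform position in the distal unbalanced region, replacing everything
    distal to the exchange point with an independent donor haplotype.
    DCOs replace internal intervals per ``dco_specs``, one shared donor
    per spec.
    """
    config.validate()
    bmap = build_balancer_map(config)
    deleted = _deleted_mask(bmap, config.ref_length)

    rng_snp = config.rng(_S_SNP)
    anc_pos, anc_alt = _draw_snps(
        rng_snp, 1, config.ref_length, config.snp_density, reference, deleted
    )

    bp_coords = [c for j in bmap.junctions for c in (j.five_prime, j.three_prime)]
    distal_bp = min(bp_coords) if bp_coords else config.ref_length
    donor_density = config.donor_snp_density or config.snp_density

    # one shared donor per DCO spec
    dco_donors = []
    for k, spec in enumerate(config.dco_specs):
        a, b = spec.interval
        if not any(
            s.orient == "-" and s.start <= a and b <= s.end for s in bmap.segments
        ):
            raise InvalidConfigError(
                f"DCO interval {spec.interval} is not inside an inverted segment"
            )
        rng_d = config.rng(_S_DONOR, 1, k)
        dco_donors.append(_draw_snps(rng_d, a, b, donor_density, reference, deleted))

    stocks: list[StockTruth] = []
    for i in range(config.n_stocks):
        rng_i = config.rng(_S_STOCK, i)
        name = f"stock{i:02d}"
        tracts: list[TractTruth] = []
        keep = np.ones(len(anc_pos), dtype=bool)
        extra_pos: list[np.ndarray] = []
        extra_alt: list[np.ndarray] = []

        if config.sco_stocks is not None:
            has_sco = i in config.sco_stocks
            _ = rng_i.random()  # keep stream alignment with rate mode
        else:
            has_sco = rng_i.random() < config.sco_rate
        if has_sco and distal_bp > 1:
            lo = int(config.sco_telomere_margin * (distal_bp - 1)) + 1
            hi = distal_bp - 1 - config.sco_exclusion_bp
            if hi <= lo:
                raise InvalidConfigError(
                    "SCO position range empty: check exclusion/margin settings"
                )
            c = int(rng_i.integers(lo, hi + 1))
            keep &= anc_pos > c
            rng_d = config.rng(_S_DONOR, 0, i)
            dpos, dalt = _draw_snps(rng_d, 1, c, donor_density, reference, deleted)
            extra_pos.append(dpos)
            extra_alt.append(dalt)
            tracts.append(TractTruth(name, 1, c, "SCO", donor=1000 + i))

        for k, spec in enumerate(config.dco_specs):
            if spec.stocks is not None and i not in spec.stocks:
                continue
            if rng_i.random() >= spec.probability:
                continue
            a, b = spec.interval
            keep &= (anc_pos < a) | (anc_pos > b)
            dpos, dalt = dco_donors[k]
            extra_pos.append(dpos)
            extra_alt.append(dalt)
            tracts.append(TractTruth(name, a, b, "DCO", donor=2000 + k))

        pos = np.concatenate([anc_pos[keep], *extra_pos]) if extra_pos else anc_pos[keep]
        alt = np.concatenate([anc_alt[keep], *extra_alt]) if extra_alt else anc_alt[keep]
        order = np.argsort(pos, kind="stable")
        stocks.append(StockTruth(name, pos[order], alt[order], tracts))

    return bmap, TruthSet(list(bmap.junctions), stocks)


# --------------------------------------------------------------------- reads


def _sam_header(config: SimConfig, stock: str) -> str:
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{config.chrom}\tLN:{config.ref_length}",
        f"@RG\tID:{stock}.pe\tSM:{stock}\tLB:pe\tPL:ILLUMINA",
        f"@RG\tID:{stock}.mp\tSM:{stock}\tLB:mp\tPL:ILLUMINA",
        "@PG\tID:balancerkit\tPN:balancerkit",
    ]
    return "\n".join(lines) + "\n"


def _read_pieces(bmap: BalancerMap | None, a: int, b: int):
    """Reference pieces for derived read interval [a, b]; identity map if None."""
    if bmap is None:
        return [(a, b, a, b, "+")]
    return bmap.pieces(a, b)


def _piece_records(pieces, a, b, is_read1, read_seq_fwd, min_anchor):
    """Per-piece (pos, strand, lclip, mlen, rclip, stored_seq) in read order.

    ``read_seq_fwd`` is the derived-forward sequence of the read interval;
    read2 is sequenced in reverse, which flips clip sides and strands.
    """
    R = b - a + 1
    recs = []
    for (d1, d2, r1, r2, orient) in pieces:
        if is_read1:
            off1, off2 = d1 - a, d2 - a
            strand = orient
        else:
            off1, off2 = b - d2, b - d1
            strand = "+" if orient == "-" else "-"
        if strand == "+":
            lclip, rclip = off1, R - 1 - off2
        else:
            lclip, rclip = R - 1 - off2, off1
        recs.append((r1, strand, lclip, d2 - d1 + 1, rclip))
    # drop pieces too short to anchor an alignment, unless it is the only one
    anchored = [r for r in recs if r[3] >= min_anchor]
    if not anchored:
        anchored = [max(recs, key=lambda r: r[3])]
    return anchored, R


def _cigar(lclip: int, mlen: int, rclip: int) -> str:
    parts = []
    if lclip:
        parts.append(f"{lclip}S")
    parts.append(f"{mlen}M")
    if rclip:
        parts.append(f"{rclip}S")
    return "".join(parts)


def simulate_read_pairs(
    bmap: BalancerMap | None,
    derived_seq: str,
    config: SimConfig,
    library: str,
    coverage: float,
    rng: np.random.Generator,
    out,
    stock: str = "stock00",
    qname_prefix: str = "frag",
    min_anchor: int = 20,
) -> int:
    """Emit aligned read pairs for one haplotype and library to ``out``.

    Fragments are drawn uniformly from the derived chromosome; each read's
    reference placement is computed through the balancer map.  Reads whole
    within one segment become plain records; reads crossing a junction
    become split records (primary + supplementary with soft clips); pairs
    straddling a junction without a read crossing it become orientation-
    or insert-discordant records.  Returns the number of fragments drawn.
    Fragment derived coordinates are encoded in the read name
    (``prefix:index:start:end``) for truth back-checks.
    """
    if coverage <= 0:
        raise InvalidConfigError("coverage must be > 0")
    R = config.read_length
    L = bmap.derived_length if bmap is not None else len(derived_seq)
    n_frags = int(round(coverage * L / (2 * R)))
    if n_frags == 0:
        return 0

    if library == "pe":
        mean, sd = config.pe_insert
        insert = np.clip(
            np.rint(rng.normal(mean, sd, n_frags)).astype(np.int64),
            2 * R, int(mean + 4 * sd),
        )
        bounds = (max(2 * R, int(mean - 4 * sd)), int(mean + 4 * sd))
    elif library == "mp":
        lo, hi = config.mp_insert_range
        insert = rng.integers(lo, hi + 1, n_frags)
        bounds = (min(lo, 2 * R), hi)
    else:
        raise InvalidConfigError(f"unknown library {library!r}")
    insert = np.minimum(insert, L)
    start = (rng.random(n_frags) * (L - insert + 1)).astype(np.int64) + 1

    err_rate = config.base_error
    rg = f"{stock}.{library}"
    emitted = 0
    lines: list[str] = []
    for i in range(n_frags):
        s = int(start[i])
        e = s + int(insert[i]) - 1
        name = f"{qname_prefix}:{i}:{s}:{e}"
        mates = []
        for is_read1, (a, b) in ((True, (s, s + R - 1)), (False, (e - R + 1, e))):
            seq_fwd = derived_seq[a - 1: b]
            if err_rate > 0:
                nerr = rng.binomial(R, err_rate)
                if nerr:
                    sb = bytearray(seq_fwd, "ascii")
                    for p in rng.integers(0, R, nerr):
                        sb[p] = b"ACGT"[(b"ACGT".index(sb[p: p + 1]) + 1) % 4]
                    seq_fwd = sb.decode()
            recs, _ = _piece_records(
                _read_pieces(bmap, a, b), a, b, is_read1, seq_fwd, min_anchor
            )
            recs.sort(key=lambda r: (-r[3], r[0]))
            mates.append((recs, seq_fwd, is_read1))

        p1, p2 = mates[0][0][0], mates[1][0][0]
        end1, end2 = p1[0] + p1[3] - 1, p2[0] + p2[3] - 1
        span = max(end1, end2) - min(p1[0], p2[0]) + 1
        fr = (
            p1[1] != p2[1]
            and (p1[0] <= p2[0]) == (p1[1] == "+")
        )
        proper = fr and bounds[0] <= span <= bounds[1]
        for mi, (recs, seq_fwd, is_read1) in enumerate(mates):
            mate_primary = p2 if is_read1 else p1
            for ri, (pos, strand, lclip, mlen, rclip) in enumerate(recs):
                flag = 0x1 | (0x40 if is_read1 else 0x80)
                if strand == "-":
                    flag |= 0x10
                if mate_primary[1] == "-":
                    flag |= 0x20
                if proper:
                    flag |= 0x2
                if ri > 0:
                    flag |= 0x800
                stored = seq_fwd if strand == "+" else reverse_complement(seq_fwd)
                if ri == 0:
                    this, other = (p1, p2) if is_read1 else (p2, p1)
                    if proper:
                        tlen = span if this[0] <= other[0] else -span
                    else:
                        tlen = 0
                else:
                    tlen = 0
                tags = f"RG:Z:{rg}\tNM:i:0"
                if len(recs) > 1:
                    sa = ";".join(
                        f"{config.chrom},{r[0]},{r[1]},{_cigar(r[2], r[3], r[4])},60,0"
                        for rj, r in enumerate(recs) if rj != ri
                    )
                    tags += f"\tSA:Z:{sa};"
                lines.append(
                    f"{name}\t{flag}\t{config.chrom}\t{pos}\t60\t"
                    f"{_cigar(lclip, mlen, rclip)}\t=\t{mate_primary[0]}\t{tlen}\t"
                    f"{stored}\t{'I' * len(stored)}\t{tags}"
                )
        emitted += 1
        if len(lines) >= 20000:
            out.write("\n".join(lines) + "\n")
            lines = []
    if lines:
        out.write("\n".join(lines) + "\n")
    return emitted


def _stock_reference(reference: str, truth: StockTruth) -> str:
    buf = bytearray(reference, "ascii")
    for pos, alt in zip(truth.snp_pos, truth.snp_alt):
        buf[pos - 1] = ord(str(alt))
    return buf.decode()


def write_stock_sam(
    path: str,
    reference: str,
    bmap: BalancerMap,
    truth: StockTruth,
    config: SimConfig,
    stock_index: int,
) -> None:
    """One SAM per stock: PE + MP libraries, balancer haplotype at
    ``coverage`` fold plus (optionally) the normal-sequence homolog at the
    same depth, as in a heterozygote."""
    stock_ref = _stock_reference(reference, truth)
    derived = bmap.derived_sequence(stock_ref)
    hap_cov = config.coverage
    with open(path, "w") as out:
        out.write(_sam_header(config, truth.stock))
        for lib, frac in (("pe", config.pe_fraction), ("mp", 1 - config.pe_fraction)):
            cov = hap_cov * frac
            if cov <= 0:
                continue
            rng = config.rng(_S_READS, stock_index, 0 if lib == "pe" else 1)
            simulate_read_pairs(
                bmap, derived, config, lib, cov, rng, out,
                stock=truth.stock, qname_prefix=f"bal.{lib}",
            )
            if config.include_homolog:
                rng_h = config.rng(_S_READS, stock_index, 2 if lib == "pe" else 3)
                simulate_read_pairs(
                    None, reference, config, lib, cov, rng_h, out,
                    stock=truth.stock, qname_prefix=f"hom.{lib}",
                )


def sam_to_fastq(sam_path: str, out1: str, out2: str) -> int:
    """Export primary records of a simulated SAM back to paired FASTQ."""
    n = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam, \
            open(out1, "w") as f1, open(out2, "w") as f2:
        for rec in sam:
            if rec.is_supplementary or rec.is_secondary:
                continue
            seq = rec.get_forward_sequence()
            qual = "I" * len(seq)
            fh = f1 if rec.is_read1 else f2
            fh.write(f"@{rec.query_name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ----------------------------------------------------------------------- VCF


def emit_stock_vcf(
    path: str,
    truth: StockTruth,
    reference: str,
    config: SimConfig,
    stock_index: int,
) -> int:
    """Heterozygous VCF for one stock: SNVs at the truth positions plus
    interleaved indel records at ``indel_fraction`` of emitted variants;
    QUAL drawn from the configured normal model (clipped at 1), so records
    fall on both sides of a downstream quality cutoff."""
    rng = config.rng(_S_VCF, stock_index)
    mean, sd = config.qual_model
    n_snv = len(truth.snp_pos)
    f = config.indel_fraction
    n_ind = int(round(n_snv * f / (1 - f))) if f > 0 else 0

    taken = set(truth.snp_pos.tolist())
    ind_pos: list[int] = []
    ind_alleles: list[tuple[str, str]] = []
    while len(ind_pos) < n_ind:
        p = int(rng.integers(1, config.ref_length - 4))
        if p in taken:
            continue
        taken.add(p)
        ind_pos.append(p)
        if rng.random() < 0.5:  # deletion of 1-3 bases
            k = int(rng.integers(1, 4))
            ind_alleles.append((reference[p - 1: p + k], reference[p - 1]))
        else:  # insertion of 1-3 bases
            ins = "".join("ACGT"[j] for j in rng.integers(0, 4, int(rng.integers(1, 4))))
            ind_alleles.append((reference[p - 1], reference[p - 1] + ins))

    records = [
        (int(p), reference[p - 1], str(a)) for p, a in zip(truth.snp_pos, truth.snp_alt)
    ] + [(p, r, a) for p, (r, a) in zip(ind_pos, ind_alleles)]
    records.sort(key=lambda r: r[0])
    quals = np.clip(rng.normal(mean, sd, len(records)), 1.0, None)

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={config.chrom},length={config.ref_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(truth.stock)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for (pos, ref, alt), q in zip(records, quals):
            rec = vcf.new_record(
                contig=config.chrom, start=pos - 1, alleles=(ref, alt),
                qual=round(float(q), 1),
            )
            rec.samples[truth.stock]["GT"] = (0, 1)
            rec.samples[truth.stock].phased = False
            vcf.write(rec)
    return len(records)


# ------------------------------------------------------------------ fixtures


def _toy_gene_gff3(config: SimConfig, bmap: BalancerMap) -> str:
    """Toy gene models: a multi-isoform gene spanning the distal junction
    (so the breakpoint falls in intron 5 of each isoform), plus one
    intergenic-control gene well away from any junction."""
    chrom = config.chrom
    bp_coords = [c for j in bmap.junctions for c in (j.five_prime, j.three_prime)]
    bp = min(bp_coords) if bp_coords else config.ref_length // 2
    g1s, g1e = bp - 9_999, bp + 10_000
    lines = [
        "##gff-version 3",
        f"{chrom}\tsim\tgene\t{g1s}\t{g1e}\t.\t+\t.\tID=gene:tsg1;Name=tsg1",
    ]
    # 4 isoforms, each with 6 exons; intron 5 always contains `bp`
    for iso in range(1, 5):
        tid = f"tsg1.{iso}"
        lines.append(
            f"{chrom}\tsim\tmRNA\t{g1s}\t{g1e}\t.\t+\t.\t"
            f"ID=transcript:{tid};Parent=gene:tsg1"
        )
        # exons 1-5 upstream of bp, exon 6 downstream; vary exon sizes by iso
        w = 400 + 50 * iso
        starts = [g1s + k * (w + 600) for k in range(5)]
        exons = [(s0, s0 + w - 1) for s0 in starts]
        exons.append((bp + 5_000, g1e))
        for k, (a, b) in enumerate(exons, 1):
            lines.append(
                f"{chrom}\tsim\texon\t{a}\t{b}\t.\t+\t.\t"
                f"ID=exon:{tid}.{k};Parent=transcript:{tid}"
            )
            lines.append(
                f"{chrom}\tsim\tCDS\t{a}\t{b}\t.\t+\t0\t"
                f"ID=cds:{tid}.{k};Parent=transcript:{tid}"
            )
    # control gene far from all junctions
    g2s, g2e = 100_000, 104_999
    lines.append(f"{chrom}\tsim\tgene\t{g2s}\t{g2e}\t.\t-\t.\tID=gene:ctl1;Name=ctl1")
    lines.append(
        f"{chrom}\tsim\tmRNA\t{g2s}\t{g2e}\t.\t-\t.\t"
        "ID=transcript:ctl1.1;Parent=gene:ctl1"
    )
    for k, (a, b) in enumerate([(g2s, g2s + 999), (g2e - 999, g2e)], 1):
        lines.append(
            f"{chrom}\tsim\texon\t{a}\t{b}\t.\t-\t.\t"
            f"ID=exon:ctl1.1.{k};Parent=transcript:ctl1.1"
        )
    return "\n".join(lines) + "\n"


def emit_fixtures(config: SimConfig, bmap: BalancerMap, truth: TruthSet,
                  outdir: str) -> dict[str, str]:
    """Write repeat-mask BED, toy GFF3 gene models, and truth TSVs."""
    paths = {}
    bed = os.path.join(outdir, "mask.bed")
    with open(bed, "w") as fh:
        for a, b in config.mask_intervals:
            fh.write(f"{config.chrom}\t{a - 1}\t{b}\n")  # 1-based -> BED half-open
    paths["mask"] = bed

    gff = os.path.join(outdir, "genes.gff3")
    with open(gff, "w") as fh:
        fh.write(_toy_gene_gff3(config, bmap))
    paths["genes"] = gff

    jt = os.path.join(outdir, "truth_junctions.tsv")
    bmap.junction_table("synthetic").to_csv(jt, sep="\t", index=False)
    paths["truth_junctions"] = jt

    tt = os.path.join(outdir, "truth_tracts.tsv")
    with open(tt, "w") as fh:
        fh.write("stock\tstart\tend\tkind\tdonor\n")
        for t in truth.tracts:
            fh.write(f"{t.stock}\t{t.start}\t{t.end}\t{t.kind}\t{t.donor}\n")
    paths["truth_tracts"] = tt

    st = os.path.join(outdir, "truth_snps.tsv")
    with open(st, "w") as fh:
        fh.write("stock\tpos\talt\n")
        for s in truth.stocks:
            for p, a in zip(s.snp_pos, s.snp_alt):
                fh.write(f"{s.stock}\t{p}\t{a}\n")
    paths["truth_snps"] = st
    return paths


def simulate_all(config: SimConfig, outdir: str) -> dict[str, object]:
    """Run the full generator: reference FASTA, karyotype file, per-stock
    VCFs, per-stock SAMs (for ``read_stocks``), fixtures and truth."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    reference = make_reference(config.ref_length, config.seed)
    fa = os.path.join(outdir, "reference.fa")
    with open(fa, "w") as fh:
        fh.write(f">{config.chrom}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i: i + 70] + "\n")

    kary = os.path.join(outdir, "karyotype.ini")
    write_karyotype(config.karyotype, kary)

    bmap, truth = derive_panel(reference, config)

    vcf_dir = os.path.join(outdir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    vcf_paths = []
    for i, st in enumerate(truth.stocks):
        p = os.path.join(vcf_dir, f"{st.stock}.vcf")
        emit_stock_vcf(p, st, reference, config, i)
        vcf_paths.append(p)

    sam_dir = os.path.join(outdir, "sam")
    os.makedirs(sam_dir, exist_ok=True)
    sam_paths = []
    for i in config.read_stocks:
        p = os.path.join(sam_dir, f"{truth.stocks[i].stock}.sam")
        write_stock_sam(p, reference, bmap, truth.stocks[i], config, i)
        sam_paths.append(p)

    fixture_paths = emit_fixtures(config, bmap, truth, outdir)
    return {
        "reference": fa,
        "karyotype": kary,
        "vcfs": vcf_paths,
        "sams": sam_paths,
        "map": bmap,
        "truth": truth,
        **fixture_paths,
    }
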