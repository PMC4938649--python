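"""Inversion-breakpoint calling from split and discordant read pairs.

The caller classifies each aligned read pair as concordant, discordant
(mate orientation or insert size violates the library expectation) or
split (soft-clipped read with a supplementary placement), masks events in
repeat regions, scans fixed 1-kb windows for regions supported by more
than ``min_support`` split+discordant events, links breakpoint regions
through mate and split-alignment evidence, and refines each breakpoint
locus to base-pair resolution by soft-clip consensus.

A called junction reports the last retained reference base on the 5' side
(``five_prime``, the consensus of alignment-end clips), the first retained
base on the 3' side (``three_prime``, the consensus of alignment-start
clips) and the deletion/duplication implied by the pair, matching the
breakpoint-table convention of the rearrangement model.

Breakend orientation alphabet: each side of a derived junction points
either forward (``F``: evidence is a right soft clip, or a ``+``-strand
mate) or reverse (``R``: left clip / ``-``-strand mate).  The two-letter
signature in reference-position order separates the two junctions of an
inversion (``FF`` and ``RR``) from deletion-like (``FR``) and
duplication-like (``RF``) joins, so links with different signatures are
distinct junctions even between the same pair of regions.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .errors import InvalidConfigError, ParseError
from .rearrangement import Junction, junction_delta

__all__ = [
    "Placement",
    "ReadPairRecord",
    "Event",
    "LinkObs",
    "ClipObs",
    "CandidateWindow",
    "RegionLink",
    "CalledJunction",
    "classify_pair",
    "collect_pairs",
    "build_events",
    "estimate_insert_bounds",
    "load_bed",
    "mask_filter",
    "window_scan",
    "pair_junctions",
    "refine_breakpoint",
    "call_breakpoints",
    "CallResult",
]


@dataclass(frozen=True)
class Placement:
    """One aligned read placement (1-based, inclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str
    lclip: int
    rclip: int
    mapq: int

    @property
    def breakend_side(self) -> str:
        """'F' if the dominant clip points 3'-ward (right clip), else 'R'."""
        return "F" if self.rclip >= self.lclip else "R"


@dataclass
class ReadPairRecord:
    """Primary placements of a read pair plus split-alignment evidence."""

    qname: str
    library: str = ""
    r1: Placement | None = None
    r2: Placement | None = None
    supp1: bool = False
    supp2: bool = False
    supp1_placements: list = None
    supp2_placements: list = None

    @property
    def both_mapped(self) -> bool:
        return self.r1 is not None and self.r2 is not None

    @property
    def same_chrom(self) -> bool:
        return self.both_mapped and self.r1.chrom == self.r2.chrom

    @property
    def span(self) -> int | None:
        if not self.same_chrom:
            return None
        return max(self.r1.end, self.r2.end) - min(self.r1.start, self.r2.start) + 1


@dataclass(frozen=True)
class Event:
    """One anchored split/discordant observation (one per pair side)."""

    chrom: str
    pos: int            # anchor: leftmost aligned base of the anchoring read
    kind: str           # 'split' | 'discordant'
    qname: str
    library: str
    mate_pos: int       # anchor of the other side (for window linking)


@dataclass(frozen=True)
class LinkObs:
    """Two-sided junction evidence: a discordant pair's two anchors, or a
    split read's primary and supplementary anchors, with the breakend
    orientation signature in reference-position order."""

    chrom: str
    pos1: int
    pos2: int
    sig: str            # 'FF' | 'RR' | 'FR' | 'RF'
    qname: str


@dataclass(frozen=True)
class ClipObs:
    """A soft-clip boundary from a split read.

    ``side == 'right'`` means the alignment ends at ``pos`` and the clip
    extends 3'-ward (a candidate ``five_prime``); ``side == 'left'`` means
    the alignment starts at ``pos`` (a candidate ``three_prime``).
    """

    chrom: str
    pos: int
    side: str
    qname: str


@dataclass(frozen=True)
class CandidateWindow:
    chrom: str
    start: int          # 0-based half-open in interchange
    end: int
    support: int
    n_split: int
    n_discordant: int


@dataclass(frozen=True)
class Region:
    """A merged run of candidate windows (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_split: int
    n_discordant: int


@dataclass(frozen=True)
class RegionLink:
    """Two breakpoint regions joined by one derived junction's evidence."""

    r1: Region
    r2: Region
    sig: str
    n_pairs: int


@dataclass
class CalledJunction:
    chrom: str
    five_prime: int
    three_prime: int
    delta: int | None
    n_split: int
    n_discordant: int
    resolution: str           # 'base-pair' | 'window-level'
    microhomology: int = 0
    ambiguous: bool = False
    alt_coords: tuple[int, int] | None = None

    def as_junction(self) -> Junction:
        return Junction(self.chrom, self.five_prime, self.three_prime, self.delta)


# ------------------------------------------------------------- SAM ingestion


def collect_pairs(sam_path: str, min_clip: int = 20,
                  min_mapq: int = 20) -> tuple[dict[str, ReadPairRecord], list[ClipObs]]:
    """Read a SAM/BAM once, grouping primary placements by read name and
    collecting soft-clip boundaries (>= ``min_clip``) from every placement,
    supplementary alignments included."""
    pairs: dict[str, ReadPairRecord] = {}
    clips: list[ClipObs] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.mapping_quality < min_mapq:
                continue
            ct = rec.cigartuples or []
            lclip = ct[0][1] if ct and ct[0][0] in (4, 5) else 0
            rclip = ct[-1][1] if ct and ct[-1][0] in (4, 5) else 0
            chrom = rec.reference_name
            start = rec.reference_start + 1
            end = rec.reference_end  # 1-based inclusive
            qname = rec.query_name
            pr = pairs.get(qname)
            if pr is None:
                try:
                    lib = rec.get_tag("RG").rsplit(".", 1)[-1]
                except KeyError:
                    lib = ""
                pr = pairs[qname] = ReadPairRecord(qname, lib,
                                                   supp1_placements=[],
                                                   supp2_placements=[])
            if lclip >= min_clip:
                clips.append(ClipObs(chrom, start, "left", qname))
            if rclip >= min_clip:
                clips.append(ClipObs(chrom, end, "right", qname))
            p = Placement(chrom, start, end, "-" if rec.is_reverse else "+",
                          lclip, rclip, rec.mapping_quality)
            if rec.is_supplementary:
                if rec.is_read1:
                    pr.supp1 = True
                    pr.supp1_placements.append(p)
                else:
                    pr.supp2 = True
                    pr.supp2_placements.append(p)
                continue
            has_sa = rec.has_tag("SA")
            if rec.is_read1:
                pr.r1 = p
                pr.supp1 = pr.supp1 or has_sa
            else:
                pr.r2 = p
                pr.supp2 = pr.supp2 or has_sa
    return pairs, clips


# ------------------------------------------------------------ classification


def classify_pair(pair: ReadPairRecord,
                  expected_orientation: str = "fr",
                  insert_bounds: tuple[int, int] = (0, 10**9),
                  min_clip: int = 20) -> str:
    """Classify one pair: 'split' | 'discordant' | 'concordant' | 'unusable'.

    Split (a soft clip >= ``min_clip`` with a supplementary placement on
    the same read) takes precedence over discordant (mate orientation not
    matching ``expected_orientation``, different chromosomes, or inferred
    insert outside ``insert_bounds``).
    """
    if not pair.both_mapped:
        return "unusable"
    r1, r2 = pair.r1, pair.r2
    split1 = pair.supp1 and max(r1.lclip, r1.rclip) >= min_clip
    split2 = pair.supp2 and max(r2.lclip, r2.rclip) >= min_clip
    if split1 or split2:
        return "split"
    if not pair.same_chrom:
        return "discordant"
    left, right = (r1, r2) if r1.start <= r2.start else (r2, r1)
    if expected_orientation == "fr":
        orient_ok = left.strand == "+" and right.strand == "-"
    elif expected_orientation == "rf":
        orient_ok = left.strand == "-" and right.strand == "+"
    else:
        raise InvalidConfigError(f"unknown orientation {expected_orientation!r}")
    if not orient_ok:
        return "discordant"
    lo, hi = insert_bounds
    if not lo <= pair.span <= hi:
        return "discordant"
    return "concordant"


def estimate_insert_bounds(pairs: dict[str, ReadPairRecord],
                           library: str | None = None,
                           n_sd: float = 3.0) -> tuple[int, int]:
    """Empirical mean +/- ``n_sd`` SD of FR same-chromosome pair spans."""
    spans = []
    for pr in pairs.values():
        if library is not None and pr.library != library:
            continue
        if not pr.same_chrom or pr.supp1 or pr.supp2:
            continue
        left, right = (pr.r1, pr.r2) if pr.r1.start <= pr.r2.start else (pr.r2, pr.r1)
        if left.strand == "+" and right.strand == "-":
            spans.append(pr.span)
    if len(spans) < 10:
        return (0, 10**9)
    s = pd.Series(spans, dtype="float64")
    mu, sd = float(s.mean()), float(s.std())
    return (max(0, int(mu - n_sd * sd)), int(math.ceil(mu + n_sd * sd)))


def _pair_sig(r1: Placement, r2: Placement) -> str:
    left, right = (r1, r2) if r1.start <= r2.start else (r2, r1)
    return ("F" if left.strand == "+" else "R") + \
           ("F" if right.strand == "+" else "R")


def build_events(pairs: dict[str, ReadPairRecord],
                 insert_bounds_by_lib: dict[str, tuple[int, int]],
                 expected_orientation: str = "fr",
                 min_clip: int = 20) -> tuple[list[Event], list[LinkObs], Counter]:
    """Classify every pair; split/discordant pairs contribute one anchored
    event per side (anchor = leftmost aligned base of each read) plus the
    two-sided link observations used to pair breakpoint regions."""
    events: list[Event] = []
    links: list[LinkObs] = []
    stats: Counter = Counter()
    default_bounds = insert_bounds_by_lib.get("", (0, 10**9))
    for pr in pairs.values():
        bounds = insert_bounds_by_lib.get(pr.library, default_bounds)
        cls = classify_pair(pr, expected_orientation, bounds, min_clip)
        stats[cls] += 1
        if cls not in ("split", "discordant"):
            continue
        for this, other in ((pr.r1, pr.r2), (pr.r2, pr.r1)):
            events.append(Event(this.chrom, this.start, cls, pr.qname,
                                pr.library, other.start))
        if cls == "split":
            # supplementary placements are split records in their own right
            # and anchor the far side of the junction they cross
            for prim, supps in ((pr.r1, pr.supp1_placements),
                                (pr.r2, pr.supp2_placements)):
                for sp in supps or []:
                    events.append(Event(sp.chrom, sp.start, cls, pr.qname,
                                        pr.library,
                                        prim.start if prim else sp.start))
        if cls == "discordant" and pr.same_chrom:
            links.append(LinkObs(pr.r1.chrom, min(pr.r1.start, pr.r2.start),
                                 max(pr.r1.start, pr.r2.start),
                                 _pair_sig(pr.r1, pr.r2), pr.qname))
        elif cls == "split":
            for prim, supps in ((pr.r1, pr.supp1_placements),
                                (pr.r2, pr.supp2_placements)):
                if prim is None:
                    continue
                for sp in supps or []:
                    if sp.chrom != prim.chrom:
                        continue
                    a, b = sorted([prim, sp], key=lambda p: p.start)
                    links.append(LinkObs(prim.chrom, a.start, b.start,
                                         a.breakend_side + b.breakend_side,
                                         pr.qname))
    return events, links, stats


# ----------------------------------------------------------------- BED/masks


def load_bed(path: str) -> dict[str, IntervalTree]:
    """Load a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line has fewer than 3 fields",
                                 filename=path, lineno=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer BED coordinates: {exc}",
                                 filename=path, lineno=lineno) from exc
            if end > start:
                trees[parts[0]].addi(start, end)
    return dict(trees)


def _in_mask(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    t = trees.get(chrom)
    return bool(t is not None and t.overlaps(pos - 1))  # 1-based point


def mask_filter(events: list, mask: dict[str, IntervalTree]) -> list:
    """Drop events (or clip observations) anchored inside a masked interval."""
    if not mask:
        return list(events)
    return [e for e in events if not _in_mask(mask, e.chrom, e.pos)]


# -------------------------------------------------------------- window logic


def window_scan(events: list[Event], window_size: int = 1000,
                min_support: int = 10) -> list[CandidateWindow]:
    """Tile fixed windows from position 1 and keep those whose
    split+discordant event count is strictly greater than ``min_support``."""
    counts: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0])
    for e in events:
        w = (e.pos - 1) // window_size
        c = counts[(e.chrom, w)]
        if e.kind == "split":
            c[0] += 1
        else:
            c[1] += 1
    out = []
    for (chrom, w), (ns, nd) in sorted(counts.items()):
        if ns + nd > min_support:
            out.append(CandidateWindow(chrom, w * window_size,
                                       (w + 1) * window_size, ns + nd, ns, nd))
    return out


def merge_windows(windows: list[CandidateWindow],
                  window_size: int = 1000, merge_gap: int = 2) -> list[Region]:
    """Merge candidate windows separated by at most ``merge_gap`` empty
    windows into breakpoint regions (both flanks of one locus usually fall
    in nearby windows, with the deleted bases unpopulated in between)."""
    regions: list[Region] = []
    for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
        if regions and regions[-1].chrom == w.chrom and \
                w.start + 1 - regions[-1].end <= merge_gap * window_size + 1:
            r = regions[-1]
            regions[-1] = Region(r.chrom, r.start, w.end,
                                 r.n_split + w.n_split,
                                 r.n_discordant + w.n_discordant)
        else:
            regions.append(Region(w.chrom, w.start + 1, w.end,
                                  w.n_split, w.n_discordant))
    return regions


def pair_junctions(windows: list[CandidateWindow], link_obs: list[LinkObs],
                   window_size: int = 1000, min_link: int = 3,
                   merge_gap: int = 2) -> tuple[list[RegionLink], list[Region]]:
    """Link breakpoint regions supported by >= ``min_link`` two-sided
    observations with one anchor in each and a common breakend signature;
    one derived junction produces exactly one link.  Returns the links and
    the regions with no link at all (one-sided candidates)."""
    regions = merge_windows(windows, window_size, merge_gap)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, r in enumerate(regions):
        trees[r.chrom].addi(r.start - 1, r.end, i)

    def region_of(chrom: str, pos: int) -> int | None:
        t = trees.get(chrom)
        if t is None:
            return None
        hits = t[pos - 1]
        return min(h.data for h in hits) if hits else None

    link_qnames: dict[tuple[int, int, str], set[str]] = defaultdict(set)
    for lo in link_obs:
        i1 = region_of(lo.chrom, lo.pos1)
        i2 = region_of(lo.chrom, lo.pos2)
        if i1 is None or i2 is None:
            continue
        if i1 > i2:
            i1, i2 = i2, i1
        link_qnames[(i1, i2, lo.sig)].add(lo.qname)

    links = []
    linked_regions: set[int] = set()
    for (i1, i2, sig), qnames in sorted(link_qnames.items()):
        if len(qnames) >= min_link:
            links.append(RegionLink(regions[i1], regions[i2], sig, len(qnames)))
            linked_regions.update((i1, i2))
    one_sided = [r for i, r in enumerate(regions) if i not in linked_regions]
    return links, one_sided


# ---------------------------------------------------------------- refinement


def _clip_consensus(positions: list[int], cluster_gap: int = 10) -> list[tuple[int, int]]:
    """Single-linkage clusters of clip positions; per cluster the modal
    position (ties toward the smaller coordinate) and the cluster support."""
    if not positions:
        return []
    positions = sorted(positions)
    clusters: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - clusters[-1][-1] <= cluster_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    for cl in clusters:
        cnt = Counter(cl)
        top = max(cnt.values())
        pos = min(p for p, c in cnt.items() if c == top)
        out.append((pos, len(cl)))
    return out


def refine_breakpoint(region: Region, clips: list[ClipObs],
                      pad: int = 2500, cluster_gap: int = 10) -> CalledJunction:
    """Refine one breakpoint locus to base-pair resolution.

    The consensus of right-side clips in the region (padded) gives
    ``five_prime`` and of left-side clips ``three_prime``; with no usable
    clips the call stays at window resolution (region midpoint, no delta).
    Two equally supported clip modes on a side yield an ambiguous call
    reporting both positions.
    """
    lo, hi = region.start - pad, region.end + pad
    right = [c.pos for c in clips
             if c.side == "right" and c.chrom == region.chrom and lo <= c.pos <= hi]
    left = [c.pos for c in clips
            if c.side == "left" and c.chrom == region.chrom and lo <= c.pos <= hi]
    rcl = _clip_consensus(right, cluster_gap)
    lcl = _clip_consensus(left, cluster_gap)
    if not rcl or not lcl:
        mid = (region.start + region.end) // 2
        return CalledJunction(region.chrom, mid, mid + 1, None,
                              region.n_split, region.n_discordant, "window-level")
    rcl.sort(key=lambda t: (-t[1], t[0]))
    lcl.sort(key=lambda t: (-t[1], t[0]))
    five, fsup = rcl[0]
    three, tsup = lcl[0]
    ambiguous = (len(rcl) > 1 and rcl[1][1] == fsup) or \
                (len(lcl) > 1 and lcl[1][1] == tsup)
    alt = None
    if ambiguous:
        alt = (rcl[1][0] if len(rcl) > 1 and rcl[1][1] == fsup else five,
               lcl[1][0] if len(lcl) > 1 and lcl[1][1] == tsup else three)
    delta = junction_delta(five, three)
    return CalledJunction(region.chrom, five, three, delta,
                          region.n_split, region.n_discordant, "base-pair",
                          microhomology=max(delta, 0),
                          ambiguous=ambiguous, alt_coords=alt)


@dataclass
class CallResult:
    junctions: list[CalledJunction]
    windows: list[CandidateWindow]
    links: list[RegionLink]
    stats: Counter
    insert_bounds: dict[str, tuple[int, int]]

    def junction_table(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": j.chrom,
                "five_prime": j.five_prime,
                "three_prime": j.three_prime,
                "delta": "" if j.delta is None else j.delta,
                "n_split": j.n_split,
                "n_discordant": j.n_discordant,
                "resolution": j.resolution,
                "microhomology": j.microhomology,
                "ambiguous": j.ambiguous,
            }
            for j in self.junctions
        ]
        return pd.DataFrame(rows, columns=[
            "chrom", "five_prime", "three_prime", "delta", "n_split",
            "n_discordant", "resolution", "microhomology", "ambiguous",
        ])

    def bedpe(self) -> pd.DataFrame:
        rows = [
            {
                "chrom1": l.r1.chrom, "start1": l.r1.start - 1, "end1": l.r1.end,
                "chrom2": l.r2.chrom, "start2": l.r2.start - 1, "end2": l.r2.end,
                "name": f"link{i}.{l.sig}", "score": l.n_pairs,
            }
            for i, l in enumerate(self.links)
        ]
        return pd.DataFrame(rows, columns=[
            "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score",
        ])

    def bnd_vcf(self, path: str, contigs: dict[str, int]) -> None:
        """Write the called junctions as breakend (BND)-style VCF records."""
        header = pysam.VariantHeader()
        for name, length in contigs.items():
            header.add_line(f"##contig=<ID={name},length={length}>")
        header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
        header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate">')
        header.add_line('##INFO=<ID=DELTA,Number=1,Type=Integer,'
                        'Description="Junction deletion(-)/duplication(+) bp">')
        with pysam.VariantFile(path, "w", header=header) as vcf:
            for i, j in enumerate(self.junctions):
                for side, pos, mate in (
                    ("a", j.five_prime, j.three_prime),
                    ("b", j.three_prime, j.five_prime),
                ):
                    rec = vcf.new_record(contig=j.chrom, start=pos - 1,
                                         alleles=("N", f"N]{j.chrom}:{mate}]"))
                    rec.id = f"bnd_{i}{side}"
                    rec.info["SVTYPE"] = "BND"
                    rec.info["MATEID"] = f"bnd_{i}{'b' if side == 'a' else 'a'}"
                    if j.delta is not None:
                        rec.info["DELTA"] = j.delta
                    vcf.write(rec)


def call_breakpoints(
    sam_paths: list[str] | str,
    mask_bed: str | None = None,
    priors_bed: str | None = None,
    window_size: int = 1000,
    min_support: int = 10,
    min_clip: int = 20,
    min_link: int = 3,
    min_mapq: int = 20,
    merge_gap: int = 2,
    expected_orientation: str = "fr",
    insert_bounds: dict[str, tuple[int, int]] | None = None,
) -> CallResult:
    """Full breakpoint-calling pipeline over one or more SAM/BAM files.

    Candidate windows must hold strictly more than ``min_support``
    split/discordant events; with a prior-regions BED only events inside a
    prior region are considered, otherwise the whole chromosome is
    scanned.  Insert bounds default to the per-library empirical mean
    +/- 3 SD of concordant-orientation pair spans.
    """
    if isinstance(sam_paths, str):
        sam_paths = [sam_paths]
    all_pairs: dict[str, ReadPairRecord] = {}
    all_clips: list[ClipObs] = []
    for i, path in enumerate(sam_paths):
        pairs, clips = collect_pairs(path, min_clip=min_clip, min_mapq=min_mapq)
        if i:
            pairs = {f"f{i}:{q}": pr for q, pr in pairs.items()}
        all_pairs.update(pairs)
        all_clips.extend(clips)

    libs = {pr.library for pr in all_pairs.values()}
    bounds = dict(insert_bounds or {})
    for lib in libs:
        if lib not in bounds:
            bounds[lib] = estimate_insert_bounds(all_pairs, lib or None)

    events, link_obs, stats = build_events(all_pairs, bounds,
                                           expected_orientation, min_clip)

    mask = load_bed(mask_bed) if mask_bed else {}
    n_before = len(events)
    events = mask_filter(events, mask)
    clips = mask_filter(all_clips, mask)
    stats["masked_events"] = n_before - len(events)

    if priors_bed:
        priors = load_bed(priors_bed)
        events = [e for e in events if _in_mask(priors, e.chrom, e.pos)]

    windows = window_scan(events, window_size, min_support)
    links, one_sided = pair_junctions(windows, link_obs, window_size,
                                      min_link, merge_gap)

    split_q = {e.qname for e in events if e.kind == "split"}
    split_clips = [c for c in clips if c.qname in split_q]
    regions = {r for l in links for r in (l.r1, l.r2)} | set(one_sided)
    junctions = [
        refine_breakpoint(r, split_clips)
        for r in sorted(regions, key=lambda r: (r.chrom, r.start))
    ]
    return CallResult(junctions, windows, links, stats, bounds)
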