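"""Base-exact model of multiply inverted (balancer) chromosomes.

A balancer chromosome is represented as an ordered list of reference
segments, each carried in forward (``+``) or inverted (``-``) orientation.
Rearrangements are superimposed sequentially, as they were historically
(X-ray induced inversions applied one after another to an already
rearranged chromosome), so event breakpoints are expressed in the *current
derived frame* of the chromosome being modified.

Every junction between retained material is described by a pair of
reference coordinates in the convention used for breakpoint tables:
``five_prime`` is the last retained base on the 5' side of the lesion and
``three_prime`` the first retained base on the 3' side, both 1-based.  The
signed junction delta (bases deleted ``-``, bases duplicated ``+``) is
fully determined by that pair -- see :func:`junction_delta`.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .errors import (
    InvalidCoordinateError,
    InvalidEventError,
    InvalidIntervalError,
    ParseError,
)

__all__ = [
    "junction_delta",
    "span_mb",
    "Junction",
    "Segment",
    "Inversion",
    "ThreeBreakpointRearrangement",
    "BalancerMap",
    "load_karyotype",
    "write_karyotype",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def junction_delta(five_prime: int, three_prime: int) -> int:
    """Signed bp deleted (-) or duplicated (+) at a rearrangement junction.

    ``five_prime`` is the last retained base on the 5' side of the
    junction and ``three_prime`` the first retained base on the 3' side,
    both 1-based coordinates on the same reference sequence.  When the 3'
    coordinate lies downstream, the bases strictly between the two are
    lost (``-(three - five - 1)``); when it lies at or upstream of the 5'
    coordinate, the overlapping bases are retained on both sides of the
    junction (``+(five - three + 1)``).  Adjacent coordinates are a clean
    join (0).

    Equivalently: joining ``ref[:five]`` to ``ref[three-1:]`` changes the
    sequence length by exactly this amount.
    """
    if five_prime < 1 or three_prime < 1:
        raise InvalidCoordinateError(
            f"junction coordinates must be >= 1, got ({five_prime}, {three_prime})"
        )
    if three_prime > five_prime:
        return -(three_prime - five_prime - 1)
    return five_prime - three_prime + 1


def span_mb(left: int, right: int, decimals: int = 1) -> float:
    """Span of ``[left, right]`` in Mb, rounded half-up to ``decimals``.

    This is the coordinate difference ``right - left`` (the convention
    used when a tract or inverted segment is quoted by its two bounding
    coordinates), not an inclusive base count.
    """
    if right < left:
        raise InvalidIntervalError(f"right ({right}) < left ({left})")
    mb = Decimal(right - left) / Decimal(10**6)
    q = Decimal(1).scaleb(-decimals)
    return float(mb.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Junction:
    """A breakpoint locus: 5'/3' retained reference coordinates + delta."""

    chrom: str
    five_prime: int
    three_prime: int
    delta: int | None = None
    event: str = ""

    def __post_init__(self):
        d = junction_delta(self.five_prime, self.three_prime)
        if self.delta is None:
            object.__setattr__(self, "delta", d)
        elif self.delta != d:
            raise InvalidEventError(
                f"delta {self.delta} inconsistent with coordinates "
                f"({self.five_prime}, {self.three_prime}); rule gives {d}"
            )


@dataclass(frozen=True)
class Segment:
    """A reference interval (1-based inclusive) carried with an orientation."""

    start: int
    end: int
    orient: str  # '+' or '-'

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise InvalidIntervalError(f"bad segment [{self.start}, {self.end}]")
        if self.orient not in "+-":
            raise InvalidEventError(f"orientation must be '+' or '-', got {self.orient!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


Locus = tuple[int, int]  # (five_prime, three_prime) in the current derived frame


def _check_locus(locus: Locus, length: int, label: str) -> None:
    f, t = locus
    if not (1 <= f <= length and 1 <= t <= length):
        raise InvalidEventError(f"locus {label} {locus} out of bounds 1..{length}")


@dataclass(frozen=True)
class Inversion:
    """A two-breakpoint inversion specified by its two junction loci.

    The derived chromosome becomes ``D[1..f1] + rc(D[t1..f2]) + D[t2..]``
    where ``(f1, t1)`` and ``(f2, t2)`` are the distal and proximal loci in
    the current frame.  Each locus carries its own deletion/duplication.
    """

    name: str
    locus1: Locus
    locus2: Locus

    @property
    def n_breakpoints(self) -> int:
        return 2

    def loci(self) -> list[Locus]:
        return [self.locus1, self.locus2]

    def validate(self, length: int) -> None:
        _check_locus(self.locus1, length, "1")
        _check_locus(self.locus2, length, "2")
        f1, t1 = self.locus1
        f2, t2 = self.locus2
        if not (f1 < f2 and t1 < t2 and t1 <= f2 and f1 < t2):
            raise InvalidEventError(f"inversion {self.name}: loci unordered {self.loci()}")


@dataclass(frozen=True)
class ThreeBreakpointRearrangement:
    """A three-breakpoint rearrangement (three loci A < B < C).

    Cutting at the three loci leaves four blocks S1..S4; the derived
    order is ``S1 + rc(S3) + rc(S2) + S4``: the interval between the two
    proximal cuts is inverted and the interval between the two distal
    cuts is relocated beyond it, also inverted.  This produces three
    derived junctions and three breakpoint loci, the topology seen when a
    nominally simple inversion turns out to carry an extra internal
    breakpoint (e.g. an inversion whose distal end hides a relocated
    ~165-kb segment).
    """

    name: str
    locus_a: Locus
    locus_b: Locus
    locus_c: Locus

    @property
    def n_breakpoints(self) -> int:
        return 3

    def loci(self) -> list[Locus]:
        return [self.locus_a, self.locus_b, self.locus_c]

    def validate(self, length: int) -> None:
        for lab, loc in zip("ABC", self.loci()):
            _check_locus(loc, length, lab)
        fa, ta = self.locus_a
        fb, tb = self.locus_b
        fc, tc = self.locus_c
        if not (fa < fb < fc and ta < tb < tc and ta <= fb and tb <= fc and fa < tc):
            raise InvalidEventError(
                f"three-breakpoint event {self.name}: loci unordered {self.loci()}"
            )


Rearrangement = Inversion | ThreeBreakpointRearrangement


class BalancerMap:
    """Ordered reference segments describing a rearranged chromosome.

    Supports coordinate liftover between the derived (balancer) frame and
    the reference frame, sequential application of rearrangements, and
    reconstruction of the derived sequence.
    """

    def __init__(self, chrom: str, ref_length: int,
                 segments: list[Segment] | None = None,
                 junctions: list[Junction] | None = None,
                 history: list[str] | None = None):
        if ref_length < 1:
            raise InvalidCoordinateError("reference length must be >= 1")
        self.chrom = chrom
        self.ref_length = ref_length
        self.segments = segments or [Segment(1, ref_length, "+")]
        for seg in self.segments:
            if seg.end > ref_length:
                raise InvalidCoordinateError(
                    f"segment {seg} exceeds reference length {ref_length}"
                )
        self.junctions: list[Junction] = junctions or []
        self.history: list[str] = history or []
        self._offsets = self._cumulative()

    @classmethod
    def identity(cls, chrom: str, ref_length: int) -> "BalancerMap":
        return cls(chrom, ref_length)

    def _cumulative(self) -> list[int]:
        offs = [0]
        for seg in self.segments:
            offs.append(offs[-1] + len(seg))
        return offs

    @property
    def derived_length(self) -> int:
        return self._offsets[-1]

    @property
    def is_identity(self) -> bool:
        return self.segments == [Segment(1, self.ref_length, "+")]

    # ---------------------------------------------------------------- lift

    def lift_to_reference(self, pos: int) -> tuple[int, str]:
        """Reference base and orientation underlying derived position ``pos``."""
        if not 1 <= pos <= self.derived_length:
            raise InvalidCoordinateError(
                f"derived position {pos} outside 1..{self.derived_length}"
            )
        i = bisect_right(self._offsets, pos - 1) - 1
        seg = self.segments[i]
        off = pos - 1 - self._offsets[i]
        if seg.orient == "+":
            return seg.start + off, "+"
        return seg.end - off, "-"

    def lift_to_derived(self, ref_pos: int) -> tuple[int, str]:
        """First derived position carrying reference base ``ref_pos``.

        Bases deleted at a junction are unreachable; bases duplicated at a
        junction occur twice and the leftmost derived copy is returned.
        """
        if not 1 <= ref_pos <= self.ref_length:
            raise InvalidCoordinateError(
                f"reference position {ref_pos} outside 1..{self.ref_length}"
            )
        for i, seg in enumerate(self.segments):
            if seg.start <= ref_pos <= seg.end:
                if seg.orient == "+":
                    return self._offsets[i] + (ref_pos - seg.start) + 1, "+"
                return self._offsets[i] + (seg.end - ref_pos) + 1, "-"
        raise InvalidCoordinateError(
            f"reference base {ref_pos} is deleted on the derived chromosome"
        )

    # ------------------------------------------------------------ intervals

    def _extract(self, lo: int, hi: int) -> list[Segment]:
        """Segments covering derived interval [lo, hi] (inclusive)."""
        if lo > hi:
            return []
        out: list[Segment] = []
        for i, seg in enumerate(self.segments):
            ds, de = self._offsets[i] + 1, self._offsets[i + 1]
            a, b = max(lo, ds), min(hi, de)
            if a > b:
                continue
            o1, o2 = a - ds, b - ds
            if seg.orient == "+":
                out.append(Segment(seg.start + o1, seg.start + o2, "+"))
            else:
                out.append(Segment(seg.end - o2, seg.end - o1, "-"))
        return out

    def pieces(self, lo: int, hi: int) -> list[tuple[int, int, int, int, str]]:
        """Map derived interval [lo, hi] to reference pieces.

        Returns ``(d_start, d_end, ref_start, ref_end, orient)`` tuples in
        derived order; used to place simulated reads on the reference.
        """
        if not (1 <= lo <= hi <= self.derived_length):
            raise InvalidCoordinateError(f"bad derived interval [{lo}, {hi}]")
        out = []
        d = lo
        for seg in self._extract(lo, hi):
            out.append((d, d + len(seg) - 1, seg.start, seg.end, seg.orient))
            d += len(seg)
        return out

    # -------------------------------------------------------------- events

    @staticmethod
    def _reverse_block(block: list[Segment]) -> list[Segment]:
        flip = {"+": "-", "-": "+"}
        return [Segment(s.start, s.end, flip[s.orient]) for s in reversed(block)]

    def _locus_junction(self, five_d: int, three_d: int, event: str) -> Junction:
        """Reference-frame Junction for a cut whose retained derived flanks
        are ``five_d`` (last kept base before the lesion, current frame) and
        ``three_d`` (first kept base after it)."""
        delta = junction_delta(five_d, three_d)
        u, _ = self.lift_to_reference(five_d)
        v, _ = self.lift_to_reference(three_d)
        if delta > 0:
            five, three = max(u, v), min(u, v)
        else:
            five, three = min(u, v), max(u, v)
        return Junction(self.chrom, five, three, delta, event)

    def apply(self, event: Rearrangement) -> "BalancerMap":
        """Superimpose ``event`` (breakpoints in the current derived frame).

        Returns a new map; ``self`` is unchanged.
        """
        event.validate(self.derived_length)
        L = self.derived_length
        if isinstance(event, Inversion):
            (f1, t1), (f2, t2) = event.locus1, event.locus2
            blocks = (
                self._extract(1, f1)
                + self._reverse_block(self._extract(t1, f2))
                + self._extract(t2, L)
            )
            new_j = [
                self._locus_junction(f1, t1, event.name),
                self._locus_junction(f2, t2, event.name),
            ]
        elif isinstance(event, ThreeBreakpointRearrangement):
            (fa, ta), (fb, tb), (fc, tc) = event.loci()
            blocks = (
                self._extract(1, fa)
                + self._reverse_block(self._extract(tb, fc))
                + self._reverse_block(self._extract(ta, fb))
                + self._extract(tc, L)
            )
            new_j = [
                self._locus_junction(fa, ta, event.name),
                self._locus_junction(fb, tb, event.name),
                self._locus_junction(fc, tc, event.name),
            ]
        else:  # pragma: no cover - defensive
            raise InvalidEventError(f"unknown event type {type(event).__name__}")
        return BalancerMap(
            self.chrom,
            self.ref_length,
            blocks,
            self.junctions + new_j,
            self.history + [event.name],
        )

    # ------------------------------------------------------------ sequence

    def derived_sequence(self, ref_seq: str) -> str:
        """Reconstruct the derived chromosome sequence from the reference."""
        if len(ref_seq) < self.ref_length:
            raise InvalidCoordinateError(
                f"reference sequence length {len(ref_seq)} < {self.ref_length}"
            )
        parts = []
        for seg in self.segments:
            s = ref_seq[seg.start - 1: seg.end]
            parts.append(s if seg.orient == "+" else reverse_complement(s))
        return "".join(parts)

    # ------------------------------------------------------------- exports

    def junction_table(self, balancer: str = "synthetic") -> pd.DataFrame:
        """Junction list as a breakpoint-table DataFrame (TSV-ready)."""
        rows = [
            {
                "balancer": balancer,
                "inversion": j.event,
                "chrom": j.chrom,
                "five_prime": j.five_prime,
                "three_prime": j.three_prime,
                "delta": j.delta,
            }
            for j in self.junctions
        ]
        return pd.DataFrame(
            rows,
            columns=["balancer", "inversion", "chrom", "five_prime",
                     "three_prime", "delta"],
        )


def load_karyotype(path: str) -> list[Rearrangement]:
    """Read an ordered karyotype configuration (INI-style sections).

    Each section defines one rearrangement, applied in file order::

        [inversion In(toy)A]
        locus1 = 1000000 1001091
        locus2 = 3500000 3500001

        [three_breakpoint In(toy)B]
        locus_a = 97494 97495
        locus_b = 263127 263132
        locus_c = 1638378 1638377
    """
    import configparser

    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise ParseError("karyotype file not found or empty", filename=str(path))
    events: list[Rearrangement] = []
    for section in cp.sections():
        parts = section.split(None, 1)
        kind = parts[0].lower()
        name = parts[1] if len(parts) > 1 else section

        def locus(key: str) -> Locus:
            try:
                f, t = cp.get(section, key).split()
                return int(f.replace(",", "")), int(t.replace(",", ""))
            except Exception as exc:
                raise ParseError(
                    f"bad locus {key!r} in section [{section}]: {exc}",
                    filename=str(path),
                ) from exc

        if kind == "inversion":
            events.append(Inversion(name, locus("locus1"), locus("locus2")))
        elif kind in ("three_breakpoint", "threebreakpoint"):
            events.append(
                ThreeBreakpointRearrangement(
                    name, locus("locus_a"), locus("locus_b"), locus("locus_c")
                )
            )
        else:
            raise ParseError(
                f"unknown rearrangement type {kind!r} in section [{section}]",
                filename=str(path),
            )
    return events


def write_karyotype(events: list[Rearrangement], path: str) -> None:
    lines = []
    for ev in events:
        if isinstance(ev, Inversion):
            lines.append(f"[inversion {ev.name}]")
            lines.append(f"locus1 = {ev.locus1[0]} {ev.locus1[1]}")
            lines.append(f"locus2 = {ev.locus2[0]} {ev.locus2[1]}")
        else:
            lines.append(f"[three_breakpoint {ev.name}]")
            lines.append(f"locus_a = {ev.locus_a[0]} {ev.locus_a[1]}")
            lines.append(f"locus_b = {ev.locus_b[0]} {ev.locus_b[1]}")
            lines.append(f"locus_c = {ev.locus_c[0]} {ev.locus_c[1]}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
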