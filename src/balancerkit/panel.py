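"""Crossover detection from a multi-stock balancer SNP panel.

Because no balancer reference sequence exists, crossovers are inferred by
comparison across a panel of stocks carrying the same balancer, each
sequenced as a balancer/reference heterozygote so that every heterozygous
SNP is attributable to the balancer.  A SNP carried by few stocks
("rare": shared by at most ``max_share`` stocks, 5 by default for an
18-stock panel) marks material acquired by recombination in one lineage;
contiguous runs of rare SNPs are crossover tracts.  Tracts distal to the
distal-most inversion breakpoint (or reaching a chromosome end) are
single-crossover (SCO) products; tracts strictly between two breakpoints
inside an inverted segment are double crossovers (DCO).

The panel is assembled from per-stock VCFs after the standard filters:
indels dropped, records with QUAL below ``qual_min`` (default 200)
removed, heterozygous SNVs kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import InvalidConfigError

__all__ = [
    "PanelMatrix",
    "WindowMatrix",
    "Tract",
    "load_panel",
    "share_counts",
    "rare_snp_windows",
    "call_tracts",
    "shared_tracts",
]


@dataclass
class PanelMatrix:
    """SNP-by-stock boolean presence matrix.

    ``presence`` is indexed by (chrom, pos, alt) -- the identity of a
    polymorphism; two different alt alleles at one site are two rows.
    """

    presence: pd.DataFrame          # bool, index (chrom, pos, alt), cols stocks
    ref_alleles: pd.Series          # ref allele per SNP row
    qual_min: float
    n_dropped_qual: int = 0
    n_dropped_indel: int = 0

    @property
    def stocks(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_stocks(self) -> int:
        return self.presence.shape[1]

    def __len__(self) -> int:
        return self.presence.shape[0]


@dataclass
class WindowMatrix:
    """Rare-SNP counts per fixed window per stock (heatmap-ready)."""

    counts: pd.DataFrame            # index window start (1-based), cols stocks
    window_size: int
    max_share: int

    def to_tsv(self, path: str) -> None:
        out = self.counts.copy()
        out.insert(0, "window_start", out.index)
        out.insert(1, "window_end", out.index + self.window_size - 1)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class Tract:
    """A contiguous rare-SNP region in one stock."""

    stock: str
    chrom: str
    start: int                      # outermost rare SNPs (1-based)
    end: int
    kind: str                       # 'SCO' | 'DCO' | 'unclassified'
    n_rare_snps: int
    ci_start: tuple[int, int]       # CI to nearest flanking shared-by-all SNP
    ci_end: tuple[int, int]
    dist_start_bp: int | None       # distance to nearest breakpoint
    dist_end_bp: int | None

    @property
    def span_display_mb(self) -> str:
        return f"{self.start / 1e6:.1f}-{self.end / 1e6:.1f} Mb"


def load_panel(vcf_paths: list[str], qual_min: float = 200.0,
               drop_indels: bool = True) -> PanelMatrix:
    """Assemble the presence matrix over the union of passing sites.

    A SNP is present in a stock iff that stock's VCF holds a passing
    heterozygous record at the same position with the same alt allele.
    Records with QUAL below ``qual_min`` are filtered out (a record at
    exactly the cutoff is retained); indel records are not considered.
    """
    if len(vcf_paths) < 2:
        raise InvalidConfigError("panel requires at least 2 stock VCFs")
    presence_sets: dict[str, set] = {}
    refs: dict[tuple, str] = {}
    n_qual = n_indel = 0
    for path in vcf_paths:
        vcf = VCF(str(path))
        sample = vcf.samples[0] if vcf.samples else str(path)
        seen: set = set()
        for var in vcf:
            if drop_indels and (var.is_indel or var.is_sv):
                n_indel += 1
                continue
            if var.QUAL is None or var.QUAL < qual_min:
                n_qual += 1
                continue
            if var.gt_types is not None and len(var.gt_types) and \
                    var.gt_types[0] != 1:  # keep heterozygous calls only
                continue
            for alt in var.ALT:
                if drop_indels and len(alt) != len(var.REF):
                    n_indel += 1
                    continue
                key = (var.CHROM, var.POS, alt)
                seen.add(key)
                refs.setdefault(key, var.REF)
        presence_sets[sample] = seen
        vcf.close()

    all_keys = sorted(set().union(*presence_sets.values()))
    if not all_keys:
        warnings.warn("no passing sites: panel is empty", stacklevel=2)
    index = pd.MultiIndex.from_tuples(all_keys, names=["chrom", "pos", "alt"]) \
        if all_keys else pd.MultiIndex.from_arrays(
            [[], [], []], names=["chrom", "pos", "alt"])
    data = {
        stock: [k in keys for k in all_keys]
        for stock, keys in presence_sets.items()
    }
    presence = pd.DataFrame(data, index=index, dtype=bool)
    ref_alleles = pd.Series([refs[k] for k in all_keys], index=index, dtype=object)
    return PanelMatrix(presence, ref_alleles, qual_min, n_qual, n_indel)


def share_counts(panel: PanelMatrix) -> pd.Series:
    """Per-SNP sharing count k (row sums); k = 1 is a unique polymorphism,
    k = n_stocks is shared-by-all."""
    if len(panel) == 0:
        return pd.Series(dtype=int)
    return panel.presence.sum(axis=1).astype(int)


def sharing_label(k: int, n_stocks: int) -> str:
    if k == 1:
        return "unique"
    if k == n_stocks:
        return "shared-by-all"
    return f"shared-by-{k}"


def rare_snp_windows(panel: PanelMatrix, max_share: int = 5,
                     window: int = 10_000,
                     chrom_length: int | None = None) -> WindowMatrix:
    """Count rare SNPs (k <= ``max_share``) per fixed window per stock.

    Windows tile from position 1.  For a 3-stock panel the alternative
    "any SNP not shared by all" rule is ``max_share = n_stocks - 1``.
    """
    if len(panel) == 0:
        return WindowMatrix(pd.DataFrame(columns=panel.stocks), window, max_share)
    k = share_counts(panel)
    rare = panel.presence[k <= max_share]
    pos = rare.index.get_level_values("pos").to_numpy()
    widx = (pos - 1) // window
    counts = rare.groupby(widx * window + 1).sum()
    last = chrom_length if chrom_length is not None else \
        int(panel.presence.index.get_level_values("pos").max())
    full = np.arange(0, (last - 1) // window + 1) * window + 1
    counts = counts.reindex(full, fill_value=0).astype(int)
    counts.index.name = "window_start"
    return WindowMatrix(counts, window, max_share)


def _runs_with_gaps(flags: np.ndarray, max_gap: int) -> list[tuple[int, int, int]]:
    """Maximal runs of True allowing gaps of at most ``max_gap`` False
    entries; returns (first_idx, last_idx, n_true)."""
    idx = np.nonzero(flags)[0]
    if len(idx) == 0:
        return []
    runs = []
    s = p = idx[0]
    n = 1
    for i in idx[1:]:
        if i - p - 1 <= max_gap:
            p = i
            n += 1
        else:
            runs.append((s, p, n))
            s = p = i
            n = 1
    runs.append((s, p, n))
    return runs


def _nearest(sorted_pos: np.ndarray, x: int, side: str) -> int | None:
    """Nearest element strictly below ('lo') or above ('hi') x."""
    if len(sorted_pos) == 0:
        return None
    if side == "lo":
        i = np.searchsorted(sorted_pos, x, side="left") - 1
        return int(sorted_pos[i]) if i >= 0 else None
    i = np.searchsorted(sorted_pos, x, side="right")
    return int(sorted_pos[i]) if i < len(sorted_pos) else None


def call_tracts(wm: WindowMatrix, panel: PanelMatrix,
                breakpoints: list[int] | None,
                min_windows: int = 2, max_gap: int = 0,
                min_snps: int = 10,
                chrom_length: int | None = None) -> list[Tract]:
    """Call crossover tracts per stock from the rare-SNP window matrix.

    A tract is a maximal run of windows with at least one rare SNP,
    allowing gaps of at most ``max_gap`` windows, containing at least
    ``min_windows`` populated windows and at least ``min_snps`` rare SNPs
    in total.  A genuine crossover tract carries the donor haplotype's
    full SNP complement (dozens of SNPs per window at typical densities),
    whereas rare SNPs arising from filter dropout in related stocks are
    sparse and isolated -- hence the density requirements and the
    zero-gap default.  Boundaries are refined to the outermost rare SNPs;
    each boundary's confidence interval extends to the nearest flanking
    shared-by-all SNP.  With breakpoints supplied, a tract wholly distal
    to the distal-most breakpoint (or reaching the chromosome end) is an
    SCO product and a tract strictly between two breakpoints is a DCO;
    otherwise tracts are 'unclassified'.
    """
    if len(panel) == 0 or wm.counts.empty:
        return []
    k = share_counts(panel)
    chroms = panel.presence.index.get_level_values("chrom")
    if chroms.nunique() > 1:
        raise InvalidConfigError("call_tracts expects a single-chromosome panel")
    chrom = chroms[0] if len(chroms) else "NA"
    all_pos = panel.presence.index.get_level_values("pos").to_numpy()
    shared_pos = np.unique(all_pos[(k == panel.n_stocks).to_numpy()])
    end_pos = chrom_length if chrom_length is not None else int(all_pos.max())
    bps = sorted(breakpoints) if breakpoints else []

    tracts: list[Tract] = []
    win_starts = wm.counts.index.to_numpy()
    rare_mask = (k <= wm.max_share).to_numpy()
    for stock in panel.stocks:
        counts = wm.counts[stock].to_numpy()
        col = panel.presence[stock].to_numpy()
        stock_rare_pos = np.unique(all_pos[rare_mask & col])
        for si, ei, ntrue in _runs_with_gaps(counts > 0, max_gap):
            if ntrue < min_windows:
                continue
            wlo = int(win_starts[si])
            whi = int(win_starts[ei]) + wm.window_size - 1
            inside = stock_rare_pos[(stock_rare_pos >= wlo) & (stock_rare_pos <= whi)]
            if len(inside) < max(1, min_snps):
                continue
            start, end = int(inside[0]), int(inside[-1])
            ci_lo = _nearest(shared_pos, start, "lo")
            ci_hi = _nearest(shared_pos, end, "hi")
            ci_start = (ci_lo if ci_lo is not None else 1, start)
            ci_end = (end, ci_hi if ci_hi is not None else end_pos)
            if not bps:
                kind = "unclassified"
                d1 = d2 = None
            else:
                d1 = min(abs(start - b) for b in bps)
                d2 = min(abs(end - b) for b in bps)
                distal = end < min(bps)
                reaches_end = start > max(bps) and ci_end[1] >= end_pos
                between = any(b <= start for b in bps) and any(b >= end for b in bps)
                if distal or reaches_end:
                    kind = "SCO"
                elif between:
                    kind = "DCO"
                else:
                    kind = "unclassified"
            tracts.append(Tract(stock, chrom, start, end, kind, int(len(inside)),
                                ci_start, ci_end, d1, d2))
    return tracts


def tract_table(tracts: list[Tract]) -> pd.DataFrame:
    rows = [
        {
            "stock": t.stock, "chrom": t.chrom, "start": t.start, "end": t.end,
            "kind": t.kind, "n_rare_snps": t.n_rare_snps,
            "ci_start_lo": t.ci_start[0], "ci_start_hi": t.ci_start[1],
            "ci_end_lo": t.ci_end[0], "ci_end_hi": t.ci_end[1],
            "dist_start_bp": t.dist_start_bp, "dist_end_bp": t.dist_end_bp,
            "display": t.span_display_mb,
        }
        for t in tracts
    ]
    return pd.DataFrame(rows, columns=[
        "stock", "chrom", "start", "end", "kind", "n_rare_snps",
        "ci_start_lo", "ci_start_hi", "ci_end_lo", "ci_end_hi",
        "dist_start_bp", "dist_end_bp", "display",
    ])


def shared_tracts(tracts: list[Tract], panel: PanelMatrix,
                  max_share: int = 5,
                  min_overlap_frac: float = 0.8,
                  min_identity: float = 0.9) -> pd.DataFrame:
    """Pairwise tract relatedness: reciprocal overlap and rare-SNP identity.

    For every pair of overlapping tracts from different stocks, reports
    the reciprocal overlap fraction and the Jaccard identity of the two
    stocks' rare SNPs inside the overlap; pairs exceeding both thresholds
    are flagged as likely sharing a common recombinant origin.
    """
    k = share_counts(panel)
    all_pos = panel.presence.index.get_level_values("pos").to_numpy()
    rare_mask = (k <= max_share).to_numpy()
    rows = []
    for i in range(len(tracts)):
        for j in range(i + 1, len(tracts)):
            a, b = tracts[i], tracts[j]
            if a.stock == b.stock or a.chrom != b.chrom:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo > hi:
                continue
            ov = hi - lo + 1
            frac = min(ov / (a.end - a.start + 1), ov / (b.end - b.start + 1))
            in_ov = rare_mask & (all_pos >= lo) & (all_pos <= hi)
            sa = set(map(tuple, panel.presence.index[in_ov & panel.presence[a.stock].to_numpy()]))
            sb = set(map(tuple, panel.presence.index[in_ov & panel.presence[b.stock].to_numpy()]))
            union = sa | sb
            ident = len(sa & sb) / len(union) if union else 0.0
            rows.append({
                "stock1": a.stock, "stock2": b.stock,
                "overlap_start": lo, "overlap_end": hi,
                "reciprocal_overlap": round(frac, 4),
                "identity": round(ident, 4),
                "likely_common_origin": frac >= min_overlap_frac
                and ident >= min_identity,
            })
    return pd.DataFrame(rows, columns=[
        "stock1", "stock2", "overlap_start", "overlap_end",
        "reciprocal_overlap", "identity", "likely_common_origin",
    ])
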