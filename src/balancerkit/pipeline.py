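"""End-to-end pipeline: simulate -> call breakpoints -> call tracts ->
annotate, with a summary report and truth-comparison metrics.

Configuration is a plain-text INI file with one section per stage; all
values have defaults, and command-line flags override the file.  For a
fixed seed and config every output table is byte-identical across runs.
"""

from __future__ import annotations

import configparser
import hashlib
import os
from dataclasses import dataclass, field, fields, replace

import pandas as pd

from . import __version__
from .annotate import annotation_table, intersect_breakpoints, load_gene_models
from .breakpoints import CallResult, CalledJunction, call_breakpoints
from .errors import InvalidConfigError
from .panel import (
    call_tracts,
    load_panel,
    rare_snp_windows,
    shared_tracts,
    tract_table,
)
from .rearrangement import Junction, load_karyotype
from .simulate import SimConfig, simulate_all

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "match_junctions",
    "match_tracts",
]


@dataclass
class PipelineConfig:
    outdir: str = "balancerkit_out"
    seed: int = 1
    stages: tuple[str, ...] = ("simulate", "callbp", "tracts", "annotate", "report")
    # simulate
    sim: SimConfig = field(default_factory=SimConfig)
    # callbp
    bp_window: int = 1000
    bp_min_support: int = 10
    bp_min_clip: int = 20
    bp_min_link: int = 3
    bp_merge_gap: int = 2
    mask_bed: str | None = None
    priors_bed: str | None = None
    # tracts
    qual_min: float = 200.0
    max_share: int = 5
    tract_window: int = 10_000
    min_windows: int = 2
    max_gap: int = 0
    min_snps: int = 10

    @classmethod
    def from_ini(cls, path: str, seed: int | None = None,
                 outdir: str | None = None) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise InvalidConfigError(f"cannot read pipeline config {path!r}")
        cfg = cls()
        if cp.has_section("pipeline"):
            p = cp["pipeline"]
            cfg.outdir = p.get("outdir", cfg.outdir)
            cfg.seed = p.getint("seed", cfg.seed)
            if "stages" in p:
                cfg.stages = tuple(s.strip() for s in p["stages"].split(","))
        if cp.has_section("simulate"):
            s = cp["simulate"]
            kw = {}
            for f in fields(SimConfig):
                if f.name in s:
                    raw = s[f.name]
                    if f.name == "karyotype":
                        kw["karyotype"] = load_karyotype(raw)
                    elif f.type in ("int", int):
                        kw[f.name] = int(raw)
                    elif f.type in ("float", float):
                        kw[f.name] = float(raw)
                    elif f.name == "chrom":
                        kw[f.name] = raw
                    elif f.name == "include_homolog":
                        kw[f.name] = s.getboolean(f.name)
            cfg.sim = replace(cfg.sim, **kw)
            # the default DCO specs and mask are tied to the default
            # karyotype; drop whatever no longer fits an overridden genome
            if "karyotype" in s and "dco_specs" not in s:
                cfg.sim = replace(cfg.sim, dco_specs=[])
            cfg.sim = replace(cfg.sim, mask_intervals=tuple(
                (a, b) for a, b in cfg.sim.mask_intervals
                if b <= cfg.sim.ref_length))
        if cp.has_section("callbp"):
            b = cp["callbp"]
            cfg.bp_window = b.getint("window", cfg.bp_window)
            cfg.bp_min_support = b.getint("min_support", cfg.bp_min_support)
            cfg.bp_min_clip = b.getint("min_clip", cfg.bp_min_clip)
            cfg.bp_min_link = b.getint("min_link", cfg.bp_min_link)
            cfg.bp_merge_gap = b.getint("merge_gap", cfg.bp_merge_gap)
            cfg.mask_bed = b.get("mask_bed", cfg.mask_bed)
            cfg.priors_bed = b.get("priors_bed", cfg.priors_bed)
        if cp.has_section("tracts"):
            t = cp["tracts"]
            cfg.qual_min = t.getfloat("qual_min", cfg.qual_min)
            cfg.max_share = t.getint("max_share", cfg.max_share)
            cfg.tract_window = t.getint("window", cfg.tract_window)
            cfg.min_windows = t.getint("min_windows", cfg.min_windows)
            cfg.max_gap = t.getint("max_gap", cfg.max_gap)
            cfg.min_snps = t.getint("min_snps", cfg.min_snps)
        if seed is not None:
            cfg.seed = seed
        if outdir is not None:
            cfg.outdir = outdir
        cfg.sim = replace(cfg.sim, seed=cfg.seed)
        return cfg

    def param_hash(self) -> str:
        d = {k: v for k, v in vars(self).items() if k != "outdir"}
        return hashlib.md5(repr(sorted(d.items(), key=lambda kv: kv[0]))
                           .encode()).hexdigest()[:12]


def match_junctions(called: list[CalledJunction], truth: list[Junction],
                    tol: int = 1) -> dict:
    """Recall/precision of called junctions vs truth (+/- tol bp on both
    coordinates; delta compared exactly when base-pair resolved)."""
    matched_truth = set()
    matched_called = set()
    for ci, c in enumerate(called):
        for ti, t in enumerate(truth):
            if ti in matched_truth or c.chrom != t.chrom:
                continue
            if abs(c.five_prime - t.five_prime) <= tol and \
                    abs(c.three_prime - t.three_prime) <= tol:
                if c.resolution == "base-pair" and c.delta != t.delta:
                    continue
                matched_truth.add(ti)
                matched_called.add(ci)
                break
    recall = len(matched_truth) / len(truth) if truth else 1.0
    precision = len(matched_called) / len(called) if called else 1.0
    return {"recall": recall, "precision": precision,
            "n_true": len(truth), "n_called": len(called),
            "n_matched": len(matched_truth)}


def match_tracts(called, truth_tracts, min_overlap: float = 0.5) -> dict:
    """Recall/precision of called tracts vs truth (same stock, same type,
    reciprocal overlap >= ``min_overlap``)."""
    matched_truth = set()
    matched_called = set()
    for ci, c in enumerate(called):
        for ti, t in enumerate(truth_tracts):
            if ti in matched_truth or c.stock != t.stock or c.kind != t.kind:
                continue
            lo, hi = max(c.start, t.start), min(c.end, t.end)
            if lo > hi:
                continue
            ov = hi - lo + 1
            if ov / (c.end - c.start + 1) >= min_overlap and \
                    ov / (t.end - t.start + 1) >= min_overlap:
                matched_truth.add(ti)
                matched_called.add(ci)
                break
    recall = len(matched_truth) / len(truth_tracts) if truth_tracts else 1.0
    precision = len(matched_called) / len(called) if called else 1.0
    return {"recall": recall, "precision": precision,
            "n_true": len(truth_tracts), "n_called": len(called),
            "n_matched": len(matched_truth)}


def _write_tsv(df: pd.DataFrame, path: str, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# balancerkit {__version__} params={cfg.param_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in order; returns paths and result objects.

    Stage failures raise; partial outputs written so far are preserved in
    ``cfg.outdir``.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    results: dict = {"outdir": cfg.outdir}
    report_lines = [f"balancerkit {__version__} report",
                    f"parameter hash: {cfg.param_hash()}",
                    f"seed: {cfg.seed}", ""]

    sim_out = None
    if "simulate" in cfg.stages:
        sim_dir = os.path.join(cfg.outdir, "sim")
        sim_out = simulate_all(replace(cfg.sim, seed=cfg.seed), sim_dir)
        results["sim"] = sim_out
        truth = sim_out["truth"]
        report_lines += [
            "[simulate]",
            f"  reference: {cfg.sim.ref_length} bp, {cfg.sim.n_stocks} stocks",
            f"  true junctions: {len(truth.junctions)}",
            f"  true tracts: {len(truth.tracts)}",
            "",
        ]

    call: CallResult | None = None
    if "callbp" in cfg.stages:
        if sim_out is None:
            raise InvalidConfigError("callbp stage requires simulate stage "
                                     "(or use the library API on your own SAMs)")
        mask = cfg.mask_bed or sim_out.get("mask")
        call = call_breakpoints(
            sim_out["sams"], mask_bed=mask, priors_bed=cfg.priors_bed,
            window_size=cfg.bp_window, min_support=cfg.bp_min_support,
            min_clip=cfg.bp_min_clip, min_link=cfg.bp_min_link,
            merge_gap=cfg.bp_merge_gap,
        )
        results["call"] = call
        _write_tsv(call.junction_table(),
                   os.path.join(cfg.outdir, "junctions.tsv"), cfg)
        _write_tsv(call.bedpe(), os.path.join(cfg.outdir, "junctions.bedpe"), cfg)
        report_lines += [
            "[callbp]",
            f"  pairs: {dict(call.stats)}",
            f"  candidate windows: {len(call.windows)}; links: {len(call.links)}",
            f"  called junctions: {len(call.junctions)}",
        ]
        if sim_out is not None:
            m = match_junctions(call.junctions, sim_out["truth"].junctions)
            results["junction_metrics"] = m
            report_lines.append(
                f"  vs truth: recall={m['recall']:.3f} "
                f"precision={m['precision']:.3f} ({m['n_matched']}/{m['n_true']})"
            )
        report_lines.append("")

    tracts = None
    if "tracts" in cfg.stages:
        if sim_out is None:
            raise InvalidConfigError("tracts stage requires simulate stage "
                                     "(or use the library API on your own VCFs)")
        panel = load_panel(sim_out["vcfs"], qual_min=cfg.qual_min)
        # a SNP shared by every stock is never "rare": clamp to n - 1
        # (for a 3-stock panel this is the "not shared by all" rule)
        max_share = min(cfg.max_share, panel.n_stocks - 1)
        wm = rare_snp_windows(panel, max_share, cfg.tract_window,
                              chrom_length=cfg.sim.ref_length)
        bps = sorted({c for j in sim_out["map"].junctions
                      for c in (j.five_prime, j.three_prime)})
        if call is not None and call.junctions:
            bps = sorted({c for j in call.junctions
                          for c in (j.five_prime, j.three_prime)})
        tracts = call_tracts(wm, panel, bps, cfg.min_windows, cfg.max_gap,
                             cfg.min_snps, chrom_length=cfg.sim.ref_length)
        results["panel"] = panel
        results["tracts"] = tracts
        wm.to_tsv(os.path.join(cfg.outdir, "rare_snp_windows.tsv"))
        _write_tsv(tract_table(tracts), os.path.join(cfg.outdir, "tracts.tsv"), cfg)
        rel = shared_tracts(tracts, panel, cfg.max_share)
        _write_tsv(rel, os.path.join(cfg.outdir, "tract_relatedness.tsv"), cfg)
        report_lines += [
            "[tracts]",
            f"  panel: {len(panel)} SNP rows x {panel.n_stocks} stocks "
            f"(QUAL<{cfg.qual_min:g} dropped: {panel.n_dropped_qual}; "
            f"indels dropped: {panel.n_dropped_indel})",
            f"  tracts called: {len(tracts)} "
            f"(SCO: {sum(t.kind == 'SCO' for t in tracts)}, "
            f"DCO: {sum(t.kind == 'DCO' for t in tracts)})",
        ]
        m = match_tracts(tracts, sim_out["truth"].tracts)
        results["tract_metrics"] = m
        report_lines.append(
            f"  vs truth: recall={m['recall']:.3f} "
            f"precision={m['precision']:.3f} ({m['n_matched']}/{m['n_true']})"
        )
        report_lines.append("")

    if "annotate" in cfg.stages and sim_out is not None:
        models = load_gene_models(sim_out["genes"])
        if call is not None and call.junctions:
            bp_list = [(j.chrom, j.five_prime) for j in call.junctions] + \
                      [(j.chrom, j.three_prime) for j in call.junctions]
        else:
            bp_list = [(j.chrom, j.five_prime) for j in sim_out["map"].junctions]
        ann = intersect_breakpoints(sorted(set(bp_list)), models)
        results["annotations"] = ann
        _write_tsv(annotation_table(ann),
                   os.path.join(cfg.outdir, "annotations.tsv"), cfg)
        n_bis = sum(a.status == "bisected" for a in ann)
        report_lines += [
            "[annotate]",
            f"  breakpoints annotated: {len(ann)}; bisecting a gene: {n_bis}",
            "",
        ]

    report = os.path.join(cfg.outdir, "report.txt")
    with open(report, "w") as fh:
        fh.write("\n".join(report_lines) + "\n")
    results["report"] = report
    return results
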