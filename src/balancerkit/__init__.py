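"""balancerkit: balancer-chromosome rearrangement modelling, inversion
breakpoint calling from split/discordant read pairs, and crossover-tract
detection from multi-stock SNP panels."""

__version__ = "0.1.0"

from .rearrangement import (  # noqa: F401
    BalancerMap,
    Inversion,
    Junction,
    ThreeBreakpointRearrangement,
    junction_delta,
    load_karyotype,
    span_mb,
)
from .simulate import SimConfig, make_reference, derive_panel, simulate_all  # noqa: F401
from .breakpoints import call_breakpoints, classify_pair, window_scan  # noqa: F401
from .panel import load_panel, rare_snp_windows, call_tracts, share_counts  # noqa: F401
from .annotate import classify_deletion, intersect_breakpoints, load_gene_models  # noqa: F401
from .pipeline import PipelineConfig, run_pipeline  # noqa: F401


def breakpoint_table():
    """The published third-chromosome balancer breakpoint table bundled
    with the package (balancer, inversion, chrom, 5'/3' breaks, delta)."""
    import importlib.resources as res

    import pandas as pd

    with res.files("balancerkit").joinpath(
        "data/tm_balancer_breakpoints.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
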