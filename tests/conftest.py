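import os

import pytest

from balancerkit.rearrangement import Inversion, ThreeBreakpointRearrangement
from balancerkit.simulate import (
    DcoSpec,
    SimConfig,
    derive_panel,
    emit_stock_vcf,
    make_reference,
    write_stock_sam,
)


def scaled_karyotype():
    """A 1-Mb analogue of the default karyotype: one inversion with a
    1090-bp junction deletion and one three-breakpoint rearrangement with
    a 4-bp deletion and a 7-bp duplication (5 breakpoint loci)."""
    return [
        Inversion("invA", (400_000, 401_091), (900_000, 900_001)),
        ThreeBreakpointRearrangement(
            "tbrB", (520_000, 520_001), (553_000, 553_005), (760_000, 759_994)
        ),
    ]


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """1-Mb balancer stock with aligned PE+MP reads at 30x per haplotype."""
    cfg = SimConfig(
        seed=11, ref_length=1_000_000, karyotype=scaled_karyotype(),
        n_stocks=2, sco_rate=0.0, dco_specs=[], coverage=30.0,
        read_stocks=(0,),
    )
    ref = make_reference(cfg.ref_length, cfg.seed)
    bmap, truth = derive_panel(ref, cfg)
    d = tmp_path_factory.mktemp("small_sim")
    sam = os.path.join(d, "stock00.sam")
    write_stock_sam(sam, ref, bmap, truth.stocks[0], cfg, 0)
    return {"cfg": cfg, "ref": ref, "map": bmap, "truth": truth, "sam": sam}


@pytest.fixture(scope="session")
def panel_sim(tmp_path_factory):
    """18-stock, 2-Mb crossover panel: 11 stocks with distal SCOs and a
    shared-origin DCO pair inside the inverted segment."""
    kary = [Inversion("inv", (800_000, 800_001), (1_800_000, 1_800_001))]
    cfg = SimConfig(
        seed=5, ref_length=2_000_000, karyotype=kary, n_stocks=18,
        sco_stocks=tuple(range(2, 13)),
        dco_specs=[DcoSpec((1_000_000, 1_300_000), stocks=(0, 1))],
        read_stocks=(),
        mask_intervals=((100_000, 102_000),),
    )
    ref = make_reference(cfg.ref_length, cfg.seed)
    bmap, truth = derive_panel(ref, cfg)
    d = tmp_path_factory.mktemp("panel_sim")
    vcfs = []
    for i, st in enumerate(truth.stocks):
        p = os.path.join(d, f"{st.stock}.vcf")
        emit_stock_vcf(p, st, ref, cfg, i)
        vcfs.append(p)
    return {"cfg": cfg, "ref": ref, "map": bmap, "truth": truth, "vcfs": vcfs}
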