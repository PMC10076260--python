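import numpy as np
import pandas as pd
import pytest

from introscan.io_formats import HaplotypePanel
from introscan.synthetic_data import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """The reference synthetic study: f=0.4, m=0.1, g=20, 2 x 5 Mb,
    3000 SNPs, 60 donors + 40 recipients (shared across tests)."""
    return simulate_panel(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_painting(default_panel):
    from introscan.painting import paint_panel
    sp = default_panel
    return paint_panel(sp.recipients, sp.donors, sp.groups, n_em_iter=3)


@pytest.fixture(scope="session")
def default_window_map(default_panel, default_painting):
    from introscan.ancestry_blocks import assign_windows
    chrom_len = {c: default_panel.config.chrom_len_bp
                 for c in default_panel.config.chrom_names}
    return assign_windows(default_painting, chrom_len=chrom_len)


def make_panel(haps, pos=None, chrom=None, sample_ids=None, **kw):
    """Small literal panel helper for unit tests."""
    haps = np.asarray(haps, dtype=np.int8)
    n_sites = haps.shape[1]
    if pos is None:
        pos = np.arange(n_sites) * 100
    if chrom is None:
        chrom = np.array(["Chr01"] * n_sites, dtype=object)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(haps.shape[0] // 2)]
    return HaplotypePanel(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        haplotypes=haps, sample_ids=sample_ids, **kw)
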