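import numpy as np
import pandas as pd
import pytest

from introscan.ancestry_blocks import (UNKNOWN, AncestryWindowMap,
                                       assign_windows, call_genepool,
                                       extract_blocks, mask_introgression)
from introscan.io_formats import ANDEAN, MESOAMERICAN, MISSING
from introscan.painting import PaintingResult

from conftest import make_panel

GROUPS = ["AM_M1", "AM_M2", "AM_A1", "AM_A2", "AM_A3"]


def make_painting(probs, pos, chrom=None, hap_ids=None):
    probs = np.asarray(probs, dtype=float)
    if chrom is None:
        chrom = np.array(["Chr01"] * len(pos), dtype=object)
    if hap_ids is None:
        hap_ids = [(f"s{i // 2}", i % 2)
                   for i in range(probs.shape[0])]
    return PaintingResult(probs=probs, group_names=GROUPS,
                          hap_ids=hap_ids,
                          chrom=np.asarray(chrom, dtype=object),
                          pos=np.asarray(pos, dtype=np.int64))


def window_map_from_labels(label_rows, window_bp=10_000, chrom="Chr01"):
    """Build an AncestryWindowMap directly from literal window labels."""
    labels = np.asarray(label_rows, dtype=object)
    n_hap, W = labels.shape
    windows = pd.DataFrame({
        "chrom": [chrom] * W,
        "start": np.arange(W) * window_bp,
        "end": (np.arange(W) + 1) * window_bp,
    })
    mean_probs = np.zeros((n_hap, W, len(GROUPS)))
    hap_ids = [(f"s{i // 2}", i % 2) for i in range(n_hap)]
    return AncestryWindowMap(windows=windows, labels=labels,
                             mean_probs=mean_probs, group_names=GROUPS,
                             hap_ids=hap_ids, window_bp=window_bp)


def test_window_label_rules():
    # 3 SNPs in one 10-kb window, all p(AM_A1)=1 -> label AM_A1
    e = np.zeros(5)
    pA1 = np.array([0, 0, 1, 0, 0.0])
    uni = np.full(5, 0.2)
    mixed = np.array([0.85, 0.05, 0.05, 0.03, 0.02])
    probs = np.stack([[pA1, pA1, pA1],        # hap 0: pure A1
                      [uni, uni, uni],        # hap 1: uniform
                      [mixed, mixed, mixed]]) # hap 2: mean 0.85 on M1
    painting = make_painting(probs, [1000, 4000, 9000],
                             hap_ids=[("s0", 0), ("s0", 1), ("s1", 0)])
    wmap = assign_windows(painting, chrom_len={"Chr01": 10_000})
    assert wmap.labels[0, 0] == "AM_A1"
    assert wmap.labels[1, 0] == UNKNOWN        # max 0.2 < 0.8
    assert wmap.labels[2, 0] == "AM_M1"        # mean 0.85 >= 0.8


def test_empty_window_is_unknown_and_tiling():
    pA1 = np.array([0, 0, 1, 0, 0.0])
    probs = np.tile(pA1, (2, 2, 1))
    painting = make_painting(probs, [1000, 34000],
                             hap_ids=[("s0", 0), ("s0", 1)])
    wmap = assign_windows(painting, chrom_len={"Chr01": 45_000})
    # ceil(45000/10000) = 5 windows
    assert wmap.n_windows == 5
    assert wmap.windows["end"].iloc[-1] == 45_000
    assert wmap.labels[0, 1] == UNKNOWN   # no SNPs in [10k, 20k)
    assert wmap.labels[0, 3] == "AM_A1"


def test_genepool_call_rules():
    # 100% Andean windows
    wmap = window_map_from_labels([["AM_A1"] * 10, ["AM_A2"] * 10])
    call = call_genepool(wmap, "s0")
    assert call.call == ANDEAN and not call.ambiguous
    assert call.andean_proportion == 1.0

    # 60% Andean and majority chromosome vote -> Andean
    row = ["AM_A1"] * 6 + ["AM_M1"] * 4
    call = call_genepool(window_map_from_labels([row, row]), "s0")
    assert call.call == ANDEAN

    # 50/50 -> ambiguous
    row = ["AM_A1"] * 5 + ["AM_M1"] * 5
    call = call_genepool(window_map_from_labels([row, row]), "s0")
    assert call.ambiguous and call.call is None

    # all-unknown -> unassignable
    with pytest.raises(ValueError, match="unassignable"):
        call_genepool(window_map_from_labels([[UNKNOWN] * 4] * 2), "s0")


def _blocks_for(rows, call_pool=ANDEAN, gap_bp=50_000):
    wmap = window_map_from_labels(rows)
    calls = {"s0": type("C", (), {"call": call_pool})()}
    return extract_blocks(wmap, calls, gap_bp=gap_bp)


def test_block_gap_joining_trace():
    """[M, M, unknown, M] on an Andean haplotype -> one 40-kb block."""
    row = ["AM_M1", "AM_M1", UNKNOWN, "AM_M2"] + ["AM_A1"] * 4
    blocks, medians = _blocks_for([row, ["AM_A1"] * 8])
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.start, b.end) == (0, 40_000)
    assert b.n_windows == 3
    assert b.ancestry == MESOAMERICAN
    assert medians["s0"] == 40_000


def test_single_window_blocks_dropped():
    """[M, A x6, M]: two isolated single-window candidates -> none."""
    row = ["AM_M1"] + ["AM_A1"] * 6 + ["AM_M1"]
    blocks, medians = _blocks_for([row, ["AM_A1"] * 8])
    assert blocks == []
    assert np.isnan(medians["s0"])


def test_no_introgression_no_blocks():
    blocks, medians = _blocks_for([["AM_A1"] * 8, ["AM_A3"] * 8])
    assert blocks == []
    assert np.isnan(medians["s0"])


def test_gap_exceeding_limit_not_joined():
    # runs of 2 M-windows separated by 6 unknown windows (60 kb > 50 kb)
    row = (["AM_M1"] * 2 + [UNKNOWN] * 6 + ["AM_M1"] * 2
           + ["AM_A1"] * 2)
    blocks, _ = _blocks_for([row, ["AM_A1"] * 12])
    assert len(blocks) == 2
    assert [(b.start, b.end) for b in blocks] == [(0, 20_000),
                                                  (80_000, 100_000)]


def test_block_recovery_against_truth(default_panel, default_window_map):
    """Inferred block-length median within 25% of the truth-tract
    median after the same >= 2-window filter."""
    from introscan.ancestry_blocks import call_all_genepools
    sp = default_panel
    wmap = default_window_map
    from introscan.io_formats import genepool_of
    calls = call_all_genepools(wmap)
    blocks, medians = extract_blocks(wmap, calls)
    inferred = np.array([b.length for b in blocks], dtype=float)
    # truth: other-genepool runs >= 2 windows on the haplotypes of
    # unambiguously called accessions (the same material the block
    # extractor sees)
    truth_lengths = []
    for sid, c in calls.items():
        if c.ambiguous:
            continue
        other = MESOAMERICAN if c.call == ANDEAN else ANDEAN
        for h in (0, 1):
            for chrom, segs in sp.truth.tracts[(sid, h)].items():
                run = 0
                for s, e, race in segs:
                    if genepool_of(race) == other:
                        run += e - s
                    else:
                        if run >= 20_000:
                            truth_lengths.append(run)
                        run = 0
                if run >= 20_000:
                    truth_lengths.append(run)
    med_inf = np.median(inferred)
    med_truth = np.median(truth_lengths)
    assert abs(med_inf - med_truth) / med_truth < 0.25


def test_masking_coordinates_and_partition():
    """A 3-window Mesoamerican block masks exactly its SNPs in the
    Andean-masked panel; the two masks + unknown partition alleles."""
    row0 = ["AM_A1", "AM_M1", "AM_M1", "AM_M2", "AM_A1", UNKNOWN]
    row1 = ["AM_A1"] * 6
    wmap = window_map_from_labels([row0, row1])
    pos = np.array([5000, 15000, 25000, 35000, 45000, 55000])
    panel = make_panel(np.ones((2, 6), dtype=np.int8), pos=pos,
                       sample_ids=["s0"])
    and_masked, mes_masked = mask_introgression(panel, wmap)
    assert and_masked.haplotypes[0].tolist() == \
        [1, MISSING, MISSING, MISSING, 1, MISSING]
    assert mes_masked.haplotypes[0].tolist() == \
        [MISSING, 1, 1, 1, MISSING, MISSING]
    assert and_masked.haplotypes[1].tolist() == [1] * 6

    # partition: each (hap, site) allele survives in at most one mask,
    # and unknown windows in neither
    a = and_masked.haplotypes != MISSING
    m = mes_masked.haplotypes != MISSING
    assert not (a & m).any()
    # only hap 0's unknown-window allele is lost from both masks
    assert (a | m).sum() == 12 - 1
    # idempotence
    a2, m2 = mask_introgression(and_masked, wmap)
    np.testing.assert_array_equal(a2.haplotypes, and_masked.haplotypes)


def test_window_tiling_conservation(default_panel, default_window_map):
    cfg = default_panel.config
    expected = cfg.n_chrom * int(np.ceil(cfg.chrom_len_bp / 10_000))
    assert default_window_map.n_windows == expected
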