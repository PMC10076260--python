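"""End-to-end orchestration: synthetic panel -> painting -> windows ->
excess introgression -> hapFLK + FST -> PAIL."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ancestry_blocks import (AncestryWindowMap, assign_windows,
                              call_all_genepools, extract_blocks)
from .introgression_pail import (PailResult, build_excess_regions,
                                 excess_thresholds, scan_excess)
from .io_formats import ANDEAN, MESOAMERICAN, RegionSet, RunConfig
from .painting import PaintingResult, paint_panel
from .selection_scan import (FstResult, ScanResult, build_kinship,
                             fst_outlier_windows, hapflk,
                             make_scan_result, scale_and_extract,
                             windowed_fst)
from .synthetic_data import SyntheticPanel
from .variant_filtering import thin_variants

logger = logging.getLogger("introscan")


@dataclass
class PipelineResult:
    painting: PaintingResult
    window_map: AncestryWindowMap
    genepool_calls: dict
    thresholds: tuple
    excess_regions: RegionSet
    selection_extended: RegionSet
    selection_restricted: RegionSet
    fst: FstResult
    pail: PailResult
    blocks: list
    block_medians: dict


def fourway_groups(sp: SyntheticPanel, calls: dict) -> dict:
    """Continental x genepool population map (AM_A / AM_M / EU_A / EU_M);
    ambiguous recipients are left out."""
    out = {}
    for s, g in sp.groups.labels.items():
        if g.startswith("AM_A"):
            out[s] = "AM_A"
        elif g.startswith("AM_M"):
            out[s] = "AM_M"
    for sid, c in calls.items():
        if c.call == ANDEAN:
            out[sid] = "EU_A"
        elif c.call == MESOAMERICAN:
            out[sid] = "EU_M"
    return out


def run_pail_pipeline(sp: SyntheticPanel, seed: int = 0,
                      config: RunConfig | None = None,
                      n_em_iter: int = 3, n_fits: int = 3,
                      k_pair: tuple = (5, 8),
                      hapflk_max_iter: int = 15,
                      hapflk_tol: float = 1e-3) -> PipelineResult:
    """Run the full adaptive-introgression detection chain.

    The EM budget parameters (painting iterations, number of hapFLK
    fits and their iteration cap) default to desk-scale values; the
    published operating point uses 10 painting EM iterations and 20
    hapFLK fits.
    """
    cfg = config or RunConfig()
    chrom_len = {c: sp.config.chrom_len_bp for c in sp.config.chrom_names}

    painting = paint_panel(sp.recipients, sp.donors, sp.groups,
                           rho=cfg.rho_per_bp, n_em_iter=n_em_iter)
    wmap = assign_windows(painting, window_bp=cfg.window_bp,
                          prob=cfg.prob_threshold, chrom_len=chrom_len)
    calls = call_all_genepools(wmap)
    blocks, medians = extract_blocks(wmap, calls, gap_bp=cfg.gap_bp,
                                     min_windows=cfg.min_block_windows)

    n_and = sum(1 for c in calls.values() if c.call == ANDEAN)
    n_mes = sum(1 for c in calls.values() if c.call == MESOAMERICAN)
    thresholds = excess_thresholds(max(n_and, 1), max(n_mes, 1))
    excess = scan_excess(wmap, sp.recipients, thresholds)
    flagged = excess.per_snp[excess.per_snp["excess_and"]
                             | excess.per_snp["excess_mes"]]
    excess_regions = build_excess_regions(
        flagged, chrom_len=chrom_len, slop=cfg.slop_bp,
        merge=cfg.merge_bp, min_snps=cfg.min_region_snps)

    group4 = fourway_groups(sp, calls)
    pops = ["AM_A", "AM_M", "EU_A", "EU_M"]
    kin = build_kinship(thin_variants(sp.combined, cfg.thin_bp),
                        group4, pops)
    scan_a = make_scan_result(
        hapflk(sp.combined, group4, kin.F, pops, K=k_pair[0],
               n_fits=n_fits, seed=seed * 2 + 1,
               max_iter=hapflk_max_iter, tol=hapflk_tol), "hapflk")
    scan_b = make_scan_result(
        hapflk(sp.combined, group4, kin.F, pops, K=k_pair[1],
               n_fits=n_fits, seed=seed * 2 + 2,
               max_iter=hapflk_max_iter, tol=hapflk_tol), "hapflk")

    group2 = {s: ("EU" if s.startswith("EU_r") else "AM")
              for s in sp.combined.sample_ids}
    fst = windowed_fst(sp.combined, group2, ["AM", "EU"],
                       window_bp=cfg.window_bp, chrom_len=chrom_len)
    extended, restricted = scale_and_extract(
        scan_a, scan_b, fst, p_thr=cfg.p_threshold, fdr=cfg.fdr,
        halfwidth=cfg.selection_region_halfwidth,
        merge_bp=cfg.selection_merge_bp,
        fst_top_quantile=cfg.fst_top_quantile)

    from .introgression_pail import call_pail
    pail = call_pail(excess_regions, extended,
                     fst_outlier_windows(fst, cfg.fst_top_quantile),
                     sp.annotation.genes)
    return PipelineResult(painting=painting, window_map=wmap,
                          genepool_calls=calls, thresholds=thresholds,
                          excess_regions=excess_regions,
                          selection_extended=extended,
                          selection_restricted=restricted, fst=fst,
                          pail=pail, blocks=blocks,
                          block_medians=medians)
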