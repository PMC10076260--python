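"""Excess-introgression scan and PAIL calling.

For every SNP, Fobs is the proportion of recipient haplotypes whose
local ancestry (the label of the containing window) is Andean (resp.
Mesoamerican).  Excess thresholds derive from the recipient genepool
composition: with n_and Andean-assigned and n_mes Mesoamerican-
assigned accessions, the Andean threshold is the Andean haplotype
share expected if, in addition to all Andean haplotypes, half of the
Mesoamerican ones carried Andean ancestry:
F_A = (2 n_and + n_mes) / (2 (n_and + n_mes)), and symmetrically
F_M = (2 n_mes + n_and) / (2 (n_and + n_mes)); thresholds are
reported truncated to three decimals.  Flagged SNPs are expanded by
+/-2.5 kb, merged within 10 kb, and regions with fewer than three
supporting SNPs are dropped.  A putative adaptive introgressed locus
(PAIL) is a region jointly showing excess introgression, a
haplotype-based selection signature and an outlier FST window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry_blocks import AncestryWindowMap
from .io_formats import ANDEAN, MESOAMERICAN, HaplotypePanel, RegionSet

logger = logging.getLogger("introscan")


def truncate3(x: float) -> float:
    """Truncate (not round) to three decimal places."""
    return math.floor(x * 1000) / 1000


def excess_thresholds(n_and: int, n_mes: int) -> tuple[float, float]:
    """Excess-introgression thresholds (F_A, F_M) from accession counts.

    Both are >= 0.5 and satisfy the exchange symmetry
    F_A(a, m) == F_M(m, a).  Degenerate compositions (one count zero)
    give a threshold of 1.0 with a warning.
    """
    if n_and < 0 or n_mes < 0 or (n_and == 0 and n_mes == 0):
        raise ValueError("need at least one assigned accession")
    tot = 2 * (n_and + n_mes)
    f_a = (2 * n_and + n_mes) / tot
    f_m = (2 * n_mes + n_and) / tot
    if n_and == 0 or n_mes == 0:
        logger.warning("degenerate genepool composition "
                       "(n_and=%d, n_mes=%d)", n_and, n_mes)
    return truncate3(f_a), truncate3(f_m)


@dataclass
class ExcessScanResult:
    """Per-SNP ancestry proportions among recipient haplotypes."""

    per_snp: pd.DataFrame   # chrom, pos, fobs_and, fobs_mes, flags
    f_a: float
    f_m: float
    n_haplotypes: int


def scan_excess(wmap: AncestryWindowMap, panel: HaplotypePanel,
                thresholds: tuple[float, float]) -> ExcessScanResult:
    """Flag SNPs with an excess of one ancestry among recipients.

    A SNP's per-haplotype assignment is the genepool of its containing
    window's label; unknown windows are excluded from the numerator
    but all recipient haplotypes count in the denominator.  Flags use
    ``Fobs >= threshold`` for both genepools.
    """
    f_a, f_m = thresholds
    gl = wmap.genepool_labels()          # (n_hap, W)
    win = wmap.windows
    n_hap = gl.shape[0]

    site_window = np.full(panel.n_sites, -1, dtype=int)
    for chrom in dict.fromkeys(win["chrom"]):
        wc = (win["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(wc)
        starts = win["start"].to_numpy()[wc]
        in_c = panel.chrom == chrom
        j = np.searchsorted(starts, panel.pos[in_c], side="right") - 1
        tgt = np.full(int(in_c.sum()), -1, dtype=int)
        tgt[j >= 0] = idx[j[j >= 0]]
        site_window[np.flatnonzero(in_c)] = tgt

    valid = site_window >= 0
    lab = gl[:, site_window]             # (n_hap, L)
    fobs_and = np.where(valid, (lab == ANDEAN).sum(axis=0) / n_hap, np.nan)
    fobs_mes = np.where(valid, (lab == MESOAMERICAN).sum(axis=0) / n_hap,
                        np.nan)
    per_snp = pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.pos,
        "fobs_and": fobs_and, "fobs_mes": fobs_mes,
        "excess_and": fobs_and >= f_a,
        "excess_mes": fobs_mes >= f_m,
    })
    return ExcessScanResult(per_snp=per_snp, f_a=f_a, f_m=f_m,
                            n_haplotypes=n_hap)


def build_excess_regions(flagged: pd.DataFrame,
                         chrom_len: dict | None = None,
                         slop: int = 2_500, merge: int = 10_000,
                         min_snps: int = 3,
                         provenance: str = "excess-introgression"
                         ) -> RegionSet:
    """SNP point coordinates -> supported excess regions.

    Each flagged SNP becomes a +/-``slop`` interval (clipped at
    chromosome ends), intervals within ``merge`` bp are merged, the
    number of supporting SNPs is accumulated, and regions with fewer
    than ``min_snps`` are dropped.  ``flagged`` needs chrom/pos columns.
    """
    if not len(flagged):
        return RegionSet.empty(provenance)
    start = np.maximum(flagged["pos"].to_numpy() - slop, 0)
    end = flagged["pos"].to_numpy() + slop
    if chrom_len:
        lens = flagged["chrom"].map(chrom_len).to_numpy()
        end = np.minimum(end, lens)
    df = pd.DataFrame({"chrom": flagged["chrom"].to_numpy(),
                       "start": start, "end": end, "n_snps": 1})
    merged = RegionSet(df, provenance=provenance).merge(merge)
    keep = merged.df["n_snps"] >= min_snps
    return RegionSet(merged.df[keep].reset_index(drop=True),
                     provenance=provenance)


@dataclass
class PailResult:
    """Region-level evidence intersection and gene assignments."""

    regions: pd.DataFrame    # all excess regions with evidence flags
    pail: RegionSet          # regions with all three lines of evidence
    genes: pd.DataFrame      # gene-level summary
    n_selection_only: int
    n_introgression_only: int
    n_both: int


def call_pail(excess_regions: RegionSet, selection_regions: RegionSet,
              fst_outliers: RegionSet,
              genes: pd.DataFrame | None = None) -> PailResult:
    """Intersect the three evidence tracks and assign genes.

    PAIL regions show (a) excess introgression, (b) a selection
    signature and (c) overlap with an FST-outlier window; selection
    regions here are expected to be pre-filtered by FST outliers, and
    the FST check is re-applied region-wise for safety.
    """
    df = excess_regions.df.copy()
    if not len(df):
        empty = RegionSet.empty("pail")
        return PailResult(regions=df, pail=empty,
                          genes=pd.DataFrame(columns=["gene_id",
                                                      "evidence"]),
                          n_selection_only=len(selection_regions),
                          n_introgression_only=0, n_both=0)
    df["excess_introgression"] = True
    df["hapflk_selection"] = excess_regions.overlaps_any(selection_regions)
    df["fst_outlier"] = excess_regions.overlaps_any(fst_outliers)
    is_pail = df["hapflk_selection"] & df["fst_outlier"]
    pail = RegionSet(df.loc[is_pail, ["chrom", "start", "end"]].copy(),
                     provenance="pail")

    gene_rows = []
    if genes is not None and len(genes):
        gr = RegionSet(genes.rename(columns={})[
            ["chrom", "start", "end"]].assign(gene_id=genes["gene_id"]),
            provenance="genes")
        sel_and_fst = selection_regions.intersect_filter(fst_outliers) \
            if len(selection_regions) else RegionSet.empty("sel")
        in_pail = gr.overlaps_any(pail)
        in_excess = gr.overlaps_any(excess_regions)
        in_sel = gr.overlaps_any(sel_and_fst)
        for i, g in enumerate(gr.df["gene_id"]):
            if not (in_excess[i] or in_sel[i]):
                continue
            if in_pail[i]:
                ev = "pail"
            elif in_excess[i] and in_sel[i]:
                ev = "both"
            elif in_sel[i]:
                ev = "selection_only"
            else:
                ev = "introgression_only"
            gene_rows.append({"gene_id": g, "evidence": ev})
    gene_df = pd.DataFrame(gene_rows, columns=["gene_id", "evidence"])
    n_sel = int((gene_df["evidence"] == "selection_only").sum())
    n_intro = int((gene_df["evidence"] == "introgression_only").sum())
    n_both = int(gene_df["evidence"].isin(("both", "pail")).sum())
    return PailResult(regions=df, pail=pail, genes=gene_df,
                      n_selection_only=n_sel,
                      n_introgression_only=n_intro, n_both=n_both)
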