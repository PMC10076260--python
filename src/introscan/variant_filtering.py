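"""Site- and genotype-level filters producing the analysis-ready callset.

The filter chain reproduces a resequencing QC recipe for inbred panels:
QUAL >= 30, a global depth band of 1/3x to 4x the mean site depth,
masking of genotypes supported by two reads or fewer, a per-genotype
minimum depth of 3, a maximum missingness of 50%, a minimum minor
allele frequency of 0.05, a cap of 1% on the proportion of
heterozygous genotypes (inbred lines), and optional 250-kb thinning
for structure analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, HaplotypePanel

logger = logging.getLogger("introscan")


@dataclass
class FilterSpec:
    """Thresholds for the site/genotype filter chain (QC defaults)."""

    min_qual: float = 30.0
    depth_band: tuple = (1 / 3, 4.0)    # multiples of the mean site depth
    mask_genotype_max_reads: int = 2    # <=2 reads -> genotype missing
    min_dp: int = 3                     # per-genotype minimum depth
    max_missing: float = 0.5            # min fraction of non-missing gts
    min_maf: float = 0.05
    max_het_prop: float = 0.01
    thin_bp: int = 250_000

    def validate(self) -> None:
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        lo, hi = self.depth_band
        if not 0 < lo < hi:
            raise ValueError("depth_band must satisfy 0 < low < high")
        for name, lo_ok in (("max_missing", 0), ("min_maf", 0),
                            ("max_het_prop", 0)):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.thin_bp <= 0:
            raise ValueError("thin_bp must be positive")


def _genotype_stats(panel: HaplotypePanel):
    """Per-site counts: non-missing genotypes, het genotypes, MAF."""
    H = panel.haplotypes
    a1 = H[0::2]
    a2 = H[1::2]
    gt_called = (a1 != MISSING) & (a2 != MISSING)
    het = gt_called & (a1 != a2)
    n_called = gt_called.sum(axis=0)
    n_het = het.sum(axis=0)
    alt = np.where(a1 == MISSING, 0, a1) + np.where(a2 == MISSING, 0, a2)
    alt_count = np.where(gt_called, alt, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt_count / (2 * n_called), np.nan)
    maf = np.minimum(p, 1 - p)
    return n_called, n_het, maf


def apply_site_filters(panel: HaplotypePanel, spec: FilterSpec
                       ) -> tuple[HaplotypePanel, dict]:
    """Apply the fixed filter chain; returns (panel, removal counts).

    Order: QUAL -> depth band -> genotype-depth masking -> missingness
    -> MAF -> heterozygosity.  Depth filters are skipped with a warning
    when the panel carries no depth information.  Genotype masking
    precedes the missingness/MAF computations, so masked genotypes
    count as missing there.
    """
    spec.validate()
    counts: dict = {}
    keep = np.ones(panel.n_sites, dtype=bool)

    # QUAL >= threshold (boundary inclusive)
    if panel.qual is not None and np.isfinite(panel.qual).any():
        bad = ~(panel.qual >= spec.min_qual)
        counts["qual"] = int((bad & keep).sum())
        keep &= ~bad
    else:
        counts["qual"] = 0
        logger.warning("no QUAL scores: QUAL filter skipped")

    # global depth band around the mean site depth
    if panel.site_depth is not None and np.isfinite(panel.site_depth).any():
        mean_dp = np.nanmean(panel.site_depth)
        lo, hi = spec.depth_band
        bad = ~((panel.site_depth >= lo * mean_dp)
                & (panel.site_depth <= hi * mean_dp))
        counts["depth_band"] = int((bad & keep).sum())
        keep &= ~bad
    else:
        counts["depth_band"] = 0
        logger.warning("no site depth: depth-band filter skipped")

    panel = panel.take_sites(np.flatnonzero(keep))

    # genotype-level masking: <= mask_genotype_max_reads, or < min_dp
    n_masked = 0
    if panel.genotype_depth is not None:
        gd = panel.genotype_depth
        low = (gd <= spec.mask_genotype_max_reads) | (gd < spec.min_dp)
        H = panel.haplotypes.copy()
        rows_low = np.repeat(low, 2, axis=0)
        n_masked = int((rows_low & (H != MISSING)).sum())
        H[rows_low] = MISSING
        panel = HaplotypePanel(
            chrom=panel.chrom, pos=panel.pos, ref=panel.ref, alt=panel.alt,
            haplotypes=H, sample_ids=panel.sample_ids, phased=panel.phased,
            qual=panel.qual, site_depth=panel.site_depth,
            genotype_depth=panel.genotype_depth)
    else:
        logger.warning("no genotype depth: genotype masking skipped")
    counts["genotypes_masked"] = n_masked

    n_called, n_het, maf = _genotype_stats(panel)
    keep = np.ones(panel.n_sites, dtype=bool)

    # missingness: keep sites with >= max_missing fraction called
    bad = n_called < spec.max_missing * panel.n_samples
    counts["missingness"] = int((bad & keep).sum())
    keep &= ~bad

    # MAF on non-missing alleles
    bad = ~(maf >= spec.min_maf)
    counts["maf"] = int((bad & keep).sum())
    keep &= ~bad

    # heterozygosity proportion over non-missing genotypes
    with np.errstate(invalid="ignore", divide="ignore"):
        het_prop = np.where(n_called > 0, n_het / n_called, 0.0)
    bad = het_prop > spec.max_het_prop
    counts["het"] = int((bad & keep).sum())
    keep &= ~bad

    out = panel.take_sites(np.flatnonzero(keep))
    for name, n in counts.items():
        logger.info("filter %s: removed/masked %d", name, n)
    return out, counts


def thin_variants(panel: HaplotypePanel, thin_bp: int = 250_000
                  ) -> HaplotypePanel:
    """Greedy per-chromosome thinning: keep the first SNP, then the
    next SNP at least ``thin_bp`` downstream, and so on."""
    keep: list = []
    for chrom in panel.chrom_ids:
        idx = np.flatnonzero(panel.chrom == chrom)
        last = None
        for i in idx:
            if last is None or panel.pos[i] - last >= thin_bp:
                keep.append(i)
                last = panel.pos[i]
    return panel.take_sites(np.array(keep, dtype=int))
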