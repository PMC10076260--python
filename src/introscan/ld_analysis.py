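"""Linkage-disequilibrium decay and private inter-chromosomal LD.

r2 is the squared Pearson correlation between haplotype allele
indicators at two sites (phased haplotypes, not genotype dosage).  The
decay analysis bins r2 by physical distance (MAF >= 0.1, pairs up to
5 Mb apart) and reports the distance at which the interpolated curve
crosses r2 = 0.2.  The inter-chromosomal analysis thins to one SNP
per 10-kb grid cell (MAF >= 0.05), scores all cross-chromosome pairs,
retains pairs with r2 >= 0.8, merges pairs pointing at the same
region pair (both sides within 100 kb), and keeps region pairs at
least 500 kb wide on each side (50 kb in the selection-region
variant).  A region pair is private to a group when no other group
links the same two regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, HaplotypePanel, RegionSet

logger = logging.getLogger("introscan")


@dataclass
class LdDecayCurve:
    group: str
    bins: pd.DataFrame        # dist_lo, dist_hi, mean_r2, n_pairs
    crossing_bp: float        # distance at r2 = 0.2 (nan if not crossed)


def _group_rows(panel: HaplotypePanel, group_of: dict, group: str
                ) -> np.ndarray:
    rows = []
    for i, s in enumerate(panel.sample_ids):
        if group_of.get(s, "").startswith(group):
            rows.extend([2 * i, 2 * i + 1])
    return np.array(rows, dtype=int)


def _maf_mask(H: np.ndarray, maf: float) -> np.ndarray:
    called = H != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, H, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
    m = np.minimum(p, 1 - p)
    return (m >= maf) & (n >= 2)


def _corr_matrix(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between columns of A (and B), haplotypes as
    observations; missing alleles handled by pairwise-complete masking
    only when present."""
    if (A == MISSING).any() or (B is not None and (B == MISSING).any()):
        Am = np.ma.masked_equal(A, MISSING).astype(float)
        if B is None:
            return np.asarray(np.ma.corrcoef(Am, rowvar=False))
        Bm = np.ma.masked_equal(B, MISSING).astype(float)
        full = np.ma.corrcoef(np.ma.hstack([Am, Bm]), rowvar=False)
        return np.asarray(full[:A.shape[1], A.shape[1]:])
    Af = A.astype(float)
    Az = (Af - Af.mean(axis=0)) / np.maximum(Af.std(axis=0), 1e-12)
    if B is None:
        return (Az.T @ Az) / A.shape[0]
    Bf = B.astype(float)
    Bz = (Bf - Bf.mean(axis=0)) / np.maximum(Bf.std(axis=0), 1e-12)
    return (Az.T @ Bz) / A.shape[0]


def ld_decay(panel: HaplotypePanel, group_of: dict, group: str,
             maf: float = 0.1, max_dist: float = 5e6,
             n_bins: int = 50) -> LdDecayCurve:
    """Binned mean r2 against physical distance for one group."""
    rows = _group_rows(panel, group_of, group)
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 haplotypes in group {group}")
    H = panel.haplotypes[rows]
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom in panel.chrom_ids:
        in_c = np.flatnonzero(panel.chrom == chrom)
        ok = _maf_mask(H[:, in_c], maf)
        idx = in_c[ok]
        if len(idx) < 2:
            continue
        pos = panel.pos[idx]
        r = _corr_matrix(H[:, idx])
        r2 = np.asarray(r) ** 2
        iu, ju = np.triu_indices(len(idx), k=1)
        d = pos[ju] - pos[iu]
        keep = (d <= max_dist) & np.isfinite(r2[iu, ju])
        b = np.clip(np.digitize(d[keep], edges) - 1, 0, n_bins - 1)
        np.add.at(sums, b, r2[iu, ju][keep])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    bins = pd.DataFrame({"dist_lo": edges[:-1], "dist_hi": edges[1:],
                         "mean_r2": mean_r2, "n_pairs": counts})
    centers = (edges[:-1] + edges[1:]) / 2
    crossing = float("nan")
    fin = np.isfinite(mean_r2)
    x, y = centers[fin], mean_r2[fin]
    for i in range(len(y) - 1):
        if (y[i] - 0.2) * (y[i + 1] - 0.2) <= 0 and y[i] != y[i + 1]:
            crossing = x[i] + (0.2 - y[i]) * (x[i + 1] - x[i]) \
                / (y[i + 1] - y[i])
            break
    return LdDecayCurve(group=group, bins=bins, crossing_bp=crossing)


# ---------------------------------------------------------------------------
# Inter-chromosomal LD
# ---------------------------------------------------------------------------

def _thin_grid(panel: HaplotypePanel, rows: np.ndarray, thin_bp: int,
               maf: float) -> np.ndarray:
    """First MAF-passing SNP per thin_bp grid cell (deterministic)."""
    H = panel.haplotypes[rows]
    ok = _maf_mask(H, maf)
    keep = []
    for chrom in panel.chrom_ids:
        idx = np.flatnonzero((panel.chrom == chrom) & ok)
        cells: set = set()
        for i in idx:
            cell = panel.pos[i] // thin_bp
            if cell not in cells:
                cells.add(cell)
                keep.append(i)
    return np.array(keep, dtype=int)


def interchrom_ld(panel: HaplotypePanel, group_of: dict, group: str,
                  thin_bp: int = 10_000, maf: float = 0.05,
                  r2_min: float = 0.8, merge_bp: int = 100_000,
                  min_width: int = 500_000,
                  regions: RegionSet | None = None) -> pd.DataFrame:
    """Private inter-chromosomal high-LD region pairs for one group.

    Returns a table with one row per region pair: chrom_a, start_a,
    end_a, chrom_b, start_b, end_b, n_pairs, group.  ``regions``
    restricts the analysis to SNPs inside the given intervals (the
    selection-region variant, typically with ``min_width`` lowered).
    """
    if len(panel.chrom_ids) < 2:
        raise ValueError("at least 2 chromosomes required")
    rows = _group_rows(panel, group_of, group)
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 haplotypes in group {group}")
    keep = _thin_grid(panel, rows, thin_bp, maf)
    if regions is not None:
        inside = np.zeros(panel.n_sites, dtype=bool)
        for c, s, e in regions.intervals():
            inside |= (panel.chrom == c) & (panel.pos >= s) \
                & (panel.pos < e)
        keep = keep[inside[keep]]
    H = panel.haplotypes[rows][:, keep]
    chrom = panel.chrom[keep]
    pos = panel.pos[keep]

    # high-LD SNP pairs across chromosome pairs
    pair_rows = []
    chroms = list(dict.fromkeys(chrom))
    for ia, ca in enumerate(chroms):
        a_idx = np.flatnonzero(chrom == ca)
        for cb in chroms[ia + 1:]:
            b_idx = np.flatnonzero(chrom == cb)
            if not len(a_idx) or not len(b_idx):
                continue
            r = _corr_matrix(H[:, a_idx], H[:, b_idx])
            r2 = np.asarray(r) ** 2
            hit_a, hit_b = np.nonzero(r2 >= r2_min)
            for i, j in zip(hit_a, hit_b):
                pair_rows.append({"chrom_a": ca, "pos_a": pos[a_idx[i]],
                                  "chrom_b": cb, "pos_b": pos[b_idx[j]]})
    pairs = pd.DataFrame(pair_rows,
                         columns=["chrom_a", "pos_a", "chrom_b", "pos_b"])

    # union-find merge of SNP pairs pointing at the same region pair
    out_rows = []
    for (ca, cb), sub in pairs.groupby(["chrom_a", "chrom_b"]):
        pts = sub[["pos_a", "pos_b"]].to_numpy()
        n = len(pts)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (abs(pts[i, 0] - pts[j, 0]) <= merge_bp
                        and abs(pts[i, 1] - pts[j, 1]) <= merge_bp):
                    parent[find(i)] = find(j)
        clusters: dict = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            pa = pts[members, 0]
            pb = pts[members, 1]
            start_a, end_a = int(pa.min()), int(pa.max()) + 1
            start_b, end_b = int(pb.min()), int(pb.max()) + 1
            if end_a - start_a < min_width or end_b - start_b < min_width:
                continue
            out_rows.append({"chrom_a": ca, "start_a": start_a,
                             "end_a": end_a, "chrom_b": cb,
                             "start_b": start_b, "end_b": end_b,
                             "n_pairs": len(members), "group": group})
    return pd.DataFrame(out_rows, columns=[
        "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
        "n_pairs", "group"])


def _sides_overlap(row_a, row_b) -> bool:
    """Do both sides of two region pairs overlap (in either pairing)?"""
    def ov(c1, s1, e1, c2, s2, e2):
        return c1 == c2 and s1 < e2 and s2 < e1

    direct = (ov(row_a.chrom_a, row_a.start_a, row_a.end_a,
                 row_b.chrom_a, row_b.start_a, row_b.end_a)
              and ov(row_a.chrom_b, row_a.start_b, row_a.end_b,
                     row_b.chrom_b, row_b.start_b, row_b.end_b))
    crossed = (ov(row_a.chrom_a, row_a.start_a, row_a.end_a,
                  row_b.chrom_b, row_b.start_b, row_b.end_b)
               and ov(row_a.chrom_b, row_a.start_b, row_a.end_b,
                      row_b.chrom_a, row_b.start_a, row_b.end_a))
    return direct or crossed


def private_pairs(pair_sets: dict) -> dict:
    """Per-group private region pairs.

    A pair is private to group G when no other group has a pair whose
    BOTH sides overlap it; a one-sided overlap leaves it private.
    """
    out = {}
    for g, df in pair_sets.items():
        flags = []
        for row in df.itertuples(index=False):
            shared = False
            for g2, df2 in pair_sets.items():
                if g2 == g:
                    continue
                for row2 in df2.itertuples(index=False):
                    if _sides_overlap(row, row2):
                        shared = True
                        break
                if shared:
                    break
            flags.append(not shared)
        out[g] = df[np.array(flags, dtype=bool)].reset_index(drop=True) \
            if len(df) else df
    return out
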