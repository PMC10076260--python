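"""Selection scans: windowed Weir & Cockerham FST, the FLK statistic
with a Reynolds-distance kinship model, a haplotype-cluster (LD model)
extension of FLK, cross-validated cluster number, chi-square scaling
and selection-region extraction.

FLK tests whether allele frequencies across populations deviate from
the drift expectation encoded in a kinship matrix F built from a
population tree: with p the vector of population frequencies,
p0 = (1' F^-1 p) / (1' F^-1 1) and
T = (p - p0 1)' [p0 (1 - p0) F]^-1 (p - p0 1), chi-square with
(n_pop - 1) degrees of freedom under neutrality.  The haplotype-based
extension fits a fastPHASE-style hidden-Markov cluster model to the
phased panel by EM and replaces allele frequencies by per-population
cluster frequencies, summing the FLK quadratic form over clusters;
the statistic is averaged over independent EM fits.  Raw statistics
are scaled to a chi-square null by robust moment matching (median and
75th percentile), converted to p-values and Benjamini-Hochberg
q-values, and significant SNPs are expanded into merged regions that
are intersected with FST-outlier windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .io_formats import MISSING, HaplotypePanel, RegionSet

logger = logging.getLogger("introscan")


# ---------------------------------------------------------------------------
# Allele frequencies by population
# ---------------------------------------------------------------------------

def population_stats(panel: HaplotypePanel, group_of: dict,
                     populations: list | None = None):
    """Per-site per-population freq, diploid count and het proportion."""
    if populations is None:
        populations = sorted(set(group_of.values()))
    L = panel.n_sites
    P = len(populations)
    freq = np.full((L, P), np.nan)
    n = np.zeros((L, P))
    het = np.zeros((L, P))
    for j, pop in enumerate(populations):
        idx = [i for i, s in enumerate(panel.sample_ids)
               if group_of.get(s) == pop]
        if not idx:
            continue
        a1 = panel.haplotypes[[2 * i for i in idx]]
        a2 = panel.haplotypes[[2 * i + 1 for i in idx]]
        called = (a1 != MISSING) & (a2 != MISSING)
        nj = called.sum(axis=0).astype(float)
        alt = (np.where(called, a1, 0) + np.where(called, a2, 0)).sum(axis=0)
        hj = (called & (a1 != a2)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, j] = np.where(nj > 0, alt / (2 * nj), np.nan)
            het[:, j] = np.where(nj > 0, hj / nj, 0.0)
        n[:, j] = nj
    return np.array(populations, dtype=object), freq, n, het


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def wc_components(freq: np.ndarray, n: np.ndarray, het: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site W&C (1984) variance components a, b, c.

    Sites where any population has fewer than 2 genotypes, or where
    frequencies are undefined, yield NaN components.
    """
    L, r = freq.shape
    ok = np.all(n >= 2, axis=1) & ~np.isnan(freq).any(axis=1)
    a = np.full(L, np.nan)
    b = np.full(L, np.nan)
    c = np.full(L, np.nan)
    if not ok.any():
        return a, b, c
    p = freq[ok]
    ni = n[ok]
    hi = het[ok]
    nbar = ni.mean(axis=1)
    s2n = (ni ** 2).sum(axis=1)
    nc = (r * nbar - s2n / (r * nbar)) / (r - 1)
    pbar = (ni * p).sum(axis=1) / (r * nbar)
    s2 = (ni * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (ni * hi).sum(axis=1) / (r * nbar)
    av = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        / (nbar - 1))
    bv = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar)
    cv = hbar / 2
    a[ok], b[ok], c[ok] = av, bv, cv
    return a, b, c


@dataclass
class FstResult:
    per_snp: pd.DataFrame      # chrom, pos, a, b, c, fst
    windows: pd.DataFrame      # chrom, start, end, fst, n_snps
    mean: float
    iqr: float


def windowed_fst(panel: HaplotypePanel, group_of: dict,
                 populations: list | None = None,
                 window_bp: int = 10_000,
                 chrom_len: dict | None = None) -> FstResult:
    """W&C FST per SNP and as a ratio-of-sums in tiling windows.

    Window estimate = sum(a) / sum(a + b + c) over contributing SNPs;
    negative estimates are retained; windows without polymorphic sites
    are NA.
    """
    pops, freq, n, het = population_stats(panel, group_of, populations)
    if len(pops) < 2:
        raise ValueError("at least 2 populations required")
    a, b, c = wc_components(freq, n, het)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        snp_fst = np.where(np.abs(denom) > 0, a / denom, np.nan)
    per_snp = pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos,
                            "a": a, "b": b, "c": c, "fst": snp_fst})
    rows = []
    for chrom in panel.chrom_ids:
        in_c = panel.chrom == chrom
        if chrom_len and chrom in chrom_len:
            length = chrom_len[chrom]
        else:
            length = int(panel.pos[in_c].max()) + 1
        for s in range(0, length, window_bp):
            e = min(s + window_bp, length)
            m = in_c & (panel.pos >= s) & (panel.pos < e) & ~np.isnan(a)
            num = np.nansum(a[m])
            den = np.nansum(denom[m])
            fst = num / den if m.any() and den != 0 else np.nan
            rows.append({"chrom": chrom, "start": s, "end": e,
                         "fst": fst, "n_snps": int(m.sum())})
    windows = pd.DataFrame(rows)
    w = windows["fst"].dropna()
    return FstResult(per_snp=per_snp, windows=windows,
                     mean=float(w.mean()) if len(w) else float("nan"),
                     iqr=float(w.quantile(0.75) - w.quantile(0.25))
                     if len(w) else float("nan"))


def fst_outlier_windows(fst: FstResult, top_quantile: float = 0.05
                        ) -> RegionSet:
    """Windows in the top tail of the window FST distribution."""
    w = fst.windows.dropna(subset=["fst"])
    if not len(w):
        return RegionSet.empty("fst-outliers")
    cut = w["fst"].quantile(1 - top_quantile)
    top = w[w["fst"] >= cut]
    return RegionSet(top[["chrom", "start", "end"]].copy(),
                     provenance="fst-outliers")


# ---------------------------------------------------------------------------
# Kinship model
# ---------------------------------------------------------------------------

@dataclass
class KinshipModel:
    populations: list
    distances: np.ndarray    # Reynolds D, (P, P)
    F: np.ndarray            # kinship, (P, P)
    newick: str = ""


def reynolds_distance(panel: HaplotypePanel, group_of: dict,
                      populations: list | None = None
                      ) -> tuple[list, np.ndarray]:
    """Pairwise Reynolds genetic distance D = -ln(1 - theta) with
    theta the two-population multi-locus W&C ratio estimator."""
    pops, freq, n, het = population_stats(panel, group_of, populations)
    P = len(pops)
    D = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            a, b, c = wc_components(freq[:, [i, j]], n[:, [i, j]],
                                    het[:, [i, j]])
            theta = np.nansum(a) / np.nansum(a + b + c)
            theta = min(theta, 0.999)
            d = -np.log1p(-theta) if theta > 0 else 0.0
            D[i, j] = D[j, i] = d
    return list(pops), D


def build_kinship(panel_thinned: HaplotypePanel, group_of: dict,
                  populations: list | None = None) -> KinshipModel:
    """Kinship matrix from a midpoint-rooted NJ tree of Reynolds
    distances: F_ij = shared root-to-MRCA branch length."""
    pops, D = reynolds_distance(panel_thinned, group_of, populations)
    P = len(pops)
    if P < 3:
        logger.warning("fewer than 3 populations: star kinship fallback")
        F = np.zeros((P, P))
        for i in range(P):
            F[i, i] = D[i].sum() / max(P - 1, 1) / 2
        return KinshipModel(populations=pops, distances=D, F=F)

    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(np.maximum(D, 0.0), ids=pops)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    tree = tree.root_at_midpoint()
    tips = {t.name: t for t in tree.tips()}
    depth = {p: tips[p].accumulate_to_ancestor(tree) for p in pops}
    F = np.zeros((P, P))
    for i in range(P):
        F[i, i] = depth[pops[i]]
        for j in range(i + 1, P):
            lca = tree.lowest_common_ancestor([pops[i], pops[j]])
            shared = lca.accumulate_to_ancestor(tree) \
                if lca is not tree else 0.0
            F[i, j] = F[j, i] = shared
    return KinshipModel(populations=pops, distances=D, F=F,
                        newick=str(tree))


# ---------------------------------------------------------------------------
# FLK
# ---------------------------------------------------------------------------

def flk(p: np.ndarray, F: np.ndarray) -> tuple[float, float]:
    """FLK statistic and chi-square p-value for one SNP.

    NA (nan, nan) for monomorphic SNPs (estimated ancestral frequency
    0 or 1).
    """
    T = flk_scan(p[None, :], F)[0]
    if np.isnan(T):
        return float("nan"), float("nan")
    return float(T), float(stats.chi2.sf(T, len(p) - 1))


def flk_scan(freqs: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Vectorised FLK over SNPs: freqs is (L, P)."""
    Finv = np.linalg.inv(F)
    one = np.ones(F.shape[0])
    w = Finv @ one
    denom = one @ w
    p0 = (freqs @ w) / denom
    dev = freqs - p0[:, None]
    quad = np.einsum("li,ij,lj->l", dev, Finv, dev)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = quad / (p0 * (1 - p0))
    T[(p0 <= 0) | (p0 >= 1) | np.isnan(p0)] = np.nan
    bad = np.isnan(freqs).any(axis=1)
    T[bad] = np.nan
    return T


# ---------------------------------------------------------------------------
# Haplotype-cluster (LD) model and hapFLK
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """fastPHASE-style haplotype-cluster HMM fitted by EM."""

    theta: np.ndarray        # (L, K) cluster allele frequencies
    alpha: np.ndarray        # (L, K) cluster weights
    jump: np.ndarray         # (L-1,) per-interval jump probability
    loglik: float
    converged: bool
    n_iter: int


def _cluster_em(H: np.ndarray, pos: np.ndarray, K: int,
                rng: np.random.Generator, max_iter: int = 100,
                tol: float = 1e-4,
                return_gamma: bool = False):
    """Fit the K-cluster HMM to haplotypes H (n_hap, L) by EM."""
    n_hap, L = H.shape
    obs = H != MISSING
    x = np.where(obs, H, 0).astype(float)

    theta = np.clip(rng.uniform(0.1, 0.9, size=(L, K)), 1e-3, 1 - 1e-3)
    alpha = np.full((L, K), 1.0 / K)
    jump = np.full(max(L - 1, 0), 0.05)

    prev_ll = -np.inf
    converged = False
    gamma = np.empty((n_hap, L, K))
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: scaled forward-backward over all haplotypes at once
        alphas = np.empty((n_hap, L, K))
        cs = np.empty((n_hap, L))
        e = np.where(obs[:, 0][:, None],
                     np.where(H[:, 0][:, None] == 1, theta[0], 1 - theta[0]),
                     1.0)
        a = alpha[0] * e
        cs[:, 0] = a.sum(axis=1)
        a /= cs[:, 0][:, None]
        alphas[:, 0] = a
        for t in range(1, L):
            rho = jump[t - 1]
            e = np.where(obs[:, t][:, None],
                         np.where(H[:, t][:, None] == 1,
                                  theta[t], 1 - theta[t]), 1.0)
            a = ((1 - rho) * a + rho * alpha[t]) * e
            cs[:, t] = a.sum(axis=1)
            a /= cs[:, t][:, None]
            alphas[:, t] = a
        ll = float(np.log(cs).sum())

        b = np.ones((n_hap, K))
        gamma[:, L - 1] = alphas[:, L - 1]
        jump_to = np.zeros((L - 1, K)) if L > 1 else np.zeros((0, K))
        jump_tot = np.zeros(max(L - 1, 0))
        for t in range(L - 2, -1, -1):
            rho = jump[t]
            e = np.where(obs[:, t + 1][:, None],
                         np.where(H[:, t + 1][:, None] == 1,
                                  theta[t + 1], 1 - theta[t + 1]), 1.0)
            eb = e * b
            # expected jumps into each cluster at interval t
            contrib = rho * alpha[t + 1] * eb / cs[:, t + 1][:, None]
            jump_to[t] = contrib.sum(axis=0)
            jump_tot[t] = contrib.sum()
            s = eb.sum(axis=1)[:, None]
            b = ((1 - rho) * eb + rho * (alpha[t + 1] * eb).sum(
                axis=1)[:, None]) / cs[:, t + 1][:, None]
            g = alphas[:, t] * b
            g /= g.sum(axis=1)[:, None]
            gamma[:, t] = g

        # M-step
        w = gamma * obs[:, :, None]
        num = (w * x[:, :, None]).sum(axis=0)
        den = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(den > 0, num / den, theta)
        theta = np.clip(theta, 1e-3, 1 - 1e-3)
        alpha_new = alpha.copy()
        alpha_new[0] = gamma[:, 0].mean(axis=0)
        if L > 1:
            prior = 1e-3
            alpha_new[1:] = (jump_to + prior) / (
                jump_tot[:, None] + K * prior)
        alpha = np.clip(alpha_new, 1e-6, None)
        alpha /= alpha.sum(axis=1)[:, None]
        if L > 1:
            jump = np.clip(jump_tot / n_hap, 1e-6, 1 - 1e-6)

        if np.isfinite(ll) and abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    model = ClusterModel(theta=theta, alpha=alpha, jump=jump,
                         loglik=prev_ll, converged=converged, n_iter=it)
    if return_gamma:
        return model, gamma
    return model


def hapflk(panel: HaplotypePanel, group_of: dict, F: np.ndarray,
           populations: list, K: int = 5, n_fits: int = 20,
           seed: int = 0, max_iter: int = 100, tol: float = 1e-4,
           p0_min: float = 0.01) -> pd.DataFrame:
    """Per-SNP haplotype-cluster FLK statistic, averaged over
    independent EM fits; computed independently per chromosome.

    For each fit, per-population cluster frequencies (mean posterior
    cluster memberships) replace allele frequencies in the FLK
    quadratic form, summed over the K clusters.  Clusters whose
    estimated ancestral frequency is within ``p0_min`` of 0 or 1 are
    excluded from the sum: their 1/(p0 (1 - p0)) variance weight is
    unstable and would dominate the statistic.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    pop_rows = {}
    for j, pop in enumerate(populations):
        rows = []
        for i, s in enumerate(panel.sample_ids):
            if group_of.get(s) == pop:
                rows.extend([2 * i, 2 * i + 1])
        pop_rows[pop] = np.array(rows)

    Finv = np.linalg.inv(F)
    one = np.ones(F.shape[0])
    w_vec = Finv @ one
    denom = one @ w_vec

    seeds = np.random.SeedSequence(seed).spawn(n_fits)
    stat_sum = np.zeros(panel.n_sites)
    n_used = 0
    for fit_i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        stat = np.zeros(panel.n_sites)
        ok = True
        for chrom in panel.chrom_ids:
            in_c = np.flatnonzero(panel.chrom == chrom)
            H = panel.haplotypes[:, in_c]
            model, gamma = _cluster_em(H, panel.pos[in_c], K, rng,
                                       max_iter=max_iter, tol=tol,
                                       return_gamma=True)
            if not np.isfinite(model.loglik):
                ok = False
                break
            # per-population cluster frequencies (L, P, K)
            pk = np.stack([gamma[pop_rows[p]].mean(axis=0)
                           for p in populations], axis=1)
            p0 = np.einsum("lpk,p->lk", pk, w_vec) / denom
            dev = pk - p0[:, None, :]
            quad = np.einsum("lpk,pq,lqk->lk", dev, Finv, dev)
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = np.where((p0 > p0_min) & (p0 < 1 - p0_min),
                                 quad / (p0 * (1 - p0)), 0.0)
            stat[in_c] = terms.sum(axis=1)
        if ok:
            stat_sum += stat
            n_used += 1
        else:
            logger.warning("hapflk: EM fit %d diverged, excluded", fit_i)
    if n_used == 0:
        raise RuntimeError("all hapFLK EM fits failed")
    return pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos,
                         "hapflk": stat_sum / n_used})


def choose_k(panel: HaplotypePanel,
             k_grid: tuple = (5, 10, 20, 30, 40, 50),
             n_sets: int = 5, mask_frac: float = 0.1,
             seed: int = 0, max_iter: int = 30,
             tol: float = 1e-3) -> tuple[int, pd.DataFrame]:
    """Cross-validated number of haplotype clusters.

    For each K and each of ``n_sets`` replicate copies of the panel
    with ``mask_frac`` of the alleles masked, the cluster model is
    fitted and the masked alleles are imputed from the fitted model;
    Wp is the wrongly-imputed proportion.  Returns (K*, score table)
    where K* minimises the mean Wp.
    """
    if mask_frac <= 0:
        raise ValueError("mask_frac must be positive (nothing to score)")
    root = np.random.SeedSequence(seed)
    set_seeds = root.spawn(n_sets)
    rows = []
    for rep, ss in enumerate(set_seeds):
        rng = np.random.default_rng(ss)
        mask = rng.random(panel.haplotypes.shape) < mask_frac
        mask &= panel.haplotypes != MISSING
        H = panel.haplotypes.copy()
        truth = panel.haplotypes[mask]
        H[mask] = MISSING
        for K in k_grid:
            wrong = 0
            total = 0
            for chrom in panel.chrom_ids:
                in_c = np.flatnonzero(panel.chrom == chrom)
                sub = H[:, in_c]
                m_sub = mask[:, in_c]
                if not m_sub.any():
                    continue
                model, gamma = _cluster_em(
                    sub, panel.pos[in_c], K,
                    np.random.default_rng(ss.spawn(1)[0]),
                    max_iter=max_iter, tol=tol, return_gamma=True)
                p1 = np.einsum("hlk,lk->hl", gamma, model.theta)
                imputed = (p1 > 0.5).astype(np.int8)
                wrong += int((imputed[m_sub]
                              != panel.haplotypes[:, in_c][m_sub]).sum())
                total += int(m_sub.sum())
            rows.append({"replicate": rep, "K": K,
                         "Wp": wrong / total if total else np.nan})
    scores = pd.DataFrame(rows)
    mean_wp = scores.groupby("K")["Wp"].mean()
    k_star = int(mean_wp.idxmin())
    return k_star, scores


# ---------------------------------------------------------------------------
# Scaling and region extraction
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-SNP statistics with scaled p-values and q-values."""

    per_snp: pd.DataFrame    # chrom, pos, stat, p, q
    scale: float
    df: float


def scale_statistic(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Scale a statistic to a chi-square null by robust moment matching.

    Finds (s, d) such that the median and 75th percentile of the
    genome-wide distribution equal those of s * chi2_d, and returns
    upper-tail p-values chi2.sf(x / s, d).
    """
    v = values[np.isfinite(values)]
    med = np.median(v)
    q75 = np.quantile(v, 0.75)
    if med <= 0 or q75 <= med:
        raise ValueError("degenerate statistic distribution")
    target = q75 / med

    def f(d):
        return stats.chi2.ppf(0.75, d) / stats.chi2.ppf(0.5, d) - target

    lo, hi = 1e-2, 1e3
    if f(lo) * f(hi) > 0:   # ratio outside achievable range: clamp
        d = lo if abs(f(lo)) < abs(f(hi)) else hi
    else:
        d = brentq(f, lo, hi)
    s = med / stats.chi2.ppf(0.5, d)
    with np.errstate(invalid="ignore"):
        p = stats.chi2.sf(values / s, d)
    return p, s, d


def make_scan_result(per_snp: pd.DataFrame, stat_col: str) -> ScanResult:
    """Attach scaled p-values and BH q-values to a per-SNP table."""
    vals = per_snp[stat_col].to_numpy(dtype=float)
    p, s, d = scale_statistic(vals)
    q = np.full(len(p), np.nan)
    fin = np.isfinite(p)
    if fin.any():
        q[fin] = multipletests(p[fin], method="fdr_bh")[1]
    out = per_snp[["chrom", "pos"]].copy()
    out["stat"] = vals
    out["p"] = p
    out["q"] = q
    return ScanResult(per_snp=out, scale=s, df=d)


def selection_regions(scan: ScanResult, p_thr: float = 1e-3,
                      fdr: float = 0.05, halfwidth: int = 5_000,
                      merge_bp: int = 5_000) -> RegionSet:
    """Regions centred on significant SNPs, merged within merge_bp."""
    sig = scan.per_snp[(scan.per_snp["p"] < p_thr)
                       & (scan.per_snp["q"] < fdr)]
    if not len(sig):
        return RegionSet.empty("selection")
    df = pd.DataFrame({
        "chrom": sig["chrom"].to_numpy(),
        "start": np.maximum(sig["pos"].to_numpy() - halfwidth, 0),
        "end": sig["pos"].to_numpy() + halfwidth,
        "n_snps": 1,
    })
    return RegionSet(df, provenance="selection").merge(merge_bp)


def scale_and_extract(scan_a: ScanResult, scan_b: ScanResult,
                      fst: FstResult, p_thr: float = 1e-3,
                      fdr: float = 0.05, halfwidth: int = 5_000,
                      merge_bp: int = 5_000,
                      fst_top_quantile: float = 0.05
                      ) -> tuple[RegionSet, RegionSet]:
    """Extended (union) and restricted (both-run) selection region
    sets, filtered to regions containing an FST-outlier window."""
    ra = selection_regions(scan_a, p_thr, fdr, halfwidth, merge_bp)
    rb = selection_regions(scan_b, p_thr, fdr, halfwidth, merge_bp)
    extended = ra.union(rb, gap=merge_bp)
    extended.provenance = "selection-extended"
    if len(extended) and len(ra) and len(rb):
        keep = extended.overlaps_any(ra) & extended.overlaps_any(rb)
        restricted = RegionSet(extended.df[keep].reset_index(drop=True),
                               provenance="selection-restricted")
    else:
        restricted = RegionSet.empty("selection-restricted")
    top = fst_outlier_windows(fst, fst_top_quantile)
    return extended.intersect_filter(top), restricted.intersect_filter(top)
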