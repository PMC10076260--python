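"""Nucleotide diversity, private-allele spectra and genetic load.

Per-site nucleotide diversity uses the unbiased pairwise estimator
pi_site = 2 p (1 - p) n / (n - 1) over the n non-missing alleles at a
site, which equals the fraction of differing pairs among all pairs of
non-missing alleles.  Region-level theta-pi/bp sums per-site values
and divides by the region span; a 100-kb non-overlapping window track
is also emitted.  On ancestry-masked panels, sites are filtered by
PIND, the proportion of non-masked individuals.

Genetic load is summarised per accession as non-reference allele
counts by effect class, with missense/synonymous and
loss-of-function/synonymous ratios, compared between groups by
two-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, AnnotationTable, GroupAssignment, \
    HaplotypePanel

logger = logging.getLogger("introscan")


@dataclass
class DiversityEstimate:
    """theta-pi summaries for one panel/region."""

    per_site: pd.DataFrame     # chrom, pos, pi, n_alleles, pind
    theta_pi_bp: float         # sum(pi) / region span
    region_bp: int
    windows: pd.DataFrame      # chrom, start, end, theta_pi_bp, n_sites
    n_sites_used: int
    n_sites_skipped: int       # n < 2 non-missing alleles


@dataclass
class LoadSummary:
    """Per-accession deleterious-allele burden and group comparisons."""

    per_accession: pd.DataFrame   # counts + ratios per accession
    group_tests: pd.DataFrame     # pairwise rank-sum results


def _site_pi(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pi and non-missing allele count for a hap matrix."""
    called = H != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, H, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
        pi = np.where(n > 1, 2.0 * p * (1.0 - p) * n / (n - 1.0), np.nan)
    return pi, n


def theta_pi(panel: HaplotypePanel,
             region: tuple | None = None,
             min_pind: float = 0.0,
             window_bp: int = 100_000,
             chrom_len: dict | None = None) -> DiversityEstimate:
    """theta-pi per site, per region and in tiling windows.

    ``region`` is (chrom, start, end) 0-based half-open; by default the
    whole panel span is used (per-chromosome spans summed).  Sites with
    fewer than 2 non-missing alleles are skipped; sites with
    PIND < ``min_pind`` are excluded.
    """
    if region is not None:
        c, s, e = region
        if e <= s:
            raise ValueError("region length must be positive")
        mask = (panel.chrom == c) & (panel.pos >= s) & (panel.pos < e)
        sub = panel.take_sites(np.flatnonzero(mask))
        region_bp = e - s
    else:
        sub = panel
        region_bp = 0
        for c in panel.chrom_ids:
            if chrom_len and c in chrom_len:
                region_bp += chrom_len[c]
            else:
                region_bp += int(panel.pos[panel.chrom == c].max()) + 1

    pi, n = _site_pi(sub.haplotypes)
    # PIND: proportion of individuals with at least one non-missing allele
    called = sub.haplotypes != MISSING
    ind_called = called[0::2] | called[1::2]
    pind = ind_called.mean(axis=0) if sub.n_samples else np.zeros(len(pi))

    usable = (n >= 2) & (pind >= min_pind)
    skipped = int((n < 2).sum())
    per_site = pd.DataFrame({
        "chrom": sub.chrom, "pos": sub.pos, "pi": pi,
        "n_alleles": n.astype(int), "pind": pind, "used": usable,
    })
    total = float(np.nansum(pi[usable]))
    tp_bp = total / region_bp if region_bp else float("nan")

    wrows = []
    for c in sub.chrom_ids:
        in_c = (sub.chrom == c) & usable
        if chrom_len and c in chrom_len:
            length = chrom_len[c]
        else:
            length = int(sub.pos[sub.chrom == c].max()) + 1
        for s in range(0, length, window_bp):
            e = min(s + window_bp, length)
            m = in_c & (sub.pos >= s) & (sub.pos < e)
            wrows.append({
                "chrom": c, "start": s, "end": e,
                "theta_pi_bp": float(np.nansum(pi[m])) / (e - s),
                "n_sites": int(m.sum()),
            })
    windows = pd.DataFrame(
        wrows, columns=["chrom", "start", "end", "theta_pi_bp", "n_sites"])
    return DiversityEstimate(per_site=per_site, theta_pi_bp=tp_bp,
                             region_bp=region_bp, windows=windows,
                             n_sites_used=int(usable.sum()),
                             n_sites_skipped=skipped)


def theta_pi_by_class(panel: HaplotypePanel, class_regions: dict,
                      min_pind: float = 0.0) -> pd.DataFrame:
    """Global theta-pi/bp per region class (e.g. callable / coding /
    neutral), each class supplied as a RegionSet of intervals; the
    per-site sum is divided by the class's total span."""
    pi, n = _site_pi(panel.haplotypes)
    called = panel.haplotypes != MISSING
    ind_called = called[0::2] | called[1::2]
    pind = ind_called.mean(axis=0)
    usable = (n >= 2) & (pind >= min_pind)
    rows = []
    for name, regions in class_regions.items():
        inside = np.zeros(panel.n_sites, dtype=bool)
        span = 0
        for c, s, e in regions.intervals():
            inside |= (panel.chrom == c) & (panel.pos >= s) \
                & (panel.pos < e)
            span += e - s
        total = float(np.nansum(pi[inside & usable]))
        rows.append({"class": name, "span_bp": span,
                     "theta_pi_bp": total / span if span else np.nan,
                     "n_sites": int((inside & usable).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------

def private_allele_spectrum(panel: HaplotypePanel, groups: GroupAssignment,
                            annotation: AnnotationTable,
                            group_a: str = "AM", group_b: str = "EU",
                            freq_split: float = 0.05) -> pd.DataFrame:
    """Counts of private variants per group, frequency bin and class.

    A variant is private to a group when it segregates there (freq > 0
    on non-missing alleles) and is absent (freq 0) in the other group.
    Frequency bins split at ``freq_split`` (low: < split, else
    medium-high).  Effect classes collapse to synonymous vs
    nonsynonymous (missense + loss_of_function); 'other' is excluded.
    Returns a tidy table plus a per-gene burden table attribute-free.
    """
    members = {
        group_a: [s for s in panel.sample_ids
                  if groups.labels.get(s, "").startswith(group_a)],
        group_b: [s for s in panel.sample_ids
                  if groups.labels.get(s, "").startswith(group_b)],
    }
    freqs = {}
    for g, mem in members.items():
        rows = np.ravel([[2 * panel.sample_ids.index(s),
                          2 * panel.sample_ids.index(s) + 1] for s in mem])
        H = panel.haplotypes[rows]
        called = H != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, H, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[g] = np.where(n > 0, alt / n, np.nan)

    effect = annotation.effect_of_sites(panel)
    klass = np.where(effect == "synonymous", "synonymous",
                     np.where(np.isin(effect,
                                      ("missense", "loss_of_function")),
                              "nonsynonymous", "other"))
    rows = []
    fa, fb = freqs[group_a], freqs[group_b]
    for g, own, oth in ((group_a, fa, fb), (group_b, fb, fa)):
        private = (own > 0) & (oth == 0)
        for bin_name, sel in (
                ("low", private & (own < freq_split)),
                ("medium_high", private & (own >= freq_split))):
            for k in ("synonymous", "nonsynonymous"):
                rows.append({"group": g, "bin": bin_name, "class": k,
                             "count": int((sel & (klass == k)).sum())})
    return pd.DataFrame(rows)


def nonsyn_syn_ratio_fold(spectrum: pd.DataFrame, group_a: str,
                          group_b: str, bin_name: str = "low") -> float:
    """Fold difference of the nonsynonymous/synonymous ratio between
    two groups in one frequency bin (group_b over group_a)."""
    def ratio(g):
        sub = spectrum[(spectrum["group"] == g)
                       & (spectrum["bin"] == bin_name)]
        ns = int(sub.loc[sub["class"] == "nonsynonymous", "count"].sum())
        s = int(sub.loc[sub["class"] == "synonymous", "count"].sum())
        return ns / s if s else float("nan")
    return ratio(group_b) / ratio(group_a)


# ---------------------------------------------------------------------------
# Genetic load
# ---------------------------------------------------------------------------

def genetic_load(panel: HaplotypePanel, annotation: AnnotationTable,
                 group_of: dict, dosage: bool = True) -> LoadSummary:
    """Per-accession load counts, ratios and pairwise rank-sum tests.

    Counts non-reference alleles per effect class on both haplotypes
    (dosage 0/1/2 by default; presence 0/1 with ``dosage=False``);
    missing genotypes contribute 0.  Ratios are missense/synonymous
    and loss-of-function/synonymous, NA when the synonymous count is 0.
    """
    effect = annotation.effect_of_sites(panel)
    masks = {k: effect == k
             for k in ("synonymous", "missense", "loss_of_function")}
    rows = []
    for i, sid in enumerate(panel.sample_ids):
        h = panel.haplotypes[2 * i:2 * i + 2]
        alt = np.where(h == MISSING, 0, h).sum(axis=0)
        if not dosage:
            alt = (alt > 0).astype(int)
        rec = {"accession": sid, "group": group_of.get(sid, "NA")}
        for k, m in masks.items():
            rec[k] = int(alt[m].sum())
        rec["missense_ratio"] = (rec["missense"] / rec["synonymous"]
                                 if rec["synonymous"] else float("nan"))
        rec["lof_ratio"] = (rec["loss_of_function"] / rec["synonymous"]
                            if rec["synonymous"] else float("nan"))
        rows.append(rec)
    per_acc = pd.DataFrame(rows)

    groups = sorted(set(per_acc["group"]) - {"NA"})
    for g in groups:
        if not len(per_acc[per_acc["group"] == g]):
            raise ValueError(f"empty group {g}")
    tests = []
    for stat in ("missense_ratio", "lof_ratio"):
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                x = per_acc.loc[per_acc["group"] == ga, stat].dropna()
                y = per_acc.loc[per_acc["group"] == gb, stat].dropna()
                if len(x) == 0 or len(y) == 0:
                    continue
                pooled = np.concatenate([x, y])
                no_ties = len(np.unique(pooled)) == len(pooled)
                method = ("exact" if max(len(x), len(y)) <= 20 and no_ties
                          else "asymptotic")
                if np.ptp(pooled) == 0:
                    p = 1.0   # all values identical
                else:
                    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                             method=method)
                    p = float(res.pvalue)
                tests.append({"statistic": stat, "group_a": ga,
                              "group_b": gb, "p_value": p})
    return LoadSummary(per_accession=per_acc,
                       group_tests=pd.DataFrame(
                           tests, columns=["statistic", "group_a",
                                           "group_b", "p_value"]))
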