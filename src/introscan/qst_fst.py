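"""Trait heritability, photoperiod sensitivity, QST and the
QST-vs-reference outlier test.

Broad-sense heritability H2 is estimated by a random-effects
variance decomposition (ANOVA method of moments) with genotype and
environment as random effects: H2 = s2_G / (s2_G + s2_env + s2_res),
components truncated at zero.  QST for a trait is
s2_B / (s2_B + 2 s2_W) (between vs within population additive
variance; an inbred-lineage variant s2_B / (s2_B + s2_W) is available
for selfing lines), with components from a one-way random-effects
decomposition of accession-level genotypic values (replicate means).
The focal-trait QST is located as an empirical percentile within a
reference distribution of QSTs for highly heritable metabolites
(H2 > 0.65) and within the per-SNP FST distribution; a focal QST at
or above the 97.5th percentile of the metabolite-QST distribution is
called a selection candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("introscan")


@dataclass
class QstResult:
    trait: str
    sigma2_between: float
    sigma2_within: float
    qst: float
    convention: str          # "outbred" (2 s2_W) or "inbred" (s2_W)


@dataclass
class OutlierVerdict:
    trait: str
    qst: float
    percentile_metabolites: float
    percentile_fst: float
    selection_candidate: bool
    n_reference: int
    wide_interval: bool      # fewer than 20 reference metabolites


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

def broad_heritability(traits: pd.DataFrame, trait: str | None = None
                       ) -> float:
    """Broad-sense H2 from a replicated trait table.

    ``traits`` columns: accession, environment, replicate, value (and
    optionally trait, filtered by the ``trait`` argument).  Returns
    NaN for designs with a single replicate in a single environment.
    """
    df = traits
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    if "environment" not in df.columns:
        df = df.assign(environment="env1")
    y = df["value"].to_numpy(dtype=float)
    acc = df["accession"].to_numpy()
    env = df["environment"].to_numpy()
    G = len(np.unique(acc))
    E = len(np.unique(env))
    N = len(y)
    if G < 2:
        return float("nan")
    reps_per_cell = N / (G * E)
    if E == 1 and reps_per_cell <= 1:
        return float("nan")

    grand = y.mean()
    acc_means = pd.Series(y).groupby(acc).mean()
    env_means = pd.Series(y).groupby(env).mean()
    ms_g = (N / G) * float(((acc_means - grand) ** 2).sum()) / (G - 1)
    fitted = acc_means[acc].to_numpy()
    if E > 1:
        fitted = fitted + env_means[env].to_numpy() - grand
        df_res = N - G - E + 1
    else:
        df_res = N - G
    ss_res = float(((y - fitted) ** 2).sum())
    ms_res = ss_res / df_res if df_res > 0 else float("nan")
    s2_res = max(ms_res, 0.0)
    s2_g = max((ms_g - ms_res) / (N / G), 0.0)
    if E > 1:
        ms_e = (N / E) * float(((env_means - grand) ** 2).sum()) / (E - 1)
        s2_env = max((ms_e - ms_res) / (N / E), 0.0)
    else:
        s2_env = 0.0
    tot = s2_g + s2_env + s2_res
    return s2_g / tot if tot > 0 else float("nan")


def heritability_table(traits: pd.DataFrame) -> pd.DataFrame:
    """H2 for every trait in a long-format table."""
    rows = [{"trait": t, "h2": broad_heritability(traits, t)}
            for t in dict.fromkeys(traits["trait"])]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Derived traits
# ---------------------------------------------------------------------------

def photoperiod_sensitivity(dtf_longday: float, dtf_shortday: float
                            ) -> tuple[float, str]:
    """PS = DTF(long day) / DTF(short day); flags non-flowering.

    Returns (ps, flag); ps is NaN when either value is missing or the
    short-day DTF is zero; a missing long-day DTF flags delayed or no
    flowering under long days.
    """
    if dtf_longday is None or (isinstance(dtf_longday, float)
                               and np.isnan(dtf_longday)):
        return float("nan"), "delayed_or_no_flowering"
    if not dtf_shortday or (isinstance(dtf_shortday, float)
                            and np.isnan(dtf_shortday)):
        return float("nan"), "missing_shortday"
    if dtf_longday <= 0 or dtf_shortday <= 0:
        raise ValueError("DTF values must be positive")
    return dtf_longday / dtf_shortday, ""


def trait_pc1(matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of a traits matrix (accessions x
    traits): columns standardised, missing values mean-imputed (i.e.
    zero after standardisation, count logged); PC1 oriented to
    correlate positively with the first column.  Returns (scores,
    fraction of variance explained)."""
    if matrix.shape[1] < 2:
        raise ValueError("at least 2 traits required for PCA")
    X = matrix.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_imputed = int(np.isnan(Z).sum())
    if n_imputed:
        logger.info("trait_pc1: mean-imputed %d missing cells", n_imputed)
        Z = np.nan_to_num(Z, nan=0.0)
    U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    scores = U[:, 0] * S[0]
    explained = float(S[0] ** 2 / (S ** 2).sum())
    if np.corrcoef(scores, Z[:, 0])[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=matrix.index, name="PC1"), explained


# ---------------------------------------------------------------------------
# QST
# ---------------------------------------------------------------------------

def qst(traits: pd.DataFrame, group_of: dict, trait: str | None = None,
        inbred: bool = False) -> QstResult:
    """QST from a one-way random-effects decomposition.

    Accession-level genotypic values are replicate means; groups are
    the continental populations.  Negative variance-component
    estimates are truncated at zero (logged).
    """
    df = traits
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    means = df.groupby("accession")["value"].mean()
    groups = pd.Series({a: group_of[a] for a in means.index})
    counts = groups.value_counts()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 groups with >= 3 accessions each")

    y = means.to_numpy()
    g = groups.to_numpy()
    labels = np.unique(g)
    k = len(labels)
    N = len(y)
    grand = y.mean()
    ss_b = ss_w = 0.0
    for lab in labels:
        sub = y[g == lab]
        ss_b += len(sub) * (sub.mean() - grand) ** 2
        ss_w += ((sub - sub.mean()) ** 2).sum()
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (N - k)
    n0 = (N - (counts ** 2).sum() / N) / (k - 1)
    s2_w = ms_w
    s2_b = (ms_b - ms_w) / n0
    if s2_b < 0:
        logger.info("qst: negative between-group component truncated")
        s2_b = 0.0
    denom = s2_b + (s2_w if inbred else 2 * s2_w)
    q = s2_b / denom if denom > 0 else 0.0
    name = trait if trait is not None else "trait"
    return QstResult(trait=name, sigma2_between=s2_b, sigma2_within=s2_w,
                     qst=q, convention="inbred" if inbred else "outbred")


def empirical_percentile(focal: float, reference: np.ndarray) -> float:
    """Percentile of focal in reference (fraction <= focal, x100)."""
    ref = np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    if len(ref) == 0:
        return float("nan")
    return 100.0 * float((ref <= focal).mean())


def qst_outlier_test(focal: QstResult, metabolite_qsts: np.ndarray,
                     fst_values: np.ndarray,
                     candidate_quantile: float = 97.5) -> OutlierVerdict:
    """Locate the focal-trait QST in the reference distributions.

    The metabolite references are expected to be pre-filtered to high
    heritability (H2 > 0.65); a focal QST at or above the candidate
    quantile of the metabolite-QST distribution is flagged a
    selection candidate.
    """
    ref = np.asarray(metabolite_qsts, dtype=float)
    ref = ref[np.isfinite(ref)]
    wide = len(ref) < 20
    if wide:
        logger.warning("qst_outlier_test: only %d reference metabolites",
                       len(ref))
    pm = empirical_percentile(focal.qst, ref)
    pf = empirical_percentile(
        focal.qst, np.asarray(fst_values, dtype=float))
    return OutlierVerdict(trait=focal.trait, qst=focal.qst,
                          percentile_metabolites=pm, percentile_fst=pf,
                          selection_candidate=bool(pm >=
                                                   candidate_quantile),
                          n_reference=len(ref), wide_interval=wide)
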