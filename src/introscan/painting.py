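"""Haplotype painting under a Li & Stephens copying model.

Each recipient haplotype is modelled as an imperfect mosaic of the
donor haplotypes.  The hidden state at a site is the donor haplotype
being copied; between adjacent sites d bp apart the chain switches to
a uniformly chosen donor with probability 1 - exp(-Ne * rho * d / N)
(so the current donor also receives a 1/N share of the switch mass),
and the emitted allele matches the copied donor with probability
1 - Mu.  Posterior copying probabilities are obtained by a scaled
forward-backward pass (per-site normalisation, O(L*N) per haplotype);
Ne and Mu are estimated per recipient accession by EM on the expected
switch and miscopy counts, after which the fitted parameters are fixed
for the final painting.  Donor-level posteriors are aggregated to
donor-group (race) probabilities by summation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import MISSING, GroupAssignment, HaplotypePanel

logger = logging.getLogger("introscan")


@dataclass
class CopyingParams:
    """Copying-model parameters for one recipient accession."""

    ne: float = 1e5      # recombination scaling (switch intensity)
    mu: float = 1e-3     # miscopy / emission error probability
    n_em_iter: int = 10
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        if not 0 < self.mu < 0.5:
            raise ValueError("Mu must lie in (0, 0.5)")


@dataclass
class PaintingResult:
    """Per-haplotype, per-SNP posterior over donor groups.

    ``probs`` has shape (n_haplotypes, n_sites, n_groups); each
    per-SNP vector sums to 1.  ``hap_ids`` are (sample_id, hap_index)
    pairs aligned with the rows.
    """

    probs: np.ndarray
    group_names: list
    hap_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    params: dict = field(default_factory=dict)  # sample -> CopyingParams

    def check_conservation(self, tol: float = 1e-9) -> None:
        s = self.probs.sum(axis=2)
        if not np.allclose(s, 1.0, atol=tol):
            raise AssertionError("group probabilities do not sum to 1")
        if (self.probs < -tol).any():
            raise AssertionError("negative posterior probability")


# ---------------------------------------------------------------------------
# Forward-backward machinery
# ---------------------------------------------------------------------------

def _emissions(recips: np.ndarray, donors: np.ndarray, t: int,
               mu: np.ndarray) -> np.ndarray:
    """Emission matrix (R, N) at site t; missing alleles emit 1."""
    r = recips[:, t][:, None]           # (R, 1)
    d = donors[:, t][None, :]           # (1, N)
    match = (r == d)
    e = np.where(match, 1.0 - mu, mu)
    e = np.where((r == MISSING) | (d == MISSING), 1.0, e)
    return e


def forward_backward(recips: np.ndarray, donors: np.ndarray,
                     pos: np.ndarray, ne: float | np.ndarray,
                     mu: float | np.ndarray, rho: float = 1e-8,
                     want_expectations: bool = False):
    """Scaled forward-backward for a batch of recipient haplotypes.

    Parameters
    ----------
    recips : (R, L) recipient alleles
    donors : (N, L) donor alleles (hidden states)
    pos : (L,) positions on one chromosome, strictly increasing
    ne, mu : scalars or per-recipient arrays of shape (R,)
    rho : per-bp recombination rate
    want_expectations : also return per-interval expected jump
        probabilities and per-site expected miscopy indicators

    Returns
    -------
    gamma : (R, L, N) posterior copying probabilities
    loglik : (R,) observed-data log-likelihood
    extras : dict with 'jump_prob' (R, L-1) and 'mismatch_exp' (R, L)
        when requested
    """
    R, L = recips.shape
    N = donors.shape[0]
    if N == 0:
        raise ValueError("at least one donor haplotype is required")
    if donors.shape[1] != L:
        raise ValueError("recipient / donor site-list mismatch")
    ne = np.broadcast_to(np.asarray(ne, dtype=float), (R,))[:, None]
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (R,))[:, None]

    d = np.diff(pos.astype(float))
    # switch probability per interval, per recipient: (R, L-1)
    q = 1.0 - np.exp(-(ne * rho / N) * d[None, :])

    alpha = np.empty((R, L, N))
    c = np.empty((R, L))
    e0 = _emissions(recips, donors, 0, mu_arr)
    a = e0 / N
    c[:, 0] = a.sum(axis=1)
    a /= c[:, 0][:, None]
    alpha[:, 0] = a
    for t in range(1, L):
        qt = q[:, t - 1][:, None]
        e = _emissions(recips, donors, t, mu_arr)
        a = ((1.0 - qt) * a + qt / N) * e
        c[:, t] = a.sum(axis=1)
        a /= c[:, t][:, None]
        alpha[:, t] = a
    loglik = np.log(c).sum(axis=1)

    gamma = np.empty((R, L, N))
    b = np.ones((R, N))
    gamma[:, L - 1] = alpha[:, L - 1] * b
    jump = np.empty((R, L - 1)) if want_expectations else None
    for t in range(L - 2, -1, -1):
        qt = q[:, t][:, None]
        e = _emissions(recips, donors, t + 1, mu_arr)
        eb = e * b
        s = eb.sum(axis=1)[:, None]
        if want_expectations:
            jump[:, t] = (q[:, t] / N) * s[:, 0] / c[:, t + 1]
        b = ((1.0 - qt) * eb + qt / N * s) / c[:, t + 1][:, None]
        g = alpha[:, t] * b
        g /= g.sum(axis=1)[:, None]
        gamma[:, t] = g

    if not want_expectations:
        return gamma, loglik, {}
    # expected miscopy indicator per site (observed-pair sites only)
    mismatch = np.zeros((R, L))
    observed = np.zeros((R, L), dtype=bool)
    for t in range(L):
        r = recips[:, t][:, None]
        dn = donors[:, t][None, :]
        obs = (r != MISSING) & (dn != MISSING)
        mm = (r != dn) & obs
        mismatch[:, t] = (gamma[:, t] * mm).sum(axis=1)
        observed[:, t] = obs.any(axis=1)
    return gamma, loglik, {"jump_prob": jump, "mismatch_exp": mismatch,
                           "observed": observed, "q": q,
                           "distance": d}


def paint_haplotype(recipient: np.ndarray, donors: np.ndarray,
                    pos: np.ndarray, params: CopyingParams,
                    rho: float = 1e-8) -> np.ndarray:
    """Posterior copying probability (L, N) for one haplotype."""
    gamma, _, _ = forward_backward(recipient[None, :], donors, pos,
                                   params.ne, params.mu, rho)
    return gamma[0]


# ---------------------------------------------------------------------------
# EM estimation of Ne and Mu
# ---------------------------------------------------------------------------

def _maximise_ne(jump_probs: list, distances: list, n_donors: int,
                 rho: float, ne0: float) -> float:
    """M-step for Ne: maximise the expected complete-data transition
    log-likelihood sum_t [J_t log q_t + (1 - J_t) log(1 - q_t)]."""
    J = np.concatenate(jump_probs)
    d = np.concatenate(distances)

    def neg_q(log_ne: float) -> float:
        q = 1.0 - np.exp(-(np.exp(log_ne) * rho / n_donors) * d)
        q = np.clip(q, 1e-300, 1 - 1e-12)
        return -float(np.sum(J * np.log(q) + (1 - J) * np.log1p(-q)))

    res = minimize_scalar(neg_q, bounds=(np.log(1e-2), np.log(1e9)),
                          method="bounded",
                          options={"xatol": 1e-6})
    return float(np.exp(res.x))


def fit_params_em(donors_by_chrom: dict,
                  recips_by_chrom: dict, pos_by_chrom: dict,
                  rho: float = 1e-8, n_em_iter: int = 10,
                  init: CopyingParams | None = None) -> CopyingParams:
    """EM estimation of (Ne, Mu) for one recipient accession.

    ``recips_by_chrom[c]`` is the (2, Lc) pair of accession haplotypes
    on chromosome c, ``donors_by_chrom[c]`` the (N, Lc) donor matrix
    and ``pos_by_chrom[c]`` the positions.  Runs exactly ``n_em_iter``
    iterations; the observed-data log-likelihood trace is recorded and
    is non-decreasing up to numerical tolerance.
    """
    params = init or CopyingParams()
    ne, mu = params.ne, params.mu
    trace: list = []
    polymorphic = any(
        len(np.unique(m[m != MISSING])) > 1
        for m in donors_by_chrom.values())
    if not polymorphic:
        logger.warning("degenerate donor panel (monomorphic): EM skipped")
        return CopyingParams(ne=ne, mu=mu, n_em_iter=n_em_iter,
                             loglik_trace=trace)

    n_donors = next(iter(donors_by_chrom.values())).shape[0]
    for _ in range(n_em_iter):
        total_ll = 0.0
        jumps, dists = [], []
        mm_sum = 0.0
        n_obs = 0
        for c, donors in donors_by_chrom.items():
            recips = recips_by_chrom[c]
            _, ll, ex = forward_backward(recips, donors, pos_by_chrom[c],
                                         ne, mu, rho,
                                         want_expectations=True)
            total_ll += float(ll.sum())
            jumps.append(ex["jump_prob"].ravel())
            dists.append(np.tile(ex["distance"], recips.shape[0]))
            mm_sum += float(ex["mismatch_exp"][ex["observed"]].sum())
            n_obs += int(ex["observed"].sum())
        trace.append(total_ll)
        mu = float(np.clip(mm_sum / max(n_obs, 1), 1e-6, 0.499))
        ne = _maximise_ne(jumps, dists, n_donors, rho, ne)
    return CopyingParams(ne=ne, mu=mu, n_em_iter=n_em_iter,
                         loglik_trace=trace)


# ---------------------------------------------------------------------------
# Group aggregation and the panel-level pipeline
# ---------------------------------------------------------------------------

def aggregate_groups(donor_posterior: np.ndarray,
                     donor_hap_groups: list,
                     group_names: list) -> np.ndarray:
    """Sum donor-haplotype posteriors into group probabilities.

    ``donor_posterior`` has trailing axis over donor haplotypes;
    ``donor_hap_groups`` names each donor haplotype's group.  Raises
    if a donor is mapped to no declared group.
    """
    unmapped = set(donor_hap_groups) - set(group_names)
    if unmapped:
        raise ValueError(f"unmapped donor groups: {sorted(unmapped)}")
    idx = np.array([group_names.index(g) for g in donor_hap_groups])
    out = np.zeros(donor_posterior.shape[:-1] + (len(group_names),))
    for k in range(len(group_names)):
        out[..., k] = donor_posterior[..., idx == k].sum(axis=-1)
    return out


def paint_panel(recipients: HaplotypePanel, donors: HaplotypePanel,
                groups: GroupAssignment, rho: float = 1e-8,
                n_em_iter: int = 10, fit_em: bool = True,
                init: CopyingParams | None = None) -> PaintingResult:
    """Paint every recipient haplotype against the donor panel.

    Per accession, (Ne, Mu) are first estimated by EM (``n_em_iter``
    iterations) and then fixed for the final painting.  Donor-level
    posteriors are aggregated to group level on the fly, so memory
    stays O(L * n_groups) per haplotype.
    """
    group_names = groups.donor_groups()
    donor_hap_groups = []
    for s in donors.sample_ids:
        donor_hap_groups.extend([groups.labels[s]] * 2)

    chroms = recipients.chrom_ids
    donors_by_chrom = {c: donors.haplotypes[:, donors.chrom == c]
                       for c in chroms}
    pos_by_chrom = {c: recipients.pos[recipients.chrom == c]
                    for c in chroms}
    site_order = np.concatenate(
        [np.flatnonzero(recipients.chrom == c) for c in chroms])

    n_hap = recipients.n_haplotypes
    L = recipients.n_sites
    probs = np.empty((n_hap, L, len(group_names)))
    hap_ids = []
    params: dict = {}
    for i, sid in enumerate(recipients.sample_ids):
        rows = recipients.sample_haplotype_rows(i)
        recips_by_chrom = {
            c: recipients.haplotypes[np.array(rows)][:,
                                                     recipients.chrom == c]
            for c in chroms}
        if fit_em:
            p = fit_params_em(donors_by_chrom, recips_by_chrom,
                              pos_by_chrom, rho=rho, n_em_iter=n_em_iter,
                              init=init)
        else:
            p = init or CopyingParams()
        params[sid] = p
        col = 0
        for c in chroms:
            gamma, _, _ = forward_backward(recips_by_chrom[c],
                                           donors_by_chrom[c],
                                           pos_by_chrom[c], p.ne, p.mu,
                                           rho)
            gprob = aggregate_groups(gamma, donor_hap_groups, group_names)
            Lc = gamma.shape[1]
            for h in range(2):
                probs[2 * i + h, col:col + Lc] = gprob[h]
            col += Lc
        hap_ids.extend([(sid, 0), (sid, 1)])

    # undo the per-chromosome column ordering if panel interleaves
    inv = np.empty_like(site_order)
    inv[site_order] = np.arange(L)
    probs = probs[:, inv]

    result = PaintingResult(probs=probs, group_names=group_names,
                            hap_ids=hap_ids, chrom=recipients.chrom,
                            pos=recipients.pos, params=params)
    result.check_conservation(tol=1e-6)
    return result
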