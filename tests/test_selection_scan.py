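import numpy as np
import pandas as pd
import pytest
from scipy import stats

from introscan.io_formats import RegionSet
from introscan.selection_scan import (build_kinship, choose_k, flk,
                                      flk_scan, fst_outlier_windows,
                                      hapflk, make_scan_result,
                                      reynolds_distance,
                                      scale_and_extract, scale_statistic,
                                      selection_regions, wc_components,
                                      windowed_fst)

from conftest import make_panel


def wc_reference(counts1, counts2, n1, n2, h1=0.0, h2=0.0):
    """Independently coded textbook Weir & Cockerham (1984) theta for
    one biallelic locus and two populations (diploid counts n1, n2,
    observed het proportions h1, h2)."""
    r = 2
    p1, p2 = counts1 / (2 * n1), counts2 / (2 * n2)
    nbar = (n1 + n2) / r
    CV2 = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / (r * nbar ** 2)
    nc = nbar * (1 - CV2 * ...) if False else \
        (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) \
        / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_wc_matches_independent_implementation():
    """Toy counts (pop1 12/8, pop2 3/17, n=10 diploids each) agree
    with the reference implementation to 1e-10."""
    a_ref, b_ref, c_ref = wc_reference(12, 3, 10, 10, h1=0.2, h2=0.1)
    freq = np.array([[12 / 20, 3 / 20]])
    n = np.array([[10.0, 10.0]])
    het = np.array([[0.2, 0.1]])
    a, b, c = wc_components(freq, n, het)
    assert abs(a[0] - a_ref) < 1e-10
    assert abs(b[0] - b_ref) < 1e-10
    assert abs(c[0] - c_ref) < 1e-10


def test_fst_fixed_differences_and_identical():
    # populations fixed for alternative alleles -> FST 1
    H = np.zeros((8, 4), dtype=np.int8)
    H[4:] = 1
    panel = make_panel(H, sample_ids=["a1", "a2", "b1", "b2"])
    group_of = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"}
    res = windowed_fst(panel, group_of, window_bp=1000)
    assert np.allclose(res.per_snp["fst"], 1.0)
    assert np.allclose(res.windows["fst"].dropna(), 1.0)

    # identical frequencies, large n -> FST near 0
    rng = np.random.default_rng(0)
    col = rng.integers(0, 2, size=(80, 1)).astype(np.int8)
    H = np.tile(col, (1, 10))
    perm = rng.permutation(80)
    samples = [f"s{i}" for i in range(40)]
    panel = make_panel(H[perm], sample_ids=samples)
    group_of = {s: ("P1" if i < 20 else "P2")
                for i, s in enumerate(samples)}
    res = windowed_fst(panel, group_of, window_bp=100_000)
    assert abs(res.windows["fst"].iloc[0]) < 0.05


def test_reynolds_distance_identity():
    """Two Balding-Nichols populations at F = t give Reynolds distance
    about -ln(1 - t)."""
    rng = np.random.default_rng(1)
    t = 0.1
    L, n_per = 4000, 40
    p = rng.uniform(0.05, 0.95, L)
    g1 = rng.beta(p * (1 - t) / t, (1 - p) * (1 - t) / t)
    g2 = rng.beta(p * (1 - t) / t, (1 - p) * (1 - t) / t)
    rows = []
    samples = []
    group_of = {}
    for g, f in (("P1", g1), ("P2", g2)):
        for i in range(n_per):
            h = (rng.random(L) < f).astype(np.int8)
            rows.extend([h, h.copy()])
            samples.append(f"{g}_{i}")
            group_of[f"{g}_{i}"] = g
    panel = make_panel(np.vstack(rows), pos=np.arange(L) * 10,
                       sample_ids=samples)
    pops, D = reynolds_distance(panel, group_of)
    assert abs(D[0, 1] - (-np.log(1 - t))) < 0.02


def test_kinship_from_hand_built_tree():
    """F entries from a 4-taxon distance matrix equal hand-computed
    shared branch lengths: ((A:1,B:1):2,(C:2,D:2):1) rooted at top."""
    pops = ["A", "B", "C", "D"]
    # additive distances on that tree
    D = np.array([
        [0, 2, 6, 6],
        [2, 0, 6, 6],
        [6, 6, 0, 4],
        [6, 6, 4, 0]], dtype=float)
    import skbio
    from skbio.tree import nj
    tree = nj(skbio.DistanceMatrix(D, ids=pops)).root_at_midpoint()
    # emulate build_kinship's F computation on a literal tree
    tips = {t.name: t for t in tree.tips()}
    depth = {p: tips[p].accumulate_to_ancestor(tree) for p in pops}
    F = np.zeros((4, 4))
    for i in range(4):
        F[i, i] = depth[pops[i]]
        for j in range(i + 1, 4):
            lca = tree.lowest_common_ancestor([pops[i], pops[j]])
            F[i, j] = F[j, i] = (lca.accumulate_to_ancestor(tree)
                                 if lca is not tree else 0.0)
    # midpoint root sits on the central branch (length 3), 3 from A
    assert F[0, 0] == pytest.approx(3.0)
    assert F[0, 1] == pytest.approx(2.0)   # shared path of A,B to root
    assert F[2, 3] == pytest.approx(1.0)
    assert F[0, 2] == pytest.approx(0.0)
    # PSD with diagonal dominating its row entries
    assert np.all(np.diag(F)[:, None] >= F - 1e-12)


def test_flk_identical_frequencies():
    F = np.diag([0.05] * 4)
    T, p = flk(np.array([0.3, 0.3, 0.3, 0.3]), F)
    assert T == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_flk_star_kinship_closed_form():
    """With F = c*I the statistic equals the explicit weighted sum."""
    rng = np.random.default_rng(2)
    c = 0.08
    F = c * np.eye(5)
    p = rng.uniform(0.2, 0.8, 5)
    T, _ = flk(p, F)
    p0 = p.mean()          # uniform weights under F = c I
    expect = np.sum((p - p0) ** 2) / (c * p0 * (1 - p0))
    assert abs(T - expect) < 1e-12


def test_flk_reduces_to_lk_and_label_swap_invariance():
    rng = np.random.default_rng(3)
    c = 0.05
    F = c * np.eye(4)
    freqs = rng.uniform(0.05, 0.95, size=(50, 4))
    T = flk_scan(freqs, F)
    # classical LK: n-1 times ratio of variance to binomial variance
    p0 = freqs.mean(axis=1)
    lk = freqs.shape[1] * np.var(freqs, axis=1) / (c * p0 * (1 - p0))
    np.testing.assert_allclose(T, lk, atol=1e-10)
    # allele relabelling
    T_swap = flk_scan(1 - freqs, F)
    np.testing.assert_allclose(T, T_swap, atol=1e-10)


def test_flk_null_calibration():
    """Drift-only Balding-Nichols simulation consistent with a star F:
    empirical type-I error at alpha 0.05 within [0.035, 0.065]."""
    rng = np.random.default_rng(4)
    c, P, L = 0.05, 4, 2000
    F = np.diag([c] * P)
    p0 = rng.uniform(0.1, 0.9, L)
    a = p0 * (1 - c) / c
    b = (1 - p0) * (1 - c) / c
    freqs = np.column_stack([rng.beta(a, b) for _ in range(P)])
    T = flk_scan(freqs, F)
    pv = stats.chi2.sf(T, P - 1)
    pv = pv[np.isfinite(pv)]
    assert 0.035 <= (pv < 0.05).mean() <= 0.065


def test_flk_monomorphic_is_nan():
    F = np.diag([0.05] * 3)
    T, p = flk(np.array([0.0, 0.0, 0.0]), F)
    assert np.isnan(T) and np.isnan(p)


# ---------------------------------------------------------------------------
# hapFLK
# ---------------------------------------------------------------------------

def _two_pop_panel(seed=5, L=200, n_per=25, shift=None):
    """Two drifted populations; optionally swap frequencies of a
    contiguous region in pop 2 to mimic local selection."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, L)
    f = 0.05
    g1 = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    g2 = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    if shift is not None:
        lo, hi = shift
        g2[lo:hi] = 1 - g2[lo:hi]
    rows, samples, group_of = [], [], {}
    for g, fr in (("P1", g1), ("P2", g2)):
        for i in range(n_per):
            h = (rng.random(L) < fr).astype(np.int8)
            rows.extend([h, h.copy()])
            sid = f"{g}_{i}"
            samples.append(sid)
            group_of[sid] = g
    panel = make_panel(np.vstack(rows), pos=np.arange(L) * 5000,
                       sample_ids=samples)
    return panel, group_of


def test_hapflk_deterministic_and_nonnegative():
    panel, group_of = _two_pop_panel()
    F = np.diag([0.05, 0.05])
    a = hapflk(panel, group_of, F, ["P1", "P2"], K=3, n_fits=2, seed=7,
               max_iter=10, tol=1e-3)
    b = hapflk(panel, group_of, F, ["P1", "P2"], K=3, n_fits=2, seed=7,
               max_iter=10, tol=1e-3)
    pd.testing.assert_frame_equal(a, b)
    assert (a["hapflk"] >= 0).all()
    assert np.isfinite(a["hapflk"]).all()


def test_hapflk_signal_injection():
    """A locally frequency-swapped region scores above the genome
    background (rank-sum p < 0.01)."""
    panel, group_of = _two_pop_panel(seed=6, shift=(90, 110))
    F = np.diag([0.05, 0.05])
    df = hapflk(panel, group_of, F, ["P1", "P2"], K=4, n_fits=3,
                seed=8, max_iter=15, tol=1e-3)
    v = df["hapflk"].to_numpy()
    inside = v[90:110]
    outside = np.concatenate([v[:90], v[110:]])
    res = stats.mannwhitneyu(inside, outside, alternative="greater")
    assert res.pvalue < 0.01
    assert inside.mean() > np.median(outside)


def test_hapflk_invalid_k():
    panel, group_of = _two_pop_panel()
    with pytest.raises(ValueError):
        hapflk(panel, group_of, np.eye(2) * 0.05, ["P1", "P2"], K=1)


def _cluster_mosaic_panel(seed=9, K_true=5, L=150, n_hap=60,
                          jump=0.02, noise=0.02):
    """Haplotypes generated from a true K-cluster mosaic model."""
    rng = np.random.default_rng(seed)
    protos = rng.integers(0, 2, size=(K_true, L)).astype(np.int8)
    rows = []
    for _ in range(n_hap):
        k = rng.integers(K_true)
        h = np.empty(L, dtype=np.int8)
        for t in range(L):
            if t > 0 and rng.random() < jump:
                k = rng.integers(K_true)
            a = protos[k, t]
            h[t] = 1 - a if rng.random() < noise else a
        rows.append(h)
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return make_panel(np.vstack(rows), pos=np.arange(L) * 100_000,
                      sample_ids=samples)


def test_choose_k_guard_and_recovery():
    panel = _cluster_mosaic_panel()
    with pytest.raises(ValueError):
        choose_k(panel, mask_frac=0.0)
    k_star, scores = choose_k(panel, k_grid=(2, 5, 10), n_sets=2,
                              mask_frac=0.1, seed=3, max_iter=25,
                              tol=1e-3)
    # data from a K=5 model: cross-validation prefers K >= 5
    assert k_star in (5, 10)
    # fitted model beats the allele-frequency baseline imputer
    rng = np.random.default_rng(0)
    H = panel.haplotypes
    p1 = H.mean(axis=0)
    mask = rng.random(H.shape) < 0.1
    baseline = (p1 > 0.5).astype(np.int8)
    base_wp = np.mean(
        np.broadcast_to(baseline, H.shape)[mask] != H[mask])
    best_wp = scores.groupby("K")["Wp"].mean().min()
    assert best_wp < base_wp


# ---------------------------------------------------------------------------
# Scaling and regions
# ---------------------------------------------------------------------------

def test_scale_statistic_recovers_chi2():
    rng = np.random.default_rng(10)
    x = 3.0 * rng.chisquare(4, size=20_000)
    p, s, d = scale_statistic(x)
    assert abs(s - 3.0) < 0.25
    assert abs(d - 4.0) < 0.4
    # scaled p-values uniform-ish: KS sanity
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 0.01


def test_selection_region_merge_trace():
    """Significant SNPs at 1.000 and 1.012 Mb give regions
    [0.995-1.005] and [1.007-1.017], gap 2 kb <= 5 kb -> merged."""
    per_snp = pd.DataFrame({
        "chrom": ["Chr01", "Chr01"],
        "pos": [1_000_000, 1_012_000],
        "stat": [50.0, 60.0],
        "p": [1e-5, 1e-6],
        "q": [1e-3, 1e-4],
    })
    scan = type("S", (), {"per_snp": per_snp})()
    regions = selection_regions(scan)
    assert regions.df[["start", "end"]].values.tolist() == \
        [[995_000, 1_017_000]]


def test_extended_restricted_set_semantics():
    mk = lambda rows: RegionSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end"]))
    def scan_from(positions):
        df = pd.DataFrame({
            "chrom": ["Chr01"] * len(positions), "pos": positions,
            "stat": 50.0, "p": 1e-5, "q": 1e-3})
        return type("S", (), {"per_snp": df})()
    ra = selection_regions(scan_from([100_000, 500_000]))
    rb = selection_regions(scan_from([102_000]))
    union = ra.union(rb, gap=5000)
    both = union.overlaps_any(ra) & union.overlaps_any(rb)
    # region near 100 kb supported by both; 500 kb by run A only
    assert both.tolist() == [True, False]
    # restricted subset of union subset relation
    restricted = RegionSet(union.df[both])
    assert restricted.overlaps_any(union).all()


def test_fdr_control_under_null():
    """On null chi-square statistics the p<1e-3 & q<0.05 rule yields
    at most ~fdr x tests discoveries (50 replicates)."""
    rng = np.random.default_rng(11)
    total_disc = 0
    n_tests = 500
    for _ in range(50):
        x = 2.0 * rng.chisquare(3, size=n_tests)
        df = pd.DataFrame({"chrom": "c", "pos": np.arange(n_tests),
                           "hapflk": x})
        scan = make_scan_result(df, "hapflk")
        sig = (scan.per_snp["p"] < 1e-3) & (scan.per_snp["q"] < 0.05)
        total_disc += int(sig.sum())
    assert total_disc <= 0.05 * n_tests * 50 * 0.2


def test_fst_outlier_windows_tail():
    rows = [{"chrom": "c", "start": i * 10_000, "end": (i+1) * 10_000,
             "fst": v, "n_snps": 5}
            for i, v in enumerate(np.linspace(0, 1, 100))]
    fake = type("F", (), {"windows": pd.DataFrame(rows)})()
    top = fst_outlier_windows(fake, 0.05)
    assert len(top) == 5
    assert top.df["start"].min() == 95 * 10_000
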