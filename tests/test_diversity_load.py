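import itertools

import numpy as np
import pandas as pd
import pytest

from introscan.ancestry_blocks import mask_introgression
from introscan.diversity_load import (genetic_load,
                                      nonsyn_syn_ratio_fold,
                                      private_allele_spectrum, theta_pi,
                                      theta_pi_by_class)
from introscan.io_formats import (MISSING, AnnotationTable,
                                  GroupAssignment, RegionSet)

from conftest import make_panel


def brute_force_pi(H):
    """Average pairwise difference per site over all haplotype pairs,
    restricted to pairs where both alleles are observed."""
    n_hap, L = H.shape
    out = np.zeros(L)
    for j in range(L):
        alleles = H[:, j][H[:, j] != MISSING]
        pairs = list(itertools.combinations(alleles, 2))
        if not pairs:
            out[j] = np.nan
            continue
        out[j] = np.mean([a != b for a, b in pairs]) if pairs else np.nan
    return out


def test_site_pi_worked_example():
    """4 haplotypes with allele counts 2/2: 4 of 6 pairs differ."""
    panel = make_panel([[0], [0], [1], [1]])
    est = theta_pi(panel, region=("Chr01", 0, 1))
    assert abs(est.per_site["pi"].iloc[0] - 2 / 3) < 1e-12


def test_monomorphic_region_zero():
    panel = make_panel(np.zeros((4, 5), dtype=np.int8))
    est = theta_pi(panel, region=("Chr01", 0, 1000))
    assert est.theta_pi_bp == 0.0


def test_two_haplotypes_k_over_L():
    H = np.zeros((2, 10), dtype=np.int8)
    H[1, [2, 5, 7]] = 1    # k = 3 differing sites
    panel = make_panel(H, pos=np.arange(10) * 10, sample_ids=["s0"])
    est = theta_pi(panel, region=("Chr01", 0, 100))
    assert abs(est.theta_pi_bp - 3 / 100) < 1e-12


@pytest.mark.parametrize("with_missing", [False, True])
def test_theta_pi_equals_bruteforce(with_missing):
    """Estimator equals direct pairwise differences to 1e-12 on
    panels up to 20 haplotypes x 200 sites."""
    rng = np.random.default_rng(8)
    H = rng.integers(0, 2, size=(20, 200)).astype(np.int8)
    if with_missing:
        H[rng.random(H.shape) < 0.15] = MISSING
    pos = np.sort(rng.choice(100_000, 200, replace=False))
    panel = make_panel(H, pos=pos)
    est = theta_pi(panel, region=("Chr01", 0, 100_000))
    expect = brute_force_pi(H)
    got = est.per_site["pi"].to_numpy()
    ok = ~np.isnan(expect)
    assert np.nanmax(np.abs(got[ok] - expect[ok])) < 1e-12
    assert abs(est.theta_pi_bp - np.nansum(expect) / 100_000) < 1e-12


def test_theta_pi_by_class_partitions():
    """Class-wise theta-pi/bp matches region-wise computation."""
    rng = np.random.default_rng(15)
    H = rng.integers(0, 2, size=(10, 100)).astype(np.int8)
    panel = make_panel(H, pos=np.arange(100) * 100)
    classes = {
        "left": RegionSet(pd.DataFrame(
            [{"chrom": "Chr01", "start": 0, "end": 5000}])),
        "right": RegionSet(pd.DataFrame(
            [{"chrom": "Chr01", "start": 5000, "end": 10_000}])),
    }
    out = theta_pi_by_class(panel, classes).set_index("class")
    left = theta_pi(panel, region=("Chr01", 0, 5000))
    right = theta_pi(panel, region=("Chr01", 5000, 10_000))
    assert out.loc["left", "theta_pi_bp"] == pytest.approx(
        left.theta_pi_bp, abs=1e-12)
    assert out.loc["right", "theta_pi_bp"] == pytest.approx(
        right.theta_pi_bp, abs=1e-12)


def test_min_pind_monotonicity():
    rng = np.random.default_rng(9)
    H = rng.integers(0, 2, size=(12, 100)).astype(np.int8)
    H[rng.random(H.shape) < 0.3] = MISSING
    panel = make_panel(H, pos=np.arange(100) * 50)
    used = [theta_pi(panel, min_pind=t).n_sites_used
            for t in (0.0, 0.3, 0.6, 0.9)]
    assert all(b <= a for a, b in zip(used, used[1:]))


def test_masked_vs_unmasked_ordering(default_panel, default_window_map):
    """Admixture inflates unmasked diversity: recipient-panel theta-pi
    is higher unmasked than on the same-ancestry masked panel."""
    sp = default_panel
    and_masked, _ = mask_introgression(sp.recipients,
                                      default_window_map)
    chrom_len = {c: sp.config.chrom_len_bp
                 for c in sp.config.chrom_names}
    unmasked = theta_pi(sp.recipients, chrom_len=chrom_len)
    masked = theta_pi(and_masked, chrom_len=chrom_len)
    assert unmasked.theta_pi_bp > masked.theta_pi_bp > 0


def _annotation(panel, effects):
    return AnnotationTable(variants=pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.pos,
        "effect": effects, "gene_id": ""}))


def test_private_allele_classification_rules():
    # 2 AM + 2 EU samples; site0 EU-private low, site1 shared
    H = np.zeros((8, 3), dtype=np.int8)
    H[4, 0] = 1                      # EU freq 1/4 -> private, low? 0.25
    H[[0, 4], 1] = 1                 # segregates in both -> not private
    H[[4, 5, 6], 2] = 1              # EU freq 3/4 -> private, high
    panel = make_panel(H, sample_ids=["AM_1", "AM_2", "EU_1", "EU_2"])
    groups = GroupAssignment(
        labels={"AM_1": "AM_A1", "AM_2": "AM_M1",
                "EU_1": "EU", "EU_2": "EU"},
        roles={s: "donor" for s in ["AM_1", "AM_2", "EU_1", "EU_2"]})
    ann = _annotation(panel, ["missense", "missense", "synonymous"])
    spec = private_allele_spectrum(panel, groups, ann)
    def count(g, b, k):
        m = (spec["group"] == g) & (spec["bin"] == b) & (spec["class"] == k)
        return int(spec.loc[m, "count"].iloc[0])
    # site0: EU freq 0.25 (>= 0.05) missense; site2: EU freq 0.75 syn
    assert count("EU", "medium_high", "nonsynonymous") == 1
    assert count("EU", "medium_high", "synonymous") == 1
    assert count("EU", "low", "nonsynonymous") == 0
    assert count("AM", "low", "nonsynonymous") == 0
    assert spec["count"].sum() == 2   # shared site not private


def test_private_spectrum_matches_bruteforce():
    rng = np.random.default_rng(10)
    H = rng.integers(0, 2, size=(12, 20)).astype(np.int8)
    samples = [f"AM_{i}" for i in range(3)] + [f"EU_{i}" for i in range(3)]
    panel = make_panel(H, sample_ids=samples)
    groups = GroupAssignment(
        labels={s: ("AM_A1" if s.startswith("AM") else "EU")
                for s in samples},
        roles={s: "donor" for s in samples})
    effects = rng.choice(["synonymous", "missense", "loss_of_function",
                          "other"], size=20)
    ann = _annotation(panel, effects)
    spec = private_allele_spectrum(panel, groups, ann)
    # exhaustive manual classification
    expect = {}
    fa = H[:6].mean(axis=0)
    fb = H[6:].mean(axis=0)
    for j in range(20):
        k = ("synonymous" if effects[j] == "synonymous" else
             "nonsynonymous" if effects[j] in ("missense",
                                               "loss_of_function")
             else None)
        if k is None:
            continue
        for g, own, oth in (("AM", fa[j], fb[j]), ("EU", fb[j], fa[j])):
            if own > 0 and oth == 0:
                b = "low" if own < 0.05 else "medium_high"
                expect[(g, b, k)] = expect.get((g, b, k), 0) + 1
    for row in spec.to_dict("records"):
        assert row["count"] == expect.get(
            (row["group"], row["bin"], row["class"]), 0)


def test_load_ratio_arithmetic():
    """10 missense, 2 LoF, 5 synonymous alt alleles -> 2.0 and 0.4."""
    effects = (["missense"] * 5 + ["loss_of_function"] * 1
               + ["synonymous"] * 5)
    H = np.zeros((2, 11), dtype=np.int8)
    H[:, :5] = 1          # 10 missense alleles (dosage 2 x 5)
    H[:, 5] = 1           # 2 LoF
    H[0, 6:11] = 1        # 5 synonymous
    panel = make_panel(H, sample_ids=["s0"])
    ann = _annotation(panel, effects)
    summary = genetic_load(panel, ann, {"s0": "EU_AND"})
    rec = summary.per_accession.iloc[0]
    assert rec["missense"] == 10 and rec["loss_of_function"] == 2
    assert rec["synonymous"] == 5
    assert rec["missense_ratio"] == 2.0
    assert rec["lof_ratio"] == pytest.approx(0.4)


def test_identical_loads_give_p_one():
    H = np.zeros((8, 6), dtype=np.int8)
    H[:, 0] = 1   # everyone same counts
    H[:, 3] = 1
    panel = make_panel(H, sample_ids=["a", "b", "c", "d"])
    ann = _annotation(panel, ["missense", "missense", "missense",
                              "synonymous", "synonymous", "synonymous"])
    group_of = {"a": "G1", "b": "G1", "c": "G2", "d": "G2"}
    summary = genetic_load(panel, ann, group_of)
    assert (summary.group_tests["p_value"] == 1.0).all()


def test_simulated_load_difference_detected():
    """2x missense alt-allele rate in group B detected at p < 0.01."""
    rng = np.random.default_rng(12)
    n, L = 30, 400
    effects = ["missense"] * 200 + ["synonymous"] * 200
    rows = []
    samples = []
    group_of = {}
    for g, rate in (("A", 0.1), ("B", 0.2)):
        for i in range(n):
            sid = f"{g}{i}"
            h = np.zeros(L, dtype=np.int8)
            h[:200] = rng.random(200) < rate        # missense
            h[200:] = rng.random(200) < 0.1         # synonymous
            rows.extend([h, h.copy()])
            samples.append(sid)
            group_of[sid] = g
    panel = make_panel(np.vstack(rows), pos=np.arange(L) * 10,
                       sample_ids=samples)
    ann = _annotation(panel, effects)
    summary = genetic_load(panel, ann, group_of)
    p = summary.group_tests.set_index("statistic").loc[
        "missense_ratio", "p_value"]
    assert float(p) < 0.01


def test_load_empty_group_rejected():
    panel = make_panel(np.zeros((2, 2), dtype=np.int8),
                       sample_ids=["s0"])
    ann = _annotation(panel, ["missense", "synonymous"])
    summary = genetic_load(panel, ann, {"s0": "G1"})
    assert len(summary.group_tests) == 0
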