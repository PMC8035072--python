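import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_matrix
from ryekit.popgen import (
    STRINGENT_FILTERS,
    filter_genotypes,
    fst_components,
    patterson_d,
    pca_and_kmeans,
    polarize_by_outgroup,
    windowed_fst,
    windowed_ibs,
    windowed_pnps,
)
from ryekit.synthetic import PopSimConfig, Tract, simulate_structured_genotypes

# ---------------------------------------------------------------- filtering


def test_missingness_filter_direct_count():
    """10 sites, 3 of them 40% missing: max_missing=0.3 keeps 7."""
    calls = np.zeros((5, 10), dtype=np.int8)
    for site in (2, 5, 9):
        calls[:2, site] = -1  # 2 of 5 samples missing = 40%
    gm = make_matrix(calls)
    filtered, n = filter_genotypes(gm, max_missing=0.3)
    assert n == 7
    assert not set(filtered.sites["pos"]) & {3000, 6000, 10000}


def test_maf_filter_removes_monomorphic():
    calls = np.array([[0, 1], [0, 1], [0, 0], [0, 2]], dtype=np.int8)
    gm = make_matrix(calls)
    filtered, n = filter_genotypes(gm, max_missing=1.0, maf=0.01)
    assert n == 1  # the monomorphic first site is gone


def test_depth_filter_applies_before_missingness():
    """Low-depth calls become missing first, which can push a site over the
    missingness threshold."""
    calls = np.zeros((4, 2), dtype=np.int8)
    depth = np.full((4, 2), 10)
    depth[:3, 0] = 2  # 3 of 4 calls under-covered at site 0
    gm = make_matrix(calls, depth=depth)
    filtered, n = filter_genotypes(gm, max_missing=0.5, min_depth=6)
    assert n == 1
    assert (filtered.calls != -1).all()


def test_quality_filter_and_stringent_preset():
    assert STRINGENT_FILTERS == {"min_depth": 6, "max_missing": 0.05, "min_quality": 250}
    calls = np.zeros((3, 3), dtype=np.int8)
    gm = make_matrix(calls, depth=np.full((3, 3), 20), qual=[100.0, 300.0, 260.0])
    filtered, n = filter_genotypes(gm, **STRINGENT_FILTERS)
    assert n == 2


def test_filtering_is_idempotent():
    cfg = PopSimConfig(n_clusters=2, samples_per_cluster=10, n_sites=300, seed=5)
    gm, _, _ = simulate_structured_genotypes(cfg)
    once, n1 = filter_genotypes(gm, **STRINGENT_FILTERS)
    twice, n2 = filter_genotypes(once, **STRINGENT_FILTERS)
    assert n1 == n2
    assert np.array_equal(once.calls, twice.calls)


def test_all_sites_removed_warns_not_raises():
    gm = make_matrix(np.full((3, 4), -1, dtype=np.int8))
    with pytest.warns(UserWarning, match="all sites removed"):
        filtered, n = filter_genotypes(gm, max_missing=0.1)
    assert n == 0


# --------------------------------------------------------------- PCA/kmeans


def test_duplicated_sample_gets_identical_scores():
    cfg = PopSimConfig(n_clusters=2, samples_per_cluster=10, n_sites=400, seed=6)
    gm, _, _ = simulate_structured_genotypes(cfg)
    gm.calls[1] = gm.calls[0]
    model = pca_and_kmeans(gm, k=2)
    assert np.allclose(model.pc_scores.iloc[0], model.pc_scores.iloc[1])


def test_two_cluster_truth_recovery():
    cfg = PopSimConfig(n_clusters=2, samples_per_cluster=15, n_sites=800, divergence=0.2, seed=7)
    gm, _, truth = simulate_structured_genotypes(cfg)
    model = pca_and_kmeans(gm, k=2)
    assert adjusted_rand_score(truth.values, model.assignments.values) == 1.0


def test_seven_cluster_default_recovery():
    """The default seven-cluster panel is recovered from three PCs."""
    cfg = PopSimConfig(seed=12)
    gm, _, truth = simulate_structured_genotypes(cfg)
    model = pca_and_kmeans(gm)
    assert model.pc_scores.shape[1] == 3
    assert adjusted_rand_score(truth.values, model.assignments.values) > 0.9


def test_k_larger_than_samples_rejected():
    gm = make_matrix(np.zeros((3, 5), dtype=np.int8))
    with pytest.raises(ValueError):
        pca_and_kmeans(gm, k=4)


# --------------------------------------------------------------------- IBS


def test_ibs_identical_and_opposite_samples():
    n_sites = 120
    base = np.tile([0, 2], n_sites // 2).astype(np.int8)
    calls = np.vstack([base, base, 2 - base])
    gm = make_matrix(calls)
    ibs = windowed_ibs(gm, "s0", window=100, step=25)
    same = ibs[ibs["sample"] == "s1"]["value"]
    opposite = ibs[ibs["sample"] == "s2"]["value"]
    assert np.allclose(same, 1.0)
    assert np.allclose(opposite, 0.0)
    assert ibs["value"].between(0, 1).all()


def test_ibs_window_count_250_sites():
    gm = make_matrix(np.zeros((2, 250), dtype=np.int8))
    ibs = windowed_ibs(gm, "s0")
    assert (ibs.groupby("sample").size() == 7).all()


def test_ibs_focal_missing_window_is_nan():
    calls = np.zeros((2, 100), dtype=np.int8)
    calls[0, :] = -1  # focal entirely missing
    gm = make_matrix(calls)
    ibs = windowed_ibs(gm, "s0")
    assert ibs[ibs["sample"] == "s1"]["value"].isna().all()


def test_ibs_rises_inside_gene_flow_tract():
    """A donor->recipient tract lifts windowed IBS between a recipient focal
    sample and donor-cluster samples inside the tract."""
    cfg = PopSimConfig(
        n_clusters=4,
        samples_per_cluster=10,
        n_sites=3000,
        divergence=0.25,
        tracts=[Tract(donor=4, recipient=3, chrom="chr1", start=20_000_000, end=60_000_000)],
        seed=7,
    )
    gm, _, _ = simulate_structured_genotypes(cfg)
    ibs = windowed_ibs(gm, "c3_s000")
    donors = ibs[ibs["sample"].str.startswith("c4_")]
    in_tract = (donors["chrom"] == "chr1") & donors["mean_pos"].between(20e6, 60e6)
    assert donors[in_tract]["value"].mean() > donors[~in_tract]["value"].mean() + 0.03


# --------------------------------------------------------------------- Fst


def oracle_fst(dosages_by_group):
    """Direct loop implementation of the two-level allele-count ANOVA."""
    r = len(dosages_by_group)
    m, p = [], []
    for dosages in dosages_by_group:
        called = [d for d in dosages if d >= 0]
        m.append(2 * len(called))
        p.append(sum(called) / (2 * len(called)))
    M = sum(m)
    p_bar = sum(mi * pi for mi, pi in zip(m, p)) / M
    msp = sum(mi * (pi - p_bar) ** 2 for mi, pi in zip(m, p)) / (r - 1)
    msg = sum(mi * pi * (1 - pi) for mi, pi in zip(m, p)) / (M - r)
    n_c = (M - sum(mi**2 for mi in m) / M) / (r - 1)
    return (msp - msg), (msp + (n_c - 1) * msg)


def test_fst_single_site_frozen_value():
    """Hand-computed single-site instance: dosages (0,1) vs (2,2) give
    MSP=1.125, MSG=0.125, n_c=4, Fst = 1/1.5 = 2/3."""
    num, den = fst_components(np.array([[4.0], [4.0]]), np.array([[0.25], [1.0]]))
    assert num[0] / den[0] == pytest.approx(2.0 / 3.0, rel=1e-12)


def test_fst_fixed_differences_give_one():
    calls = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
    gm = make_matrix(calls)
    fst = windowed_fst(gm, {"a": ["s0", "s1"], "b": ["s2", "s3"]}, window=2, step=2)
    assert np.allclose(fst["value"], 1.0)


def test_fst_matches_loop_oracle_on_small_instances():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n1, n2, n_sites = rng.integers(2, 6), rng.integers(2, 6), rng.integers(1, 6)
        calls = rng.integers(0, 3, size=(n1 + n2, n_sites)).astype(np.int8)
        calls[0, 0] = rng.choice([0, 1, 2])  # keep group 1 fully called at site 0
        gm = make_matrix(calls)
        groups = {
            "a": [f"s{i}" for i in range(n1)],
            "b": [f"s{i}" for i in range(n1, n1 + n2)],
        }
        fst = windowed_fst(gm, groups, window=n_sites, step=n_sites)
        num = den = 0.0
        for s in range(n_sites):
            n_s, d_s = oracle_fst([calls[:n1, s], calls[n1:, s]])
            num += n_s
            den += d_s
        assert fst["value"].iloc[0] == pytest.approx(num / den, rel=1e-9)


def test_fst_invariant_to_allele_label_swap():
    rng = np.random.default_rng(4)
    calls = rng.integers(0, 3, size=(8, 120)).astype(np.int8)
    groups = {"a": [f"s{i}" for i in range(4)], "b": [f"s{i}" for i in range(4, 8)]}
    f1 = windowed_fst(make_matrix(calls), groups)
    f2 = windowed_fst(make_matrix(2 - calls), groups)
    assert np.allclose(f1["value"], f2["value"])


def test_fst_panmictic_mean_near_zero():
    """Two groups of 50 drawn from one panmictic population."""
    cfg = PopSimConfig(n_clusters=2, samples_per_cluster=50, n_sites=2000, divergence=0.0, seed=11)
    gm, _, _ = simulate_structured_genotypes(cfg)
    groups = {
        "g1": [s for s in gm.samples if s.startswith("c1")],
        "g2": [s for s in gm.samples if s.startswith("c2")],
    }
    fst = windowed_fst(gm, groups)
    assert abs(fst["value"].mean()) < 0.02


def test_fst_group_size_validation():
    gm = make_matrix(np.zeros((3, 10), dtype=np.int8))
    with pytest.raises(ValueError, match="at least two samples"):
        windowed_fst(gm, {"a": ["s0"], "b": ["s1", "s2"]})


# ------------------------------------------------------------ polarization


def test_polarization_consensus_rules():
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [1, 2, 3, 4],
            "ref": ["A", "A", "G", "C"],
            "alt": ["G", "G", "A", "T"],
        }
    )
    ann = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [1, 2, 3, 4],
            "out1": ["A", "A", "G", "A"],
            "out2": ["A", "G", "G", "A"],
            "out3": ["G", "T", "G", "A"],
        }
    )
    pol = polarize_by_outgroup(sites, ann)
    assert pol.loc[0, "status"] == "ok" and pol.loc[0, "ancestral"] == "A"
    assert pol.loc[0, "derived"] == "G"
    assert pol.loc[1, "status"] == "no_majority"  # A, G, T: no allele twice
    assert pol.loc[2, "status"] == "ok" and pol.loc[2, "ancestral"] == "G"
    assert pol.loc[3, "status"] == "allele_mismatch"  # majority A not in C/T


def test_polarization_unannotated_flagged():
    sites = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [99], "ref": ["A"], "alt": ["G"]}
    )
    ann = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [1], "out1": ["A"], "out2": ["A"], "out3": ["A"]}
    )
    assert polarize_by_outgroup(sites, ann).loc[0, "status"] == "unannotated"


# ------------------------------------------------------------------- Pn/Ps


def _pnps_fixture(pn_sites, ps_sites, window):
    """One window with pn_sites segregating nonsynonymous and ps_sites
    synonymous derived polymorphisms; remaining sites monomorphic."""
    n_sites = window
    calls = np.zeros((4, n_sites), dtype=np.int8)
    seg = pn_sites + ps_sites
    calls[0, :seg] = 1  # derived present and polymorphic at the first sites
    gm = make_matrix(calls)
    effect = ["nonsynonymous"] * pn_sites + ["synonymous"] * (n_sites - pn_sites)
    ann = pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "effect": effect,
            "out1": "A",
            "out2": "A",
            "out3": "A",
        }
    )
    pol = polarize_by_outgroup(gm.sites, ann)
    return gm, ann, pol


def test_pnps_reported_at_threshold():
    gm, ann, pol = _pnps_fixture(5, 5, window=40)
    out = windowed_pnps(gm, ann, pol, gm.samples, window=40, step=40)
    assert out.loc[0, "reported"]
    assert out.loc[0, "value"] == pytest.approx(1.0)
    assert out.loc[0, ["pn", "ps"]].tolist() == [5, 5]


def test_pnps_suppressed_below_threshold():
    """Pn + Ps = 9 does not exceed nine: the bin is suppressed."""
    gm, ann, pol = _pnps_fixture(4, 5, window=40)
    out = windowed_pnps(gm, ann, pol, gm.samples, window=40, step=40)
    assert not out.loc[0, "reported"]
    assert np.isnan(out.loc[0, "value"])


def test_pnps_infinite_flag_when_ps_zero():
    gm, ann, pol = _pnps_fixture(10, 0, window=40)
    out = windowed_pnps(gm, ann, pol, gm.samples, window=40, step=40)
    assert out.loc[0, "reported"] and out.loc[0, "infinite"]
    assert np.isinf(out.loc[0, "value"])


def test_pnps_empty_group_rejected():
    gm, ann, pol = _pnps_fixture(5, 5, window=40)
    with pytest.raises(ValueError):
        windowed_pnps(gm, ann, pol, [], window=40, step=40)


def test_selection_lowers_group_pnps():
    """Purifying selection (sel_differential < 1) on one cluster lowers its
    mean Pn/Ps relative to the neutral cluster."""
    cfg = PopSimConfig(
        n_clusters=2,
        samples_per_cluster=25,
        n_sites=4000,
        divergence=0.1,
        sel_differential=0.25,
        sel_group=1,
        seed=21,
    )
    gm, ann, truth = simulate_structured_genotypes(cfg)
    pol = polarize_by_outgroup(gm.sites, ann)
    vals = {}
    for k in (1, 2):
        group = [s for s in gm.samples if s.startswith(f"c{k}_")]
        out = windowed_pnps(gm, ann, pol, group)
        finite = out["value"].replace(np.inf, np.nan).dropna()
        vals[k] = finite.mean()
    assert vals[1] < vals[2]


# --------------------------------------------------------------------- D


def _polarized_all_ref(gm):
    ann = pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "out1": gm.sites["ref"],
            "out2": gm.sites["ref"],
            "out3": gm.sites["ref"],
        }
    )
    return polarize_by_outgroup(gm.sites, ann)


def _three_groups(n=2):
    names = [f"s{i}" for i in range(3 * n)]
    return names[:n], names[n : 2 * n], names[2 * n :]


def test_d_zero_when_p1_equals_p2():
    calls = np.array(
        [[1, 0, 2, 1], [0, 1, 1, 2], [1, 0, 2, 1], [0, 1, 1, 2], [1, 1, 1, 1], [2, 0, 1, 2]],
        dtype=np.int8,
    )
    gm = make_matrix(calls)
    p1, p2, p3 = _three_groups()
    res = patterson_d(gm, p1, p2, p3, _polarized_all_ref(gm))
    assert res.d == pytest.approx(0.0, abs=1e-12)


def test_d_one_for_pure_abba():
    calls = np.vstack(
        [np.zeros((2, 6)), np.full((2, 6), 2), np.full((2, 6), 2)]
    ).astype(np.int8)
    gm = make_matrix(calls)
    p1, p2, p3 = _three_groups()
    res = patterson_d(gm, p1, p2, p3, _polarized_all_ref(gm))
    assert res.d == pytest.approx(1.0)


def test_d_sign_flips_with_p1_p2_swap_and_bounded():
    rng = np.random.default_rng(8)
    calls = rng.integers(0, 3, size=(9, 400)).astype(np.int8)
    gm = make_matrix(calls)
    pol = _polarized_all_ref(gm)
    p1, p2, p3 = [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)], [f"s{i}" for i in range(6, 9)]
    fwd = patterson_d(gm, p1, p2, p3, pol)
    rev = patterson_d(gm, p2, p1, p3, pol)
    assert fwd.d == pytest.approx(-rev.d, rel=1e-9)
    assert abs(fwd.d) <= 1.0


def test_d_matches_loop_oracle_small_instance():
    rng = np.random.default_rng(9)
    calls = rng.integers(0, 3, size=(6, 5)).astype(np.int8)
    gm = make_matrix(calls)
    pol = _polarized_all_ref(gm)
    p1, p2, p3 = _three_groups()
    res = patterson_d(gm, p1, p2, p3, pol)
    num = den = 0.0
    for s in range(5):
        freqs = []
        for grp in (range(0, 2), range(2, 4), range(4, 6)):
            d = [calls[i, s] for i in grp if calls[i, s] >= 0]
            freqs.append(sum(d) / (2 * len(d)))
        f1, f2, f3 = freqs
        num += (1 - f1) * f2 * f3 - f1 * (1 - f2) * f3
        den += (1 - f1) * f2 * f3 + f1 * (1 - f2) * f3
    assert res.d == pytest.approx(num / den, rel=1e-9)


def test_d_groups_must_be_disjoint():
    gm = make_matrix(np.zeros((4, 10), dtype=np.int8))
    with pytest.raises(ValueError):
        patterson_d(gm, ["s0"], ["s0"], ["s2"], _polarized_all_ref(gm))


def test_d_few_blocks_flags_undefined_se():
    calls = np.array([[0, 1], [1, 0], [2, 1], [1, 2], [2, 2], [1, 2]], dtype=np.int8)
    gm = make_matrix(calls, pos=[100, 200])  # a single 5-Mb block
    p1, p2, p3 = _three_groups()
    res = patterson_d(gm, p1, p2, p3, _polarized_all_ref(gm))
    assert not res.se_defined
    assert np.isnan(res.se)


def test_d_positive_under_planted_gene_flow():
    """A donor(P3) -> recipient(P2) tract yields D > 0 with Z > 3."""
    cfg = PopSimConfig(
        n_clusters=3,
        samples_per_cluster=15,
        n_sites=8000,
        divergence=0.3,
        tracts=[Tract(donor=3, recipient=2, chrom="chr1", start=0, end=80_000_000)],
        seed=201,
    )
    gm, ann, _ = simulate_structured_genotypes(cfg)
    pol = polarize_by_outgroup(gm.sites, ann)
    g = {k: [s for s in gm.samples if s.startswith(f"c{k}_")] for k in (1, 2, 3)}
    res = patterson_d(gm, g[1], g[2], g[3], pol)
    assert res.d > 0
    assert res.z > 3
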