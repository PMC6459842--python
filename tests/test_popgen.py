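import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betaln, comb

from splicevo import popgen


# -- mediation ----------------------------------------------------------------

def _mediation_data(seed=0, n=200, beta=0.15, direct=0.0,
                    f_a=0.8, f_b=0.3):
    rng = np.random.default_rng(seed)
    pop = np.array(["AFB"] * (n // 2) + ["EUB"] * (n // 2))
    f = np.where(pop == "AFB", f_a, f_b)
    g = rng.binomial(2, f).astype(float)
    psi = 0.4 + beta * g + direct * (pop == "AFB") + rng.normal(0, 0.03, n)
    return psi, g, pop


def test_mediation_identity_zeta_plus_delta():
    for seed in range(5):
        psi, g, pop = _mediation_data(seed, direct=0.05)
        out = popgen.mediation_decompose(psi, g, pop, n_boot=20)
        assert out["zeta"] + out["delta"] == pytest.approx(out["dpsi"],
                                                           abs=1e-10)


def test_mediation_closed_form_zeta():
    psi, g, pop = _mediation_data(1)
    out = popgen.mediation_decompose(psi, g, pop, n_boot=20)
    # dual route: fit the same OLS with numpy and apply Eq. directly
    in_a = pop == "AFB"
    X = np.column_stack([np.ones(len(g)), g, in_a.astype(float)])
    coef, *_ = np.linalg.lstsq(X, psi, rcond=None)
    f_a, f_b = g[in_a].mean() / 2, g[~in_a].mean() / 2
    assert out["zeta"] == pytest.approx(2 * coef[1] * (f_a - f_b), abs=1e-12)
    assert out["beta"] == pytest.approx(coef[1], abs=1e-12)


def test_mediation_fully_mediated_tau_near_one():
    psi, g, pop = _mediation_data(2, direct=0.0)
    out = popgen.mediation_decompose(psi, g, pop, n_boot=200, seed=5)
    assert out["tau_defined"]
    assert 0.9 <= out["tau"] <= 1.1
    lo, hi = out["tau_ci"]
    assert lo < out["tau"] < hi


def test_mediation_tau_undefined_without_population_difference():
    rng = np.random.default_rng(3)
    n = 400
    pop = np.array(["AFB", "EUB"] * (n // 2))
    g = rng.binomial(2, 0.5, n).astype(float)
    psi = np.full(n, 0.5)
    out = popgen.mediation_decompose(psi, g, pop, n_boot=20)
    assert not out["tau_defined"]
    assert np.isnan(out["tau"])


def test_mediation_requires_both_populations():
    with pytest.raises(ValueError):
        popgen.mediation_decompose([0.5, 0.6], [1.0, 2.0],
                                   np.array(["AFB", "AFB"]))


# -- FST ----------------------------------------------------------------------

def wc_fst_oracle(d, pops):
    """Loop-based Weir & Cockerham (1984) theta for two populations,
    written directly from the published component formulas."""
    out = []
    subpops = ["AFB", "EUB"]
    r = 2
    n_i = [float((pops == s).sum()) for s in subpops]
    n_bar = sum(n_i) / r
    n_c = (r * n_bar - sum(ni ** 2 for ni in n_i) / (r * n_bar)) / (r - 1)
    for snp in d:
        p_i = [snp[pops == s].mean() / 2 for s in subpops]
        h_i = [(snp[pops == s] == 1).mean() for s in subpops]
        p_bar = sum(ni * pi for ni, pi in zip(n_i, p_i)) / (r * n_bar)
        s2 = sum(ni * (pi - p_bar) ** 2
                 for ni, pi in zip(n_i, p_i)) / ((r - 1) * n_bar)
        h_bar = sum(ni * hi for ni, hi in zip(n_i, h_i)) / (r * n_bar)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar)
                                   - (r - 1) / r * s2 - h_bar / 4)
                             / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                     - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        out.append(a / denom if denom != 0 else np.nan)
    return np.array(out)


def _fst_data(seed=0, n_snps=60, n=50):
    rng = np.random.default_rng(seed)
    pops = np.array(["AFB"] * n + ["EUB"] * n)
    f_a = rng.uniform(0.05, 0.95, n_snps)
    f_b = np.clip(f_a + rng.normal(0, 0.2, n_snps), 0.02, 0.98)
    d = np.concatenate([rng.binomial(2, f_a[:, None], (n_snps, n)),
                        rng.binomial(2, f_b[:, None], (n_snps, n))],
                       axis=1).astype(float)
    return d, pops


def test_wc_fst_matches_loop_oracle():
    d, pops = _fst_data()
    got = popgen.fst(d, pops)
    expect = wc_fst_oracle(d, pops)
    pooled = d.mean(axis=1) / 2
    expect[(pooled == 0) | (pooled == 1)] = np.nan
    np.testing.assert_allclose(got, expect, atol=1e-10)


def test_fst_fixed_difference_is_one():
    pops = np.array(["AFB"] * 30 + ["EUB"] * 30)
    d = np.concatenate([np.full((1, 30), 2.0), np.zeros((1, 30))], axis=1)
    assert popgen.fst(d, pops)[0] == pytest.approx(1.0)
    assert popgen.fst(d, pops, estimator="hudson")[0] == pytest.approx(1.0)


def test_fst_monomorphic_is_nan():
    pops = np.array(["AFB"] * 10 + ["EUB"] * 10)
    d = np.zeros((1, 20))
    assert np.isnan(popgen.fst(d, pops)[0])
    assert np.isnan(popgen.fst(d, pops, estimator="hudson")[0])


def test_fst_hudson_tracks_wc():
    d, pops = _fst_data(1)
    wc = popgen.fst(d, pops)
    hu = popgen.fst(d, pops, estimator="hudson")
    ok = np.isfinite(wc) & np.isfinite(hu)
    assert ok.sum() > 50
    assert np.corrcoef(wc[ok], hu[ok])[0, 1] > 0.95


def test_fst_unknown_estimator():
    d, pops = _fst_data(2, n_snps=2)
    with pytest.raises(ValueError):
        popgen.fst(d, pops, estimator="nei")


# -- EHH / iHS ----------------------------------------------------------------

def test_ehh_decay_hand_oracle():
    # 4 carrier haplotypes; the first marker on each side splits them
    # into two pairs (EHH = 2/6), the second into singletons (EHH = 0)
    H = np.array([
        [0, 1, 0, 1],   # far left marker: pairs -> singletons
        [0, 0, 1, 1],   # near left marker: two pairs
        [1, 1, 1, 1],   # focal (all carriers)
        [0, 0, 1, 1],   # near right marker
        [0, 1, 0, 1],   # far right marker
    ])
    pos = np.array([0.0, 100.0, 200.0, 350.0, 400.0])
    ihh, unbounded = popgen.ehh_decay(H, 2, np.arange(4), pos)
    expect = (100 * (1 + 1 / 3) / 2 + 100 * (1 / 3) / 2   # left trapezoids
              + 150 * (1 + 1 / 3) / 2 + 50 * (1 / 3) / 2)  # right
    assert ihh == pytest.approx(expect, abs=1e-10)
    assert not unbounded     # both sides decayed below cutoff


def test_ehh_unbounded_flag():
    H = np.ones((3, 4), dtype=int)     # identical haplotypes never decay
    pos = np.array([0.0, 50.0, 100.0])
    ihh, unbounded = popgen.ehh_decay(H, 1, np.arange(4), pos)
    assert unbounded


def test_ihs_symmetric_alleles_give_zero_raw():
    # derived and ancestral carriers have mirror-image haplotype
    # structure -> iHH_A == iHH_D -> raw iHS == 0
    rng = np.random.default_rng(0)
    n_h = 40
    flank = rng.integers(0, 2, size=(30, n_h))
    focal = np.array([0, 1] * (n_h // 2))
    perm = np.argsort(focal, kind="stable")
    # force exact mirror: ancestral columns get the same flank pattern
    # as derived columns
    half = flank[:, : n_h // 2]
    H = np.vstack([np.hstack([half, half])])
    H = np.vstack([H[:15], np.concatenate([np.zeros(n_h // 2, int),
                                           np.ones(n_h // 2, int)])[None, :],
                   H[15:]])
    pos = np.arange(H.shape[0]) * 1000.0
    out = popgen.ihs(H, pos, standardize=False)
    assert out.ihs_raw.iloc[15] == pytest.approx(0.0, abs=1e-12)


def test_ihs_rare_snps_not_scored():
    H = np.zeros((5, 40), dtype=int)
    H[2, 0] = 1          # DAF 2.5% < 5%
    pos = np.arange(5) * 1000.0
    out = popgen.ihs(H, pos)
    assert np.isnan(out.ihs_raw.iloc[2])


def test_ihs_bin_standardization_exact():
    rng = np.random.default_rng(1)
    H = rng.integers(0, 2, size=(120, 60))
    pos = np.sort(rng.uniform(0, 2e6, 120))
    out = popgen.ihs(H, pos)
    out["bin"] = np.minimum((out.daf / 0.02).astype(int), 49)
    for _, grp in out.dropna(subset=["ihs"]).groupby("bin"):
        if len(grp) >= 2:
            assert grp.ihs.mean() == pytest.approx(0.0, abs=1e-10)
            assert grp.ihs.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


# -- beta-binomial outliers ---------------------------------------------------

def bb_tail_oracle(k, n, a, b):
    """P(X >= k) by direct summation of the beta-binomial pmf."""
    tot = 0.0
    for x in range(k, n + 1):
        tot += comb(n, x) * np.exp(betaln(x + a, n - x + b) - betaln(a, b))
    return tot


def test_beta_binomial_tail_matches_summation():
    for k, n, a, b in [(3, 10, 2.0, 5.0), (0, 8, 1.0, 1.0),
                       (15, 30, 0.5, 3.5), (30, 30, 4.0, 0.3)]:
        assert popgen.beta_binomial_tail(k, n, a, b) == pytest.approx(
            bb_tail_oracle(k, n, a, b), abs=1e-12)


def test_empirical_rank_p_mid_rank():
    v = np.array([1.0, 2.0, 3.0, 3.0, 4.0])
    assert popgen.empirical_rank_p(v, 3.0) == pytest.approx(
        (1 + 0.5 * 2) / 5)
    assert popgen.empirical_rank_p(v, 10.0) == 0.0


def test_fit_beta_moments_roundtrip():
    rng = np.random.default_rng(2)
    x = rng.beta(3.0, 7.0, 50_000)
    a, b = popgen.fit_beta_moments(x)
    assert a == pytest.approx(3.0, rel=0.05)
    assert b == pytest.approx(7.0, rel=0.05)
    assert popgen.fit_beta_moments(np.full(10, 0.3)) is None


def test_outlier_enrichment_extreme_cluster():
    rng = np.random.default_rng(3)
    n = 2000
    pos = np.sort(rng.uniform(0, 5e6, n))
    v = rng.normal(0, 1, n)
    focal = int(np.argmin(np.abs(pos - 2.5e6)))
    near = np.abs(pos - pos[focal]) <= 50_000
    v[near] += 4.0                        # local cluster of outliers
    out = popgen.outlier_enrichment(v, pos, focal)
    assert out["p_enrich"] < 1e-3
    assert out["p_emp"] < 0.05
    # null focal region: no enrichment
    v2 = rng.normal(0, 1, n)
    out2 = popgen.outlier_enrichment(v2, pos, focal)
    assert out2["p_enrich"] > 0.01


def test_outlier_enrichment_sparse_window_raises():
    pos = np.array([0.0, 1.0, 2.0, 1e9])
    v = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError, match="informative"):
        popgen.outlier_enrichment(v, pos, 3)


# -- MAF-matched resampling ---------------------------------------------------

def _snp_universe(seed=0, n=600):
    rng = np.random.default_rng(seed)
    snps = [f"s{i}" for i in range(n)]
    maf = {s: float(rng.uniform(0.01, 0.5)) for s in snps}
    return snps, maf, rng


def test_null_counts_respect_maf_bins():
    snps, maf, rng = _snp_universe()
    peaks = snps[:30]
    # target set = all SNPs in the same bins as the peaks; every matched
    # draw must then land in the target, making every null count == 30
    def b(s):
        return int(maf[s] / 0.02)
    peak_bins = {b(s) for s in peaks}
    target = {s for s in snps if b(s) in peak_bins}
    obs, nulls = popgen.maf_matched_null_counts(
        peaks, target, snps[30:], maf, n_resamples=50)
    assert obs == 30
    assert (nulls == 30).all()


def test_null_counts_deterministic_under_seed():
    snps, maf, rng = _snp_universe(1)
    target = set(rng.choice(snps, 100, replace=False))
    a = popgen.maf_matched_null_counts(snps[:40], target, snps[40:], maf,
                                       n_resamples=100, seed=9)
    b = popgen.maf_matched_null_counts(snps[:40], target, snps[40:], maf,
                                       n_resamples=100, seed=9)
    assert a[0] == b[0]
    np.testing.assert_array_equal(a[1], b[1])


def test_archaic_enrichment_null_and_planted():
    snps, maf, rng = _snp_universe(2, n=2000)
    background = snps[200:]
    # null: peaks are a random background-like subset; target membership
    # is independent of peak status at rate 10%
    target = {s for s in snps if rng.random() < 0.10}
    peaks = list(rng.choice(background, 60, replace=False))
    out = popgen.archaic_enrichment(peaks, target, background, maf,
                                    n_resamples=400, seed=3)
    assert out["p_value"] > 0.01
    assert 0.3 < out["fold"] < 2.5
    # planted: peaks overlap the target 3x more often
    hot = [s for s in background if s in target]
    cold = [s for s in background if s not in target]
    peaks = hot[:18] + cold[:42]          # 30% vs 10% base rate
    out = popgen.archaic_enrichment(peaks, target, background, maf,
                                    n_resamples=400, seed=3)
    assert out["fold"] > 2.0
    assert out["p_value"] < 0.05


def test_archaic_enrichment_empty_set_raises():
    snps, maf, _ = _snp_universe(3, n=50)
    with pytest.raises(ValueError):
        popgen.archaic_enrichment(snps[:5], set(), snps[5:], maf)


def test_gwas_overlap_skips_small_categories():
    snps, maf, rng = _snp_universe(4, n=800)
    cats = {"big": set(rng.choice(snps, 100, replace=False)),
            "tiny": set(snps[:3])}
    out = popgen.gwas_overlap_enrichment(snps[:40], cats, snps[40:], maf,
                                         n_resamples=100)
    assert out.category.tolist() == ["big"]
    assert 0.0 <= out.p_value.iloc[0] <= 1.0


def test_gwas_overlap_whole_background_category_not_enriched():
    snps, maf, _ = _snp_universe(5, n=400)
    cats = {"all": set(snps)}
    out = popgen.gwas_overlap_enrichment(snps[:30], cats, snps[30:], maf,
                                         n_resamples=100)
    # every draw hits the category, so the observed count is not extreme
    assert out.p_value.iloc[0] == 1.0
    assert out.mean_null.iloc[0] == 30.0
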