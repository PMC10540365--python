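"""Whitened association scans: GLS equivalence, model tests, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adqtl.genotype_io import GenotypeMatrix, SnpRecord, encode_additive, encode_heterozygote
from adqtl.relatedness import GrmPair, build_grms
from adqtl.scan import (
    anova_a_vs_ad,
    conditional_scan,
    fit_snp,
    genome_scan,
    whitening_operator,
)
from adqtl.simulate import simulate_genotypes, simulate_trait
from adqtl.varcomp import VarianceComponents, reml_fit


def _vc(sa, sd, se, n=0):
    return VarianceComponents(sa, sd, se, 0, 0, 0, 0.0, True, 1, n)


def _gls_oracle(y, X, V):
    """Direct generalised least squares via explicit V^{-1}."""
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    n, k = X.shape
    resid = y - X @ beta
    sigma2 = float(resid @ Vinv @ resid) / (n - k)
    se = np.sqrt(np.diag(np.linalg.inv(XtVX)) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return beta, se, t, p


# ---------------------------------------------------------------------------
# Whitening
# ---------------------------------------------------------------------------


def test_whitening_identity_for_pure_environment(medium_grms):
    n = len(medium_grms.samples)
    W = whitening_operator(_vc(0.0, 0.0, 1.0), medium_grms).matrix
    assert np.allclose(W, np.eye(n), atol=1e-10)


def test_whitening_defining_property(medium_grms):
    vc = _vc(0.4, 0.2, 0.4)
    n = len(medium_grms.samples)
    V = 0.4 * medium_grms.K_a + 0.2 * medium_grms.K_d + 0.4 * np.eye(n)
    W = whitening_operator(vc, medium_grms).matrix
    assert np.abs(W @ V @ W - np.eye(n)).max() < 1e-6


def test_whitening_all_zero_components_rejected(medium_grms):
    with pytest.raises(ValueError, match="zero"):
        whitening_operator(_vc(0.0, 0.0, 0.0), medium_grms)


def test_whitened_ols_equals_gls_oracle():
    """Whitened-OLS scan statistics match explicit-V^{-1} GLS to 1e-6."""
    g = simulate_genotypes(50, 60, seed=31)
    grms = build_grms(g)
    vc = _vc(0.3, 0.2, 0.5)
    rng = np.random.default_rng(32)
    y = rng.standard_normal(50)
    scan = genome_scan(y, g, vc, grms)
    V = 0.3 * grms.K_a + 0.2 * grms.K_d + 0.5 * np.eye(50)
    xa, xh = encode_additive(g), encode_heterozygote(g)
    ones = np.ones(50)
    for j in range(g.n_snps):
        if scan.loc[j, "flags"]:
            continue
        X = np.column_stack([ones, xa[:, j], xh[:, j]])
        beta, se, t, p = _gls_oracle(y, X, V)
        assert scan.loc[j, "beta_a"] == pytest.approx(beta[1], abs=1e-6)
        assert scan.loc[j, "beta_d"] == pytest.approx(beta[2], abs=1e-6)
        assert scan.loc[j, "t_add"] == pytest.approx(t[1], abs=1e-6)
        assert scan.loc[j, "t_dom"] == pytest.approx(t[2], abs=1e-6)
        assert scan.loc[j, "p_AvsAD"] == pytest.approx(p[2], abs=1e-6)


# ---------------------------------------------------------------------------
# Single-SNP fits and the A-vs-AD ANOVA
# ---------------------------------------------------------------------------


def test_pure_additive_signal_identity_whitening():
    rng = np.random.default_rng(33)
    xa = rng.binomial(2, 0.5, size=200).astype(float)
    xh = (xa == 1).astype(float)
    y = 0.8 * xa + 0.01 * rng.standard_normal(200)
    ones = np.ones(200)
    fit = fit_snp(y, ones, xa, xh, "AD", raw_xa=xa, raw_xh=xh)
    assert fit.p_AD < 1e-20
    assert abs(fit.t_dom) < 3
    fit_a = fit_snp(y, ones, xa, None, "A", raw_xa=xa)
    assert fit_a.p_A < 1e-20


def test_pure_heterozygote_signal_at_half_frequency():
    # at p = 0.5 the centred additive and heterozygote codings are
    # orthogonal, so a pure dominance signal leaves the A model null
    rng = np.random.default_rng(34)
    xa = rng.binomial(2, 0.5, size=500).astype(float)
    xh = (xa == 1).astype(float)
    y = 0.6 * xh + 0.3 * rng.standard_normal(500)
    ones = np.ones(500)
    fit_d = fit_snp(y, ones, None, xh, "D", raw_xh=xh)
    assert fit_d.p_D < 1e-20
    fit_a = fit_snp(y, ones, xa, None, "A", raw_xa=xa)
    assert fit_a.p_A > 1e-4


def test_no_heterozygote_snp_flagged_monomorphic():
    y = np.random.default_rng(35).standard_normal(20)
    ones = np.ones(20)
    xa = np.array([0.0, 2.0] * 10)
    xh = np.zeros(20)
    fit = fit_snp(y, ones, xa, xh, "AD", raw_xa=xa, raw_xh=xh)
    assert fit.flags == "monomorphic"
    assert fit.p_AD == 1.0


def test_two_genotype_class_snp_falls_back_to_additive():
    y = np.random.default_rng(36).standard_normal(30)
    ones = np.ones(30)
    xa = np.array([0.0, 1.0] * 15)
    xh = xa.copy()  # classes {0,1}: heterozygote dosage equals additive
    fit = fit_snp(y, ones, xa, xh, "AD", raw_xa=xa, raw_xh=xh)
    assert fit.flags == "ad_collinear"
    assert fit.p_AD == pytest.approx(fit.p_A)


def test_anova_identity_f_equals_t_squared():
    rng = np.random.default_rng(37)
    for _ in range(5):
        xa = rng.binomial(2, 0.4, size=80).astype(float)
        xh = (xa == 1).astype(float)
        y = 0.2 * xa + 0.3 * xh + rng.standard_normal(80)
        ones = np.ones(80)
        fit_a = fit_snp(y, ones, xa, None, "A", raw_xa=xa)
        fit_ad = fit_snp(y, ones, xa, xh, "AD", raw_xa=xa, raw_xh=xh)
        p = anova_a_vs_ad(fit_a, fit_ad)
        f = (fit_a.rss - fit_ad.rss) / (fit_ad.rss / fit_ad.df_resid)
        assert f == pytest.approx(fit_ad.t_dom**2, abs=1e-6)
        assert p == pytest.approx(fit_ad.p_AvsAD, abs=1e-10)


def test_anova_identical_rss_gives_p_one():
    rng = np.random.default_rng(38)
    xa = rng.binomial(2, 0.4, size=50).astype(float)
    xh = (xa == 1).astype(float)
    y = rng.standard_normal(50)
    ones = np.ones(50)
    fit_a = fit_snp(y, ones, xa, None, "A", raw_xa=xa)
    fake_ad = fit_snp(y, ones, xa, xh, "AD", raw_xa=xa, raw_xh=xh)
    fake_ad.rss = fit_a.rss
    assert anova_a_vs_ad(fit_a, fake_ad) == pytest.approx(1.0)


def test_anova_non_nested_rejected():
    rng = np.random.default_rng(39)
    xa = rng.binomial(2, 0.4, size=50).astype(float)
    xh = (xa == 1).astype(float)
    y = rng.standard_normal(50)
    ones = np.ones(50)
    fit_a = fit_snp(y, ones, xa, None, "A", raw_xa=xa)
    fit_a2 = fit_snp(y[:40], ones[:40], xa[:40], None, "A", raw_xa=xa[:40])
    fit_ad = fit_snp(y, ones, xa, xh, "AD", raw_xa=xa, raw_xh=xh)
    with pytest.raises(ValueError, match="nested"):
        anova_a_vs_ad(fit_a2, fit_ad)
    with pytest.raises(ValueError, match="nested"):
        anova_a_vs_ad(fit_ad, fit_ad)


# ---------------------------------------------------------------------------
# Genome scan properties
# ---------------------------------------------------------------------------


def test_scan_recovers_planted_additive_qtl(medium_genotypes, medium_grms, medium_trait):
    y, truth = medium_trait
    vc = reml_fit(y, medium_grms)
    scan = genome_scan(y, medium_genotypes, vc, medium_grms)
    peak = scan.loc[scan["p_AD"].idxmin()]
    causal_ids = {q["snp_id"] for q in truth.qtls["trait"]}
    assert peak["snp_id"] in causal_ids
    assert peak["p_AD"] < 0.05 / medium_genotypes.n_snps


def test_scan_invariant_to_sample_permutation(medium_genotypes, medium_grms, medium_trait):
    y, _ = medium_trait
    vc = reml_fit(y, medium_grms)
    scan = genome_scan(y, medium_genotypes, vc, medium_grms)
    rng = np.random.default_rng(40)
    perm = rng.permutation(medium_genotypes.n_samples)
    gp = medium_genotypes.subset_samples(perm)
    grms_p = GrmPair(
        samples=[medium_grms.samples[i] for i in perm],
        K_a=medium_grms.K_a[np.ix_(perm, perm)],
        K_d=medium_grms.K_d[np.ix_(perm, perm)],
        n_snps_used=medium_grms.n_snps_used,
    )
    scan_p = genome_scan(y.values[perm], gp, vc, grms_p)
    assert np.allclose(scan["p_AD"], scan_p["p_AD"], atol=1e-8)
    assert np.allclose(scan["p_AvsAD"], scan_p["p_AvsAD"], atol=1e-8)


def test_scan_allele_relabelling_flips_only_beta_a_sign():
    g = simulate_genotypes(150, 80, seed=41)
    rng = np.random.default_rng(42)
    y = rng.standard_normal(150)
    grms = build_grms(g)
    vc = _vc(0.2, 0.1, 0.7)
    scan = genome_scan(y, g, vc, grms)
    flipped = GenotypeMatrix.from_calls(
        list(g.samples),
        [SnpRecord(s.id, s.chromosome, s.position) for s in g.snps],
        np.where(g.calls >= 0, 2 - g.calls, g.calls),
    )
    scan_f = genome_scan(y, flipped, vc, grms)
    ok = scan["flags"] == ""
    assert np.allclose(scan.loc[ok, "beta_a"], -scan_f.loc[ok, "beta_a"], atol=1e-8)
    assert np.allclose(scan.loc[ok, "beta_d"], scan_f.loc[ok, "beta_d"], atol=1e-8)
    assert np.allclose(scan.loc[ok, "p_AD"], scan_f.loc[ok, "p_AD"], atol=1e-10)
    assert np.allclose(scan.loc[ok, "p_AvsAD"], scan_f.loc[ok, "p_AvsAD"], atol=1e-10)


def test_scan_handles_missing_phenotypes(medium_genotypes, medium_grms, medium_trait):
    y, _ = medium_trait
    vals = y.values.copy()
    vals[:15] = np.nan
    vc = reml_fit(vals, medium_grms)
    scan = genome_scan(vals, medium_genotypes, vc, medium_grms)
    assert (scan["n_used"] == len(vals) - 15).all()


# ---------------------------------------------------------------------------
# Conditional scans
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def ld_setup():
    """Genotypes with strong within-block LD plus a causal additive SNP."""
    g = simulate_genotypes(400, 200, ld_blocks=(10, 0.9), seed=43)
    grms = build_grms(g)
    causal = "snp00055"
    y, _ = simulate_trait(g, [(causal, 0.6, 0.0)], sigma_a2=0.0, sigma_d2=0.0,
                          sigma_e2=1.0, grms=None, seed=44)
    vc = reml_fit(y, grms)
    return g, grms, y, vc, causal


def test_conditioning_on_causal_snp_collapses_signal(ld_setup):
    g, grms, y, vc, causal = ld_setup
    base = genome_scan(y, g, vc, grms)
    cond = conditional_scan(y, g, vc, grms, [causal])
    jc = base.index[base["snp_id"] == causal][0]
    assert base.loc[jc, "p_AD"] < 1e-4
    assert cond.loc[jc, "p_AD"] > 0.9  # conditioning column absorbs itself
    # linked neighbours (same LD block) collapse too
    block = base.loc[(base.index // 10) == jc // 10]
    others = cond.loc[block.index.drop(jc)]
    strong = block.drop(jc)[block.drop(jc)["p_AD"] < 1e-6]
    if len(strong):
        assert (cond.loc[strong.index, "p_AD"] > 1e-4).all()


def test_conditioning_on_unlinked_snp_changes_little(ld_setup):
    g, grms, y, vc, causal = ld_setup
    base = genome_scan(y, g, vc, grms)
    unlinked = "snp00190"  # different chromosome from the causal SNP
    cond = conditional_scan(y, g, vc, grms, [unlinked])
    # null region: SNPs on chromosomes without the causal locus
    null = (base["chrom"] != base.loc[base["snp_id"] == causal, "chrom"].iloc[0]) & (
        base["snp_id"] != unlinked
    ) & (base["flags"] == "") & (cond["flags"] == "")
    d = np.abs(
        np.log10(base.loc[null, "p_AD"]) - np.log10(cond.loc[null, "p_AD"])
    )
    assert d.max() < 0.5


def test_empty_condition_list_is_plain_scan(ld_setup):
    g, grms, y, vc, _ = ld_setup
    a = genome_scan(y, g, vc, grms)
    b = conditional_scan(y, g, vc, grms, [])
    pd.testing.assert_frame_equal(a, b)


def test_unknown_conditioning_snp_errors(ld_setup):
    g, grms, y, vc, _ = ld_setup
    with pytest.raises(KeyError, match="nope"):
        conditional_scan(y, g, vc, grms, ["nope"])
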