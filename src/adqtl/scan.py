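"""Mixed-model association scans under the A, D and AD models.

The mixed model ``y = X beta + g_a + g_d + e`` with covariance
``V = K_a sa2 + K_d sd2 + I se2`` is converted to ordinary least squares by
multiplying the phenotype and design by ``W = V^{-1/2}`` (symmetric inverse
square root, eigenvalues floored before inversion).  Variance components
are estimated once per trait and the same whitening reused at every SNP.

Per SNP, three nested fixed-effect designs are fitted on the whitened data:

* A model:  intercept + additive dosage (0/1/2)
* D model:  intercept + heterozygote dosage (0/1/0)
* AD model: intercept + both columns

with t-tests on each coefficient, a 2-df F-test of the AD model against the
intercept-only null (``p_AD``, the headline scan statistic) and a 1-df
F-test of AD against A (``p_AvsAD``, the dominance-specific test, equal to
the square of the t-test on the heterozygote coefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, PhenotypeVector, encode_additive, encode_heterozygote, allele_frequencies
from .relatedness import GrmPair
from .varcomp import VarianceComponents

__all__ = [
    "WhiteningOperator",
    "SnpAssociation",
    "whitening_operator",
    "fit_snp",
    "anova_a_vs_ad",
    "genome_scan",
    "conditional_scan",
]

_MONO_TOL = 1e-12


@dataclass
class WhiteningOperator:
    """Symmetric V^{-1/2} with the eigenvalue floor used to build it."""

    matrix: np.ndarray
    eigen_floor: float


@dataclass
class SnpAssociation:
    """Association summary for one SNP (AD-model effects, all model p-values)."""

    snp_id: str
    beta_a: float = np.nan
    beta_d: float = np.nan
    t_add: float = np.nan
    t_dom: float = np.nan
    p_A: float = 1.0
    p_D: float = 1.0
    p_AD: float = 1.0
    p_AvsAD: float = 1.0
    n_used: int = 0
    flags: str = ""
    # residual bookkeeping for model comparison
    rss: float = np.nan
    df_resid: int = 0
    k: int = 0


def whitening_operator(vc: VarianceComponents, grms: GrmPair) -> WhiteningOperator:
    """W = V^{-1/2} by eigendecomposition of V = K_a sa2 + K_d sd2 + I se2.

    Eigenvalues below ``1e-8 * max eigenvalue`` are floored there before
    inversion so that near-singular V never blows up the transform.
    """
    comps = (vc.sigma_a2, vc.sigma_d2, vc.sigma_e2)
    if any(c < 0 for c in comps):
        raise ValueError("variance components must be non-negative")
    if sum(comps) <= 0:
        raise ValueError("all variance components are zero")
    n = len(grms.samples)
    V = vc.sigma_a2 * grms.K_a + vc.sigma_d2 * grms.K_d + vc.sigma_e2 * np.eye(n)
    w, U = np.linalg.eigh(V)
    floor = 1e-8 * w.max()
    w = np.clip(w, floor, None)
    W = (U / np.sqrt(w)) @ U.T
    return WhiteningOperator(matrix=W, eigen_floor=float(floor))


def _ols(yw: np.ndarray, Xw: np.ndarray):
    """Plain OLS on whitened data: coefficients, SEs, rss, df."""
    n, k = Xw.shape
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    beta = np.linalg.solve(XtX, Xty)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df if df > 0 else np.nan
    se = np.sqrt(np.clip(np.diag(np.linalg.inv(XtX)) * sigma2, 0, None))
    return beta, se, rss, df


def _t_pvalue(t: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def _f_pvalue(rss0: float, rss1: float, df_num: int, df_den: int) -> float:
    if df_den <= 0:
        return 1.0
    num = max(rss0 - rss1, 0.0) / df_num
    den = rss1 / df_den
    if den <= 0:
        return 0.0 if num > 0 else 1.0
    return float(stats.f.sf(num / den, df_num, df_den))


def fit_snp(
    yw: np.ndarray,
    intercept_w: np.ndarray,
    xa_w: np.ndarray | None,
    xh_w: np.ndarray | None,
    model: str = "AD",
    snp_id: str = "",
    raw_xa: np.ndarray | None = None,
    raw_xh: np.ndarray | None = None,
) -> SnpAssociation:
    """Fit one whitened SNP design; fills only the model-relevant fields.

    ``raw_xa``/``raw_xh`` (pre-whitening dosages) are used for the
    monomorphic check; if omitted the whitened columns are checked instead.
    """
    if model not in ("A", "D", "AD"):
        raise ValueError(f"unknown model {model!r}")
    need_a = model in ("A", "AD")
    need_h = model in ("D", "AD")
    out = SnpAssociation(snp_id=snp_id)
    chk_a = raw_xa if raw_xa is not None else xa_w
    chk_h = raw_xh if raw_xh is not None else xh_w
    if (need_a and (chk_a is None or np.var(chk_a) < _MONO_TOL)) or (
        need_h and (chk_h is None or np.var(chk_h) < _MONO_TOL)
    ):
        out.flags = "monomorphic"
        out.n_used = yw.size
        out.beta_a = out.beta_d = out.t_add = out.t_dom = 0.0
        return out
    cols = [intercept_w]
    if need_a:
        cols.append(xa_w)
    if need_h:
        cols.append(xh_w)
    Xw = np.column_stack(cols)
    if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
        # two-genotype-class SNP: xh is collinear with (1, xa)
        out.flags = "ad_collinear"
        if model == "AD":
            sub = fit_snp(yw, intercept_w, xa_w, None, "A", snp_id, raw_xa=raw_xa)
            sub.flags = "ad_collinear"
            sub.p_AD = sub.p_A
            return sub
        out.n_used = yw.size
        out.beta_a = out.beta_d = out.t_add = out.t_dom = 0.0
        return out
    beta, se, rss, df = _ols(yw, Xw)
    _, _, rss0, _ = _ols(yw, intercept_w[:, None])
    out.n_used = yw.size
    out.rss, out.df_resid, out.k = rss, df, Xw.shape[1]
    j = 1
    if need_a:
        t = beta[j] / se[j] if se[j] > 0 else np.inf * np.sign(beta[j])
        out.beta_a, out.t_add = float(beta[j]), float(t)
        p = _t_pvalue(t, df)
        if model == "A":
            out.p_A = p
        j += 1
    if need_h:
        t = beta[j] / se[j] if se[j] > 0 else np.inf * np.sign(beta[j])
        out.beta_d, out.t_dom = float(beta[j]), float(t)
        p = _t_pvalue(t, df)
        if model == "D":
            out.p_D = p
        else:
            out.p_AvsAD = p  # 1-df dominance test within AD (F = t^2)
    if model == "AD":
        out.p_AD = _f_pvalue(rss0, rss, 2, df)
    return out


def anova_a_vs_ad(fit_A: SnpAssociation, fit_AD: SnpAssociation) -> float:
    """1-df F-test of the AD model against the nested A model."""
    if fit_A.n_used != fit_AD.n_used or fit_AD.k != fit_A.k + 1:
        raise ValueError("fits are not nested on the same samples")
    return _f_pvalue(fit_A.rss, fit_AD.rss, 1, fit_AD.df_resid)


# ---------------------------------------------------------------------------
# Vectorised genome scan
# ---------------------------------------------------------------------------


def _batched_scan(yw, base_w, Sa, Sh, need_a, need_h):
    """OLS over all SNPs at once for one model.

    base_w: (n, b) whitened base design; Sa/Sh: (n, m) whitened SNP columns.
    Returns dict of arrays over SNPs: beta/t per SNP column, rss, df.
    """
    n, b = base_w.shape
    m = Sa.shape[1] if Sa is not None else Sh.shape[1]
    cols = []
    if need_a:
        cols.append(Sa)
    if need_h:
        cols.append(Sh)
    s = len(cols)
    k = b + s
    BtB = base_w.T @ base_w  # (b, b)
    Bty = base_w.T @ yw  # (b,)
    yty = float(yw @ yw)
    XtX = np.empty((m, k, k))
    Xty = np.empty((m, k))
    XtX[:, :b, :b] = BtB
    Xty[:, :b] = Bty
    for i, Si in enumerate(cols):
        BtS = base_w.T @ Si  # (b, m)
        XtX[:, :b, b + i] = BtS.T
        XtX[:, b + i, :b] = BtS.T
        Xty[:, b + i] = Si.T @ yw
        for jj, Sj in enumerate(cols):
            XtX[:, b + i, b + jj] = np.einsum("ns,ns->s", Si, Sj)
    # rank-deficient designs (e.g. only two genotype classes, xh == xa up
    # to the intercept) are solved with the identity placeholder and
    # reported through the ``bad`` mask for the caller to handle
    eigs = np.linalg.eigvalsh(XtX)
    bad = eigs[:, 0] < 1e-9 * np.maximum(eigs[:, -1], 1e-300)
    XtX_safe = np.where(bad[:, None, None], np.eye(k)[None], XtX)
    beta = np.linalg.solve(XtX_safe, Xty[..., None])[..., 0]  # (m, k)
    rss = yty - np.einsum("mk,mk->m", beta, Xty)
    rss = np.clip(rss, 0.0, None)
    df = n - k
    sigma2 = rss / df
    inv = np.linalg.inv(XtX_safe)
    se = np.sqrt(np.clip(inv[:, np.arange(k), np.arange(k)] * sigma2[:, None], 0, None))
    se[se == 0] = np.inf
    return {"beta": beta, "se": se, "rss": rss, "df": df, "k": k, "b": b, "bad": bad}


def genome_scan(
    y: PhenotypeVector | np.ndarray,
    g: GenotypeMatrix,
    vc: VarianceComponents,
    grms: GrmPair,
    model: str = "AD",
    condition_snps: list[str] | None = None,
) -> pd.DataFrame:
    """Whitened mixed-model scan over all SNPs.

    Always fits the A, D and AD designs (they share the whitening and are
    cheap together); ``model`` selects which p-value column downstream
    callers treat as primary but all columns are returned.  Samples with a
    missing phenotype are dropped for the whole scan.  A per-SNP failure
    (monomorphic column) is flagged, never fatal.
    """
    yv = np.asarray(y.values if isinstance(y, PhenotypeVector) else y, dtype=float)
    if yv.size != g.n_samples:
        raise ValueError("phenotype does not align with genotype samples")
    keep = ~np.isnan(yv)
    idx = np.flatnonzero(keep)
    n = idx.size
    sub = g.subset_samples(idx) if n < g.n_samples else g
    yv = yv[keep]
    grms_sub = (
        grms
        if n == len(grms.samples)
        else GrmPair(
            samples=[grms.samples[i] for i in idx],
            K_a=grms.K_a[np.ix_(idx, idx)],
            K_d=grms.K_d[np.ix_(idx, idx)],
            n_snps_used=grms.n_snps_used,
        )
    )
    W = whitening_operator(vc, grms_sub).matrix

    Xa = encode_additive(sub)
    Xh = encode_heterozygote(sub)
    freqs = allele_frequencies(sub)
    mono_a = Xa.var(axis=0) < _MONO_TOL
    mono_h = Xh.var(axis=0) < _MONO_TOL

    yw = W @ yv
    ones_w = W @ np.ones(n)
    base_cols = [ones_w]
    if condition_snps:
        snp_index = {s.id: j for j, s in enumerate(sub.snps)}
        for cs in condition_snps:
            if cs not in snp_index:
                raise KeyError(f"conditioning SNP {cs!r} not in genotype matrix")
            j = snp_index[cs]
            for col, mono in ((Xa[:, j], mono_a[j]), (Xh[:, j], mono_h[j])):
                if mono:
                    warnings.warn(
                        f"conditioning column for {cs} is constant; dropped",
                        stacklevel=2,
                    )
                    continue
                base_cols.append(W @ col)
    base_w = np.column_stack(base_cols)
    # collinear conditioning columns: keep an orthonormal basis of the span
    # (only the span of the base design matters for the SNP tests)
    if base_w.shape[1] > 1:
        u, sv, _ = np.linalg.svd(base_w, full_matrices=False)
        ok = sv > 1e-10 * sv[0]
        if ok.sum() < base_w.shape[1]:
            warnings.warn("dropping collinear conditioning column(s)", stacklevel=2)
        base_w = u[:, ok]

    Sa = W @ Xa
    Sh = W @ Xh

    ok_ad = ~(mono_a | mono_h)
    ok_a = ~mono_a
    ok_d = ~mono_h
    m = sub.n_snps
    out = pd.DataFrame(
        {
            "snp_id": sub.snp_ids,
            "chrom": [s.chromosome for s in sub.snps],
            "pos": [s.position for s in sub.snps],
            "freq": freqs,
            "maf": [s.maf for s in sub.snps],
            "beta_a": 0.0,
            "beta_d": 0.0,
            "t_add": 0.0,
            "t_dom": 0.0,
            "p_A": 1.0,
            "p_D": 1.0,
            "p_AD": 1.0,
            "p_AvsAD": 1.0,
            "n_used": n,
            "flags": "",
        }
    )
    _, _, rss_null, _ = _ols(yw, base_w)

    b = base_w.shape[1]
    ta_A = np.zeros(m)
    beta_A = np.zeros(m)
    pA = np.ones(m)
    if ok_a.any():
        fa = _batched_scan(yw, base_w, Sa[:, ok_a], None, True, False)
        t = fa["beta"][:, b] / fa["se"][:, b]
        pa = 2.0 * stats.t.sf(np.abs(t), fa["df"])
        pa[fa["bad"]] = 1.0
        pA[ok_a] = pa
        ta_A[ok_a] = np.where(fa["bad"], 0.0, t)
        beta_A[ok_a] = np.where(fa["bad"], 0.0, fa["beta"][:, b])
        out.loc[ok_a, "p_A"] = pA[ok_a]
    if ok_d.any():
        fd = _batched_scan(yw, base_w, None, Sh[:, ok_d], False, True)
        t = fd["beta"][:, b] / fd["se"][:, b]
        pd_ = 2.0 * stats.t.sf(np.abs(t), fd["df"])
        pd_[fd["bad"]] = 1.0
        out.loc[ok_d, "p_D"] = pd_
    if ok_ad.any():
        fad = _batched_scan(yw, base_w, Sa[:, ok_ad], Sh[:, ok_ad], True, True)
        bad = fad["bad"]
        ta = fad["beta"][:, b] / fad["se"][:, b]
        td = fad["beta"][:, b + 1] / fad["se"][:, b + 1]
        df = fad["df"]
        p_avsad = 2.0 * stats.t.sf(np.abs(td), df)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = ((rss_null - fad["rss"]) / 2.0) / (fad["rss"] / df)
        p_ad = stats.f.sf(np.clip(np.nan_to_num(fstat), 0, None), 2, df)
        # rank-deficient AD design (two genotype classes): the AD span
        # equals the A span, so report the A-model fit with no dominance
        idx_ad = np.flatnonzero(ok_ad)
        out.loc[ok_ad, "beta_a"] = np.where(bad, beta_A[idx_ad], fad["beta"][:, b])
        out.loc[ok_ad, "beta_d"] = np.where(bad, 0.0, fad["beta"][:, b + 1])
        out.loc[ok_ad, "t_add"] = np.where(bad, ta_A[idx_ad], ta)
        out.loc[ok_ad, "t_dom"] = np.where(bad, 0.0, td)
        out.loc[ok_ad, "p_AvsAD"] = np.where(bad, 1.0, p_avsad)
        out.loc[ok_ad, "p_AD"] = np.where(bad, pA[idx_ad], p_ad)
        collinear = np.zeros(m, dtype=bool)
        collinear[idx_ad] = bad
        out.loc[collinear, "flags"] = "ad_collinear"
    out.loc[mono_a | mono_h, "flags"] = "monomorphic"
    return out


def conditional_scan(
    y: PhenotypeVector | np.ndarray,
    g: GenotypeMatrix,
    vc: VarianceComponents,
    grms: GrmPair,
    condition_snps: list[str],
    model: str = "AD",
) -> pd.DataFrame:
    """Genome scan with conditioning SNPs' dosages in the fixed effects."""
    return genome_scan(y, g, vc, grms, model=model, condition_snps=list(condition_snps))
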