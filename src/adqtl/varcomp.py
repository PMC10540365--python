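"""Two-component REML: additive, dominance and environmental variances.

The model is ``y ~ N(X beta, V)`` with ``V = K_a sa2 + K_d sd2 + I se2``.
Estimation is average-information (AI) REML with an EM first step and EM
fallback whenever an AI update leaves the feasible region or decreases the
restricted likelihood; components are constrained non-negative.  On a
phenotype standardised to unit variance the components are directly the
additive and dominance heritabilities (V_a, V_d).

Also provides the classical single-locus variance partition used to
aggregate the variance explained by peak SNPs at called QTLs:
``V_A = 2pq [a + d(q - p)]^2`` and ``V_D = (2pq d)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .genotype_io import PhenotypeVector
from .relatedness import GrmPair

__all__ = [
    "VarianceComponents",
    "reml_fit",
    "single_locus_partition",
    "qtl_variance_aggregate",
]


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_d2: float
    sigma_e2: float
    se_a: float
    se_d: float
    se_e: float
    loglik: float
    converged: bool
    n_iter: int
    n: int = 0

    def near_boundary(self, floor: float = 0.05) -> bool:
        """Flag traits where either genetic component is below ``floor``
        (mirrors the V_d > 0.05 reporting filter)."""
        return self.sigma_a2 < floor or self.sigma_d2 < floor


def _chol_or_clip(V: np.ndarray):
    """Cholesky of V, clipping eigenvalues if V is numerically non-PSD."""
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(V)
        floor = 1e-10 * max(w.max(), 1.0)
        w = np.clip(w, floor, None)
        return np.linalg.cholesky((U * w) @ U.T)


def _reml_loglik_parts(theta, Ks, X, y):
    """Return (loglik, P y, P, trace terms) for current components."""
    n = y.size
    V = sum(t * K for t, K in zip(theta, Ks))
    L = _chol_or_clip(V)
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Linv = solve_triangular(L, np.eye(n), lower=True)
    Vinv = Linv.T @ Linv
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^-1 X not positive definite")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, Py, P


def reml_fit(
    y: PhenotypeVector | np.ndarray,
    grms: GrmPair,
    fixed: np.ndarray | None = None,
    include_dominance: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> VarianceComponents:
    """AI-REML estimates of (sigma_a2, sigma_d2, sigma_e2).

    ``fixed`` is the fixed-effect design (default: intercept only).  Samples
    with a missing phenotype are dropped, together with the matching GRM
    rows/columns.  With ``include_dominance=False`` the dominance component
    is omitted (single-GRM GREML) and reported as exactly 0 with SE 0.
    """
    if isinstance(y, PhenotypeVector):
        yv = np.asarray(y.values, dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    n_total = yv.size
    if n_total != len(grms.samples):
        raise ValueError("phenotype length does not match GRM samples")
    keep = ~np.isnan(yv)
    yv = yv[keep]
    n = yv.size
    if n < 3:
        raise ValueError(f"need at least 3 phenotyped samples, got {n}")
    idx = np.flatnonzero(keep)
    Ka = grms.K_a[np.ix_(idx, idx)]
    Kd = grms.K_d[np.ix_(idx, idx)]
    if fixed is None:
        X = np.ones((n_total, 1))
    else:
        X = np.atleast_2d(np.asarray(fixed, dtype=float))
        if X.shape[0] != n_total:
            raise ValueError("fixed-effect design does not align with samples")
    X = X[keep]

    names = ["a", "d", "e"] if include_dominance else ["a", "e"]
    Ks = [Ka, Kd, np.eye(n)] if include_dominance else [Ka, np.eye(n)]
    k = len(Ks)
    vary = float(np.var(yv))
    if vary == 0:
        raise ValueError("phenotype is constant")
    floor = 1e-8 * vary
    theta = np.full(k, vary / 3.0)
    if not include_dominance:
        theta = np.full(k, vary / 2.0)

    ll, Py, P = _reml_loglik_parts(theta, Ks, X, yv)
    converged = False
    AI = np.eye(k)
    it = 0
    for it in range(1, max_iter + 1):
        # score and AI matrix at the current point
        KPy = [K @ Py for K in Ks]
        trPK = np.array([float(np.sum(P * K)) for K in Ks])  # tr(P K), K symmetric
        quad = np.array([float(Py @ t) for t in KPy])  # y'P K P y
        score = -0.5 * (trPK - quad)
        PKPy = [P @ t for t in KPy]
        AI = 0.5 * np.array([[float(KPy[i] @ PKPy[j]) for j in range(k)] for i in range(k)])

        em = np.maximum(theta + theta**2 * (quad - trPK) / n, floor)
        if it == 1:
            candidates = [em]  # EM warm-up step
        else:
            # active-set AI step: components pinned at the floor whose score
            # still points outward stay fixed; the AI system is solved on
            # the free components only
            pinned = (theta <= floor * 1.01) & (score < 0)
            free = np.flatnonzero(~pinned)
            step = np.zeros(k)
            if free.size:
                sub = AI[np.ix_(free, free)]
                try:
                    step[free] = np.linalg.solve(sub, score[free])
                except np.linalg.LinAlgError:
                    step[free] = np.linalg.pinv(sub) @ score[free]
            # projected full step, then halved steps, then EM as last resort
            candidates = [
                np.maximum(theta + h * step, floor) for h in (1.0, 0.5, 0.25, 0.1)
            ] + [em]
        ll_new = -np.inf
        for new in candidates:
            try:
                cand_ll, cand_Py, cand_P = _reml_loglik_parts(new, Ks, X, yv)
            except np.linalg.LinAlgError:
                continue
            if cand_ll >= ll - 1e-10 or new is candidates[-1]:
                ll_new, Py_new, P_new = cand_ll, cand_Py, cand_P
                break
        if ll_new == -np.inf:
            break  # every candidate failed numerically; report non-convergence
        delta = abs(ll_new - ll)
        theta, ll, Py, P = new, ll_new, Py_new, P_new
        if delta < tol:
            converged = True
            break

    # standard errors from the inverse AI matrix at the optimum
    KPy = [K @ Py for K in Ks]
    PKPy = [P @ t for t in KPy]
    AI = 0.5 * np.array([[float(KPy[i] @ PKPy[j]) for j in range(k)] for i in range(k)])
    try:
        cov = np.linalg.inv(AI)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(k, np.nan)

    vals = dict(zip(names, theta))
    errs = dict(zip(names, ses))
    return VarianceComponents(
        sigma_a2=float(vals["a"]),
        sigma_d2=float(vals.get("d", 0.0)),
        sigma_e2=float(vals["e"]),
        se_a=float(errs["a"]),
        se_d=float(errs.get("d", 0.0)),
        se_e=float(errs["e"]),
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        n=n,
    )


def single_locus_partition(a: float, d: float, p: float) -> tuple[float, float]:
    """Classical one-locus partition at counted-allele frequency ``p``:
    V_A = 2pq [a + d(q-p)]^2, V_D = (2pq d)^2."""
    if not 0 < p < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    q = 1.0 - p
    va = 2.0 * p * q * (a + d * (q - p)) ** 2
    vd = (2.0 * p * q * d) ** 2
    return va, vd


def qtl_variance_aggregate(
    peaks: Iterable[Sequence[float]],
) -> tuple[float, float]:
    """Sum the single-locus (V_A, V_D) over peak SNPs.

    ``peaks`` yields (beta_a, beta_d, freq) triples; on a unit-variance trait
    the sums estimate the total additive and dominance variance explained by
    the called QTLs.
    """
    va_tot = vd_tot = 0.0
    for beta_a, beta_d, freq in peaks:
        va, vd = single_locus_partition(beta_a, beta_d, freq)
        va_tot += va
        vd_tot += vd
    return va_tot, vd_tot
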