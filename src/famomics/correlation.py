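"""Cross-omic correlation: phenotypic Fisher-Z screen and bivariate
variance-components genetic correlations.

The phenotypic screen computes all Pearson correlations between two
feature sets (e.g. expression probes x CpG sites) with asymptotic
p-values from the Fisher Z transformation, z = atanh(r), where
z*sqrt(n-3) is standard normal under the null, and flags pairs passing
Bonferroni correction over the full grid.

The bivariate model extends the univariate Vg/Vc/Ve decomposition to two
traits: the cross-trait covariance is
rho_g*sqrt(Vg1*Vg2)*A + rho_c*sqrt(Vc1*Vc2)*H + rho_e*sqrt(Ve1*Ve2)*I,
and rho_g (the genetic correlation) is tested against zero by a df=1
likelihood ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .varcomp import (
    BlockStructure,
    _as_matrix,
    _inv_softplus,
    _softplus,
    _VE_FLOOR_REL,
    block_structure,
    fit_full,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "ScreenResult",
    "BivariateFit",
    "fisher_z_pvalue",
    "bonferroni",
    "phenotypic_screen",
    "genetic_correlation",
]

_RHO_MAX = 0.999999  # |rho| pin keeping the 2n x 2n covariance PSD


@dataclass
class CorrelationResult:
    feature_a: str
    feature_b: str
    r: float
    z: float
    p: float
    passes_bonferroni: bool


@dataclass
class ScreenResult:
    """Materialized significant pairs plus exact whole-grid bookkeeping."""

    pairs: pd.DataFrame
    m_total: int
    bonferroni_threshold: float
    n_significant: int
    n_missing: int
    n_subjects: int


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def fisher_z_pvalue(r, n: int):
    """Two-sided asymptotic p-value for a Pearson correlation.

    z = atanh(r); under no correlation z*sqrt(n-3) ~ N(0, 1).  |r| = 1
    maps to p = 0 (the limit of the formula).
    """
    if n < 4:
        raise ValueError("Fisher-Z p-value needs n >= 4")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    p = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(n - 3))
    return z, p


def phenotypic_screen(
    set_a,
    set_b,
    alpha: float = 0.05,
    *,
    chunk: int = 512,
    report_threshold: float | None = None,
) -> ScreenResult:
    """All pairwise Pearson correlations between two feature sets.

    Both sets must share subjects (rows).  The Bonferroni denominator is
    the full |A| x |B| grid, including pairs involving zero-variance
    features (reported with missing r and never significant).  The grid
    is streamed in column chunks of ``set_a``; only pairs with
    p <= ``report_threshold`` (default: the Bonferroni threshold) are
    materialized, while exact counts cover all pairs.
    """
    from .preprocess import as_values_frame

    va = as_values_frame(set_a)
    vb = as_values_frame(set_b)
    if not va.index.equals(vb.index):
        raise ValueError("the two sets must be over the same subjects, in order")
    n = len(va)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    m_total = va.shape[1] * vb.shape[1]
    thr = bonferroni(alpha, m_total)
    report_thr = thr if report_threshold is None else report_threshold

    Xa = va.to_numpy(dtype=float)
    Xb = vb.to_numpy(dtype=float)
    Za, sa = _standardize(Xa)
    Zb, sb = _standardize(Xb)
    n_missing = int((~sa).sum() * vb.shape[1] + sa.sum() * (~sb).sum())

    crit_z = stats.norm.isf(report_thr / 2.0) / np.sqrt(n - 3)
    crit_r = np.tanh(crit_z)  # |r| needed to reach the report threshold
    sig_z = stats.norm.isf(thr / 2.0) / np.sqrt(n - 3)
    sig_r = np.tanh(sig_z)

    rows = []
    n_significant = 0
    a_ids = list(va.columns)
    b_ids = np.array(vb.columns)
    for start in range(0, Za.shape[1], chunk):
        block = Za[:, start : start + chunk]
        R = block.T @ Zb  # (chunk, mB)
        R[~sa[start : start + chunk], :] = np.nan
        R[:, ~sb] = np.nan
        with np.errstate(invalid="ignore"):
            n_significant += int((np.abs(R) >= sig_r).sum())
            hit_i, hit_j = np.nonzero(np.abs(R) >= crit_r)
        for i, j in zip(hit_i, hit_j):
            r = float(np.clip(R[i, j], -1.0, 1.0))
            z, p = fisher_z_pvalue(r, n)
            rows.append(
                {
                    "feature_a": a_ids[start + i],
                    "feature_b": b_ids[j],
                    "r": r,
                    "z": float(z),
                    "p": float(p),
                    "passes_bonferroni": bool(p <= thr),
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["feature_a", "feature_b", "r", "z", "p", "passes_bonferroni"]
    )
    return ScreenResult(
        pairs=pairs,
        m_total=m_total,
        bonferroni_threshold=thr,
        n_significant=n_significant,
        n_missing=n_missing,
        n_subjects=n,
    )


def _standardize(X: np.ndarray):
    """Center and unit-norm columns; returns (Z, valid mask)."""
    Xc = X - X.mean(axis=0)
    norm = np.sqrt((Xc**2).sum(axis=0))
    ok = norm > 0
    Z = np.zeros_like(Xc)
    Z[:, ok] = Xc[:, ok] / norm[ok]
    return Z, ok


# ---------------------------------------------------------------------------
# bivariate variance components
# ---------------------------------------------------------------------------


@dataclass
class BivariateFit:
    vg1: float
    vc1: float
    ve1: float
    vg2: float
    vc2: float
    ve2: float
    rho_g: float
    rho_c: float
    rho_e: float
    mu1: float
    mu2: float
    loglik: float
    lrt_rho_g: float
    p_rho_g: float
    converged: bool
    rho_g_defined: bool
    reason: str = ""


class _BivariateLikelihood:
    """Profiled (over both means) bivariate Gaussian likelihood on family
    blocks; block vectors are ordered [trait1 members, trait2 members]."""

    def __init__(self, y1: np.ndarray, y2: np.ndarray, blocks: BlockStructure):
        self.blocks = blocks
        self.n = blocks.n
        self._y = []
        for idx, _, _ in blocks.groups:
            yb = np.concatenate([y1[idx], y2[idx]], axis=1)  # (m, 2k)
            self._y.append(yb)

    def loglik(self, v, rho):
        vg1, vc1, ve1, vg2, vc2, ve2 = v
        rg, rc, re = rho
        cg = rg * np.sqrt(vg1 * vg2)
        cc = rc * np.sqrt(vc1 * vc2)
        ce = re * np.sqrt(ve1 * ve2)
        logdet = 0.0
        yy = 0.0
        b = np.zeros(2)
        M = np.zeros((2, 2))
        for (idx, A, H), yb in zip(self.blocks.groups, self._y):
            m, k = idx.shape
            I = np.eye(k)
            Sig = np.empty((m, 2 * k, 2 * k))
            Sig[:, :k, :k] = vg1 * A + vc1 * H + ve1 * I
            Sig[:, k:, k:] = vg2 * A + vc2 * H + ve2 * I
            cross = cg * A + cc * H + ce * I
            Sig[:, :k, k:] = cross
            Sig[:, k:, :k] = np.transpose(cross, (0, 2, 1))
            try:
                L = np.linalg.cholesky(Sig)
            except np.linalg.LinAlgError:
                return -np.inf, (np.nan, np.nan)
            x1 = np.concatenate([np.ones(k), np.zeros(k)])
            x2 = np.concatenate([np.zeros(k), np.ones(k)])
            rhs = np.empty((m, 2 * k, 3))
            rhs[..., 0] = yb
            rhs[..., 1] = x1
            rhs[..., 2] = x2
            z = np.linalg.solve(L, rhs)
            logdet += 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
            zy, z1, z2 = z[..., 0], z[..., 1], z[..., 2]
            yy += float((zy * zy).sum())
            b += [float((zy * z1).sum()), float((zy * z2).sum())]
            M += [
                [float((z1 * z1).sum()), float((z1 * z2).sum())],
                [float((z1 * z2).sum()), float((z2 * z2).sum())],
            ]
        mu = np.linalg.solve(M, b)
        quad = yy - b @ mu
        ll = -0.5 * (2 * self.n * np.log(2.0 * np.pi) + logdet + quad)
        return ll, (float(mu[0]), float(mu[1]))


def _fit_bivariate(lik, s1, s2, fix_rho_g: bool):
    """Maximize over 6 variances (softplus scale) and 2-3 correlations
    (tanh scale, |rho| pinned below 1)."""
    floors = (_VE_FLOOR_REL * s1, _VE_FLOOR_REL * s2)
    n_rho = 2 if fix_rho_g else 3

    def unpack(x):
        v = (
            s1 * _softplus(x[0]),
            s1 * _softplus(x[1]),
            floors[0] + s1 * _softplus(x[2]),
            s2 * _softplus(x[3]),
            s2 * _softplus(x[4]),
            floors[1] + s2 * _softplus(x[5]),
        )
        rhos = _RHO_MAX * np.tanh(x[6 : 6 + n_rho])
        if fix_rho_g:
            rho = (0.0, rhos[0], rhos[1])
        else:
            rho = tuple(rhos)
        return v, rho

    def nll(x):
        ll, _ = lik.loglik(*unpack(x))
        return 1e10 if not np.isfinite(ll) else -ll

    base = [
        _inv_softplus(1 / 3),
        _inv_softplus(1 / 3),
        _inv_softplus(1 / 3),
    ] * 2
    best = None
    any_success = False
    for r0 in (0.0, 0.5, -0.5):
        x0 = np.array(base + [np.arctanh(r0 / _RHO_MAX) if r0 else 0.0] * n_rho)
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or bool(res.success)
    v, rho = unpack(best.x)
    ll, mu = lik.loglik(v, rho)
    return v, rho, mu, ll, any_success


def genetic_correlation(y1, y2, A, H, blocks: BlockStructure | None = None) -> BivariateFit:
    """Bivariate ML fit of two traits sharing the family structure.

    Returns component estimates per trait, the three cross-trait
    correlations, and a df=1 LRT of rho_g = 0.  When either trait carries
    (numerically) no genetic variance the genetic correlation is
    undefined: the fit is flagged, not raised.  Non-convergence is
    likewise reported through ``converged``/``reason``.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("traits must cover the same subjects")
    s1, s2 = float(np.var(y1)), float(np.var(y2))
    if s1 <= 0 or s2 <= 0:
        return BivariateFit(
            *(0.0,) * 6, np.nan, np.nan, np.nan, float(np.mean(y1)), float(np.mean(y2)),
            -np.inf, 0.0, 1.0, False, False, reason="zero-variance trait",
        )
    if blocks is None:
        blocks = block_structure(A, H)
    lik = _BivariateLikelihood(y1, y2, blocks)
    v, rho, mu, ll, ok = _fit_bivariate(lik, s1, s2, fix_rho_g=False)
    v0, rho0, _, ll0, ok0 = _fit_bivariate(lik, s1, s2, fix_rho_g=True)
    lrt = max(2.0 * (ll - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, 1))
    tol1, tol2 = 1e-6 * s1, 1e-6 * s2
    rho_g_defined = v[0] > tol1 and v[3] > tol2
    rho_g = rho[0] if rho_g_defined else np.nan
    reason = ""
    if not ok:
        reason = "optimizer did not converge"
    elif not rho_g_defined:
        reason = "no genetic variance in at least one trait"
    return BivariateFit(
        vg1=v[0], vc1=v[1], ve1=v[2], vg2=v[3], vc2=v[4], ve2=v[5],
        rho_g=rho_g if ok else np.nan,
        rho_c=rho[1], rho_e=rho[2], mu1=mu[0], mu2=mu[1],
        loglik=ll, lrt_rho_g=float(lrt), p_rho_g=p,
        converged=bool(ok and ok0), rho_g_defined=bool(rho_g_defined),
        reason=reason,
    )
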